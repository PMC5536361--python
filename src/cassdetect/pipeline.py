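"""End-to-end detection pipeline and parameter sweeps.

``detect`` ties the stages together: scale-dependent gradient, surface
diagnostics, the chosen suppression model (static SS, static CASS, or the
dynamic CASS iteration), then non-maximum suppression along the original
gradient orientation and quantile hysteresis.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from pathlib import Path

import numpy as np

from .adaptive import adaptive_suppression, cass_operator
from .config import RunConfig
from .dynamics import run_dsm
from .evaluation import evaluate
from .filters import build_distance_weights, halfwave_suppress, scale_gradient, suppression_term
from .image import ImageField, as_pixels, load_image, save_image
from .postprocess import EdgeMap, hysteresis, nonmax_suppress
from .surface import diagnostics

__all__ = ["compute_response", "detect", "detect_array", "sweep"]

logger = logging.getLogger(__name__)


def compute_response(image, config: RunConfig):
    """Run the suppression stage only; returns (response, gradient, info)."""
    px = as_pixels(image)
    t0 = time.perf_counter()
    grad = scale_gradient(px, config.sigma)
    kernels = build_distance_weights(config.sigma)
    info: dict = {}
    if config.model == "ss":
        s = suppression_term(grad, kernels)
        response = halfwave_suppress(grad.magnitude, s, config.alpha)
    else:
        diag = diagnostics(px, grad, h=config.h, sigma_m=config.sigma_m)
        info["sigma_m"] = diag.sigma_m
        if config.model == "cass":
            s_a = adaptive_suppression(grad, diag, kernels, config.Thr)
            response = cass_operator(grad.magnitude, s_a, config.alpha)
        else:  # cass-dsm
            state = run_dsm(
                px,
                sigma=config.sigma,
                alpha=config.alpha,
                Thr=config.Thr,
                h=config.h,
                sigma_m=config.sigma_m,
                max_iters=config.max_iters,
                eps_rel=config.eps_rel,
                stop_fraction=config.stop_fraction,
                precomputed=(grad, diag, kernels),
                full_output=True,
            )
            response = state.E
            info["iterations"] = state.t
            info["stopped_by"] = state.history[-1].get("stopped_by")
            info["active_fraction"] = state.active_fraction
    info["suppression_seconds"] = round(time.perf_counter() - t0, 4)
    return response, grad, info


def detect_array(image, config: RunConfig) -> EdgeMap:
    """Detect contours in an in-memory image; returns a binary EdgeMap."""
    response, grad, info = compute_response(image, config)
    thinned = nonmax_suppress(response, grad.orientation)
    prov = {"config": config.to_dict(), **info}
    return hysteresis(thinned, config.p, provenance=prov)


def detect(config: RunConfig) -> EdgeMap:
    """Run detection per the config, reading/writing files when paths are set.

    Writes the edge map as an 8-bit PNG and a JSON provenance sidecar
    (full config plus termination info) next to it.
    """
    if config.input_path is None:
        raise ValueError("config.input_path is required for detect()")
    image = load_image(config.input_path)
    edge_map = detect_array(image, config)
    if config.output_path is not None:
        out = Path(config.output_path)
        save_image(out, edge_map.pixels)
        sidecar = out.with_suffix(out.suffix + ".json")
        sidecar.write_text(json.dumps(edge_map.provenance, indent=2, default=str))
        logger.info("wrote %s and %s", out, sidecar)
    return edge_map


def sweep(
    scenes,
    base_config: RunConfig,
    *,
    sigma_grid=None,
    p_grid=None,
    csv_path=None,
) -> list[dict]:
    """Detect + evaluate over a parameter grid on (image, ground-truth) pairs.

    ``scenes`` is a sequence of ``(image, gt)`` or ``(image, gt, spec)``
    tuples.  The suppression stage is computed once per (image, sigma) and
    reused across the ``p`` grid, which only changes the thresholds.
    Returns one row per (sigma, p, image); cell failures are logged and
    skipped.
    """
    sigma_grid = list(sigma_grid) if sigma_grid is not None else [base_config.sigma]
    p_grid = list(p_grid) if p_grid is not None else [base_config.p]
    rows = []
    for sigma in sigma_grid:
        for idx, scene in enumerate(scenes):
            image, gt = scene[0], scene[1]
            try:
                cfg_sigma = base_config.replace(sigma=float(sigma))
                response, grad, _ = compute_response(image, cfg_sigma)
                thinned = nonmax_suppress(response, grad.orientation)
            except Exception:  # noqa: BLE001 -- keep the sweep alive
                logger.exception("sweep cell failed: sigma=%s image=%d", sigma, idx)
                continue
            for p in p_grid:
                try:
                    em = hysteresis(thinned, float(p))
                    res = evaluate(em, gt, tolerance=base_config.tolerance)
                except Exception:  # noqa: BLE001
                    logger.exception(
                        "sweep cell failed: sigma=%s p=%s image=%d", sigma, p, idx
                    )
                    continue
                rows.append(
                    {
                        "sigma": float(sigma), "p": float(p), "image": idx,
                        "P": res.P, "e_fn": res.e_fn, "e_fp": res.e_fp,
                        "n_correct": res.n_correct,
                        "n_false_pos": res.n_false_pos,
                        "n_false_neg": res.n_false_neg,
                    }
                )
    if csv_path is not None and rows:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return rows
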