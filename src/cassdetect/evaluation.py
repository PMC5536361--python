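"""Contour-detection performance metrics against ground truth.

With ``D`` the detected and ``GT`` the ground-truth contour pixel sets,
the correctly detected set is ``E = D ∩ GT``, the misses
``E_FN = GT \\ D`` and the spurious detections ``E_FP = D \\ GT``; then

    P     = |E| / (|E| + |E_FP| + |E_FN|)
    e_fn  = |E_FN| / |GT|
    e_fp  = |E_FP| / |E|

``P`` is 1 iff the two sets coincide; ``e_fp`` is unbounded above.  A
matching tolerance ``d > 0`` relaxes the intersection: detected and
ground-truth pixels within Chebyshev distance ``d`` are paired greedily
one-to-one, nearest pairs first, so the set identities
``|E| + |E_FN| = |GT|`` and ``|E| + |E_FP| = |D|`` still hold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import InvalidInputError
from .postprocess import EdgeMap

__all__ = ["EvalResult", "evaluate", "evaluate_batch"]


@dataclass(frozen=True)
class EvalResult:
    """Counts and rates of a detected-vs-ground-truth comparison.

    ``e_fn`` is NaN when the ground truth is empty; ``e_fp`` is +inf when
    there are spurious detections but no correct ones.
    """

    n_correct: int
    n_false_neg: int
    n_false_pos: int
    n_gt: int
    P: float
    e_fn: float
    e_fp: float
    tolerance: int

    @property
    def n_detected(self) -> int:
        return self.n_correct + self.n_false_pos


def _as_bool(m) -> np.ndarray:
    if isinstance(m, EdgeMap):
        return m.pixels
    return np.asarray(m).astype(bool)


def _match_tolerant(det_xy: np.ndarray, gt_xy: np.ndarray, tol: int) -> int:
    """Greedy one-to-one nearest-first matching under Chebyshev distance."""
    if det_xy.shape[0] == 0 or gt_xy.shape[0] == 0:
        return 0
    tree = cKDTree(gt_xy)
    pairs = tree.query_ball_point(det_xy, r=tol, p=np.inf)
    cands = []
    for di, gts in enumerate(pairs):
        for gi in gts:
            dist = np.max(np.abs(det_xy[di] - gt_xy[gi]))
            cands.append((dist, di, gi))
    cands.sort()
    used_d = np.zeros(det_xy.shape[0], dtype=bool)
    used_g = np.zeros(gt_xy.shape[0], dtype=bool)
    n = 0
    for _, di, gi in cands:
        if not used_d[di] and not used_g[gi]:
            used_d[di] = used_g[gi] = True
            n += 1
    return n


def evaluate(detected, ground_truth, tolerance: int = 0) -> EvalResult:
    """Score a detected contour map against ground truth.

    Parameters
    ----------
    detected, ground_truth : EdgeMap or boolean array
        Same shape.
    tolerance : int
        Matching radius in pixels (Chebyshev).  0 means strict per-pixel
        set comparison.
    """
    D = _as_bool(detected)
    G = _as_bool(ground_truth)
    if D.shape != G.shape:
        raise InvalidInputError(f"shape mismatch {D.shape} vs {G.shape}")
    if tolerance < 0:
        raise InvalidInputError("tolerance must be >= 0")
    n_gt = int(G.sum())
    n_det = int(D.sum())
    if tolerance == 0:
        n_correct = int((D & G).sum())
    else:
        det_xy = np.argwhere(D)
        gt_xy = np.argwhere(G)
        n_correct = _match_tolerant(det_xy, gt_xy, tolerance)
    n_fn = n_gt - n_correct
    n_fp = n_det - n_correct
    denom = n_correct + n_fp + n_fn
    P = n_correct / denom if denom > 0 else 1.0  # both sets empty: perfect
    e_fn = n_fn / n_gt if n_gt > 0 else float("nan")
    if n_correct > 0:
        e_fp = n_fp / n_correct
    else:
        e_fp = float("inf") if n_fp > 0 else 0.0
    return EvalResult(
        n_correct=n_correct, n_false_neg=n_fn, n_false_pos=n_fp, n_gt=n_gt,
        P=P, e_fn=e_fn, e_fp=e_fp, tolerance=int(tolerance),
    )


def evaluate_batch(pairs, tolerance: int = 0) -> dict:
    """Evaluate a sequence of (detected, ground_truth) pairs.

    Returns per-image results plus the mean and variance of P, e_fn, e_fp
    over images where they are finite (the protocol used for corpus-level
    comparison).
    """
    results = [evaluate(d, g, tolerance) for d, g in pairs]
    summary = {"n_images": len(results), "results": results}
    for name in ("P", "e_fn", "e_fp"):
        vals = np.array([getattr(r, name) for r in results], dtype=float)
        finite = vals[np.isfinite(vals)]
        summary[f"mean_{name}"] = float(finite.mean()) if finite.size else float("nan")
        summary[f"var_{name}"] = float(finite.var()) if finite.size else float("nan")
    return summary
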