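"""Non-maximum suppression and quantile-parameterized hysteresis tracing.

The final response map is thinned to local maxima along the gradient
direction, then binarized by double-threshold hysteresis.  The high
threshold is the empirical ``(1 - p)`` quantile of the positive thinned
responses — a larger quantile parameter ``p`` admits more contour pixels —
and the low threshold is half the high one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
from scipy import ndimage

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = ["EdgeMap", "nonmax_suppress", "hysteresis"]

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class EdgeMap:
    """Binary contour raster with the parameters that produced it."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


def nonmax_suppress(response: np.ndarray, orientation: np.ndarray) -> np.ndarray:
    """Keep pixels that are maximal along their gradient direction.

    The two neighbor responses at unit distance along ``+/-(cos, sin)`` of
    the orientation are linearly interpolated between the adjacent
    8-neighbors.  A pixel survives iff its response is ``>=`` the forward
    neighbor and ``>`` the backward one; an exact two-pixel tie across an
    ideal step therefore keeps a single 1-px ridge.  Full plateaus (both
    neighbors equal to the pixel) are kept, so a constant response field
    survives everywhere.  Borders are edge-replicated.
    """
    R = np.asarray(response, dtype=np.float64)
    theta = np.asarray(orientation, dtype=np.float64)
    if R.shape != theta.shape:
        raise InvalidInputError("response/orientation shape mismatch")
    c, s = np.cos(theta), np.sin(theta)
    ac, as_ = np.abs(c), np.abs(s)
    horiz = ac >= as_
    t = np.where(horiz, as_ / np.maximum(ac, 1e-300), ac / np.maximum(as_, 1e-300))
    sgnc = np.where(c >= 0, 1, -1)
    sgns = np.where(s >= 0, 1, -1)
    # primary step: along the dominant axis; diagonal blend partner
    dx1 = np.where(horiz, sgnc, 0)
    dy1 = np.where(horiz, 0, sgns)
    dx2, dy2 = sgnc, sgns

    P = np.pad(R, 1, mode="edge")
    yy, xx = np.indices(R.shape)

    def sample(dx, dy):
        return P[yy + 1 + dy, xx + 1 + dx]

    fwd = (1.0 - t) * sample(dx1, dy1) + t * sample(dx2, dy2)
    bwd = (1.0 - t) * sample(-dx1, -dy1) + t * sample(-dx2, -dy2)
    keep = (R >= fwd) & ((R > bwd) | (fwd == bwd))
    return np.where(keep, R, 0.0)


def hysteresis(
    response: np.ndarray,
    p: float,
    *,
    low_factor: float = 0.5,
    provenance: dict | None = None,
) -> EdgeMap:
    """Double-threshold hysteresis tracing on a thinned response map.

    ``t_high`` is the ``(1 - p)`` empirical quantile of the strictly
    positive responses, ``t_low = low_factor * t_high``.  8-connected
    components of pixels ``>= t_low`` are kept iff they contain a pixel
    ``>= t_high``.
    """
    if not 0.0 < p < 1.0:
        raise InvalidParameterError(f"quantile p must be in (0, 1), got {p}")
    if not 0.0 < low_factor <= 1.0:
        raise InvalidParameterError(f"low_factor must be in (0, 1], got {low_factor}")
    R = np.asarray(response, dtype=np.float64)
    pos = R[R > 0]
    prov = dict(provenance or {})
    prov.update({"p": p, "low_factor": low_factor})
    if pos.size == 0:
        logger.warning("hysteresis: no positive responses, returning empty edge map")
        prov.update({"t_high": None, "t_low": None})
        return EdgeMap(np.zeros(R.shape, dtype=bool), prov)
    t_high = float(np.quantile(pos, 1.0 - p))
    t_low = low_factor * t_high
    weak = R >= t_low
    labels, n = ndimage.label(weak, structure=_EIGHT)
    if n == 0:
        return EdgeMap(np.zeros(R.shape, dtype=bool), {**prov, "t_high": t_high, "t_low": t_low})
    strong_labels = np.unique(labels[R >= t_high])
    strong_labels = strong_labels[strong_labels > 0]
    out = np.isin(labels, strong_labels)
    prov.update({"t_high": t_high, "t_low": t_low})
    return EdgeMap(out, prov)
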