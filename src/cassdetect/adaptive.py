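"""Context-adaptive surround suppression (CASS).

Near a detected jump (``diff > Thr``) the annular surround is split by the
local edge into an inhibitory half ``w_i`` — the side whose one-sided WRMS
is larger, i.e. the side the jump sits on — and an excitatory half
``w_e = w - w_i``.  The adaptive suppression term is then

* ``s_a = w_t * s``            where ``diff <= Thr`` (no jump nearby:
  classical suppression, damped by the homogeneity weight), and
* ``s_a = s_i - s_e``          where ``diff > Thr`` (suppression from the
  jump side minus facilitation from the smooth side; may be negative).

The operator ``E = H(M - alpha * s_a)`` therefore inhibits texture more
strongly than classical SS while weakening — or reversing — suppression at
object contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError, InvalidParameterError
from .filters import GradientField, SuppressionKernels, suppression_term
from .surface import SurfaceDiagnostics

__all__ = [
    "AdaptiveWeights",
    "adaptive_weights",
    "inhibitory_suppression_term",
    "adaptive_suppression",
    "cass_operator",
]


@dataclass(frozen=True)
class AdaptiveWeights:
    """Inhibitory/excitatory split of the distance-weight stencil.

    ``w_i + w_e`` equals the full stencil exactly; ``w_i`` is supported on
    the closed half-plane of side ``k`` (oriented by the gradient angle),
    intersected with the annulus.
    """

    w_i: np.ndarray
    w_e: np.ndarray
    k: int
    orientation: float


def adaptive_weights(kernels: SuppressionKernels, orientation: float, k: int) -> AdaptiveWeights:
    """Split the stencil into inhibitory and excitatory halves.

    Parameters
    ----------
    kernels : SuppressionKernels
    orientation : float
        Local gradient orientation in radians.  Not reduced mod pi: adding
        pi flips which offsets fall on side ``k``.
    k : int
        Which side (1 or 2) is inhibitory — the side with the larger
        one-sided WRMS.  Side 1 is the closed half-plane
        ``du*cos + dv*sin >= 0`` (ties to side 1), side 2 its complement.
    """
    if k not in (1, 2):
        raise InvalidParameterError(f"side index k must be 1 or 2, got {k}")
    r = kernels.support_radius
    offs = np.arange(-r, r + 1, dtype=np.float64)
    uu, vv = np.meshgrid(offs, offs)
    proj = uu * np.cos(orientation) + vv * np.sin(orientation)
    in_ck = proj >= 0 if k == 1 else proj < 0
    w_i = np.where(in_ck, kernels.w, 0.0)
    return AdaptiveWeights(w_i=w_i, w_e=kernels.w - w_i, k=k, orientation=float(orientation))


def inhibitory_suppression_term(
    grad_like: GradientField,
    kernels: SuppressionKernels,
    k: np.ndarray,
) -> np.ndarray:
    """Suppression term restricted per-pixel to the inhibitory half-plane.

    Like :func:`cassdetect.filters.suppression_term` but each pixel only
    sums stencil offsets lying on its own side ``k`` of the line
    perpendicular to its gradient orientation.
    """
    M, theta = grad_like.magnitude, grad_like.orientation
    if M.shape != np.asarray(k).shape:
        raise InvalidInputError("side-index grid shape mismatch")
    C, S = np.cos(theta), np.sin(theta)
    r = kernels.support_radius
    Mp = np.pad(M, r, mode="reflect")
    Cp = np.pad(C, r, mode="reflect")
    Sp = np.pad(S, r, mode="reflect")
    H, W = M.shape
    side1_wanted = np.asarray(k) == 1
    si = np.zeros_like(M)
    ii, jj = np.nonzero(kernels.w > 0)
    for i, j in zip(ii, jj):
        dv, du = i - r, j - r
        Ms = Mp[r + dv : r + dv + H, r + du : r + du + W]
        Cs = Cp[r + dv : r + dv + H, r + du : r + du + W]
        Ss = Sp[r + dv : r + dv + H, r + du : r + du + W]
        delta = np.abs(C * Cs + S * Ss)
        on_side1 = (du * C + dv * S) >= 0
        member = np.where(side1_wanted, on_side1, ~on_side1)
        si += kernels.w[i, j] * Ms * delta * member
    return si


def adaptive_suppression(
    grad: GradientField,
    diag: SurfaceDiagnostics,
    kernels: SuppressionKernels,
    Thr: float = 30.0,
    *,
    magnitude: np.ndarray | None = None,
) -> np.ndarray:
    """Context-adaptive suppression term ``s_a``.

    Per pixel: ``w_t * s`` where ``diff <= Thr``, else ``s_i - s_e``
    (which equals ``2*s_i - s`` since ``w_e = w - w_i``).  May be negative
    on the jump branch (net facilitation).

    ``magnitude`` optionally substitutes another response field for the
    gradient magnitude inside the surround sums (orientations and
    diagnostics stay those of the original image) — this is how the
    dynamic suppression iteration reuses this operator.
    """
    if not np.isfinite(Thr):
        if np.isnan(Thr):
            raise InvalidParameterError("Thr must not be NaN")
    if grad.shape != diag.diff.shape:
        raise InvalidInputError("gradient/diagnostics shape mismatch")
    field = grad if magnitude is None else GradientField(
        magnitude=np.asarray(magnitude, dtype=np.float64),
        orientation=grad.orientation,
        sigma=grad.sigma,
    )
    s = suppression_term(field, kernels)
    jump = diag.diff > Thr
    if not np.any(jump):
        return diag.w_t * s
    s_i = inhibitory_suppression_term(field, kernels, diag.k)
    return np.where(jump, 2.0 * s_i - s, diag.w_t * s)


def cass_operator(magnitude: np.ndarray, s_a: np.ndarray, alpha: float) -> np.ndarray:
    """Adaptive operator ``E = H(M - alpha * s_a)``.

    ``s_a`` may be negative (facilitation raises the response); the output
    is still nonnegative by half-wave rectification.
    """
    if alpha < 0:
        raise InvalidParameterError(f"alpha must be nonnegative, got {alpha}")
    magnitude = np.asarray(magnitude, dtype=np.float64)
    s_a = np.asarray(s_a, dtype=np.float64)
    if magnitude.shape != s_a.shape:
        raise InvalidInputError("magnitude and suppression term shapes differ")
    return np.maximum(magnitude - alpha * s_a, 0.0)
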