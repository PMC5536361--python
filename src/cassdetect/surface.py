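"""Local linear kernel regression diagnostics for jump detection.

A plane ``a + b*(X - x) + c*(Y - y)`` is fitted by weighted least squares in
a disk-shaped window around every pixel, with weights from a truncated 2-D
Gaussian kernel of bandwidth ``h``.  Three fits are compared: the full
(centered) window and the two half-windows obtained by splitting the disk
along the local edge direction (the line through the center perpendicular
to the gradient).  Their weighted residual mean squares (WRMS) behave like
local noise-variance estimates:

* in homogeneous regions all three WRMS sit near the noise variance, so the
  excess ``diff = max(WRMS_c - WRMS_1, WRMS_c - WRMS_2)`` is near zero;
* across an intensity jump the centered fit is inflated while the one-sided
  fits are not, so ``diff`` is large;
* inside uniform fine texture all three are inflated about equally, and
  ``diff`` again stays small.

``diff`` therefore discriminates isolated jumps (contours) from texture,
and the homogeneity weight ``w_t = exp(+r_m^2 / (2 sigma_m^2))`` (with
``r_m`` the smallest of the three WRMS) scales suppression up where the
local residual level is high — i.e. inside texture — and leaves
homogeneous regions (``r_m`` near the noise variance) essentially
untouched.  A sign-flipped (damped) variant is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .exceptions import DegenerateFitError, InvalidInputError, InvalidParameterError
from .filters import GradientField
from .image import as_pixels

__all__ = [
    "Side",
    "LocalLinearFit",
    "SurfaceDiagnostics",
    "kernel_K",
    "half_plane_mask",
    "fit_local_plane",
    "diagnostics",
]

_GRAD_EPS = 1e-12  # below this gradient magnitude the split direction is undefined
_KERNEL_NORM = 2.0 * np.pi - 3.0 * np.pi * np.exp(-0.5)


class Side(Enum):
    CENTER = "center"
    SIDE1 = "side1"
    SIDE2 = "side2"


@dataclass(frozen=True)
class LocalLinearFit:
    """One weighted planar fit: intercept ``a``, slopes ``b`` (x) and ``c``
    (y), its weighted residual mean square, and which window was used."""

    a: float
    b: float
    c: float
    wrms: float
    side: Side = Side.CENTER


@dataclass(frozen=True)
class SurfaceDiagnostics:
    """Per-pixel surface-fit diagnostics.

    Attributes
    ----------
    wrms_c, wrms_1, wrms_2 : ndarray
        WRMS of the centered and the two one-sided fits (intensity^2).
    diff : ndarray
        ``max(wrms_c - wrms_1, wrms_c - wrms_2)``; signed, large near jumps.
    r_m : ndarray
        ``min(wrms_1, wrms_2, wrms_c)``.
    w_t : ndarray
        Homogeneity weight in (0, 1].
    k : ndarray of int
        Side with the larger one-sided WRMS (1 or 2; ties -> 1).
    h : float
        Kernel bandwidth in pixels.
    sigma_m : float
        Decay scale of ``w_t`` (intensity^2 units).
    """

    wrms_c: np.ndarray
    wrms_1: np.ndarray
    wrms_2: np.ndarray
    diff: np.ndarray
    r_m: np.ndarray
    w_t: np.ndarray
    k: np.ndarray
    h: float
    sigma_m: float


def kernel_K(x, y):
    """Truncated 2-D Gaussian kernel on the unit disk.

    ``K(x, y) = (exp(-(x^2+y^2)/2) - exp(-1/2)) / (2*pi - 3*pi*exp(-1/2))``
    for ``x^2 + y^2 <= 1`` and 0 outside; continuous (0 on the unit circle).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    r2 = x**2 + y**2
    val = (np.exp(-r2 / 2.0) - np.exp(-0.5)) / _KERNEL_NORM
    return np.where(r2 <= 1.0, np.maximum(val, 0.0), 0.0)


def half_plane_mask(orientation: float, side: int):
    """Return a predicate on integer displacements selecting one half-window.

    The disk is split by the line through the center perpendicular to the
    gradient direction ``orientation``.  Side 1 is the half with
    ``du*cos(orientation) + dv*sin(orientation) >= 0`` (ties, i.e. the
    split line itself, belong to side 1); side 2 is the strict complement.
    """
    if side not in (1, 2):
        raise InvalidParameterError(f"side must be 1 or 2, got {side}")
    c, s = np.cos(orientation), np.sin(orientation)

    def mask(du, dv):
        proj = np.asarray(du) * c + np.asarray(dv) * s
        return proj >= 0 if side == 1 else proj < 0

    return mask


def _wls_plane(z, du, dv, wts):
    """Solve the 3-parameter weighted LS plane and its WRMS.

    Raises DegenerateFitError when the normal system is rank deficient.
    """
    sw = wts.sum()
    if sw <= 0 or np.count_nonzero(wts > 0) < 3:
        raise DegenerateFitError("not enough weighted pixels for a planar fit")
    A = np.empty((3, 3))
    A[0, 0] = sw
    A[0, 1] = A[1, 0] = np.sum(wts * du)
    A[0, 2] = A[2, 0] = np.sum(wts * dv)
    A[1, 1] = np.sum(wts * du * du)
    A[1, 2] = A[2, 1] = np.sum(wts * du * dv)
    A[2, 2] = np.sum(wts * dv * dv)
    rhs = np.array([np.sum(wts * z), np.sum(wts * z * du), np.sum(wts * z * dv)])
    scale = max(A[0, 0] * max(A[1, 1], A[2, 2]), 1e-300)
    if abs(np.linalg.det(A)) < 1e-12 * scale:
        raise DegenerateFitError("rank-deficient normal system in planar fit")
    beta = np.linalg.solve(A, rhs)
    rss = np.sum(wts * z * z) - float(beta @ rhs)
    wrms = max(rss / sw, 0.0)
    return beta, wrms


def fit_local_plane(image, x: int, y: int, h: float, side_mask=None) -> LocalLinearFit:
    """Fit a local plane at pixel ``(x, y)`` (column, row) with bandwidth ``h``.

    Parameters
    ----------
    image : ImageField or 2-D array
    x, y : int
        Window center, (column, row).
    h : float
        Kernel bandwidth (support radius) in pixels, >= 2.
    side_mask : callable, optional
        Predicate ``mask(du, dv) -> bool array`` restricting the window to
        one half (see :func:`half_plane_mask`).  ``None`` fits the full
        window.

    The window is clipped at the image borders; at least 6 pixels with
    nonzero kernel weight must remain.
    """
    if h < 2:
        raise InvalidParameterError(f"bandwidth h must be >= 2 pixels, got {h}")
    px = as_pixels(image)
    H, W = px.shape
    r = int(np.floor(h))
    du, dv = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
    xx, yy = x + du, y + dv
    inside = (xx >= 0) & (xx < W) & (yy >= 0) & (yy < H)
    wts = kernel_K(du / h, dv / h) * inside
    if side_mask is not None:
        wts = wts * side_mask(du, dv)
    keep = wts > 0
    if np.count_nonzero(keep) < 6:
        raise InvalidInputError(
            f"window at ({x},{y}) retains fewer than 6 weighted pixels"
        )
    z = px[np.clip(yy, 0, H - 1), np.clip(xx, 0, W - 1)]
    beta, wrms = _wls_plane(z[keep], du[keep].astype(float), dv[keep].astype(float), wts[keep])
    side = Side.CENTER if side_mask is None else Side.SIDE1
    return LocalLinearFit(a=float(beta[0]), b=float(beta[1]), c=float(beta[2]),
                          wrms=float(wrms), side=side)


def _disk_offsets(h: float):
    """Integer displacements inside the kernel support with their weights."""
    r = int(np.floor(h))
    du, dv = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
    k = kernel_K(du / h, dv / h)
    keep = k > 0
    return du[keep].ravel(), dv[keep].ravel(), k[keep].ravel()


def _batched_solve(A, rhs):
    """Solve stacked 3x3 systems; returns (beta, bad) with singular systems
    flagged in ``bad`` and replaced by zeros."""
    det = np.linalg.det(A)
    scale = np.maximum(A[..., 0, 0] * np.maximum(A[..., 1, 1], A[..., 2, 2]), 1e-300)
    bad = np.abs(det) < 1e-12 * scale
    A = A.copy()
    A[bad] = np.eye(3)
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    beta[bad] = 0.0
    return beta, bad


def diagnostics(
    image,
    grad: GradientField,
    h: float | None = None,
    sigma_m: float | None = None,
    *,
    damped_wt: bool = False,
) -> SurfaceDiagnostics:
    """Compute per-pixel surface-fit diagnostics for the whole image.

    Parameters
    ----------
    image : ImageField or 2-D array
    grad : GradientField
        Gradient of the same image; its orientation sets the split
        direction of the one-sided fits.
    h : float, optional
        Kernel bandwidth in pixels.  Default ``max(4*sigma, 4)``, coupling
        the estimator support to the detection scale.
    sigma_m : float, optional
        Scale of the homogeneity weight.  Default: the median of ``r_m``
        over the image (data-adaptive); ``inf`` forces ``w_t = 1``.
    damped_wt : bool
        Audit switch: use the decaying form ``exp(-r_m^2/(2 sigma_m^2))``
        (suppression damped in high-residual regions) instead of the
        default growing form ``exp(+r_m^2/(2 sigma_m^2))``, which
        amplifies suppression in texture.  See docs/methods.md.

    Notes
    -----
    Borders are reflect-padded, so every pixel sees a full window.  Where
    the gradient magnitude is below 1e-12 the split direction is undefined
    and both one-sided fits fall back to the centered fit (``diff = 0``).
    The vectorized moment accumulation is algebraically identical to an
    explicit per-pixel normal-equations solve.
    """
    px = as_pixels(image)
    if grad.shape != px.shape:
        raise InvalidInputError("gradient was not computed from this image")
    if h is None:
        h = max(4.0 * grad.sigma, 4.0)
    if h < 2:
        raise InvalidParameterError(f"bandwidth h must be >= 2 pixels, got {h}")

    du, dv, kw = _disk_offsets(h)
    r = int(np.floor(h))
    Zp = np.pad(px, r, mode="reflect")
    H, W = px.shape

    theta = grad.orientation
    C, S = np.cos(theta), np.sin(theta)
    defined = grad.magnitude >= _GRAD_EPS

    # Centered-fit moments: the design moments are pixel-independent scalars.
    sw = kw.sum()
    sx = np.sum(kw * du)
    sy = np.sum(kw * dv)
    sxx = np.sum(kw * du * du)
    sxy = np.sum(kw * du * dv)
    syy = np.sum(kw * dv * dv)

    m1 = np.zeros((H, W))
    mx = np.zeros((H, W))
    my = np.zeros((H, W))
    mzz = np.zeros((H, W))
    # Side-1 moments (side 2 follows by subtraction from the full window).
    s1 = {k: np.zeros((H, W)) for k in ("w", "x", "y", "xx", "xy", "yy", "z", "zx", "zy", "zz")}

    for o in range(du.size):
        ddu, ddv, w_o = int(du[o]), int(dv[o]), kw[o]
        Zs = Zp[r + ddv : r + ddv + H, r + ddu : r + ddu + W]
        m1 += w_o * Zs
        mx += w_o * ddu * Zs
        my += w_o * ddv * Zs
        mzz += w_o * Zs * Zs
        side1 = (ddu * C + ddv * S) >= 0  # per-pixel membership of this offset
        ws = w_o * side1
        s1["w"] += ws
        s1["x"] += ws * ddu
        s1["y"] += ws * ddv
        s1["xx"] += ws * (ddu * ddu)
        s1["xy"] += ws * (ddu * ddv)
        s1["yy"] += ws * (ddv * ddv)
        s1["z"] += ws * Zs
        s1["zx"] += ws * ddu * Zs
        s1["zy"] += ws * ddv * Zs
        s1["zz"] += ws * Zs * Zs

    # centered fit (constant 3x3 system, vector rhs per pixel)
    A_c = np.array([[sw, sx, sy], [sx, sxx, sxy], [sy, sxy, syy]])
    rhs_c = np.stack([m1, mx, my], axis=-1)
    beta_c = np.linalg.solve(A_c, rhs_c[..., None])[..., 0]
    wrms_c = np.maximum((mzz - np.einsum("...i,...i", beta_c, rhs_c)) / sw, 0.0)

    def _side_wrms(mom):
        A = np.empty((H, W, 3, 3))
        A[..., 0, 0] = mom["w"]
        A[..., 0, 1] = A[..., 1, 0] = mom["x"]
        A[..., 0, 2] = A[..., 2, 0] = mom["y"]
        A[..., 1, 1] = mom["xx"]
        A[..., 1, 2] = A[..., 2, 1] = mom["xy"]
        A[..., 2, 2] = mom["yy"]
        rhs = np.stack([mom["z"], mom["zx"], mom["zy"]], axis=-1)
        beta, bad = _batched_solve(A, rhs)
        swk = np.where(mom["w"] > 0, mom["w"], 1.0)
        wrms = np.maximum((mom["zz"] - np.einsum("...i,...i", beta, rhs)) / swk, 0.0)
        bad |= mom["w"] <= 0
        return wrms, bad

    wrms_1, bad1 = _side_wrms(s1)
    s2 = {
        "w": sw - s1["w"], "x": sx - s1["x"], "y": sy - s1["y"],
        "xx": sxx - s1["xx"], "xy": sxy - s1["xy"], "yy": syy - s1["yy"],
        "z": m1 - s1["z"], "zx": mx - s1["zx"], "zy": my - s1["zy"],
        "zz": mzz - s1["zz"],
    }
    wrms_2, bad2 = _side_wrms(s2)

    # degenerate or direction-undefined pixels: both sides = centered fit
    fallback = bad1 | bad2 | ~defined
    wrms_1 = np.where(fallback, wrms_c, wrms_1)
    wrms_2 = np.where(fallback, wrms_c, wrms_2)

    diff = np.maximum(wrms_c - wrms_1, wrms_c - wrms_2)
    r_m = np.minimum(np.minimum(wrms_1, wrms_2), wrms_c)
    k = np.where(wrms_2 > wrms_1, 2, 1).astype(np.int8)

    if sigma_m is None:
        # data-adaptive scale; residual levels at numerical-roundoff size
        # mean the image is noise-free and the weight should be inert
        sigma_m = float(np.median(r_m))
        if sigma_m <= 1e-9:
            sigma_m = float(np.mean(r_m))
        if sigma_m <= 1e-9:
            sigma_m = float("inf")
    sigma_m = float(sigma_m)
    if np.isinf(sigma_m):
        w_t = np.ones_like(r_m)
    else:
        sm = max(sigma_m, 1e-12)
        expo = np.minimum(r_m**2 / (2.0 * sm**2), 50.0)  # overflow guard
        w_t = np.exp(-expo) if damped_wt else np.exp(expo)

    return SurfaceDiagnostics(
        wrms_c=wrms_c, wrms_1=wrms_1, wrms_2=wrms_2, diff=diff, r_m=r_m,
        w_t=w_t, k=k, h=float(h), sigma_m=sigma_m,
    )
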