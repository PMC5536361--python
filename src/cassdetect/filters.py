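"""Scale-dependent gradients and classical surround suppression.

This module implements the front end shared by the classical
surround-suppression (SS) operator and its context-adaptive refinement:

* a Gaussian-derivative gradient at scale ``sigma``, yielding a magnitude
  field :math:`M_\\sigma` and an orientation field :math:`\\theta` (mod pi);
* the annular distance-weighting stencil ``w``, the positive lobe of a
  difference of Gaussians with inner scale ``sigma`` and outer scale
  ``4*sigma``, L1-normalized — the model of the non-classical receptive
  field surround;
* the orientation weighting :math:`|\\cos(\\theta_c - \\theta_n)|`;
* the suppression term ``s`` (gradient energy in the surround, weighted by
  distance and orientation alignment) and the half-wave rectified operator
  ``E = H(M - alpha*s)``.

Points in dense texture have large ``s`` (many aligned high-gradient
neighbors in the annulus) and are suppressed; isolated contours have small
``s`` and survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .exceptions import (
    DegenerateKernelError,
    InvalidInputError,
    InvalidParameterError,
)
from .image import as_pixels

__all__ = [
    "GradientField",
    "SuppressionKernels",
    "scale_gradient",
    "dog_sigma",
    "build_distance_weights",
    "orientation_weight",
    "suppression_term",
    "halfwave_suppress",
]


@dataclass(frozen=True)
class GradientField:
    """Scale-dependent gradient magnitude and orientation.

    ``magnitude`` is nonnegative; ``orientation`` is the gradient angle
    atan2(grad_y, grad_x) reduced to [0, pi).  The sign of the gradient is
    immaterial downstream because the orientation weighting uses |cos|.
    """

    magnitude: np.ndarray
    orientation: np.ndarray
    sigma: float

    def __post_init__(self):
        if self.magnitude.shape != self.orientation.shape:
            raise InvalidInputError("magnitude/orientation shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitude.shape


@dataclass(frozen=True)
class SuppressionKernels:
    """Discretized annular distance weights for the suppression surround.

    ``w`` is an odd-sided stencil, zero outside the positive lobe of the
    difference of Gaussians, with entries summing to 1.  ``annulus_inner``
    is the radius at which the continuous DoG changes sign (where
    suppression begins); ``annulus_outer = 4 * annulus_inner`` mirrors the
    4:1 ratio of the outer to inner Gaussian scales.
    """

    w: np.ndarray
    support_radius: int
    sigma: float
    annulus_inner: float
    annulus_outer: float


def _gaussian_1d(sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled unit-sum Gaussian and its offsets, truncated at ceil(3*sigma)."""
    r = int(np.ceil(3.0 * sigma))
    x = np.arange(-r, r + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    g /= g.sum()
    return x, g


def _gaussian_deriv_1d(sigma: float) -> np.ndarray:
    """Sampled Gaussian first derivative, normalized to unit ramp response.

    The samples of -x/sigma^2 * g(x) are rescaled so that convolving a
    discrete unit-slope ramp returns exactly 1; this removes the small
    truncation/sampling bias of the raw samples.
    """
    x, _ = _gaussian_1d(sigma)
    d = -x / sigma**2 * np.exp(-(x**2) / (2.0 * sigma**2))
    # response of the convolution kernel d to f(x)=x is sum(u^2 * raw)/norm
    ramp_response = np.sum(-x * d)
    if ramp_response <= 0:
        raise DegenerateKernelError(f"derivative kernel degenerate at sigma={sigma}")
    return d / ramp_response


def scale_gradient(image, sigma: float) -> GradientField:
    """Compute the scale-dependent gradient of ``image``.

    Parameters
    ----------
    image : ImageField or 2-D array
        Intensity raster.
    sigma : float
        Scale of the Gaussian whose partial derivatives form the filter.

    Returns
    -------
    GradientField
        Magnitude ``sqrt(gx^2 + gy^2)`` and orientation
        ``atan2(gy, gx) mod pi``.  Borders are reflect-padded.
    """
    if not (np.isscalar(sigma) and sigma > 0):
        raise InvalidParameterError(f"sigma must be positive, got {sigma!r}")
    px = as_pixels(image)
    _, g = _gaussian_1d(sigma)
    d = _gaussian_deriv_1d(sigma)
    # separable convolution: derivative along one axis, smoothing along the other
    gx = ndimage.convolve1d(px, d, axis=1, mode="reflect")
    gx = ndimage.convolve1d(gx, g, axis=0, mode="reflect")
    gy = ndimage.convolve1d(px, d, axis=0, mode="reflect")
    gy = ndimage.convolve1d(gy, g, axis=1, mode="reflect")
    mag = np.hypot(gx, gy)
    theta = np.mod(np.arctan2(gy, gx), np.pi)
    return GradientField(magnitude=mag, orientation=theta, sigma=float(sigma))


def dog_sigma(r2: np.ndarray, sigma: float) -> np.ndarray:
    """Difference of Gaussians (outer scale ``4*sigma`` minus inner ``sigma``)
    evaluated at squared radius ``r2``."""
    s_out = 4.0 * sigma
    return np.exp(-r2 / (2.0 * s_out**2)) / (2.0 * np.pi * s_out**2) - np.exp(
        -r2 / (2.0 * sigma**2)
    ) / (2.0 * np.pi * sigma**2)


def build_distance_weights(sigma: float) -> SuppressionKernels:
    """Build the L1-normalized annular distance-weight stencil at ``sigma``.

    The stencil is the half-wave rectified DoG sampled on integer offsets
    out to radius ``ceil(3 * 4 * sigma)`` (odd side length); it is zero at
    the origin and everywhere the DoG is negative, so its support is an
    annulus whose inner radius is the DoG sign change.
    """
    if not (np.isscalar(sigma) and sigma > 0):
        raise InvalidParameterError(f"sigma must be positive, got {sigma!r}")
    radius = int(np.ceil(3.0 * 4.0 * sigma))
    offs = np.arange(-radius, radius + 1, dtype=np.float64)
    uu, vv = np.meshgrid(offs, offs)  # uu: x offset (columns), vv: y offset (rows)
    dog = dog_sigma(uu**2 + vv**2, sigma)
    w = np.where(dog > 0, dog, 0.0)
    total = w.sum()
    if total <= 0:
        raise DegenerateKernelError(
            f"positive DoG lobe is empty on the integer grid at sigma={sigma}"
        )
    w /= total
    # inner radius: sign change of the continuous radial DoG profile
    r_inner = brentq(lambda r: dog_sigma(np.float64(r * r), sigma), 1e-6 * sigma, 4.0 * sigma)
    return SuppressionKernels(
        w=w,
        support_radius=radius,
        sigma=float(sigma),
        annulus_inner=float(r_inner),
        annulus_outer=4.0 * float(r_inner),
    )


def orientation_weight(theta_center, theta_neighbor):
    """Orientation alignment weight ``|cos(theta_center - theta_neighbor)|``.

    Equals 1 for identical gradient orientations and 0 for orthogonal ones;
    accepts scalars or arrays of any real angle.
    """
    return np.abs(np.cos(np.asarray(theta_center) - np.asarray(theta_neighbor)))


def _pad_fields(kernels: SuppressionKernels, *fields: np.ndarray):
    r = kernels.support_radius
    return [np.pad(f, r, mode="reflect") for f in fields]


def suppression_term(grad: GradientField, kernels: SuppressionKernels) -> np.ndarray:
    """Classical surround-suppression term ``s``.

    For each pixel, the sum over the annular stencil of the neighbor
    gradient magnitudes weighted by distance (``w``) and orientation
    alignment (``|cos|``).  Borders are reflect-padded.
    """
    if grad.magnitude.ndim != 2:
        raise InvalidInputError("gradient fields must be 2-D")
    M, theta = grad.magnitude, grad.orientation
    C, S = np.cos(theta), np.sin(theta)
    r = kernels.support_radius
    Mp, Cp, Sp = _pad_fields(kernels, M, C, S)
    H, W = M.shape
    s = np.zeros_like(M)
    ii, jj = np.nonzero(kernels.w > 0)
    for i, j in zip(ii, jj):
        dv, du = i - r, j - r  # row (y) and column (x) neighbor displacement
        Ms = Mp[r + dv : r + dv + H, r + du : r + du + W]
        Cs = Cp[r + dv : r + dv + H, r + du : r + du + W]
        Ss = Sp[r + dv : r + dv + H, r + du : r + du + W]
        delta = np.abs(C * Cs + S * Ss)  # |cos(theta_c - theta_n)|
        s += kernels.w[i, j] * Ms * delta
    return s


def halfwave_suppress(magnitude: np.ndarray, s: np.ndarray, alpha: float) -> np.ndarray:
    """Half-wave rectified suppression ``E = H(M - alpha * s)``."""
    if alpha < 0:
        raise InvalidParameterError(f"alpha must be nonnegative, got {alpha}")
    magnitude = np.asarray(magnitude, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if magnitude.shape != s.shape:
        raise InvalidInputError("magnitude and suppression term shapes differ")
    return np.maximum(magnitude - alpha * s, 0.0)
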