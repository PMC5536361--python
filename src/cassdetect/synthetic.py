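"""Seeded synthetic scenes with pixel-exact ground-truth contours.

Scenes emulate the statistical structure the detector assumes: homogeneous
regions carry additive zero-mean Gaussian noise; texture fields are dense
sets of oriented high-gradient edges (clutter, absent from the ground
truth); object boundaries are smooth closed curves whose rasterized 1-px
outline is the ground truth.  The regime of interest is a *weak* contour
(small boundary contrast) embedded in *strong* texture — the case where a
plain gradient detector, and even classical surround suppression at a
single inhibition level, confuse clutter with contour.

Intensities are rendered in [0, 255] (the range the default jump threshold
assumes).  Object boundaries are hard (no anti-aliasing) by default so the
ground truth is pixel-exact; a soft-edge option exists for robustness
experiments only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import line as sk_line

from .exceptions import InvalidSpecError
from .image import ImageField, save_image
from .postprocess import EdgeMap

__all__ = ["SceneSpec", "generate_scene", "generate_suite", "write_fixtures"]

TEXTURES = ("none", "oriented-sinusoid", "random-bars", "checkerboard")
SHAPES = ("disk", "rounded-rectangle", "blob-spline")

_BASE = 128.0  # mid-gray background level


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene (deterministic given ``seed``)."""

    size: tuple[int, int] = (128, 128)
    texture: str = "random-bars"
    texture_contrast: float = 45.0   # peak-to-peak intensity of the clutter
    texture_period: float = 2.5      # period (px) or bar-spacing scale
    texture_orientation: float = 0.6  # radians, for oriented patterns
    shape: str = "disk"
    interior: str = "constant"       # "constant" | "texture"
    boundary_contrast: float = 25.0  # object interior minus background level
    clear_margin: float = 12.0       # texture-free band (px) on both sides of the boundary
    noise_sigma: float = 4.0         # Gaussian observation noise (intensity)
    antialias: bool = False
    seed: int = 0

    @property
    def weak_contour(self) -> bool:
        """True when the clutter out-contrasts the object boundary."""
        return self.boundary_contrast < self.texture_contrast

    def validate(self):
        if self.texture not in TEXTURES:
            raise InvalidSpecError(f"unknown texture {self.texture!r}")
        if self.shape not in SHAPES:
            raise InvalidSpecError(f"unknown shape {self.shape!r}")
        if self.interior not in ("constant", "texture"):
            raise InvalidSpecError(f"unknown interior {self.interior!r}")
        H, W = self.size
        if min(H, W) < 32:
            raise InvalidSpecError("scene must be at least 32x32")


def _amplitude_modulation(H, W, rng):
    """Smooth positive field modulating local texture contrast.

    Natural clutter is not uniform in strength; a broad spatial spread of
    texture amplitudes is what makes rank-based thresholding meaningful.
    """
    coarse = rng.uniform(0.25, 1.0, size=(max(H // 16, 2), max(W // 16, 2)))
    zoom = (H / coarse.shape[0], W / coarse.shape[1])
    return ndimage.zoom(coarse, zoom, order=1, mode="nearest")[:H, :W]


def _texture_field(kind, H, W, contrast, period, orientation, rng):
    amp = contrast / 2.0
    yy, xx = np.indices((H, W)).astype(np.float64)
    if kind == "none":
        return np.zeros((H, W))
    if kind == "oriented-sinusoid":
        u = xx * np.cos(orientation) + yy * np.sin(orientation)
        phase = rng.uniform(0, 2 * np.pi)
        field = amp * np.sin(2 * np.pi * u / period + phase)
        return field * _amplitude_modulation(H, W, rng)
    if kind == "checkerboard":
        p = max(int(round(period / 2.0)), 1)  # cell side: half a period
        field = amp * (((xx // p + yy // p) % 2) * 2.0 - 1.0)
        return field * _amplitude_modulation(H, W, rng)
    if kind == "random-bars":
        field = np.zeros((H, W))
        density = 1.0 / (period * 6.0)  # bars per pixel area
        n_bars = max(int(H * W * density), 20)
        for _ in range(n_bars):
            cy, cx = rng.integers(0, H), rng.integers(0, W)
            ang = rng.uniform(0, np.pi)
            length = rng.integers(6, 15)
            dy = int(round(np.sin(ang) * length / 2))
            dx = int(round(np.cos(ang) * length / 2))
            r0, c0 = np.clip(cy - dy, 0, H - 1), np.clip(cx - dx, 0, W - 1)
            r1, c1 = np.clip(cy + dy, 0, H - 1), np.clip(cx + dx, 0, W - 1)
            rr, cc = sk_line(int(r0), int(c0), int(r1), int(c1))
            # per-bar contrast spread: clutter strength varies in real scenes
            field[rr, cc] = amp * rng.uniform(0.3, 1.0) * rng.choice((-1.0, 1.0))
        if rng.random() < 0.5:  # half the scenes get 2-px-thick bars
            field = ndimage.grey_dilation(field, size=(2, 2))
        return field
    raise InvalidSpecError(f"unknown texture {kind!r}")


def _object_mask(shape, H, W, rng):
    """Closed object mask at least 1 px from the border."""
    yy, xx = np.indices((H, W)).astype(np.float64)
    cy = H / 2.0 + rng.uniform(-H * 0.05, H * 0.05)
    cx = W / 2.0 + rng.uniform(-W * 0.05, W * 0.05)
    rad = 0.28 * min(H, W) * rng.uniform(0.85, 1.1)
    if shape == "disk":
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= rad**2
    elif shape == "rounded-rectangle":
        hw = rad * rng.uniform(0.9, 1.3)
        hh = rad * rng.uniform(0.7, 1.0)
        rc = 0.3 * min(hw, hh)
        qx = np.abs(xx - cx) - (hw - rc)
        qy = np.abs(yy - cy) - (hh - rc)
        dist = np.hypot(np.maximum(qx, 0), np.maximum(qy, 0)) + np.minimum(
            np.maximum(qx, qy), 0
        )
        mask = dist <= rc
    elif shape == "blob-spline":
        phi = np.arctan2(yy - cy, xx - cx)
        r_of_phi = np.full_like(phi, 1.0)
        for harm in (2, 3, 5):
            r_of_phi += rng.uniform(0.04, 0.12) * np.cos(harm * phi + rng.uniform(0, 2 * np.pi))
        mask = np.hypot(xx - cx, yy - cy) <= rad * r_of_phi
    else:
        raise InvalidSpecError(f"unknown shape {shape!r}")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise InvalidSpecError("object touches the image border")
    if not mask.any():
        raise InvalidSpecError("object mask is empty")
    return mask


def _inner_boundary(mask: np.ndarray) -> np.ndarray:
    """1-px 8-connected inner boundary of a filled mask."""
    return mask & ~ndimage.binary_erosion(mask)


def generate_scene(spec: SceneSpec) -> tuple[ImageField, EdgeMap]:
    """Render a scene and its ground-truth contour map.

    Deterministic for a given spec (all randomness from ``spec.seed``).
    Texture edges are clutter and are *not* in the ground truth; the GT is
    the 1-px inner boundary of the object mask.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.size
    bg = _BASE + _texture_field(
        spec.texture, H, W, spec.texture_contrast,
        spec.texture_period, spec.texture_orientation, rng,
    )
    mask = _object_mask(spec.shape, H, W, rng)
    sign = 1.0 if rng.random() < 0.5 else -1.0
    interior_level = _BASE + sign * spec.boundary_contrast
    if spec.interior == "texture":
        itex = _texture_field(
            spec.texture if spec.texture != "none" else "oriented-sinusoid",
            H, W, spec.texture_contrast * 0.5, spec.texture_period * 1.7,
            spec.texture_orientation + np.pi / 3, rng,
        )
        interior = interior_level + itex
    else:
        interior = np.full((H, W), interior_level)
    if spec.clear_margin > 0:
        # contours are locally isolated: clutter keeps a clear band on both
        # sides of the boundary (the premise that separates contour points,
        # with few surround stimuli, from texture points, with many)
        d_out = ndimage.distance_transform_edt(~mask)
        d_in = ndimage.distance_transform_edt(mask)
        bg = np.where((d_out > 0) & (d_out <= spec.clear_margin), _BASE, bg)
        interior = np.where(
            (d_in > 0) & (d_in <= spec.clear_margin), interior_level, interior
        )
    img = np.where(mask, interior, bg)
    if spec.antialias:
        img = ndimage.gaussian_filter(img, 0.7)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(H, W))
    img = np.clip(img, 0.0, 255.0)
    gt = _inner_boundary(mask)
    return ImageField(img), EdgeMap(gt, {"spec": asdict(spec)})


def generate_suite(
    n: int,
    seed: int,
    *,
    size: tuple[int, int] = (128, 128),
    weak_fraction: float = 0.4,
) -> list[tuple[ImageField, EdgeMap, SceneSpec]]:
    """Generate ``n`` scenes spanning the texture types, shapes and contrasts.

    A ``weak_fraction`` share of the scenes (deterministically interleaved)
    is in the weak-contour/strong-texture regime; ``weak_fraction=1.0``
    yields a suite entirely in that regime.  Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    textured = [t for t in TEXTURES if t != "none"]
    out = []
    for i in range(n):
        # interleave weak-regime scenes evenly through the suite
        weak = np.floor((i + 1) * weak_fraction) > np.floor(i * weak_fraction)
        if weak:
            boundary = float(rng.uniform(18.0, 30.0))
            tex_contrast = float(rng.uniform(35.0, 55.0))
        else:
            boundary = float(rng.uniform(60.0, 90.0))
            tex_contrast = float(rng.uniform(25.0, 45.0))
        tex = textured[i % len(textured)]
        # bars are broadband; periodic patterns need coarser grain to carry
        # gradient energy at the default detection scale
        period_rng = {"random-bars": (2.0, 3.0), "oriented-sinusoid": (3.4, 4.6),
                      "checkerboard": (3.5, 4.5)}[tex]
        spec = SceneSpec(
            size=size,
            texture=tex,
            texture_contrast=tex_contrast,
            texture_period=float(rng.uniform(*period_rng)),
            texture_orientation=float(rng.uniform(0, np.pi)),
            shape=SHAPES[(i // len(textured)) % len(SHAPES)],
            interior="constant" if i % 4 else "texture",
            boundary_contrast=boundary,
            noise_sigma=4.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        img, gt = generate_scene(spec)
        out.append((img, gt, spec))
    return out


def write_fixtures(outdir, suite) -> list[dict]:
    """Write scene/GT/spec triplets (PNG + PNG + JSON) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = []
    for i, (img, gt, spec) in enumerate(suite):
        stem = f"scene_{i:03d}"
        save_image(outdir / f"{stem}.png", img.pixels)
        save_image(outdir / f"{stem}_gt.png", gt.pixels)
        meta = asdict(spec)
        (outdir / f"{stem}.json").write_text(json.dumps(meta, indent=2))
        index.append({"stem": stem, **meta})
    return index
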