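"""Seeded synthetic B-mode ultrasound phantom and impulse-noise injector.

The phantom emulates the displayed content of a transperineal pelvic-floor
scan: a dark fan-shaped sector border (the region outside the transducer's
insonified sector), a mid-gray tissue background, dark (anechoic) elliptical
inclusions standing in for fluid-filled structures, bright curvilinear
interfaces (fascia, the urethral/bladder-neck outline), and multiplicative
speckle texture.  A piecewise-smooth anatomy layer is multiplied by
unit-mean gamma speckle with shape ``speckle_looks`` and quantised to
``[0, 255]``.

The ``speckle_looks`` default (64) models *display-domain* texture — what
is left of fully developed speckle after spatial compounding, envelope
processing and log mapping on a clinical scanner, roughly 10-15 % intensity
contrast.  Raw, single-look speckle (contrast ~ 1) is available by setting
``speckle_looks`` small, e.g. 1-4.

Impulse corruption replaces an exact pixel count (``round(density * G)``)
drawn without replacement, so tests can assert counts deterministically,
and returns the corrupted-pixel mask as detection ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .image_io import GrayImage

__all__ = ["PhantomSpec", "NoiseSpec", "make_phantom", "anatomy_layer", "add_impulse_noise"]

# anatomy layer levels (fractions of background mean, or absolute gray)
CYST_LEVEL = 0.3       # anechoic inclusions
LINE_LEVEL = 1.8       # bright curvilinear interfaces (clipped at G_max)
BORDER_GRAY = 8.0      # near-black sector border floor
FAN_HALF_ANGLE_DEG = 48.0
NOISE_MODES = ("salt", "pepper", "salt_and_pepper")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, echogenicity and speckle parameters of one phantom."""

    height: int = 128
    width: int = 128
    n_cysts: int = 3
    n_lines: int = 2
    background_mean: float = 110.0
    speckle_looks: int = 64
    fan_mask: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("phantom dimensions must be >= 32")
        if not (0.0 < self.background_mean < 255.0):
            raise ValueError("background_mean must lie strictly inside (0, 255)")
        if self.speckle_looks < 1:
            raise ValueError("speckle_looks must be >= 1")
        if self.n_cysts < 0 or self.n_lines < 0:
            raise ValueError("n_cysts and n_lines must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Impulse corruption: exact fraction ``density`` of pixels replaced."""

    density: float
    mode: str = "salt_and_pepper"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.density <= 1.0):
            raise ValueError("density must lie in [0, 1]")
        if self.mode not in NOISE_MODES:
            raise ValueError(f"mode must be one of {NOISE_MODES}")


def _fan_region(h: int, w: int) -> np.ndarray:
    """Insonified sector: apex just above the top edge, opening downward."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    ay, ax = -0.08 * h, 0.5 * (w - 1)
    dy, dx = yy - ay, xx - ax
    r = np.hypot(dy, dx)
    ang = np.arctan2(dx, dy)  # angle off the downward vertical
    return (
        (np.abs(ang) <= np.deg2rad(FAN_HALF_ANGLE_DEG))
        & (r <= 1.12 * h)
        & (r >= 0.10 * h)
    )


def _render_anatomy(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw the piecewise-smooth anatomy layer; consumes geometry RNG draws."""
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    anatomy = np.full((h, w), spec.background_mean, dtype=np.float64)
    structure = np.zeros((h, w), dtype=bool)

    for _ in range(spec.n_cysts):
        cy = rng.uniform(0.30, 0.80) * h
        cx = rng.uniform(0.25, 0.75) * w
        semi_a = rng.uniform(0.06, 0.15) * min(h, w)
        semi_b = rng.uniform(0.06, 0.15) * min(h, w)
        theta = rng.uniform(0.0, np.pi)
        u = ((xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)) / semi_a
        v = (-(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)) / semi_b
        inside = u * u + v * v <= 1.0
        anatomy[inside] = CYST_LEVEL * spec.background_mean
        structure |= inside & ~ndi.binary_erosion(inside)

    for _ in range(spec.n_lines):
        cy = rng.uniform(0.35, 0.85) * h
        cx = rng.uniform(0.20, 0.80) * w
        radius = rng.uniform(0.25, 0.55) * min(h, w)
        t0 = rng.uniform(0.0, 2.0 * np.pi)
        span = rng.uniform(0.7, 1.5)
        ts = np.linspace(t0, t0 + span, max(int(3.0 * radius * span), 32))
        py = np.rint(cy + radius * np.sin(ts)).astype(int)
        px = np.rint(cx + radius * np.cos(ts)).astype(int)
        keep = (py >= 0) & (py < h) & (px >= 0) & (px < w)
        line = np.zeros((h, w), dtype=bool)
        line[py[keep], px[keep]] = True
        line = ndi.binary_dilation(line, structure=np.ones((3, 3), dtype=bool))
        anatomy[line] = min(LINE_LEVEL * spec.background_mean, 255.0)
        structure |= line

    if spec.fan_mask:
        fan = _fan_region(h, w)
        anatomy[~fan] = BORDER_GRAY
        structure &= fan

    return anatomy, structure


def anatomy_layer(spec: PhantomSpec | None = None) -> np.ndarray:
    """Noise-free (pre-speckle) anatomy layer of :func:`make_phantom`.

    As ``speckle_looks`` grows the rendered phantom converges to this layer
    (after quantisation), which makes it the natural reference for speckle
    convergence checks.
    """
    spec = spec or PhantomSpec()
    layer, _ = _render_anatomy(spec, np.random.default_rng(spec.seed))
    return layer


def make_phantom(spec: PhantomSpec | None = None) -> tuple[GrayImage, np.ndarray]:
    """Render one phantom; returns ``(clean image, structure_mask)``.

    ``structure_mask`` marks ground-truth edge locations: cyst boundary
    rings and bright-line pixels (restricted to the fan when enabled).
    Deterministic for a fixed spec (including the seed).
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    anatomy, structure = _render_anatomy(spec, rng)
    speckle = rng.gamma(spec.speckle_looks, 1.0 / spec.speckle_looks, size=anatomy.shape)
    img = np.clip(np.rint(anatomy * speckle), 0, 255).astype(np.uint8)
    return GrayImage(img), structure


def add_impulse_noise(img: GrayImage, spec: NoiseSpec) -> tuple[GrayImage, np.ndarray]:
    """Corrupt exactly ``round(density * G)`` distinct pixels.

    Salt pixels become ``g_max``, pepper pixels 0; ``salt_and_pepper``
    flips a fair coin per corrupted pixel.  Returns the noisy image and the
    boolean mask of corrupted positions.
    """
    rng = np.random.default_rng(spec.seed)
    g = img.g
    k = int(round(spec.density * g))
    flat = img.pixels.copy().reshape(-1)
    mask = np.zeros(g, dtype=bool)
    if k > 0:
        idx = rng.choice(g, size=k, replace=False)
        mask[idx] = True
        if spec.mode == "salt":
            flat[idx] = img.g_max
        elif spec.mode == "pepper":
            flat[idx] = 0
        else:
            salt = rng.integers(0, 2, size=k).astype(bool)
            flat[idx[salt]] = img.g_max
            flat[idx[~salt]] = 0
    noisy = GrayImage(flat.reshape(img.shape), g_max=img.g_max)
    return noisy, mask.reshape(img.shape)
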