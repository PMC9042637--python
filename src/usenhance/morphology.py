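"""Flat-structuring-element grayscale morphology and gradient edge operators.

Dilation and erosion are the usual flat max/min filters,

    (g (+) D)(p) = max_{d in D} g(p - d),      (g (-) D)(p) = min_{d in D} g(p + d),

with offsets ``d`` taken relative to the structuring element's anchor, so
the adjunction and duality identities hold exactly for arbitrary anchored
SEs.  Opening and closing are the usual compositions.  Borders are extended
by reflection (configurable), matching the filtering module.

Five gradient operators are provided, written in terms of dilation ``(+)``,
erosion ``(-)``, opening ``o`` and closing ``*`` by a flat SE ``D``:

    P1 = (g (+) D) - (g * D)            dilation-type anti-noise gradient
    P2 = (g o D)  - (g (-) D)           erosion-type anti-noise gradient
    P3 = ((g o D) (+) D) - ((g * D) (-) D)
    P4 = ((g o D) (+) D) - (g o D)
    P5 = (g * D) - ((g * D) (-) D)

Opening/closing pre-smoothing is what gives these operators their
robustness to isolated impulses compared with the plain gradient
``dilate - erode``.  Differences are clamped at 0 (gradients are used as
non-negative edge maps); P1, P2, P4 and P5 are provably non-negative for an
anchored flat SE, and any clamping in P3 is counted on the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage

__all__ = [
    "StructuringElement",
    "EdgeImage",
    "GRADIENT_OPERATORS",
    "dilate",
    "erode",
    "opening",
    "closing",
    "gradient",
]

GRADIENT_OPERATORS = ("P1", "P2", "P3", "P4", "P5")

_NP_PAD = {"reflect": "reflect", "edge_replicate": "edge"}


@dataclass(frozen=True, eq=False)
class StructuringElement:
    """Flat (binary) structuring element with an explicit anchor.

    The default is the 3x3 all-true square anchored at its centre.
    """

    mask: np.ndarray
    anchor: tuple[int, int]

    def __post_init__(self) -> None:
        mask = np.ascontiguousarray(np.asarray(self.mask, dtype=bool))
        if mask.ndim != 2 or not mask.any():
            raise ValueError("structuring element mask must be 2-D with at least one true cell")
        ar, ac = self.anchor
        if not (0 <= ar < mask.shape[0] and 0 <= ac < mask.shape[1]):
            raise ValueError(f"anchor {self.anchor} outside mask of shape {mask.shape}")
        if not mask[ar, ac]:
            raise ValueError("anchor cell must be part of the structuring element")
        mask.setflags(write=False)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "anchor", (int(ar), int(ac)))

    @classmethod
    def square(cls, n: int = 3) -> "StructuringElement":
        if n < 1 or n % 2 == 0:
            raise ValueError("square SE side must be odd and >= 1")
        return cls(np.ones((n, n), dtype=bool), (n // 2, n // 2))

    @classmethod
    def cross(cls, n: int = 3) -> "StructuringElement":
        if n < 1 or n % 2 == 0:
            raise ValueError("cross SE side must be odd and >= 1")
        mask = np.zeros((n, n), dtype=bool)
        mask[n // 2, :] = True
        mask[:, n // 2] = True
        return cls(mask, (n // 2, n // 2))

    @classmethod
    def from_text(cls, text: str) -> "StructuringElement":
        """Parse a mask from rows of ``0``/``1`` with ``*`` marking the anchor.

        Example::

            010
            1*1
            010
        """
        rows = [line.strip() for line in text.strip().splitlines() if line.strip()]
        if not rows or len({len(r) for r in rows}) != 1:
            raise ValueError("SE text must be non-empty rows of equal length")
        anchor = None
        mask = np.zeros((len(rows), len(rows[0])), dtype=bool)
        for i, row in enumerate(rows):
            for j, ch in enumerate(row):
                if ch == "*":
                    if anchor is not None:
                        raise ValueError("SE text must contain exactly one '*' anchor")
                    anchor = (i, j)
                    mask[i, j] = True
                elif ch == "1":
                    mask[i, j] = True
                elif ch != "0":
                    raise ValueError(f"invalid SE character {ch!r}; expected 0, 1 or *")
        if anchor is None:
            raise ValueError("SE text must mark the anchor with '*'")
        return cls(mask, anchor)

    @property
    def offsets(self) -> np.ndarray:
        """(k, 2) array of member offsets relative to the anchor."""
        return np.argwhere(self.mask) - np.asarray(self.anchor)

    @property
    def is_symmetric(self) -> bool:
        """True when the offset set equals its own point reflection."""
        offs = {tuple(o) for o in self.offsets}
        return offs == {(-i, -j) for i, j in offs}


@dataclass(frozen=True, eq=False)
class EdgeImage:
    """Non-negative gradient-magnitude map plus the operator that made it."""

    pixels: np.ndarray
    operator_id: str
    n_clipped: int = 0
    g_max: int = 255

    def __post_init__(self) -> None:
        arr = np.ascontiguousarray(np.asarray(self.pixels, dtype=np.uint8))
        arr.setflags(write=False)
        object.__setattr__(self, "pixels", arr)
        if self.operator_id not in GRADIENT_OPERATORS:
            raise ValueError(f"operator_id must be one of {GRADIENT_OPERATORS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _shift_reduce(arr: np.ndarray, se: StructuringElement, sign: int, reduce, border: str) -> np.ndarray:
    """max/min over SE offsets; sign=-1 gives dilation's g(p - d) indexing."""
    offs = se.offsets
    pr = int(np.abs(offs[:, 0]).max(initial=0))
    pc = int(np.abs(offs[:, 1]).max(initial=0))
    h, w = arr.shape
    padded = np.pad(arr, ((pr, pr), (pc, pc)), mode=_NP_PAD[border])
    out = None
    for di, dj in offs:
        view = padded[pr + sign * di : pr + sign * di + h, pc + sign * dj : pc + sign * dj + w]
        out = view.copy() if out is None else reduce(out, view, out=out)
    return out


def _as_array(g: GrayImage | np.ndarray) -> tuple[np.ndarray, int]:
    if isinstance(g, GrayImage):
        return g.pixels.astype(np.int64), g.g_max
    arr = np.asarray(g)
    return arr.astype(np.int64), 255


def dilate(g: GrayImage, se: StructuringElement | None = None, border: str = "reflect") -> GrayImage:
    """Flat grayscale dilation (local maximum over the reflected SE)."""
    se = se or StructuringElement.square(3)
    arr, g_max = _as_array(g)
    return GrayImage(_shift_reduce(arr, se, -1, np.maximum, border), g_max=g_max)


def erode(g: GrayImage, se: StructuringElement | None = None, border: str = "reflect") -> GrayImage:
    """Flat grayscale erosion (local minimum over the SE)."""
    se = se or StructuringElement.square(3)
    arr, g_max = _as_array(g)
    return GrayImage(_shift_reduce(arr, se, +1, np.minimum, border), g_max=g_max)


def opening(g: GrayImage, se: StructuringElement | None = None, border: str = "reflect") -> GrayImage:
    return dilate(erode(g, se, border), se, border)


def closing(g: GrayImage, se: StructuringElement | None = None, border: str = "reflect") -> GrayImage:
    return erode(dilate(g, se, border), se, border)


def gradient(
    g: GrayImage,
    se: StructuringElement | None = None,
    operator_id: str = "P4",
    border: str = "reflect",
) -> EdgeImage:
    """Morphological gradient edge map under one of the operators P1..P5."""
    if operator_id not in GRADIENT_OPERATORS:
        raise ValueError(f"unknown operator_id {operator_id!r}; expected one of {GRADIENT_OPERATORS}")
    se = se or StructuringElement.square(3)
    arr, g_max = _as_array(g)

    def dil(x):
        return _shift_reduce(x, se, -1, np.maximum, border)

    def ero(x):
        return _shift_reduce(x, se, +1, np.minimum, border)

    if operator_id == "P1":
        diff = dil(arr) - ero(dil(arr))
    elif operator_id == "P2":
        diff = dil(ero(arr)) - ero(arr)
    elif operator_id == "P3":
        diff = dil(dil(ero(arr))) - ero(ero(dil(arr)))
    elif operator_id == "P4":
        ope = dil(ero(arr))
        diff = dil(ope) - ope
    else:  # P5
        clo = ero(dil(arr))
        diff = clo - ero(clo)

    n_clipped = int(np.count_nonzero(diff < 0))
    clamped = np.clip(diff, 0, g_max)
    return EdgeImage(clamped.astype(np.uint8), operator_id=operator_id, n_clipped=n_clipped, g_max=g_max)
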