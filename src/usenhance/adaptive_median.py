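"""Two-stage adaptive median filter for impulse (salt-and-pepper) noise.

The detector classifies each pixel from the ascending sorted array ``S`` of
its ``M x M`` window.  Writing ``S_min``, ``S_max``, ``S_med`` for the window
minimum/maximum/median, ``N1`` for the position of the first entry strictly
above ``S_min`` and ``N2`` for the last entry strictly below ``S_max``:

* **Stage 1 (candidate screening).**  A pixel is a *quasi-noise* candidate
  when it equals a window extreme while the window median is itself not an
  extreme (``S_min < S_med < S_max``); otherwise it is a *signal* pixel and
  is never modified.

* **Stage 2 (slope confirmation).**  For a candidate, the local slope ``K1``
  compares the pixel against its nearest non-extreme neighbours in ``S``:

  - minimum case:  ``K1 = (S[N1] - F) / ((N1 + 1) / 2)``
  - maximum case:  ``K1 = (F - S[N1]) / (M*M - 1 - N2)``   (``as_printed``),
    or with ``S[N2]`` in the numerator under the ``symmetric`` variant,

  while ``K2 = (S[N2] - S[N1]) / (N2 - N1)`` is the average interior slope
  of the window.  The adaptive threshold is ``Q = S_med / epsilon`` for a
  positive integer ``epsilon``.  The default confirmation rule flags noise
  when ``|K1| >= Q``; the stricter ``k1_vs_k2_and_q`` rule additionally
  requires ``|K1| > |K2|``.

Confirmed noise is replaced by the median of the smallest window in the
growth schedule ``M0 -> M0+2 -> ... -> M_max`` whose median is not a window
extreme (falling back to the ``M_max`` median).  Every decision reads the
*input* image; the filter is non-recursive, so results are independent of
scan order.

``brute_force_denoise`` is a deliberately literal per-pixel transcription of
the same rules, kept as an executable cross-check for the vectorized
``denoise``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage as ndi

from .image_io import GrayImage

__all__ = [
    "PixelLabel",
    "WindowStats",
    "FilterParams",
    "sorted_window",
    "classify_candidate",
    "slope_k1",
    "slope_k2",
    "threshold_q",
    "confirm_noise",
    "denoise",
    "brute_force_denoise",
]

# toolkit border name -> (numpy pad mode, scipy.ndimage mode); the pairs are
# equivalent extensions, names just differ between the two libraries.
_BORDER_MODES = {
    "reflect": ("reflect", "mirror"),
    "edge_replicate": ("edge", "nearest"),
}

K1_VARIANTS = ("as_printed", "symmetric")
CONFIRM_RULES = ("k1_vs_q", "k1_vs_k2_and_q")


class PixelLabel(IntEnum):
    """Per-pixel detector outcome (values double as label-map codes)."""

    SIGNAL = 0
    QUASI_NOISE = 1  # candidate that failed slope confirmation
    NOISE = 2        # confirmed and replaced


@dataclass(frozen=True)
class WindowStats:
    """Sorted statistics of one filter window.

    ``s`` is the ascending array of all ``m*m`` window intensities; ``n1``
    and ``n2`` bracket its non-extreme interior and are ``None`` for a
    constant window, where they are undefined.
    """

    center: int
    s: np.ndarray
    m: int

    def __post_init__(self) -> None:
        s = np.asarray(self.s)
        if s.size != self.m * self.m or np.any(np.diff(s) < 0):
            raise ValueError("s must be the ascending array of all m*m window values")

    @property
    def s_min(self) -> int:
        return int(self.s[0])

    @property
    def s_max(self) -> int:
        return int(self.s[-1])

    @property
    def s_med(self) -> int:
        return int(self.s[(self.m * self.m - 1) // 2])

    @property
    def is_constant(self) -> bool:
        return self.s_min == self.s_max

    @property
    def n1(self) -> Optional[int]:
        """Position of the first entry strictly above ``s_min``."""
        if self.is_constant:
            return None
        return int(np.count_nonzero(self.s == self.s[0]))

    @property
    def n2(self) -> Optional[int]:
        """Position of the last entry strictly below ``s_max``."""
        if self.is_constant:
            return None
        return int(self.s.size - 1 - np.count_nonzero(self.s == self.s[-1]))


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the two-stage adaptive median filter.

    epsilon
        Positive integer in the adaptive threshold ``Q = S_med / epsilon``.
        Larger values lower the confirmation bar (more replacements).
    m0, m_max
        Initial and maximum odd window sides of the growth schedule.
    k1_variant
        ``as_printed`` uses ``S[N1]`` in the maximum-case ``K1`` numerator;
        ``symmetric`` restores min/max symmetry by using ``S[N2]``.
    confirm_rule
        ``k1_vs_q`` (default) or the stricter ``k1_vs_k2_and_q``.
    border_mode
        ``reflect`` (mirror without repeating the edge sample) or
        ``edge_replicate``.
    """

    epsilon: int = 2
    m0: int = 3
    m_max: int = 7
    k1_variant: str = "as_printed"
    confirm_rule: str = "k1_vs_q"
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        if int(self.epsilon) < 1 or self.epsilon != int(self.epsilon):
            raise ValueError(f"epsilon must be a positive integer, got {self.epsilon}")
        for name, m in (("m0", self.m0), ("m_max", self.m_max)):
            if m < 3 or m % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {m}")
        if self.m0 > self.m_max:
            raise ValueError(f"m0 ({self.m0}) must not exceed m_max ({self.m_max})")
        if self.k1_variant not in K1_VARIANTS:
            raise ValueError(f"k1_variant must be one of {K1_VARIANTS}")
        if self.confirm_rule not in CONFIRM_RULES:
            raise ValueError(f"confirm_rule must be one of {CONFIRM_RULES}")
        if self.border_mode not in _BORDER_MODES:
            raise ValueError(f"border_mode must be one of {tuple(_BORDER_MODES)}")


def _pad(arr: np.ndarray, radius: int, border_mode: str) -> np.ndarray:
    np_mode = _BORDER_MODES[border_mode][0]
    return np.pad(arr, radius, mode=np_mode)


def sorted_window(
    img: GrayImage, a: int, b: int, m: int = 3, border_mode: str = "reflect"
) -> WindowStats:
    """Sorted statistics of the ``m x m`` window centred on pixel ``(a, b)``."""
    if m < 3 or m % 2 == 0:
        raise ValueError(f"window side must be odd and >= 3, got {m}")
    if border_mode not in _BORDER_MODES:
        raise ValueError(f"border_mode must be one of {tuple(_BORDER_MODES)}")
    h, w = img.shape
    if not (0 <= a < h and 0 <= b < w):
        raise ValueError(f"pixel ({a}, {b}) outside image of shape {img.shape}")
    r = m // 2
    padded = _pad(img.pixels.astype(np.int64), r, border_mode)
    window = padded[a : a + m, b : b + m]
    return WindowStats(center=int(img.pixels[a, b]), s=np.sort(window, axis=None), m=m)


def classify_candidate(w: WindowStats) -> PixelLabel:
    """Stage-1 screen: quasi-noise iff the centre is a window extreme while
    the window median is not.  Constant windows are always signal."""
    if w.is_constant:
        return PixelLabel.SIGNAL
    extreme = w.center == w.s_min or w.center == w.s_max
    median_clean = w.s_min < w.s_med < w.s_max
    return PixelLabel.QUASI_NOISE if (extreme and median_clean) else PixelLabel.SIGNAL


def slope_k1(w: WindowStats, variant: str = "as_printed") -> float:
    """Local slope at an extreme-valued centre pixel.

    Minimum case: slope from ``S[N1]`` back to the middle of the run of
    minimum values.  Maximum case: numerator ``F - S[N1]`` (``as_printed``)
    or ``F - S[N2]`` (``symmetric``) over the ``M*M - 1 - N2`` maximum run.
    """
    if variant not in K1_VARIANTS:
        raise ValueError(f"variant must be one of {K1_VARIANTS}")
    n1, n2 = w.n1, w.n2
    if n1 is None or n2 is None:
        raise ValueError("K1 undefined for a constant window (n1/n2 undefined)")
    if w.center == w.s_min:
        return (int(w.s[n1]) - w.center) / ((n1 + 1) / 2)
    if w.center == w.s_max:
        ref = int(w.s[n1]) if variant == "as_printed" else int(w.s[n2])
        return (w.center - ref) / (w.m * w.m - 1 - n2)
    raise ValueError("K1 requires the centre pixel to be a window extreme")


def slope_k2(w: WindowStats) -> float:
    """Average interior slope ``(S[N2] - S[N1]) / (N2 - N1)``; 0 when the
    interior is flat or collapses to a single position."""
    n1, n2 = w.n1, w.n2
    if n1 is None or n2 is None:
        raise ValueError("K2 undefined for a constant window (n1/n2 undefined)")
    if n2 <= n1:
        return 0.0
    return (int(w.s[n2]) - int(w.s[n1])) / (n2 - n1)


def threshold_q(s_med: float, epsilon: int) -> float:
    """Adaptive confirmation threshold ``Q = S_med / epsilon``."""
    if int(epsilon) < 1 or epsilon != int(epsilon):
        raise ValueError(f"epsilon must be a positive integer, got {epsilon}")
    return s_med / epsilon


def confirm_noise(k1: float, k2: float, q: float, rule: str = "k1_vs_q") -> bool:
    """Stage-2 decision from the slopes and the adaptive threshold."""
    if rule == "k1_vs_q":
        return abs(k1) >= q
    if rule == "k1_vs_k2_and_q":
        return abs(k1) > abs(k2) and abs(k1) >= q
    raise ValueError(f"rule must be one of {CONFIRM_RULES}")


def _replacement_median(
    arr: np.ndarray,
    confirmed: np.ndarray,
    smed0: np.ndarray,
    smin0: np.ndarray,
    smax0: np.ndarray,
    params: FilterParams,
) -> np.ndarray:
    """Replacement values for confirmed pixels under the growth schedule."""
    out = arr.copy()
    remaining = confirmed.copy()
    ok0 = (smed0 > smin0) & (smed0 < smax0)
    take = remaining & ok0
    out[take] = smed0[take]
    remaining &= ~ok0
    sc_mode = _BORDER_MODES[params.border_mode][1]
    last_med = smed0
    for m in range(params.m0 + 2, params.m_max + 1, 2):
        if not remaining.any():
            break
        med = ndi.median_filter(arr, size=m, mode=sc_mode)
        mn = ndi.minimum_filter(arr, size=m, mode=sc_mode)
        mx = ndi.maximum_filter(arr, size=m, mode=sc_mode)
        ok = (med > mn) & (med < mx)
        take = remaining & ok
        out[take] = med[take]
        remaining &= ~ok
        last_med = med
    if remaining.any():
        if params.m_max > params.m0 and last_med is smed0:
            last_med = ndi.median_filter(arr, size=params.m_max, mode=sc_mode)
        out[remaining] = last_med[remaining]
    return out


def denoise(img: GrayImage, params: FilterParams | None = None) -> tuple[GrayImage, np.ndarray]:
    """Run the two-stage adaptive median filter over a whole image.

    Returns the filtered image together with the per-pixel label map
    (``uint8`` codes of :class:`PixelLabel`).  Signal pixels are copied
    bit-identically; only confirmed noise pixels are replaced.
    """
    params = params or FilterParams()
    arr = img.pixels.astype(np.int64)
    h, w = arr.shape
    m0 = params.m0
    mm = m0 * m0
    r0 = m0 // 2

    padded = _pad(arr, r0, params.border_mode)
    win = sliding_window_view(padded, (m0, m0)).reshape(h, w, mm)
    s = np.sort(win, axis=-1)
    smin = s[..., 0]
    smax = s[..., -1]
    smed = s[..., (mm - 1) // 2]

    n1 = (s == smin[..., None]).sum(axis=-1)          # first index > s_min
    n2 = mm - 1 - (s == smax[..., None]).sum(axis=-1)  # last index < s_max

    center = arr
    quasi = ((center == smin) | (center == smax)) & (smed > smin) & (smed < smax)

    sn1 = np.take_along_axis(s, np.minimum(n1, mm - 1)[..., None], -1)[..., 0]
    sn2 = np.take_along_axis(s, np.maximum(n2, 0)[..., None], -1)[..., 0]

    min_case = center == smin
    k1_min = (sn1 - center) / ((n1 + 1) / 2)
    max_ref = sn1 if params.k1_variant == "as_printed" else sn2
    k1_max = (center - max_ref) / (mm - 1 - n2)
    k1 = np.where(min_case, k1_min, k1_max)

    gap = n2 - n1
    k2 = np.where(gap > 0, (sn2 - sn1) / np.where(gap > 0, gap, 1), 0.0)
    q = smed / params.epsilon

    abs_k1 = np.abs(k1)
    if params.confirm_rule == "k1_vs_q":
        passed = abs_k1 >= q
    else:
        passed = (abs_k1 > np.abs(k2)) & (abs_k1 >= q)
    confirmed = quasi & passed

    labels = np.zeros((h, w), dtype=np.uint8)
    labels[quasi] = PixelLabel.QUASI_NOISE
    labels[confirmed] = PixelLabel.NOISE

    out = _replacement_median(arr, confirmed, smed, smin, smax, params)
    return GrayImage(out.astype(np.uint8), g_max=img.g_max), labels


def brute_force_denoise(
    img: GrayImage, params: FilterParams | None = None
) -> tuple[GrayImage, np.ndarray]:
    """Literal per-pixel transcription of the filtering rules (test oracle).

    Slow by design; intended for small images (<= 64 x 64).  Must agree with
    :func:`denoise` pixel-for-pixel.
    """
    params = params or FilterParams()
    h, w = img.shape
    out = img.pixels.copy()
    labels = np.zeros((h, w), dtype=np.uint8)
    for a in range(h):
        for b in range(w):
            stats = sorted_window(img, a, b, params.m0, params.border_mode)
            if classify_candidate(stats) is not PixelLabel.QUASI_NOISE:
                continue
            labels[a, b] = PixelLabel.QUASI_NOISE
            k1 = slope_k1(stats, params.k1_variant)
            k2 = slope_k2(stats)
            q = threshold_q(stats.s_med, params.epsilon)
            if not confirm_noise(k1, k2, q, params.confirm_rule):
                continue
            labels[a, b] = PixelLabel.NOISE
            replacement = None
            for m in range(params.m0, params.m_max + 1, 2):
                wm = stats if m == params.m0 else sorted_window(img, a, b, m, params.border_mode)
                if wm.s_min < wm.s_med < wm.s_max:
                    replacement = wm.s_med
                    break
            if replacement is None:
                replacement = sorted_window(img, a, b, params.m_max, params.border_mode).s_med
            out[a, b] = replacement
    return GrayImage(out, g_max=img.g_max), labels
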