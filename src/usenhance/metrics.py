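"""Full-reference image quality metrics: SNR, PSNR, MSE, and global SSIM.

All four compare a reference image ``r_i`` with a test image ``r_j`` of the
same shape over all ``G`` pixels:

    MSE  = sum_p (r_i(p) - r_j(p))^2 / G
    PSNR = 10 log10( G_max^2 / MSE )                               [dB]
    SNR  = 10 log10( sum_p (r_i(p) - mu_i)^2 / sum_p (r_i - r_j)^2 ) [dB]
    SSIM = l * c * s  with
           l = (2 mu_i mu_j + c1) / (mu_i^2 + mu_j^2 + c1)
           c = (2 sg_i sg_j + c2) / (sg_i^2 + sg_j^2 + c2)
           s = (cov_ij + c3)      / (sg_i sg_j + c3)

SSIM is computed *globally* — a single window spanning the whole image —
with population (divide-by-G) moments.  With the conventional choice
``c3 = c2 / 2`` the three-factor product reduces algebraically to the
familiar two-factor form ``(2 mu_i mu_j + c1)(2 cov + c2) /
((mu_i^2 + mu_j^2 + c1)(sg_i^2 + sg_j^2 + c2))``.

Identical images give ``MSE = 0``, ``PSNR = SNR = +inf`` and ``SSIM = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage

__all__ = ["SsimParams", "MetricRecord", "mse", "psnr", "snr", "ssim", "evaluate"]


@dataclass(frozen=True)
class SsimParams:
    """SSIM stabilisation constants.

    Defaults follow the standard convention ``c1 = (k1 G_max)^2``,
    ``c2 = (k2 G_max)^2`` with ``k1 = 0.01``, ``k2 = 0.03``, and
    ``c3 = c2 / 2``.
    """

    c1: float = (0.01 * 255.0) ** 2
    c2: float = (0.03 * 255.0) ** 2
    c3: float = (0.03 * 255.0) ** 2 / 2.0

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0 or self.c3 <= 0:
            raise ValueError("SSIM constants c1, c2, c3 must all be positive")

    @classmethod
    def from_k(cls, k1: float = 0.01, k2: float = 0.03, g_max: int = 255) -> "SsimParams":
        c2 = (k2 * g_max) ** 2
        return cls(c1=(k1 * g_max) ** 2, c2=c2, c3=c2 / 2.0)


@dataclass(frozen=True)
class MetricRecord:
    """One reference/test comparison: dB ratios, MSE, and SSIM."""

    snr_db: float
    psnr_db: float
    mse: float
    ssim: float

    def to_json_dict(self) -> dict:
        """JSON-safe dict; +infinity serialises as the string ``"inf"``."""
        out = {}
        for key, value in (
            ("snr_db", self.snr_db),
            ("psnr_db", self.psnr_db),
            ("mse", self.mse),
            ("ssim", self.ssim),
        ):
            out[key] = "inf" if math.isinf(value) else value
        return out


def _pair(ri: GrayImage | np.ndarray, rj: GrayImage | np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    g_max = 255
    if isinstance(ri, GrayImage):
        g_max = ri.g_max
    a = np.asarray(ri.pixels if isinstance(ri, GrayImage) else ri, dtype=np.float64)
    b = np.asarray(rj.pixels if isinstance(rj, GrayImage) else rj, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b, g_max


def mse(ri, rj) -> float:
    """Mean squared error per pixel."""
    a, b, _ = _pair(ri, rj)
    return float(np.mean((a - b) ** 2))


def psnr(ri, rj, g_max: int | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    a, b, gm = _pair(ri, rj)
    if g_max is not None:
        gm = g_max
    err = float(np.mean((a - b) ** 2))
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(gm * gm / err)


def snr(ri, rj) -> float:
    """Signal-to-noise ratio in dB, signal power taken about the reference mean.

    +inf when the residual is zero.  A constant reference with a nonzero
    residual has no defined signal power and raises ``ValueError``.
    """
    a, b, _ = _pair(ri, rj)
    residual = float(np.sum((a - b) ** 2))
    if residual == 0.0:
        return math.inf
    signal = float(np.sum((a - a.mean()) ** 2))
    if signal == 0.0:
        raise ValueError("SNR undefined: constant reference image with nonzero residual")
    return 10.0 * math.log10(signal / residual)


def ssim(ri, rj, params: SsimParams | None = None) -> float:
    """Global three-factor structural similarity index."""
    params = params or SsimParams()
    a, b, _ = _pair(ri, rj)
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()  # population (divide-by-G) moments
    sg_a, sg_b = math.sqrt(var_a), math.sqrt(var_b)
    cov = float(np.mean((a - mu_a) * (b - mu_b)))
    luminance = (2.0 * mu_a * mu_b + params.c1) / (mu_a**2 + mu_b**2 + params.c1)
    contrast = (2.0 * sg_a * sg_b + params.c2) / (var_a + var_b + params.c2)
    structure = (cov + params.c3) / (sg_a * sg_b + params.c3)
    return float(luminance * contrast * structure)


def evaluate(ri, rj, ssim_params: SsimParams | None = None) -> MetricRecord:
    """All four metrics of a reference/test pair in one record."""
    return MetricRecord(
        snr_db=snr(ri, rj),
        psnr_db=psnr(ri, rj),
        mse=mse(ri, rj),
        ssim=ssim(ri, rj, ssim_params),
    )
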