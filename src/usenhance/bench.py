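"""Seeded before/after benchmark over a grid of study conditions.

For every combination of impulse density, threshold divisor ``epsilon``,
gradient operator and replicate seed, the benchmark renders a phantom,
corrupts it, runs the full enhancement pipeline, and records the four
quality metrics of the noisy input, the denoised intermediate and the
enhanced output against the clean phantom, together with impulse-detection
recall and false-positive rate against the known corruption mask.

The design is paired: the same phantom (same replicate seed) underlies the
before/after comparison within every condition, and phantoms are shared
across conditions at equal replicate index.  All seeds derive from a single
base seed through ``numpy.random.SeedSequence``, so a rerun with the same
configuration reproduces the results table bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adaptive_median import FilterParams, PixelLabel
from .enhancement import EnhanceParams, run_pipeline
from .phantom import NoiseSpec, PhantomSpec, add_impulse_noise, make_phantom

__all__ = ["BenchConfig", "run_benchmark", "write_benchmark_csv", "summarize"]

logger = logging.getLogger(__name__)

_STAGES = ("noisy", "denoised", "enhanced")
_METRICS = ("snr_db", "psnr_db", "mse", "ssim")


@dataclass(frozen=True)
class BenchConfig:
    """Benchmark grid: conditions x replicates, plus the phantom template."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    densities: tuple[float, ...] = (0.05, 0.10, 0.20)
    epsilons: tuple[int, ...] = (1, 2, 4)
    operators: tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5")
    n_seeds: int = 20
    base_seed: int = 0
    noise_mode: str = "salt_and_pepper"
    gain: float = 1.0
    mask_method: str = "otsu"

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if not (self.densities and self.epsilons and self.operators):
            raise ValueError("densities, epsilons and operators must be non-empty")

    @property
    def n_runs(self) -> int:
        return len(self.densities) * len(self.epsilons) * len(self.operators) * self.n_seeds


def _child_seed(*keys: int) -> int:
    """Deterministic derived seed < 2^31 from integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] & 0x7FFFFFFF)


def run_benchmark(cfg: BenchConfig | None = None) -> pd.DataFrame:
    """Run the full grid; one row per (density, epsilon, operator, replicate)."""
    cfg = cfg or BenchConfig()
    rows: list[dict] = []
    for i in range(cfg.n_seeds):
        phantom_seed = _child_seed(cfg.base_seed, 1, i)
        spec = dataclasses.replace(cfg.phantom, seed=phantom_seed)
        clean, _structure = make_phantom(spec)
        n_pixels = clean.g
        for d_idx, density in enumerate(cfg.densities):
            noise_seed = _child_seed(cfg.base_seed, 2, i, d_idx)
            noisy, corrupted = add_impulse_noise(
                clean, NoiseSpec(density=density, mode=cfg.noise_mode, seed=noise_seed)
            )
            n_corrupted = int(corrupted.sum())
            for epsilon in cfg.epsilons:
                for operator in cfg.operators:
                    params = EnhanceParams(
                        filter_params=FilterParams(epsilon=epsilon),
                        operator_id=operator,
                        gain=cfg.gain,
                        mask_method=cfg.mask_method,
                    )
                    res = run_pipeline(noisy, params, reference=clean)
                    detected = res.labels == PixelLabel.NOISE
                    hits = int(np.count_nonzero(detected & corrupted))
                    false_pos = int(np.count_nonzero(detected & ~corrupted))
                    row = {
                        "density": density,
                        "epsilon": epsilon,
                        "operator": operator,
                        "replicate": i,
                        "phantom_seed": phantom_seed,
                        "noise_seed": noise_seed,
                        "n_corrupted": n_corrupted,
                        "n_detected": int(detected.sum()),
                        "recall": hits / n_corrupted if n_corrupted else float("nan"),
                        "false_positive_rate": false_pos / (n_pixels - n_corrupted),
                    }
                    assert res.metrics is not None
                    stage_records = {
                        "noisy": res.metrics["input"],
                        "denoised": res.metrics["denoised"],
                        "enhanced": res.metrics["output"],
                    }
                    for stage, rec in stage_records.items():
                        for metric in _METRICS:
                            row[f"{metric}_{stage}"] = getattr(rec, metric)
                    rows.append(row)
        logger.info("benchmark replicate %d/%d done", i + 1, cfg.n_seeds)
    return pd.DataFrame(rows)


def summarize(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-condition means and paired mean before/after differences."""
    cols = [f"{m}_{s}" for s in _STAGES for m in _METRICS] + ["recall", "false_positive_rate"]
    grouped = runs.groupby(["density", "epsilon", "operator"], as_index=False)[cols].mean()
    for metric in _METRICS:
        grouped[f"{metric}_diff"] = grouped[f"{metric}_enhanced"] - grouped[f"{metric}_noisy"]
    return grouped


def write_benchmark_csv(runs: pd.DataFrame, path: str, cfg: BenchConfig | None = None) -> None:
    """Write the per-run table with the configuration echoed as # comments."""
    buf = io.StringIO()
    if cfg is not None:
        for fld in dataclasses.fields(cfg):
            buf.write(f"# {fld.name} = {getattr(cfg, fld.name)!r}\n")
    runs.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
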