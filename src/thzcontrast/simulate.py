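"""Synthetic six-condition x two-modality spectral datasets.

The generator emulates the statistical structure the analysis assumes, not
terahertz physics: each condition's spectrum is a smooth per-modality
baseline, plus a per-sample-type offset, plus zero or more band-localized
effects, plus per-point noise.  Noise is i.i.d. Gaussian by default — the
independence that pairing-by-frequency-point implicitly assumes — with an
optional AR(1) mode to demonstrate how autocorrelation (pseudo-replication)
inflates the paired test.

Randomness comes from numpy's default PCG64 generator; a fixed seed gives
bit-identical datasets across runs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .bands import rank_bands
from .pipeline import (
    AnalysisConfig,
    run_cross_modality,
    run_pairwise,
)
from .spectral import (
    Band,
    FrequencyGrid,
    Modality,
    SampleType,
    SpectralDataset,
    Spectrum,
    all_conditions,
    default_band_edges,
)

__all__ = [
    "EffectShape",
    "EffectSpec",
    "SimConfig",
    "generate_dataset",
    "calibration_study",
    "power_study",
]

CALIBRATION_MIN_REPS = 500
POWER_MIN_REPS = 100

#: Default smooth baselines per modality (polynomial coefficients in
#: ascending degree, evaluated at frequency in THz).  ATR absorption rises
#: then flattens with frequency; transmission decays.  Arbitrary units —
#: only differences between conditions matter to the inference.
DEFAULT_BASELINES: dict[Modality, tuple[float, ...]] = {
    Modality.ATR: (0.5, 0.30, -0.04),
    Modality.TRANSMISSION: (1.2, -0.15, 0.01),
}


class EffectShape(enum.Enum):
    FLAT = "flat"
    GAUSSIAN_BUMP = "gaussian_bump"


@dataclass(frozen=True)
class EffectSpec:
    """A band-localized additive effect on one condition's spectrum.

    ``FLAT`` adds ``magnitude`` uniformly inside the band; ``GAUSSIAN_BUMP``
    adds a Gaussian profile centred at the band midpoint with width
    (hi − lo)/4, truncated to zero outside the band so band confinement is
    exact and testable.
    """

    target: tuple[Modality, SampleType]
    band: Band
    magnitude: float
    shape: EffectShape = EffectShape.FLAT

    def profile(self, grid: FrequencyGrid) -> np.ndarray:
        freq = grid.values
        inside = (freq >= self.band.lo) & (freq <= self.band.hi)
        out = np.zeros(freq.size)
        if self.shape is EffectShape.FLAT:
            out[inside] = self.magnitude
        else:
            center = 0.5 * (self.band.lo + self.band.hi)
            width = (self.band.hi - self.band.lo) / 4.0
            out[inside] = self.magnitude * np.exp(
                -0.5 * ((freq[inside] - center) / width) ** 2
            )
        return out


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic dataset.

    Defaults describe the global null: the instrument span 0.06–4 THz at
    0.01 THz spacing (395 points), equal condition offsets, no effects, and
    noise_sd 0.1 signal units per frequency point.
    """

    grid_start: float = 0.06
    grid_stop: float = 4.0
    grid_step: float = 0.01
    baselines: dict[Modality, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    condition_offsets: dict[SampleType, float] = field(
        default_factory=lambda: {s: 0.0 for s in SampleType}
    )
    effects: tuple[EffectSpec, ...] = ()
    noise_sd: float = 0.1
    noise_ar1: float = 0.0  # AR(1) coefficient; 0 = independent noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.grid_stop <= self.grid_start:
            raise ValueError("grid_stop must exceed grid_start")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (-1.0 < self.noise_ar1 < 1.0):
            raise ValueError("noise_ar1 must lie in (-1, 1)")

    def make_grid(self) -> FrequencyGrid:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return FrequencyGrid(self.grid_start + self.grid_step * np.arange(n))

    def is_null(self) -> bool:
        offsets = set(self.condition_offsets.values())
        return not self.effects and len(offsets) <= 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config not found: {path}")
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kwargs: dict = {}
        for key in ("grid_start", "grid_stop", "grid_step", "noise_sd", "noise_ar1"):
            if key in raw:
                kwargs[key] = float(raw[key])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "baselines" in raw:
            kwargs["baselines"] = {
                Modality(k.upper()): tuple(map(float, v))
                for k, v in raw["baselines"].items()
            }
        if "condition_offsets" in raw:
            offsets = {s: 0.0 for s in SampleType}
            for k, v in raw["condition_offsets"].items():
                offsets[SampleType(k.upper())] = float(v)
            kwargs["condition_offsets"] = offsets
        if "effects" in raw:
            effects = []
            for item in raw["effects"]:
                mod, samp = item["target"].split("/")
                effects.append(
                    EffectSpec(
                        target=(Modality(mod.upper()), SampleType(samp.upper())),
                        band=Band(float(item["band"][0]), float(item["band"][1])),
                        magnitude=float(item["magnitude"]),
                        shape=EffectShape(item.get("shape", "flat").lower()),
                    )
                )
            kwargs["effects"] = tuple(effects)
        return cls(**kwargs)


def _noise(rng: np.random.Generator, n: int, sd: float, ar1: float) -> np.ndarray:
    white = rng.normal(0.0, sd, size=n)
    if ar1 == 0.0:
        return white
    # stationary AR(1) with marginal sd equal to `sd`
    innov_sd_scale = np.sqrt(1.0 - ar1**2)
    out = np.empty(n)
    out[0] = white[0]
    for i in range(1, n):
        out[i] = ar1 * out[i - 1] + innov_sd_scale * white[i]
    return out


def generate_dataset(config: SimConfig) -> SpectralDataset:
    """Draw one dataset: twelve condition spectra on the configured grid.

    signal = baseline(modality) + offset(sample type) + sum of applicable
    effect profiles + noise.  Deterministic under a fixed ``config.seed``.
    """
    grid = config.make_grid()
    freq = grid.values
    rng = np.random.default_rng(config.seed)
    dataset = SpectralDataset(grid=grid)
    for modality, sample_type in all_conditions():
        coeffs = config.baselines.get(modality, (0.0,))
        baseline = np.polynomial.polynomial.polyval(freq, coeffs)
        signal = baseline + config.condition_offsets.get(sample_type, 0.0)
        for effect in config.effects:
            if effect.target == (modality, sample_type):
                signal = signal + effect.profile(grid)
        signal = signal + _noise(rng, freq.size, config.noise_sd, config.noise_ar1)
        dataset.add(
            Spectrum(modality=modality, sample_type=sample_type, grid=grid, signal=signal)
        )
    return dataset


def _replicate_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds below 2**31 for replicate datasets."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def calibration_study(
    config_null: SimConfig,
    n_reps: int,
    alpha: float = 0.05,
    analysis: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Empirical type-I error of every table cell on null datasets.

    Runs the complete analysis (full-domain and banded within-modality
    tables for both geometries, plus the banded cross-modality table) on
    ``n_reps`` independent null datasets and reports, per cell, the
    rejection rate at ``alpha`` with a binomial 95% confidence interval.
    """
    if n_reps < CALIBRATION_MIN_REPS:
        raise ValueError(f"n_reps below minimum ({CALIBRATION_MIN_REPS})")
    if not config_null.is_null():
        raise ValueError("calibration requires a null config: no effects, equal offsets")
    analysis = analysis or AnalysisConfig(alpha=alpha)
    edges = analysis.band_edges

    seeds = _replicate_seeds(config_null.seed, n_reps)
    counts: dict[tuple[str, str, str], int] = {}
    for seed in seeds:
        dataset = generate_dataset(replace(config_null, seed=int(seed)))
        tables = []
        for modality in Modality:
            tables.append((f"{modality.value} full", run_pairwise(dataset, modality, analysis)))
            tables.append((f"{modality.value} banded", run_pairwise(dataset, modality, analysis, bands=edges)))
        tables.append(("cross-modality banded", run_cross_modality(dataset, analysis, bands=edges)))
        for table_name, table in tables:
            sig = table.significant()
            for row in table.row_labels:
                for col in table.col_labels:
                    key = (table_name, row, col)
                    counts[key] = counts.get(key, 0) + int(sig.loc[row, col])

    from statsmodels.stats.proportion import proportion_confint

    rows = []
    for (table_name, row, col), k in counts.items():
        lo, hi = proportion_confint(k, n_reps, alpha=0.05, method="wilson")
        rows.append(
            {
                "table": table_name,
                "contrast": row,
                "band": col,
                "n_reps": n_reps,
                "rejections": k,
                "rate": k / n_reps,
                "ci95_lo": lo,
                "ci95_hi": hi,
            }
        )
    return pd.DataFrame(rows)


def _target_contrast(effect: EffectSpec) -> tuple[Modality, SampleType, SampleType]:
    """The with-NP vs without-NP contrast an effect is expected to move."""
    modality, sample_type = effect.target
    pairs = {
        SampleType.MEDIUM_NP: SampleType.MEDIUM,
        SampleType.NORMAL_NP: SampleType.NORMAL,
        SampleType.TUMOR_NP: SampleType.TUMOR,
    }
    if sample_type in pairs:
        return modality, pairs[sample_type], sample_type
    inverse = {v: k for k, v in pairs.items()}
    return modality, sample_type, inverse[sample_type]


def power_study(
    config_effect: SimConfig,
    n_reps: int,
    alpha: float = 0.05,
    band_edges: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-band power for the contrast targeted by the configured effect.

    For each replicate: the within-band signed-rank test of the targeted
    with/without-nanoparticle contrast, the within-modality DoD, and the
    band that ``rank_bands`` places first.  Returns a per-band table of
    empirical power and top-rank frequency.
    """
    if n_reps < POWER_MIN_REPS:
        raise ValueError(f"n_reps below minimum ({POWER_MIN_REPS})")
    if not config_effect.effects:
        raise ValueError("power study requires at least one configured effect")
    edges = tuple(band_edges) if band_edges is not None else default_band_edges()
    modality, base, with_np = _target_contrast(config_effect.effects[0])
    analysis = AnalysisConfig(alpha=alpha, band_edges=edges)

    seeds = _replicate_seeds(config_effect.seed, n_reps)
    band_labels: list[str] | None = None
    contrast_hits = None
    dod_hits = None
    top_counts = None
    for seed in seeds:
        dataset = generate_dataset(replace(config_effect, seed=int(seed)))
        ranking = rank_bands(
            dataset.get(modality, base), dataset.get(modality, with_np), edges
        )
        if band_labels is None:
            band_labels = [b.label for b in ranking.bands]
            contrast_hits = np.zeros(len(band_labels), dtype=int)
            dod_hits = np.zeros(len(band_labels), dtype=int)
            top_counts = np.zeros(len(band_labels), dtype=int)
        contrast_hits += np.array([r.p_value < alpha for r in ranking.results])
        top_counts[int(ranking.order[0])] += 1
        table = run_pairwise(dataset, modality, analysis, bands=edges)
        dod_p = table.p_values().loc["Difference in differences"].to_numpy()
        dod_hits += dod_p < alpha

    return pd.DataFrame(
        {
            "band": band_labels,
            "n_reps": n_reps,
            "power_contrast": contrast_hits / n_reps,
            "power_dod": dod_hits / n_reps,
            "top_ranked_fraction": top_counts / n_reps,
        }
    )
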