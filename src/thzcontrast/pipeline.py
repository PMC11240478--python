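"""Inference pipeline: pairwise contrasts, difference series, band-segmented
testing, and difference-of-differences (DoD) tests.

The procedure treats each frequency point of a spectrum pair as one paired
observation and applies the signed-rank test:

* five within-modality contrasts (medium vs medium+NP, normal vs normal+NP,
  tumor vs tumor+NP, normal vs tumor, normal+NP vs tumor+NP), over the whole
  frequency domain and within 1-THz bands;
* a within-modality DoD: is the (tumor − normal) gap different with
  nanoparticles than without?  Tested as signed-rank of
  (tumor+NP − normal+NP) against (tumor − normal);
* a cross-modality DoD comparing the named difference series d1..d8 between
  the ATR and transmission geometries (d1−d2, d3−d4, d5−d6, d7−d8).

Caveat: adjacent frequency points of a spectrum are autocorrelated, so
treating each point as an independent pair inflates the effective sample
size (pseudo-replication).  ``AnalysisConfig.decimate_step`` keeps every
k-th point as a blunt mitigation; the default of 1 reproduces the
full-resolution procedure.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signed_rank import Method, SignedRankResult, signed_rank_test
from .spectral import (
    Band,
    FrequencyGrid,
    Modality,
    SampleType,
    SpectralDataset,
    Spectrum,
    default_band_edges,
    segment_bands,
)

__all__ = [
    "ContrastSpec",
    "DifferenceSeries",
    "DifferenceId",
    "ComparisonTable",
    "AnalysisConfig",
    "Correction",
    "standard_contrasts",
    "build_difference_series",
    "run_pairwise",
    "run_cross_modality",
    "dod_within_modality",
    "dod_cross_modality",
    "flag_significance",
    "CONTRAST_LABELS",
    "DOD_ROW_LABEL",
    "ENTIRE_DOMAIN_LABEL",
]

DOD_ROW_LABEL = "Difference in differences"
ENTIRE_DOMAIN_LABEL = "Entire domain"

#: Row labels of the full-domain tables, in reporting order.  The support
#: medium contrast appears only in full-domain tables; the banded tables
#: report the four cell contrasts plus the DoD row.
CONTRAST_LABELS = (
    "Support medium (without cells) vs. support medium with nanoparticles",
    "Normal cells vs. normal cells with nanoparticles",
    "Tumor cells vs. tumor cells with nanoparticles",
    "Normal cells vs. tumor cells",
    "Normal cells with nanoparticles vs. tumor cells with nanoparticles",
)

_CONTRAST_PAIRS = (
    (SampleType.MEDIUM, SampleType.MEDIUM_NP),
    (SampleType.NORMAL, SampleType.NORMAL_NP),
    (SampleType.TUMOR, SampleType.TUMOR_NP),
    (SampleType.NORMAL, SampleType.TUMOR),
    (SampleType.NORMAL_NP, SampleType.TUMOR_NP),
)


class Correction(enum.Enum):
    NONE = "none"
    HOLM = "holm"


class DifferenceId(enum.Enum):
    """Named per-frequency difference series between two conditions."""

    D1 = "d1"
    D2 = "d2"
    D3 = "d3"
    D4 = "d4"
    D5 = "d5"
    D6 = "d6"
    D7 = "d7"
    D8 = "d8"


#: Registry id -> (minuend condition, subtrahend condition).  Sign
#: conventions are frozen: tumor minus normal, with-NP minus without-NP,
#: and within each cross-modality pair the ATR-derived series comes first.
DIFFERENCE_REGISTRY: dict[DifferenceId, tuple[tuple[Modality, SampleType], tuple[Modality, SampleType]]] = {
    DifferenceId.D1: ((Modality.ATR, SampleType.TUMOR), (Modality.ATR, SampleType.NORMAL)),
    DifferenceId.D2: ((Modality.TRANSMISSION, SampleType.TUMOR), (Modality.TRANSMISSION, SampleType.NORMAL)),
    DifferenceId.D3: ((Modality.ATR, SampleType.NORMAL_NP), (Modality.ATR, SampleType.NORMAL)),
    DifferenceId.D4: ((Modality.TRANSMISSION, SampleType.NORMAL_NP), (Modality.TRANSMISSION, SampleType.NORMAL)),
    DifferenceId.D5: ((Modality.ATR, SampleType.TUMOR_NP), (Modality.ATR, SampleType.TUMOR)),
    DifferenceId.D6: ((Modality.TRANSMISSION, SampleType.TUMOR_NP), (Modality.TRANSMISSION, SampleType.TUMOR)),
    DifferenceId.D7: ((Modality.ATR, SampleType.TUMOR_NP), (Modality.ATR, SampleType.NORMAL_NP)),
    DifferenceId.D8: ((Modality.TRANSMISSION, SampleType.TUMOR_NP), (Modality.TRANSMISSION, SampleType.NORMAL_NP)),
}

#: Cross-modality DoD rows: each pairs an ATR-derived difference series with
#: its transmission counterpart.
CROSS_MODALITY_PAIRS: dict[str, tuple[DifferenceId, DifferenceId]] = {
    "d1–d2": (DifferenceId.D1, DifferenceId.D2),
    "d3–d4": (DifferenceId.D3, DifferenceId.D4),
    "d5–d6": (DifferenceId.D5, DifferenceId.D6),
    "d7–d8": (DifferenceId.D7, DifferenceId.D8),
}


@dataclass(frozen=True)
class ContrastSpec:
    """One pairwise comparison between two (modality, sample type) conditions."""

    label: str
    left: tuple[Modality, SampleType]
    right: tuple[Modality, SampleType]

    def __post_init__(self) -> None:
        if self.left == self.right:
            raise ValueError("contrast requires two distinct conditions")


@dataclass(frozen=True)
class DifferenceSeries:
    """Per-frequency difference (minuend − subtrahend) on the dataset grid."""

    id: DifferenceId
    grid: FrequencyGrid
    values: np.ndarray
    definition: tuple[tuple[Modality, SampleType], tuple[Modality, SampleType]]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.size != len(self.grid):
            raise ValueError("difference series length does not match grid")


@dataclass
class AnalysisConfig:
    """Knobs of the inference procedure.

    alpha: strict significance threshold (p < alpha flags a cell).
    band_edges: edges of the frequency windows for banded tables.
    correction: optional Holm step-down adjustment across a table's cells
        (the default NONE reports raw p-values per cell).
    decimate_step: keep every k-th grid point before testing, to blunt the
        pseudo-replication from spectral autocorrelation (1 = use all).
    """

    alpha: float = 0.05
    band_edges: tuple[float, ...] = field(default_factory=default_band_edges)
    correction: Correction = Correction.NONE
    decimate_step: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        edges = np.asarray(self.band_edges, dtype=float)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("band_edges must be strictly increasing, length >= 2")
        if self.decimate_step < 1:
            raise ValueError("decimate_step must be a positive integer")


@dataclass
class ComparisonTable:
    """Grid of signed-rank results: contrast rows x band columns.

    The machine analog of the study's p-value tables; ``cells[i][j]`` holds
    the full test result for row i in band j, ``cell_sizes`` the number of
    paired frequency points that entered each cell.  When Holm correction is
    requested the adjusted p-values are stored alongside and drive the
    significance flags; raw per-cell p-values always remain available.
    """

    row_labels: list[str]
    col_labels: list[str]
    cells: list[list[SignedRankResult]]
    cell_sizes: np.ndarray
    alpha: float = 0.05
    p_adjusted: np.ndarray | None = None

    def p_values(self) -> pd.DataFrame:
        data = [[cell.p_value for cell in row] for row in self.cells]
        return pd.DataFrame(data, index=self.row_labels, columns=self.col_labels)

    def effective_p_values(self) -> pd.DataFrame:
        if self.p_adjusted is not None:
            return pd.DataFrame(
                self.p_adjusted, index=self.row_labels, columns=self.col_labels
            )
        return self.p_values()

    def significant(self) -> pd.DataFrame:
        p = self.effective_p_values()
        return p.lt(self.alpha)

    def to_csv(self, path: str | Path) -> None:
        frame = self.p_values().copy()
        frame.insert(0, "row", frame.index)
        frame.to_csv(path, index=False, float_format="%.6g")

    def render(self) -> str:
        """Aligned plain-text table with trailing ``*`` significance flags."""
        p = self.effective_p_values()
        sig = self.significant()
        header = ["Sample Type"] + list(self.col_labels)
        rows = [header]
        for label in self.row_labels:
            cells = [label]
            for col in self.col_labels:
                star = " *" if bool(sig.loc[label, col]) else ""
                cells.append(f"{p.loc[label, col]:.4f}{star}")
            rows.append(cells)
        widths = [max(len(r[c]) for r in rows) for c in range(len(header))]
        lines = []
        for r in rows:
            lines.append("  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip())
        return "\n".join(lines) + "\n"


def flag_significance(p: float, alpha: float) -> bool:
    """Strict significance rule: flag iff p < alpha."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value out of [0, 1]: {p}")
    return p < alpha


def standard_contrasts(modality: Modality) -> list[ContrastSpec]:
    """The five within-modality pairwise contrasts, in reporting order."""
    out = []
    for label, (left, right) in zip(CONTRAST_LABELS, _CONTRAST_PAIRS):
        out.append(
            ContrastSpec(label=label, left=(modality, left), right=(modality, right))
        )
    return out


def build_difference_series(
    dataset: SpectralDataset, series_id: DifferenceId | str
) -> DifferenceSeries:
    """Materialize one of the named difference series d1..d8."""
    if isinstance(series_id, str):
        try:
            series_id = DifferenceId(series_id.lower())
        except ValueError:
            raise ValueError(f"unknown difference id: {series_id!r}") from None
    minuend_key, subtrahend_key = DIFFERENCE_REGISTRY[series_id]
    minuend = dataset.get(*minuend_key)
    subtrahend = dataset.get(*subtrahend_key)
    return DifferenceSeries(
        id=series_id,
        grid=dataset.grid,
        values=minuend.signal - subtrahend.signal,
        definition=(minuend_key, subtrahend_key),
    )


def _band_index_sets(
    dataset: SpectralDataset,
    bands: Sequence[float] | None,
    decimate_step: int,
) -> tuple[list[str], list[np.ndarray]]:
    """Column labels and (decimated) grid-index sets, full domain if bands is None."""
    if bands is None:
        idx = np.arange(len(dataset.grid))[::decimate_step]
        return [ENTIRE_DOMAIN_LABEL], [idx]
    mapping = segment_bands(dataset.grid, bands)
    labels, sets = [], []
    for band, idx in mapping.items():
        idx = idx[::decimate_step]
        if idx.size < 2:
            raise ValueError(
                f"band {band.label} has fewer than 2 usable grid points"
            )
        labels.append(band.label)
        sets.append(idx)
    return labels, sets


def _test_on(idx: np.ndarray, a: np.ndarray, b: np.ndarray) -> SignedRankResult:
    if idx.size < 2:
        raise ValueError("fewer than 2 paired points in the requested band")
    return signed_rank_test(a[idx], b[idx])


def _holm_adjust(p_flat: np.ndarray) -> np.ndarray:
    # statsmodels' multipletests is the standard route; imported lazily so
    # plain pipeline runs do not pay for it.
    from statsmodels.stats.multitest import multipletests

    return multipletests(p_flat, method="holm")[1]


def _finalize_table(
    row_labels: list[str],
    col_labels: list[str],
    cells: list[list[SignedRankResult]],
    sizes: np.ndarray,
    config: AnalysisConfig,
) -> ComparisonTable:
    p_adj = None
    if config.correction is Correction.HOLM:
        raw = np.array([[c.p_value for c in row] for row in cells])
        p_adj = _holm_adjust(raw.ravel()).reshape(raw.shape)
    return ComparisonTable(
        row_labels=row_labels,
        col_labels=col_labels,
        cells=cells,
        cell_sizes=sizes,
        alpha=config.alpha,
        p_adjusted=p_adj,
    )


def run_pairwise(
    dataset: SpectralDataset,
    modality: Modality,
    config: AnalysisConfig | None = None,
    bands: Sequence[float] | None = None,
) -> ComparisonTable:
    """Within-modality comparison table: contrasts x bands plus a DoD row.

    With ``bands=None`` every contrast is tested over the entire frequency
    domain (the full-domain tables include the support-medium contrast, six
    rows in all).  With band edges supplied, the four cell contrasts and the
    DoD row are tested within each band.
    """
    config = config or AnalysisConfig()
    contrasts = standard_contrasts(modality)
    if bands is not None:
        contrasts = contrasts[1:]  # banded tables omit the support-medium row
    col_labels, index_sets = _band_index_sets(dataset, bands, config.decimate_step)

    cells: list[list[SignedRankResult]] = []
    for contrast in contrasts:
        left = dataset.get(*contrast.left)
        right = dataset.get(*contrast.right)
        cells.append([_test_on(idx, left.signal, right.signal) for idx in index_sets])

    dod_row = []
    for idx in index_sets:
        dod_row.append(_dod_within_on_indices(dataset, modality, idx))
    cells.append(dod_row)

    row_labels = [c.label for c in contrasts] + [DOD_ROW_LABEL]
    sizes = np.array([[idx.size for idx in index_sets]] * len(row_labels))
    return _finalize_table(row_labels, col_labels, cells, sizes, config)


def _dod_within_on_indices(
    dataset: SpectralDataset, modality: Modality, idx: np.ndarray
) -> SignedRankResult:
    a = (
        dataset.get(modality, SampleType.TUMOR_NP).signal
        - dataset.get(modality, SampleType.NORMAL_NP).signal
    )
    b = (
        dataset.get(modality, SampleType.TUMOR).signal
        - dataset.get(modality, SampleType.NORMAL).signal
    )
    return _test_on(idx, a, b)


def dod_within_modality(
    dataset: SpectralDataset,
    modality: Modality,
    band: Band | None = None,
    decimate_step: int = 1,
) -> SignedRankResult:
    """Difference-of-differences within one modality.

    Tests whether nanoparticles change the tumor-vs-normal contrast:
    signed-rank of A = (tumor+NP − normal+NP) against B = (tumor − normal),
    optionally restricted to a frequency band.
    """
    idx = _restrict(dataset.grid, band, decimate_step)
    return _dod_within_on_indices(dataset, modality, idx)


def dod_cross_modality(
    dataset: SpectralDataset,
    pair: str,
    band: Band | None = None,
    decimate_step: int = 1,
) -> SignedRankResult:
    """Cross-modality DoD: one of the pairs d1−d2, d3−d4, d5−d6, d7−d8.

    Compares an ATR-derived difference series against its transmission
    counterpart; a significant result means the two geometries disagree on
    that contrast.
    """
    key = pair.replace("-", "–")
    if key not in CROSS_MODALITY_PAIRS:
        raise ValueError(
            f"unknown pair id {pair!r}; expected one of {sorted(CROSS_MODALITY_PAIRS)}"
        )
    atr_id, trans_id = CROSS_MODALITY_PAIRS[key]
    a = build_difference_series(dataset, atr_id).values
    b = build_difference_series(dataset, trans_id).values
    idx = _restrict(dataset.grid, band, decimate_step)
    return _test_on(idx, a, b)


def run_cross_modality(
    dataset: SpectralDataset,
    config: AnalysisConfig | None = None,
    bands: Sequence[float] | None = None,
) -> ComparisonTable:
    """Cross-modality DoD table: the four d-pairs x bands (or full domain)."""
    config = config or AnalysisConfig()
    col_labels, index_sets = _band_index_sets(dataset, bands, config.decimate_step)
    cells = []
    for pair, (atr_id, trans_id) in CROSS_MODALITY_PAIRS.items():
        a = build_difference_series(dataset, atr_id).values
        b = build_difference_series(dataset, trans_id).values
        cells.append([_test_on(idx, a, b) for idx in index_sets])
    row_labels = list(CROSS_MODALITY_PAIRS)
    sizes = np.array([[idx.size for idx in index_sets]] * len(row_labels))
    return _finalize_table(row_labels, col_labels, cells, sizes, config)


def _restrict(
    grid: FrequencyGrid, band: Band | None, decimate_step: int
) -> np.ndarray:
    if band is None:
        idx = np.arange(len(grid))
    else:
        freq = grid.values
        # half-open [lo, hi), closed at hi when the band reaches the grid end
        if band.hi >= freq[-1]:
            idx = np.flatnonzero((freq >= band.lo) & (freq <= band.hi))
        else:
            idx = np.flatnonzero((freq >= band.lo) & (freq < band.hi))
    idx = idx[::decimate_step]
    if idx.size < 2:
        raise ValueError("fewer than 2 usable grid points in the requested band")
    return idx
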