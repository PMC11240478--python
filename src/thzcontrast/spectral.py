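"""Core domain types for gridded terahertz spectra.

A measurement campaign produces one spectrum per experimental condition:
two measurement modalities (attenuated total reflection and transmission)
crossed with six sample types (support medium, normal gastric cells, gastric
tumor cells — each with and without contrast nanoparticles).  All spectra in
a dataset share a single strictly increasing frequency grid, because the
downstream paired tests match observations frequency-by-frequency; spectra
on different grids are rejected rather than resampled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "SampleType",
    "FrequencyGrid",
    "Spectrum",
    "SpectralDataset",
    "Band",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "align_dataset",
    "segment_bands",
    "default_band_edges",
]

#: Sanity bound on frequencies, in THz.  The instrument range is 0.06-4 THz;
#: anything outside [0, 10] is almost certainly a unit error (e.g. GHz or
#: wavenumber passed as THz).
MAX_FREQUENCY_THZ = 10.0

CSV_HEADER = ("frequency_thz", "value")


class Modality(enum.Enum):
    """Measurement geometry of a THz spectrum."""

    ATR = "ATR"
    TRANSMISSION = "TRANSMISSION"


class SampleType(enum.Enum):
    """Biological condition measured: medium, normal or tumor cells,
    each optionally incubated with contrast nanoparticles (``_NP``)."""

    MEDIUM = "MEDIUM"
    MEDIUM_NP = "MEDIUM_NP"
    NORMAL = "NORMAL"
    NORMAL_NP = "NORMAL_NP"
    TUMOR = "TUMOR"
    TUMOR_NP = "TUMOR_NP"


@dataclass(frozen=True)
class FrequencyGrid:
    """Shared, strictly increasing frequency axis in THz."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("frequency grid needs at least 2 points")
        if not np.all(np.isfinite(values)):
            raise ValueError("frequency grid contains non-finite values")
        if np.any(np.diff(values) <= 0):
            raise ValueError("grid not strictly increasing")
        if values[0] < 0.0 or values[-1] > MAX_FREQUENCY_THZ:
            raise ValueError(
                f"frequencies must lie in [0, {MAX_FREQUENCY_THZ}] THz; "
                f"got span [{values[0]}, {values[-1]}]"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


@dataclass(frozen=True)
class Spectrum:
    """One condition's signal (arbitrary units) over a frequency grid."""

    modality: Modality
    sample_type: SampleType
    grid: FrequencyGrid
    signal: np.ndarray

    def __post_init__(self) -> None:
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", signal)
        if signal.ndim != 1 or signal.size != len(self.grid):
            raise ValueError(
                f"signal length {signal.size} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def condition(self) -> tuple[Modality, SampleType]:
        return (self.modality, self.sample_type)


@dataclass
class SpectralDataset:
    """Collection of spectra on one shared grid, at most one spectrum per
    (modality, sample type) condition."""

    grid: FrequencyGrid
    spectra: dict[tuple[Modality, SampleType], Spectrum] = field(default_factory=dict)

    def add(self, spectrum: Spectrum) -> None:
        if spectrum.grid != self.grid:
            raise ValueError("grid mismatch: spectrum grid differs from dataset grid")
        key = spectrum.condition
        if key in self.spectra:
            raise ValueError(
                f"duplicate condition ({key[0].value}, {key[1].value})"
            )
        self.spectra[key] = spectrum

    def get(self, modality: Modality, sample_type: SampleType) -> Spectrum:
        try:
            return self.spectra[(modality, sample_type)]
        except KeyError:
            raise KeyError(
                f"missing condition ({modality.value}, {sample_type.value})"
            ) from None

    def __contains__(self, key: tuple[Modality, SampleType]) -> bool:
        return key in self.spectra

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass(frozen=True)
class Band:
    """Frequency window [lo, hi) in THz.

    Membership is half-open so that adjacent bands of a partition never
    double-count an edge frequency; the *final* band of a partition is closed
    at ``hi`` so the last grid point is not orphaned.
    """

    lo: float
    hi: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.lo < self.hi):
            raise ValueError(f"band requires lo < hi, got [{self.lo}, {self.hi}]")
        if not self.label:
            object.__setattr__(self, "label", format_band_label(self.lo, self.hi))


def format_band_label(lo: float, hi: float) -> str:
    """Render a band as e.g. ``"0.06–1 THz"`` (en dash, trailing unit)."""

    def fmt(x: float) -> str:
        return f"{x:g}"

    return f"{fmt(lo)}–{fmt(hi)} THz"


def default_band_edges() -> tuple[float, ...]:
    """The four 1-THz analysis windows spanning the instrument range."""
    return (0.06, 1.0, 2.0, 3.0, 4.0)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: comma separator, dot decimal, single header row
# "frequency_thz,value".  Floats are written with repr-level precision so a
# write/read round trip is bit-exact.

def read_spectrum_csv(
    path: str | Path, modality: Modality, sample_type: SampleType
) -> Spectrum:
    """Read a two-column (frequency THz, signal) CSV into a :class:`Spectrum`.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` for
    non-numeric cells, fewer than 2 data rows, or a frequency column that is
    not strictly increasing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    try:
        frame = pd.read_csv(path, header=0, dtype=float, float_precision="round_trip")
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: expected two numeric columns")
    if frame.shape[0] < 2:
        raise ValueError(f"{path}: fewer than 2 points")
    freq = frame.iloc[:, 0].to_numpy(dtype=float)
    signal = frame.iloc[:, 1].to_numpy(dtype=float)
    if np.any(~np.isfinite(freq)) or np.any(np.diff(freq) <= 0):
        raise ValueError(f"{path}: grid not strictly increasing")
    grid = FrequencyGrid(freq)
    return Spectrum(modality=modality, sample_type=sample_type, grid=grid, signal=signal)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum in the two-column CSV dialect (bit-exact round trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as handle:
        handle.write(",".join(CSV_HEADER) + "\n")
        for f, v in zip(spectrum.grid.values, spectrum.signal):
            # repr of a Python float is the shortest exact decimal: the
            # round trip is bit-exact for every double
            handle.write(f"{float(f)!r},{float(v)!r}\n")


def align_dataset(spectra: Iterable[Spectrum]) -> SpectralDataset:
    """Assemble spectra sharing an identical grid into a dataset.

    No resampling is performed: a grid that differs at even one point is an
    error, because the paired test downstream requires genuine point-for-point
    pairing and interpolation would manufacture pairs.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot align an empty collection of spectra")
    dataset = SpectralDataset(grid=spectra[0].grid)
    for spectrum in spectra:
        dataset.add(spectrum)
    return dataset


def segment_bands(
    grid: FrequencyGrid, edges: Sequence[float]
) -> dict[Band, np.ndarray]:
    """Partition grid indices into contiguous frequency bands.

    ``edges`` of length k+1 define k bands; band j covers [edges[j],
    edges[j+1]) except the last band, which is closed at the top edge.
    Returns an ordered mapping band -> sorted integer indices.  A band that
    captures no grid point is an error — a p-value cannot come from an empty
    window.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("need at least two band edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("band edges must be strictly increasing")
    freq = grid.values
    out: dict[Band, np.ndarray] = {}
    n_bands = edges.size - 1
    for j in range(n_bands):
        lo, hi = float(edges[j]), float(edges[j + 1])
        if j == n_bands - 1:
            mask = (freq >= lo) & (freq <= hi)
        else:
            mask = (freq >= lo) & (freq < hi)
        idx = np.flatnonzero(mask)
        band = Band(lo=lo, hi=hi)
        if idx.size == 0:
            raise ValueError(f"empty band {band.label}: no grid points inside")
        out[band] = idx
    return out


def condition_label(modality: Modality, sample_type: SampleType) -> str:
    """Stable string key ``"ATR/TUMOR_NP"`` used in manifests and reports."""
    return f"{modality.value}/{sample_type.value}"


def parse_condition_label(label: str) -> tuple[Modality, SampleType]:
    try:
        mod_str, samp_str = label.split("/")
        return Modality(mod_str), SampleType(samp_str)
    except ValueError:
        raise ValueError(f"malformed condition label: {label!r}") from None


def all_conditions() -> list[tuple[Modality, SampleType]]:
    """The twelve (modality, sample type) conditions in a fixed order."""
    return [(m, s) for m in Modality for s in SampleType]
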