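"""Data containers and CSV I/O for absorbance spectra and concentration tables.

The package works on first-order (full-spectrum) data: each sample is a
vector of absorbances on a shared, uniform wavelength grid, and each sample
has reference concentrations for one or more analytes in mg/L.

CSV conventions
---------------
Spectra are stored wide-by-sample: first column ``wavelength_nm``, one
additional column per sample, comma separated, ``.`` decimal, header row
required.  Concentration tables have a ``sample_id`` column followed by one
column per analyte (mg/L).

Wavelength windows are half-open, ``[low, high)``: restricting a 1-nm grid
to [225, 390) keeps 165 points (225..389).  Absorbances are stored as read —
no baseline correction, and negative values are legal (blank-subtracted
data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridError",
    "ParseError",
    "WindowError",
    "WavelengthGrid",
    "SpectraSet",
    "ConcentrationTable",
    "load_spectra",
    "write_spectra",
    "load_concentrations",
    "write_concentrations",
    "restrict_window",
]


class GridError(ValueError):
    """Wavelength grid is non-uniform, mismatched, or otherwise invalid."""


class ParseError(ValueError):
    """A CSV cell could not be interpreted."""


class WindowError(ValueError):
    """Requested wavelength window does not intersect the grid."""


_GRID_RTOL = 1e-9


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid: value_i = start_nm + i * step_nm."""

    start_nm: float
    step_nm: float
    n_points: int

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise GridError(f"step_nm must be positive, got {self.step_nm}")
        if self.n_points < 1:
            raise GridError(f"n_points must be >= 1, got {self.n_points}")

    @property
    def stop_nm(self) -> float:
        """Last grid value (inclusive)."""
        return self.start_nm + (self.n_points - 1) * self.step_nm

    def values(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    @classmethod
    def from_values(cls, wl: np.ndarray) -> "WavelengthGrid":
        wl = np.asarray(wl, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise GridError("wavelength axis must be a non-empty 1-D array")
        if wl.size == 1:
            return cls(float(wl[0]), 1.0, 1)
        steps = np.diff(wl)
        step = float(steps[0])
        if step <= 0 or not np.allclose(steps, step, rtol=_GRID_RTOL, atol=1e-9):
            raise GridError(
                "wavelength axis is not a uniform increasing grid "
                f"(first values: {wl[: min(5, wl.size)].tolist()})"
            )
        return cls(float(wl[0]), step, int(wl.size))


@dataclass
class SpectraSet:
    """A set of absorbance spectra on a shared grid.

    ``absorbance`` is (n_samples, n_points) in AU; row order is sample order.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[1] != self.grid.n_points:
            raise GridError(
                f"spectra have {self.absorbance.shape[1]} points but the grid "
                f"has {self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance values must be finite")
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(self.n_samples)]
        if len(self.sample_ids) != self.n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {self.n_samples} spectra"
            )

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.n_points

    def wavelengths(self) -> np.ndarray:
        return self.grid.values()


@dataclass
class ConcentrationTable:
    """Reference (actual) concentrations, samples x analytes, mg/L."""

    values: np.ndarray
    analyte_names: list[str]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.analyte_names):
            raise ValueError(
                f"{self.values.shape[1]} columns for "
                f"{len(self.analyte_names)} analyte names"
            )
        if np.any(self.values < 0):
            raise ValueError("reference concentrations must be >= 0")
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1}" for i in range(self.n_samples)]
        if len(self.sample_ids) != self.n_samples:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, analyte: str) -> np.ndarray:
        """Concentration vector (mg/L) for one analyte."""
        try:
            j = self.analyte_names.index(analyte)
        except ValueError:
            raise KeyError(
                f"unknown analyte {analyte!r}; have {self.analyte_names}"
            ) from None
        return self.values[:, j].copy()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

WAVELENGTH_COLUMN = "wavelength_nm"


def load_spectra(path, layout: str = "wide_by_sample") -> SpectraSet:
    """Read a wide-format spectra CSV (wavelength rows, sample columns)."""
    if layout != "wide_by_sample":
        raise ValueError(f"unsupported layout {layout!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a wavelength column plus >=1 sample column")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            row = int(bad[0]) + 2 if len(bad) else "?"  # +2: header + 1-based
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, file row {row}"
            ) from exc
    grid = WavelengthGrid.from_values(df.iloc[:, 0].to_numpy())
    sample_ids = [str(c) for c in df.columns[1:]]
    absorbance = df.iloc[:, 1:].to_numpy(dtype=float).T
    return SpectraSet(grid=grid, absorbance=absorbance, sample_ids=sample_ids)


def write_spectra(s: SpectraSet, path) -> None:
    """Write a SpectraSet in the wide-by-sample CSV layout."""
    df = pd.DataFrame({WAVELENGTH_COLUMN: s.wavelengths()})
    for i, sid in enumerate(s.sample_ids):
        df[sid] = s.absorbance[i]
    # %.17g keeps the write/read round trip lossless for float64
    df.to_csv(path, index=False, float_format="%.17g")


def load_concentrations(path) -> ConcentrationTable:
    """Read a concentration CSV: sample_id, <analyte_1>, <analyte_2>, ..."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need sample_id plus >=1 analyte column")
    sample_ids = [str(v) for v in df.iloc[:, 0]]
    analytes = [str(c) for c in df.columns[1:]]
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-numeric concentration value") from exc
    return ConcentrationTable(values=values, analyte_names=analytes, sample_ids=sample_ids)


def write_concentrations(c: ConcentrationTable, path) -> None:
    df = pd.DataFrame(c.values, columns=c.analyte_names)
    df.insert(0, "sample_id", c.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def restrict_window(s: SpectraSet, low_nm: float, high_nm: float) -> SpectraSet:
    """Keep grid points p with low_nm <= p < high_nm (half-open window).

    The half-open convention means a [225, 390) window on a 1-nm grid keeps
    165 points; it is idempotent and preserves sample order and ids.
    """
    wl = s.wavelengths()
    mask = (wl >= low_nm) & (wl < high_nm)
    if not mask.any():
        raise WindowError(
            f"window [{low_nm}, {high_nm}) does not intersect the grid "
            f"[{s.grid.start_nm}, {s.grid.stop_nm}]"
        )
    idx = np.flatnonzero(mask)
    new_grid = WavelengthGrid(float(wl[idx[0]]), s.grid.step_nm, int(idx.size))
    return SpectraSet(
        grid=new_grid,
        absorbance=s.absorbance[:, idx],
        sample_ids=list(s.sample_ids),
    )
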