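"""Face-centered central composite design (CCD) for calibration sets.

A three-level CCD over k mixture components: the 2^k factorial vertices at
{low, high}^k, 2k axial runs with one factor at low or high and the others
at center (alpha = 1, i.e. axial points on the cube faces), and one
all-center run — 2^k + 2k + 1 runs (15 for k = 3).  Each factor takes its
low value in 2^(k-1) + 1 runs, its high value in 2^(k-1) + 1 runs, and the
center in the remaining 2k - 1 runs (5/5/5 for k = 3).

Runs are emitted in a fixed canonical order (factorial block, then axial
pairs per factor, then the center point), so designs are reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .spectra_core import ConcentrationTable

__all__ = ["DesignSpec", "DesignMatrix", "central_composite_design"]


@dataclass(frozen=True)
class DesignSpec:
    """Levels of a face-centered CCD, shared by all factors (mg/L)."""

    n_factors: int
    low: float
    high: float
    center: float

    def __post_init__(self) -> None:
        if self.n_factors < 1:
            raise ValueError(f"n_factors must be >= 1, got {self.n_factors}")
        if not (self.low <= self.center <= self.high):
            raise ValueError(
                f"need low <= center <= high, got "
                f"{self.low}/{self.center}/{self.high}"
            )


@dataclass
class DesignMatrix:
    """Concentration runs (n_runs x n_factors, mg/L) with run labels."""

    runs: np.ndarray
    run_ids: list[str]

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def n_factors(self) -> int:
        return self.runs.shape[1]

    def to_concentration_table(self, analyte_names: list[str]) -> ConcentrationTable:
        return ConcentrationTable(
            values=self.runs.copy(),
            analyte_names=list(analyte_names),
            sample_ids=list(self.run_ids),
        )


def central_composite_design(spec: DesignSpec) -> DesignMatrix:
    """Generate the face-centered CCD run matrix for ``spec``.

    Order: 2^k factorial vertices (lexicographic over (high, low) per
    factor), then for each factor the (high, low) axial pair with the other
    factors at center, then one center run.
    """
    k = spec.n_factors
    rows: list[list[float]] = []
    for combo in itertools.product((spec.high, spec.low), repeat=k):
        rows.append(list(combo))
    for j in range(k):
        for level in (spec.high, spec.low):
            row = [spec.center] * k
            row[j] = level
            rows.append(row)
    rows.append([spec.center] * k)
    runs = np.asarray(rows, dtype=float)
    run_ids = [f"run{i + 1}" for i in range(len(rows))]
    return DesignMatrix(runs=runs, run_ids=run_ids)
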