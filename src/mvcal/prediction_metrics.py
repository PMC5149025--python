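"""Scalar quality statistics for prediction sets and recovery studies.

Definitions (c = actual, c_hat = predicted, m samples, c_bar = mean actual):

    RE%       = 100 (c_hat - c) / c                      per sample
    mean |RE| = mean over samples of |RE%|
    RMSEP     = sqrt( sum (c - c_hat)^2 / (m - 1) )      (or /m, see below)
    SEP       = sqrt( sum (c - c_hat)^2 / m )
    REP%      = 100 RMSEP / c_bar
    R^2       = 1 - SS_res / SS_tot
    recovery% = 100 c_hat / c                            per sample (c > 0)

The RMSEP denominator is a parameter (default m - 1, the conventional
definition) because published values are often internally consistent with
neither choice once predictions are rounded; both are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "UndefinedStatisticError",
    "StatsReport",
    "relative_error",
    "mean_abs_relative_error",
    "prediction_stats",
    "recovery_percent",
]


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for these inputs (e.g. RE at 0)."""


@dataclass(frozen=True)
class StatsReport:
    """Summary statistics for one prediction set and one analyte."""

    rmsep: float  # mg/L
    rep_percent: float  # %
    sep: float  # mg/L
    r_squared: float
    mean_abs_re: float  # %
    n: int
    c_bar: float  # mg/L

    def to_dict(self) -> dict:
        return asdict(self)


def _pair(pred, actual) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.size != a.size:
        raise ValueError(f"pred has {p.size} entries, actual has {a.size}")
    return p, a


def relative_error(pred: float, actual: float) -> float:
    """Signed relative error in percent, 100 (pred - actual) / actual."""
    if actual == 0:
        raise UndefinedStatisticError(
            "relative error undefined at actual = 0 (use recovery or raw error)"
        )
    return 100.0 * (pred - actual) / actual


def mean_abs_relative_error(pred, actual) -> float:
    """Mean absolute relative error in percent over a prediction set."""
    p, a = _pair(pred, actual)
    if np.any(a == 0):
        raise UndefinedStatisticError("relative error undefined at actual = 0")
    return float(np.mean(np.abs(100.0 * (p - a) / a)))


def prediction_stats(pred, actual, rmse_denominator: str = "m_minus_1") -> StatsReport:
    """Full statistics block (RMSEP, SEP, REP%, R^2, mean |RE|) for one set."""
    p, a = _pair(pred, actual)
    m = p.size
    if m < 2:
        raise ValueError(f"need >= 2 samples, got {m}")
    ss_res = float(np.sum((a - p) ** 2))
    c_bar = float(a.mean())
    ss_tot = float(np.sum((a - c_bar) ** 2))
    if ss_tot == 0:
        raise UndefinedStatisticError("R^2 undefined for constant actual values")
    if rmse_denominator == "m_minus_1":
        rmsep = np.sqrt(ss_res / (m - 1))
    elif rmse_denominator == "m":
        rmsep = np.sqrt(ss_res / m)
    else:
        raise ValueError(
            f"rmse_denominator must be 'm_minus_1' or 'm', got {rmse_denominator!r}"
        )
    mean_re = (
        mean_abs_relative_error(p, a) if np.all(a != 0) else float("nan")
    )
    return StatsReport(
        rmsep=float(rmsep),
        rep_percent=float(100.0 * rmsep / c_bar),
        sep=float(np.sqrt(ss_res / m)),
        r_squared=float(1.0 - ss_res / ss_tot),
        mean_abs_re=mean_re,
        n=m,
        c_bar=c_bar,
    )


def recovery_percent(pred: float, actual: float) -> float:
    """Recovery in percent, 100 pred / actual; undefined for blanks."""
    if actual <= 0:
        raise UndefinedStatisticError(
            f"recovery undefined for actual = {actual} (blank or negative)"
        )
    return 100.0 * pred / actual
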