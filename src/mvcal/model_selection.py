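"""Leave-one-out cross-validation and factor-count selection.

For each candidate factor count A, every calibration sample is in turn held
out, the model refitted on the remaining n-1 samples, and the held-out
sample predicted.  Accumulated over samples this yields

    PRESS(A)  = sum_i (c_hat_{-i}(A) - c_i)^2          (mg/L)^2
    SEP_CV(A) = sqrt(PRESS(A) / n)                     mg/L
    R2_CV(A)  = 1 - PRESS(A) / sum_i (c_i - c_bar)^2

The optimal A is the PRESS minimizer (ties broken toward smaller A), or —
with the ``f_ratio`` rule — the smallest A whose PRESS is not significantly
larger than the minimum under the Haaland-Thomas F-ratio criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calibration_models import (
    DegenerateTargetError,
    RankError,
    _fix_svd_signs,
    _hla_nas,
    _nipals_pls1,
    _pls1_regression_vector,
)
from .spectra_core import SpectraSet, GridError

__all__ = ["CVResult", "loo_press_curve", "select_factors"]


@dataclass
class CVResult:
    """PRESS/SEP/R2 curves over factor counts, from leave-one-out CV."""

    method: str
    analyte: str
    A_values: np.ndarray  # 1..A_max
    press: np.ndarray  # (mg/L)^2
    sep_cv: np.ndarray  # mg/L
    r2_cv: np.ndarray
    A_opt: int
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "analyte": self.analyte,
            "A_values": self.A_values.tolist(),
            "press": self.press.tolist(),
            "sep_cv": self.sep_cv.tolist(),
            "r2_cv": self.r2_cv.tolist(),
            "A_opt": int(self.A_opt),
            "n_samples": int(self.n_samples),
        }


def _fold_predictions_pls1(Xt, yt, x_new, A_max):
    x_mean = Xt.mean(axis=0)
    y_mean = yt.mean()
    W, P, q = _nipals_pls1(Xt - x_mean, yt - y_mean, A_max)
    xc = x_new - x_mean
    return np.array(
        [xc @ _pls1_regression_vector(W, P, q, a) + y_mean for a in range(1, A_max + 1)]
    )


def _fold_predictions_pcr(Xt, yt, x_new, A_max):
    x_mean = Xt.mean(axis=0)
    y_mean = yt.mean()
    U, s, Vt = np.linalg.svd(Xt - x_mean, full_matrices=False)
    U, Vt = _fix_svd_signs(U, Vt)
    if s[A_max - 1] < 1e-12 * max(s[0], 1.0):
        raise RankError(
            f"A_max={A_max} exceeds the rank of a leave-one-out training fold"
        )
    coef = (U.T @ (yt - y_mean)) / s  # per-PC score coefficients
    proj = Vt @ (x_new - x_mean)  # scores of the held-out spectrum
    contrib = proj * coef
    return y_mean + np.cumsum(contrib[:A_max])


def _fold_predictions_hla(Xt, yt, x_new, A_max, pure, centered):
    if centered:
        x_mean = Xt.mean(axis=0)
        y_mean = yt.mean()
    else:
        x_mean = np.zeros(Xt.shape[1])
        y_mean = 0.0
    Xc = Xt - x_mean
    yc = yt - y_mean
    s_k = (
        np.asarray(pure, dtype=float).ravel()
        if pure is not None
        else Xc.T @ yc / float(yc @ yc)
    )
    U, s, Vt = np.linalg.svd(Xc - np.outer(yc, s_k), full_matrices=False)
    _fix_svd_signs(U, Vt)
    xc = x_new - x_mean
    preds = np.empty(A_max)
    for a in range(1, A_max + 1):
        s_star = _hla_nas(s_k, Vt[:a].T)
        preds[a - 1] = xc @ s_star / float(s_star @ s_star) + y_mean
    return preds


def loo_press_curve(
    X: SpectraSet,
    y,
    method: str,
    A_max: int,
    hla_pure=None,
    hla_centered: bool = False,
    analyte: str = "",
    selection_rule: str = "min_press",
) -> CVResult:
    """Leave-one-out PRESS/SEP/R2 curves for A = 1..A_max.

    ``A_max`` must not exceed n_samples - 2, so every fold of n-1 samples
    still supports A_max factors after centering.
    """
    Xm = np.asarray(X.absorbance, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    n = Xm.shape[0]
    if yv.size != n:
        raise ValueError(f"y has {yv.size} entries for {n} spectra")
    if np.ptp(yv) == 0:
        raise DegenerateTargetError("concentration vector is constant")
    if A_max < 1:
        raise ValueError(f"A_max must be >= 1, got {A_max}")
    if A_max > n - 2:
        raise RankError(
            f"A_max={A_max} too large for leave-one-out on {n} samples "
            f"(limit {n - 2})"
        )
    key = method.upper()
    if key == "HLA" and hla_pure is not None:
        pure = np.asarray(hla_pure, dtype=float).ravel()
        if pure.size != Xm.shape[1]:
            raise GridError("pure spectrum length does not match the spectra")

    preds = np.empty((n, A_max))
    for i in range(n):
        keep = np.arange(n) != i
        Xt, yt, x_new = Xm[keep], yv[keep], Xm[i]
        if key == "PLS1":
            preds[i] = _fold_predictions_pls1(Xt, yt, x_new, A_max)
        elif key == "PCR":
            preds[i] = _fold_predictions_pcr(Xt, yt, x_new, A_max)
        elif key == "HLA":
            preds[i] = _fold_predictions_hla(
                Xt, yt, x_new, A_max, hla_pure, hla_centered
            )
        else:
            raise ValueError(f"unknown method {method!r}")

    resid = preds - yv[:, None]
    press = np.sum(resid**2, axis=0)
    sep_cv = np.sqrt(press / n)
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2_cv = 1.0 - press / ss_tot
    cv = CVResult(
        method=key,
        analyte=analyte,
        A_values=np.arange(1, A_max + 1),
        press=press,
        sep_cv=sep_cv,
        r2_cv=r2_cv,
        A_opt=0,
        n_samples=n,
    )
    cv.A_opt = select_factors(cv, rule=selection_rule)
    return cv


def select_factors(cv: CVResult, rule: str = "min_press", f_prob: float = 0.75) -> int:
    """Choose the factor count from a PRESS curve.

    ``min_press``: argmin of PRESS, smallest A on ties.  ``f_ratio``:
    smallest A whose PRESS/PRESS_min ratio stays below the F(f_prob; n, n)
    quantile — the Haaland-Thomas parsimony rule, which avoids chasing
    noise into high factor counts.
    """
    if cv.press is None or len(cv.press) == 0:
        raise ValueError("empty PRESS curve")
    press = np.asarray(cv.press, dtype=float)
    a_min = int(np.argmin(press))  # np.argmin returns the first (smallest A) tie
    if rule == "min_press":
        return int(cv.A_values[a_min])
    if rule == "f_ratio":
        f_crit = stats.f.ppf(f_prob, cv.n_samples, cv.n_samples)
        ok = press <= f_crit * press[a_min]
        return int(cv.A_values[int(np.argmax(ok))])
    raise ValueError(f"unknown selection rule {rule!r}")
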