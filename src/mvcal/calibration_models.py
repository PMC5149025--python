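"""Inverse multivariate calibration models: PLS1 (NIPALS), PCR and HLA.

All three models are fitted per analyte: given calibration spectra X
(n_samples x n_points, AU) and a concentration vector y (mg/L), each yields
a regression vector b so that an unknown spectrum r predicts

    c_hat = (r - x_mean)' b + y_mean        (centered models)
    c_hat = r' b                            (uncentered models)

PLS1 uses the classical NIPALS algorithm with deflation of X only and
per-component y-loadings.  PCR regresses y on the leading principal-
component scores of centered X.  HLA (hybrid linear analysis) removes the
analyte's own contribution y * s_k' from X, models the residual
interference space with a truncated SVD, and quantifies through the net
analyte signal s_k* — the part of the unit-concentration pure spectrum s_k
orthogonal to that interference space.

Conventions
-----------
* PLS1 and PCR mean-center X and y; HLA is uncentered by default (it
  operates on raw Beer-Lambert signals) with an opt-in ``centered`` flag.
* No variable scaling: absorbance shares units across channels.
* SVD signs are fixed (largest-magnitude element of each singular vector
  made positive) so fits are bit-reproducible across runs and platforms.
* Negative predictions are returned as-is, never truncated: blanks
  legitimately predict slightly below zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .spectra_core import GridError, SpectraSet, WavelengthGrid

__all__ = [
    "RankError",
    "DegenerateTargetError",
    "DegenerateNASError",
    "CalibrationModel",
    "HLAInternals",
    "fit_pls1",
    "fit_pcr",
    "fit_hla",
    "fit",
    "predict",
    "univariate_linear_fit",
    "UnivariateFit",
]

#: ||s_k*|| / ||s_k|| below this means the analyte lies inside the modelled
#: interference space and HLA cannot quantify it.
NAS_DEGENERACY_TOL = 1e-10


class RankError(ValueError):
    """Requested more factors than the data can support."""


class DegenerateTargetError(ValueError):
    """Concentration vector has no variance (or too few samples)."""


class DegenerateNASError(ValueError):
    """Net analyte signal vanishes: analyte is inside the interference space."""


@dataclass
class HLAInternals:
    """HLA-specific state: pure spectrum, interference basis and NAS vector."""

    pure_spectrum_unit_conc: np.ndarray  # s_k, AU per mg/L
    interference_basis: np.ndarray  # (n_points, A), orthonormal columns
    nas_vector: np.ndarray  # s_k*, orthogonal to every basis column


@dataclass
class CalibrationModel:
    """A fitted inverse calibration model for a single analyte."""

    method: str  # "PLS1" | "PCR" | "HLA"
    n_factors: int
    regression_vector: np.ndarray  # b, length n_points
    x_mean: np.ndarray
    y_mean: float
    centered: bool
    grid: WavelengthGrid
    analyte: str = ""
    internals: dict = field(default_factory=dict)
    hla: Optional[HLAInternals] = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_factors": self.n_factors,
            "analyte": self.analyte,
            "centered": self.centered,
            "y_mean": self.y_mean,
            "grid": {
                "start_nm": self.grid.start_nm,
                "step_nm": self.grid.step_nm,
                "n_points": self.grid.n_points,
            },
            "regression_vector": self.regression_vector.tolist(),
            "x_mean": self.x_mean.tolist(),
        }
        if self.hla is not None:
            d["hla"] = {
                "pure_spectrum_unit_conc": self.hla.pure_spectrum_unit_conc.tolist(),
                "interference_basis": self.hla.interference_basis.tolist(),
                "nas_vector": self.hla.nas_vector.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        hla = None
        if "hla" in d:
            hla = HLAInternals(
                pure_spectrum_unit_conc=np.asarray(d["hla"]["pure_spectrum_unit_conc"]),
                interference_basis=np.asarray(d["hla"]["interference_basis"]),
                nas_vector=np.asarray(d["hla"]["nas_vector"]),
            )
        return cls(
            method=d["method"],
            n_factors=int(d["n_factors"]),
            regression_vector=np.asarray(d["regression_vector"], dtype=float),
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            centered=bool(d["centered"]),
            grid=WavelengthGrid(
                d["grid"]["start_nm"], d["grid"]["step_nm"], int(d["grid"]["n_points"])
            ),
            analyte=d.get("analyte", ""),
            hla=hla,
        )


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _as_xy(X: SpectraSet, y) -> tuple[np.ndarray, np.ndarray]:
    Xm = np.asarray(X.absorbance, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    if yv.size != Xm.shape[0]:
        raise ValueError(f"y has {yv.size} entries for {Xm.shape[0]} spectra")
    return Xm, yv


def _check_factors(A: int, n: int, p: int, centered: bool) -> None:
    limit = min(n - 1, p) if centered else min(n, p)
    if A < 1:
        raise ValueError(f"number of factors must be >= 1, got {A}")
    if A > limit:
        raise RankError(
            f"A={A} factors exceed the data's capacity "
            f"(n_samples={n}, n_points={p}, limit={limit})"
        )


def _check_target(y: np.ndarray) -> None:
    if np.ptp(y) == 0:
        raise DegenerateTargetError("concentration vector is constant")


def _fix_svd_signs(U: np.ndarray, Vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make the largest-|.| element of each right singular vector positive."""
    for a in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[a])))
        if Vt[a, j] < 0:
            Vt[a] *= -1.0
            U[:, a] *= -1.0
    return U, Vt


# ---------------------------------------------------------------------------
# PLS1 (NIPALS)
# ---------------------------------------------------------------------------


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, A: int):
    """NIPALS PLS1 on centered data; returns (W, P, q) for A components.

    For a single response NIPALS is non-iterative per component:
    w_a = X'y / ||X'y||, t_a = X w_a, p_a = X't/(t't), q_a = y't/(t't),
    then deflate X (only) by t_a p_a'.
    """
    n, p = Xc.shape
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    Xa = Xc.copy()
    for a in range(A):
        w = Xa.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            raise RankError(
                f"NIPALS weight vanished at component {a + 1}: "
                "no covariance left between X and y"
            )
        w /= nw
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-28:
            raise RankError(f"zero-variance score at component {a + 1}")
        P[:, a] = Xa.T @ t / tt
        q[a] = float(yc @ t) / tt
        W[:, a] = w
        Xa = Xa - np.outer(t, P[:, a])
    return W, P, q


def _pls1_regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray, A: int) -> np.ndarray:
    Wa, Pa, qa = W[:, :A], P[:, :A], q[:A]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


def fit_pls1(X: SpectraSet, y, A: int, analyte: str = "") -> CalibrationModel:
    """Fit a mean-centered PLS1 model with A latent variables."""
    Xm, yv = _as_xy(X, y)
    _check_factors(A, *Xm.shape, centered=True)
    _check_target(yv)
    x_mean = Xm.mean(axis=0)
    y_mean = float(yv.mean())
    W, P, q = _nipals_pls1(Xm - x_mean, yv - y_mean, A)
    b = _pls1_regression_vector(W, P, q, A)
    return CalibrationModel(
        method="PLS1",
        n_factors=A,
        regression_vector=b,
        x_mean=x_mean,
        y_mean=y_mean,
        centered=True,
        grid=X.grid,
        analyte=analyte,
        internals={"weights": W, "x_loadings": P, "y_loadings": q},
    )


# ---------------------------------------------------------------------------
# PCR
# ---------------------------------------------------------------------------


def fit_pcr(X: SpectraSet, y, A: int, analyte: str = "") -> CalibrationModel:
    """Fit principal component regression with A components."""
    Xm, yv = _as_xy(X, y)
    _check_factors(A, *Xm.shape, centered=True)
    _check_target(yv)
    x_mean = Xm.mean(axis=0)
    y_mean = float(yv.mean())
    Xc = Xm - x_mean
    yc = yv - y_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, Vt = _fix_svd_signs(U, Vt)
    if s[A - 1] < 1e-12 * max(s[0], 1.0):
        raise RankError(
            f"A={A} exceeds the numerical rank of the centered data "
            f"(singular value {s[A - 1]:.3g})"
        )
    # score regression coefficient per PC: u_a'y / s_a, mapped back to channels
    b = Vt[:A].T @ ((U[:, :A].T @ yc) / s[:A])
    return CalibrationModel(
        method="PCR",
        n_factors=A,
        regression_vector=b,
        x_mean=x_mean,
        y_mean=y_mean,
        centered=True,
        grid=X.grid,
        analyte=analyte,
        internals={"singular_values": s, "loadings": Vt[:A].T},
    )


# ---------------------------------------------------------------------------
# HLA
# ---------------------------------------------------------------------------


def _hla_nas(s_k: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project s_k off the interference basis; raise if nothing survives."""
    s_star = s_k - basis @ (basis.T @ s_k) if basis.size else s_k.copy()
    if np.linalg.norm(s_star) < NAS_DEGENERACY_TOL * np.linalg.norm(s_k):
        raise DegenerateNASError(
            "net analyte signal is numerically zero: the analyte spectrum "
            "lies inside the modelled interference space"
        )
    return s_star


def fit_hla(
    X: SpectraSet,
    y,
    A: int,
    pure_spectrum=None,
    analyte: str = "",
    centered: bool = False,
) -> CalibrationModel:
    """Fit hybrid linear analysis with an A-dimensional interference space.

    Steps: (1) take s_k as the supplied unit-concentration pure spectrum,
    or estimate it by least squares as X'y / (y'y); (2) strip the analyte,
    X_-k = X - y s_k'; (3) interference basis = top-A right singular
    vectors of X_-k; (4) s_k* = s_k minus its projection onto the basis;
    (5) b = s_k* / (s_k*' s_k*).

    A = 0 is allowed (no interferences modelled, classical univariate NAS).
    """
    Xm, yv = _as_xy(X, y)
    n, p = Xm.shape
    if A < 0:
        raise ValueError(f"number of factors must be >= 0, got {A}")
    if A > 0:
        _check_factors(A, n, p, centered=centered)
    _check_target(yv)
    if centered:
        x_mean = Xm.mean(axis=0)
        y_mean = float(yv.mean())
    else:
        x_mean = np.zeros(p)
        y_mean = 0.0
    Xc = Xm - x_mean
    yc = yv - y_mean
    if pure_spectrum is not None:
        s_k = np.asarray(pure_spectrum, dtype=float).ravel()
        if s_k.size != p:
            raise GridError(
                f"pure spectrum has {s_k.size} points, training grid has {p}"
            )
    else:
        s_k = Xc.T @ yc / float(yc @ yc)
    X_minus = Xc - np.outer(yc, s_k)
    if A > 0:
        U, s, Vt = np.linalg.svd(X_minus, full_matrices=False)
        _fix_svd_signs(U, Vt)
        basis = Vt[:A].T
    else:
        basis = np.zeros((p, 0))
    s_star = _hla_nas(s_k, basis)
    b = s_star / float(s_star @ s_star)
    return CalibrationModel(
        method="HLA",
        n_factors=A,
        regression_vector=b,
        x_mean=x_mean,
        y_mean=y_mean,
        centered=centered,
        grid=X.grid,
        analyte=analyte,
        hla=HLAInternals(
            pure_spectrum_unit_conc=s_k,
            interference_basis=basis,
            nas_vector=s_star,
        ),
    )


_FITTERS = {"PLS1": fit_pls1, "PCR": fit_pcr, "HLA": fit_hla}


def fit(method: str, X: SpectraSet, y, A: int, **kwargs) -> CalibrationModel:
    """Dispatch to :func:`fit_pls1`, :func:`fit_pcr` or :func:`fit_hla`."""
    key = method.upper()
    if key not in _FITTERS:
        raise ValueError(f"unknown method {method!r}; choose PLS1, PCR or HLA")
    return _FITTERS[key](X, y, A, **kwargs)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict(model: CalibrationModel, X: SpectraSet) -> np.ndarray:
    """Predict concentrations (mg/L) for each spectrum in ``X``.

    Negative outputs are reported as-is.
    """
    if (
        X.grid.n_points != model.grid.n_points
        or abs(X.grid.start_nm - model.grid.start_nm) > 1e-9
        or abs(X.grid.step_nm - model.grid.step_nm) > 1e-9
    ):
        raise GridError(
            f"prediction grid ({X.grid.start_nm}..{X.grid.stop_nm}, "
            f"{X.grid.n_points} pts) does not match the training grid "
            f"({model.grid.start_nm}..{model.grid.stop_nm}, "
            f"{model.grid.n_points} pts)"
        )
    return (X.absorbance - model.x_mean) @ model.regression_vector + model.y_mean


# ---------------------------------------------------------------------------
# univariate calibration (linear dynamic range check)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UnivariateFit:
    slope: float  # AU per mg/L
    intercept: float  # AU
    correlation: float


def univariate_linear_fit(conc, abs_at_lambda) -> UnivariateFit:
    """OLS line of absorbance at one wavelength versus concentration.

    Used to establish the linear dynamic range of a single analyte at its
    absorption maximum before any multivariate work.
    """
    c = np.asarray(conc, dtype=float).ravel()
    a = np.asarray(abs_at_lambda, dtype=float).ravel()
    if c.size != a.size:
        raise ValueError("conc and absorbance vectors differ in length")
    if c.size < 3:
        raise ValueError(f"need >= 3 points, got {c.size}")
    if np.ptp(c) == 0:
        raise DegenerateTargetError("concentration vector is constant")
    res = stats.linregress(c, a)
    return UnivariateFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        correlation=float(np.clip(res.rvalue, -1.0, 1.0)),
    )
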