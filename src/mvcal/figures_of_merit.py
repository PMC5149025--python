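"""Net-analyte-signal figures of merit: SEL, SEN, analytical sensitivity, LOD.

The net analyte signal (NAS) s_k* of analyte k is the part of its
unit-concentration spectrum s_k orthogonal to the space spanned by the
interferences; it is the only portion of the signal usable for
univariate-like quantification.  From it:

    SEL   = ||s_k*|| / ||s_k||          selectivity, in [0, 1]
    SEN   = ||s_k*||                    sensitivity, AU per mg/L
    gamma = SEN / ||eps||               analytical sensitivity, (mg/L)^-1
    LOD   = 3 ||eps|| / SEN = 3 / gamma limit of detection, mg/L

||eps|| is the instrumental noise level, estimated as the standard
deviation over several blank spectra of the scalar NAS projection
r_blank' s_k* / ||s_k*||.  For inverse models (PLS1/PCR) the NAS is
recovered from the regression vector as s_k* = b / ||b||^2; HLA carries its
NAS vector explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calibration_models import CalibrationModel, DegenerateNASError
from .spectra_core import GridError, SpectraSet

__all__ = [
    "FomReport",
    "nas_from_model",
    "selectivity",
    "sensitivity",
    "estimate_noise",
    "figures_of_merit",
]


@dataclass
class FomReport:
    """Per-analyte, per-model figures of merit."""

    analyte: str
    method: str
    nas_vector: np.ndarray  # s_k*, AU per mg/L
    sel: float  # unitless, [0, 1]
    sen: float  # AU per mg/L
    gamma: float  # (mg/L)^-1
    gamma_inv: float  # mg/L
    lod: float  # mg/L
    eps_norm: float  # AU
    n_blanks: int

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "method": self.method,
            "sel": self.sel,
            "sen": self.sen,
            "gamma": self.gamma,
            "gamma_inv": self.gamma_inv,
            "lod": self.lod,
            "eps_norm": self.eps_norm,
            "n_blanks": self.n_blanks,
            "nas_vector": self.nas_vector.tolist(),
        }


def nas_from_model(model: CalibrationModel) -> np.ndarray:
    """Net analyte signal vector implied by a fitted model.

    For inverse models the regression vector b satisfies c = r' b on pure
    NAS signals, so s_k* = b / ||b||^2 (hence ||s_k*|| = 1 / ||b||).  HLA
    models return their explicitly constructed NAS vector.
    """
    if model.hla is not None:
        return model.hla.nas_vector.copy()
    b = model.regression_vector
    nb2 = float(b @ b)
    if nb2 == 0:
        raise DegenerateNASError("zero regression vector has no net analyte signal")
    return b / nb2


def selectivity(s_k, s_k_star) -> float:
    """SEL = ||s_k*|| / ||s_k||, the fraction of signal surviving overlap."""
    sk = np.asarray(s_k, dtype=float).ravel()
    st = np.asarray(s_k_star, dtype=float).ravel()
    n_sk = float(np.linalg.norm(sk))
    if n_sk == 0:
        raise DegenerateNASError("pure spectrum s_k is zero")
    sel = float(np.linalg.norm(st)) / n_sk
    if sel > 1.0 + 1e-9:
        raise ValueError(
            f"SEL = {sel:.6g} > 1: s_k* is not a projection of this s_k"
        )
    return min(sel, 1.0)


def sensitivity(s_k_star) -> float:
    """SEN = ||s_k*||, response change per unit concentration (AU per mg/L)."""
    return float(np.linalg.norm(np.asarray(s_k_star, dtype=float)))


def estimate_noise(blanks: SpectraSet, model: CalibrationModel) -> float:
    """Instrumental noise ||eps|| from blank spectra (AU).

    Each blank is projected onto the unit NAS direction (signed scalar);
    ||eps|| is the sample standard deviation of those projections.  At
    least 3 blanks are required.  Equivalently ||eps|| = SEN x SD of the
    blanks' predicted concentrations (for uncentered models).
    """
    if blanks.n_samples < 3:
        raise ValueError(
            f"need >= 3 blank spectra to estimate noise, got {blanks.n_samples}"
        )
    if blanks.grid.n_points != model.grid.n_points:
        raise GridError("blank spectra are not on the training grid")
    s_star = nas_from_model(model)
    u = s_star / np.linalg.norm(s_star)
    proj = blanks.absorbance @ u
    return float(np.std(proj, ddof=1))


def figures_of_merit(
    model: CalibrationModel,
    s_k_pure,
    blanks: SpectraSet,
    analyte: str | None = None,
) -> FomReport:
    """Compute SEL, SEN, gamma, gamma^-1 and LOD for one fitted model.

    ``s_k_pure`` is the analyte's unit-concentration (per mg/L) pure
    spectrum; when None, an HLA model's stored estimate is used.
    """
    if s_k_pure is None:
        if model.hla is None:
            raise ValueError("s_k_pure required for models without a stored estimate")
        s_k = model.hla.pure_spectrum_unit_conc
    else:
        s_k = np.asarray(s_k_pure, dtype=float).ravel()
    s_star = nas_from_model(model)
    sel = selectivity(s_k, s_star)
    sen = sensitivity(s_star)
    eps = estimate_noise(blanks, model)
    if eps == 0:
        warnings.warn(
            "zero blank noise: analytical sensitivity is infinite, LOD = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        gamma = float("inf")
        gamma_inv = 0.0
        lod = 0.0
    else:
        gamma = sen / eps
        gamma_inv = eps / sen
        lod = 3.0 * eps / sen
    return FomReport(
        analyte=analyte if analyte is not None else model.analyte,
        method=model.method,
        nas_vector=s_star,
        sel=sel,
        sen=sen,
        gamma=gamma,
        gamma_inv=gamma_inv,
        lod=lod,
        eps_norm=eps,
        n_blanks=blanks.n_samples,
    )
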