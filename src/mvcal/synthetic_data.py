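"""Synthetic three-component UV-Vis systems for end-to-end testing.

Real mixture spectra of theophylline (THEO), montelukast (MKST) and
loratadine (LORA) overlap heavily in the 225-390 nm window, with primary
absorption maxima near 275, 276 and 251 nm.  This module builds a
statistical stand-in with the same structure: pure-component spectra as
sums of Gaussian bands (AU L/mg), Beer-Lambert additive mixing over the
working range, iid (or proportional) instrument noise, and an optional
smooth plasma-like background with per-sample amplitude variation.

Band shapes are synthetic — no digitized spectra exist for these drugs in
this package — so only peak positions, overlap structure and signal scale
are emulated, not band-shape detail.  All randomness flows from one
explicit seed; replicate indices offset the stream deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .experiment_design import DesignMatrix
from .spectra_core import SpectraSet, WavelengthGrid

__all__ = [
    "BandSet",
    "BackgroundSpec",
    "SyntheticSystemSpec",
    "default_three_drug_spec",
    "make_pure_spectra",
    "simulate_mixtures",
    "simulate_blanks",
]

#: Default instrument noise, AU per channel; typical of a benchtop UV-Vis
#: spectrophotometer and of prediction errors in the low-% range.
DEFAULT_NOISE_SD = 0.002


@dataclass(frozen=True)
class BandSet:
    """One component's pure spectrum as a sum of Gaussian bands.

    Each band is (center_nm, sigma_nm, amplitude) with amplitude in
    AU L/mg — the spectrum is evaluated per mg/L of the component.
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"component {self.name!r} has no bands")
        for c, w, a in self.bands:
            if w <= 0:
                raise ValueError(f"band width must be > 0, got {w}")
            if a <= 0:
                raise ValueError(f"band amplitude must be > 0, got {a}")

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        out = np.zeros_like(wl)
        for center, sigma, amp in self.bands:
            out += amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        return out


@dataclass(frozen=True)
class BackgroundSpec:
    """Smooth plasma-like matrix background.

    An exponentially decaying baseline ``amplitude * exp(-(wl - wl0) /
    decay_scale_nm)`` whose amplitude varies log-normally between samples
    (sigma of log = ``sample_variation``).  A deliberate stand-in for a
    biological matrix, not a physical plasma absorption model.
    """

    kind: str = "plasma_like"
    amplitude: float = 0.05  # AU at the window start
    decay_scale_nm: float = 40.0
    sample_variation: float = 0.10

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("background amplitude must be >= 0")
        if self.kind != "plasma_like":
            raise ValueError(f"unknown background kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticSystemSpec:
    """Complete recipe for a synthetic spectral system."""

    grid: WavelengthGrid = WavelengthGrid(225.0, 1.0, 165)
    components: tuple[BandSet, ...] = ()
    noise_sd: float = DEFAULT_NOISE_SD  # AU
    noise_model: str = "iid_gaussian"  # or "proportional"
    baseline: Optional[BackgroundSpec] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("iid_gaussian", "proportional"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        lo, hi = self.grid.start_nm, self.grid.stop_nm
        for comp in self.components:
            for center, _, _ in comp.bands:
                if not (lo <= center <= hi):
                    raise ValueError(
                        f"band center {center} nm of {comp.name!r} lies outside "
                        f"the grid span [{lo}, {hi}]"
                    )

    def with_seed(self, seed: int) -> "SyntheticSystemSpec":
        return replace(self, seed=seed)


def default_three_drug_spec(
    noise_sd: float = DEFAULT_NOISE_SD,
    baseline: Optional[BackgroundSpec] = None,
    seed: int = 0,
) -> SyntheticSystemSpec:
    """Three heavily overlapping components with maxima at 275/276/251 nm.

    Band amplitudes give roughly 0.1-0.5 AU at mid-range concentrations
    (6 mg/L) and pairwise cosine similarity >= 0.5 between pure spectra.
    """
    components = (
        BandSet("THEO", ((275.0, 16.0, 0.070), (232.0, 12.0, 0.030))),
        BandSet("MKST", ((276.0, 24.0, 0.050), (345.0, 20.0, 0.015))),
        BandSet("LORA", ((251.0, 16.0, 0.060),)),
    )
    return SyntheticSystemSpec(
        components=components, noise_sd=noise_sd, baseline=baseline, seed=seed
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _rng(spec: SyntheticSystemSpec, stream: int, replicate: int) -> np.random.Generator:
    # one root seed; (stream, replicate) deterministically offset the stream
    return np.random.default_rng([int(spec.seed), int(stream), int(replicate)])


def make_pure_spectra(spec: SyntheticSystemSpec) -> SpectraSet:
    """Noiseless unit-concentration (1 mg/L) pure spectra, one row each."""
    if not spec.components:
        raise ValueError("spec has no components")
    wl = spec.grid.values()
    rows = np.vstack([c.evaluate(wl) for c in spec.components])
    return SpectraSet(
        grid=spec.grid,
        absorbance=rows,
        sample_ids=[c.name for c in spec.components],
    )


def _noise(rng, shape, spec, signal):
    if spec.noise_sd == 0:
        return np.zeros(shape)
    if spec.noise_model == "iid_gaussian":
        return rng.normal(0.0, spec.noise_sd, size=shape)
    # proportional: sd grows with local signal, floored at the base sd
    local_sd = spec.noise_sd * (1.0 + np.abs(signal) / max(np.abs(signal).max(), 1e-12))
    return rng.normal(0.0, 1.0, size=shape) * local_sd


def _background(rng, n_samples, spec):
    if spec.baseline is None:
        return np.zeros((n_samples, spec.grid.n_points))
    wl = spec.grid.values()
    base = spec.baseline.amplitude * np.exp(
        -(wl - spec.grid.start_nm) / spec.baseline.decay_scale_nm
    )
    scale = (
        rng.lognormal(0.0, spec.baseline.sample_variation, size=n_samples)
        if spec.baseline.sample_variation > 0
        else np.ones(n_samples)
    )
    return scale[:, None] * base[None, :]


def simulate_mixtures(
    design: DesignMatrix,
    pure: SpectraSet,
    spec: SyntheticSystemSpec,
    replicate: int = 0,
) -> SpectraSet:
    """Beer-Lambert mixtures of the design's concentration runs.

    Row i = sum_k c_ik * pure_k + baseline_i + noise_i.  Reproducible:
    the same (spec.seed, replicate) always yields the same matrix.
    """
    if design.n_factors != pure.n_samples:
        raise ValueError(
            f"design has {design.n_factors} factors but {pure.n_samples} "
            "pure spectra were given"
        )
    if pure.grid != spec.grid:
        raise ValueError("pure spectra are not on the spec's grid")
    signal = design.runs @ pure.absorbance
    rng = _rng(spec, stream=1, replicate=replicate)
    bg = _background(rng, design.n_runs, spec)
    noise = _noise(rng, signal.shape, spec, signal)
    return SpectraSet(
        grid=spec.grid,
        absorbance=signal + bg + noise,
        sample_ids=list(design.run_ids),
    )


def simulate_blanks(
    n: int, spec: SyntheticSystemSpec, replicate: int = 0
) -> SpectraSet:
    """Zero-concentration spectra: baseline + noise only."""
    if n < 1:
        raise ValueError(f"need n >= 1 blanks, got {n}")
    rng = _rng(spec, stream=2, replicate=replicate)
    bg = _background(rng, n, spec)
    noise = _noise(rng, (n, spec.grid.n_points), spec, bg)
    return SpectraSet(
        grid=spec.grid,
        absorbance=bg + noise,
        sample_ids=[f"blank{i + 1}" for i in range(n)],
    )
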