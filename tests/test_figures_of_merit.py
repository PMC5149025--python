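import numpy as np
import pytest

from mvcal import (
    DegenerateNASError,
    SpectraSet,
    WavelengthGrid,
    estimate_noise,
    figures_of_merit,
    fit_hla,
    fit_pls1,
    nas_from_model,
    selectivity,
    sensitivity,
    simulate_blanks,
    default_three_drug_spec,
)


def gram_schmidt_nas(s_k, interferents):
    """Oracle: component of s_k orthogonal to span(interferents)."""
    Q, _ = np.linalg.qr(np.column_stack(interferents))
    return s_k - Q @ (Q.T @ s_k)


class TestNasVector:
    def test_single_component_nas_is_pure_spectrum(self):
        grid = WavelengthGrid(225, 1, 40)
        s = np.linspace(0.02, 0.09, 40)
        y = np.array([2.0, 5.0, 8.0, 11.0, 14.0])
        X = SpectraSet(grid=grid, absorbance=np.outer(y, s))
        m = fit_hla(X, y, 0, pure_spectrum=s)
        np.testing.assert_allclose(nas_from_model(m), s)

    def test_inverse_model_nas_norm_is_reciprocal_of_b(self, X_noiseless, calib_design):
        m = fit_pls1(X_noiseless, calib_design.runs[:, 0], 3)
        nas = nas_from_model(m)
        b_norm = np.linalg.norm(m.regression_vector)
        assert np.linalg.norm(nas) == pytest.approx(1.0 / b_norm, rel=1e-10)

    def test_nas_norm_matches_gram_schmidt_oracle(
        self, X_noiseless, calib_design, pure
    ):
        """HLA's NAS norm equals the orthogonal complement of the pure
        spectrum w.r.t. the other two components, computed independently."""
        for k in range(3):
            others = [pure.absorbance[j] for j in range(3) if j != k]
            oracle = gram_schmidt_nas(pure.absorbance[k], others)
            m = fit_hla(X_noiseless, calib_design.runs[:, k], 2,
                        pure_spectrum=pure.absorbance[k])
            assert np.linalg.norm(nas_from_model(m)) == pytest.approx(
                np.linalg.norm(oracle), rel=1e-8
            )


class TestSelSen:
    def test_orthogonal_analyte_has_unit_selectivity(self):
        assert selectivity([0, 0, 1.0], [0, 0, 1.0]) == 1.0

    def test_fully_overlapped_analyte_has_zero_selectivity(self):
        assert selectivity([1.0, 0, 0], [0.0, 0, 0]) == 0.0

    def test_hand_projection_example(self):
        # s_k = (1,1,0) against a single interferent (1,0,0): NAS = (0,1,0)
        s_k = np.array([1.0, 1.0, 0.0])
        nas = gram_schmidt_nas(s_k, [np.array([1.0, 0.0, 0.0])])
        assert selectivity(s_k, nas) == pytest.approx(1 / np.sqrt(2))

    def test_sensitivity_is_euclidean_norm(self):
        assert sensitivity([3.0, 4.0]) == 5.0
        assert sensitivity(np.zeros(4)) == 0.0

    def test_zero_pure_spectrum_raises(self):
        with pytest.raises(DegenerateNASError):
            selectivity(np.zeros(3), np.zeros(3))


class TestNoiseEstimate:
    def test_identical_blanks_have_zero_noise(self, X_noiseless, calib_design):
        m = fit_pls1(X_noiseless, calib_design.runs[:, 0], 3)
        blanks = SpectraSet(
            grid=X_noiseless.grid,
            absorbance=np.tile(np.linspace(0, 0.01, X_noiseless.n_points), (5, 1)),
        )
        assert estimate_noise(blanks, m) == 0.0

    def test_iid_noise_projection_recovers_sigma(self, X_noiseless, calib_design):
        """Projection of iid N(0, sigma^2) blanks onto the unit NAS
        direction has SD sigma; n=1000 pins it within 10%."""
        sigma = 0.002
        m = fit_pls1(X_noiseless, calib_design.runs[:, 0], 3)
        rng = np.random.default_rng(23)
        blanks = SpectraSet(
            grid=X_noiseless.grid,
            absorbance=rng.normal(0, sigma, (1000, X_noiseless.n_points)),
        )
        assert estimate_noise(blanks, m) == pytest.approx(sigma, rel=0.10)

    def test_interference_components_do_not_inflate_hla_noise(
        self, X_noiseless, calib_design, pure
    ):
        """Blank content inside the interference space is invisible to the
        HLA NAS direction."""
        sigma = 0.002
        m = fit_hla(X_noiseless, calib_design.runs[:, 0], 2,
                    pure_spectrum=pure.absorbance[0])
        rng = np.random.default_rng(29)
        noise = rng.normal(0, sigma, (400, X_noiseless.n_points))
        clean = SpectraSet(grid=X_noiseless.grid, absorbance=noise)
        spiked = SpectraSet(
            grid=X_noiseless.grid,
            absorbance=noise
            + rng.normal(0, 1.0, (400, 2)) @ m.hla.interference_basis.T,
        )
        assert estimate_noise(spiked, m) == pytest.approx(
            estimate_noise(clean, m), rel=1e-9
        )

    def test_too_few_blanks_raises(self, X_noiseless, calib_design):
        m = fit_pls1(X_noiseless, calib_design.runs[:, 0], 3)
        blanks = SpectraSet(
            grid=X_noiseless.grid, absorbance=np.zeros((2, X_noiseless.n_points))
        )
        with pytest.raises(ValueError):
            estimate_noise(blanks, m)


class TestFomReport:
    def test_lod_equals_three_gamma_inverse(self, calib_design, pure):
        from mvcal import simulate_mixtures

        spec = default_three_drug_spec(noise_sd=0.002, seed=41)
        X = simulate_mixtures(calib_design, pure, spec)
        blanks = simulate_blanks(200, spec)
        for k in range(3):
            m = fit_pls1(X, calib_design.runs[:, k], 3)
            r = figures_of_merit(m, pure.absorbance[k], blanks)
            assert r.lod == pytest.approx(3.0 * r.gamma_inv, rel=1e-12)
            assert 0.0 <= r.sel <= 1.0
            assert r.sen >= 0.0

    def test_joint_rescaling_leaves_sel_gamma_lod_unchanged(
        self, calib_design, pure
    ):
        """Scaling every spectrum by c scales SEN and ||eps|| by c and
        cancels out of SEL, gamma and LOD."""
        from mvcal import simulate_mixtures

        spec = default_three_drug_spec(noise_sd=0.002, seed=43)
        X = simulate_mixtures(calib_design, pure, spec)
        blanks = simulate_blanks(100, spec)
        y = calib_design.runs[:, 1]
        c = 2.5
        m1 = fit_pls1(X, y, 3)
        X2 = SpectraSet(grid=X.grid, absorbance=c * X.absorbance)
        b2 = SpectraSet(grid=X.grid, absorbance=c * blanks.absorbance)
        m2 = fit_pls1(X2, y, 3)
        r1 = figures_of_merit(m1, pure.absorbance[1], blanks)
        r2 = figures_of_merit(m2, c * pure.absorbance[1], b2)
        assert r2.sen == pytest.approx(c * r1.sen, rel=1e-8)
        assert r2.eps_norm == pytest.approx(c * r1.eps_norm, rel=1e-8)
        assert r2.sel == pytest.approx(r1.sel, rel=1e-8)
        assert r2.gamma == pytest.approx(r1.gamma, rel=1e-8)
        assert r2.lod == pytest.approx(r1.lod, rel=1e-8)

    def test_zero_noise_flags_infinite_gamma(self, X_noiseless, calib_design, pure):
        m = fit_pls1(X_noiseless, calib_design.runs[:, 0], 3)
        blanks = SpectraSet(
            grid=X_noiseless.grid, absorbance=np.zeros((5, X_noiseless.n_points))
        )
        with pytest.warns(RuntimeWarning):
            r = figures_of_merit(m, pure.absorbance[0], blanks)
        assert np.isinf(r.gamma) and r.lod == 0.0
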