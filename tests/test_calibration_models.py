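import numpy as np
import pytest

from mvcal import (
    DegenerateNASError,
    DegenerateTargetError,
    GridError,
    RankError,
    SpectraSet,
    WavelengthGrid,
    fit,
    fit_hla,
    fit_pcr,
    fit_pls1,
    predict,
    univariate_linear_fit,
)
from mvcal.calibration_models import CalibrationModel

METHOD_CASES = [
    ("PLS1", 3, {}),
    ("PCR", 3, {}),
    ("HLA", 2, {"use_pure": True}),
    ("HLA", 2, {"use_pure": False}),
]


def _fit(method, X, y, A, kw, pure_row=None):
    kwargs = {}
    if kw.get("use_pure"):
        kwargs["pure_spectrum"] = pure_row
    return fit(method, X, y, A, **kwargs)


class TestExactRecovery:
    def test_single_component_beer_lambert_identity(self):
        """Noiseless X = y s: one PLS factor reproduces y exactly."""
        grid = WavelengthGrid(225, 1, 50)
        rng = np.random.default_rng(4)
        s = rng.uniform(0.01, 0.1, 50)
        y = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        X = SpectraSet(grid=grid, absorbance=np.outer(y, s))
        m = fit_pls1(X, y, 1)
        np.testing.assert_allclose(predict(m, X), y, rtol=1e-8)

    @pytest.mark.parametrize("method,A,kw", METHOD_CASES)
    def test_noiseless_three_component_matches_design(
        self, method, A, kw, X_noiseless, Xv_noiseless, calib_design, valid_design, pure
    ):
        """At rank-matched factor counts every model recovers the design
        concentrations of unseen mixtures to machine precision."""
        for k in range(3):
            m = _fit(method, X_noiseless, calib_design.runs[:, k], A, kw,
                     pure.absorbance[k])
            np.testing.assert_allclose(
                predict(m, Xv_noiseless), valid_design.runs[:, k], atol=1e-6
            )

    @pytest.mark.parametrize("method,A,kw", METHOD_CASES)
    def test_agreement_with_cls_oracle(
        self, method, A, kw, X_noiseless, Xv_noiseless, calib_design, pure, cls_oracle
    ):
        """PLS1/PCR/HLA agree with classical least squares on noiseless
        full-rank mixtures (method equivalence at full information)."""
        C = cls_oracle(Xv_noiseless.absorbance)
        for k in range(3):
            m = _fit(method, X_noiseless, calib_design.runs[:, k], A, kw,
                     pure.absorbance[k])
            np.testing.assert_allclose(predict(m, Xv_noiseless), C[:, k], atol=1e-6)


class TestStructuralProperties:
    def test_training_rss_nonincreasing_in_factors(self, calib_design, pure):
        rng = np.random.default_rng(7)
        from mvcal import default_three_drug_spec, simulate_mixtures

        spec = default_three_drug_spec(noise_sd=0.005, seed=21)
        X = simulate_mixtures(calib_design, pure, spec)
        y = calib_design.runs[:, 0]
        for fitter in (fit_pls1, fit_pcr):
            rss = [
                float(np.sum((predict(fitter(X, y, a), X) - y) ** 2))
                for a in range(1, 8)
            ]
            assert all(b <= a + 1e-10 for a, b in zip(rss, rss[1:])), rss

    def test_hla_predictions_invariant_to_interference_directions(
        self, X_noiseless, Xv_noiseless, calib_design, pure
    ):
        """Adding any combination of interference-basis vectors to a test
        spectrum leaves HLA predictions unchanged."""
        m = fit_hla(X_noiseless, calib_design.runs[:, 0], 2,
                    pure_spectrum=pure.absorbance[0])
        rng = np.random.default_rng(3)
        shift = m.hla.interference_basis @ rng.normal(0, 5.0, 2)
        shifted = SpectraSet(
            grid=Xv_noiseless.grid, absorbance=Xv_noiseless.absorbance + shift
        )
        np.testing.assert_allclose(
            predict(m, shifted), predict(m, Xv_noiseless), atol=1e-8
        )

    def test_hla_nas_orthogonal_to_interference_basis(
        self, X_noiseless, calib_design, pure
    ):
        m = fit_hla(X_noiseless, calib_design.runs[:, 1], 2,
                    pure_spectrum=pure.absorbance[1])
        inner = m.hla.interference_basis.T @ m.hla.nas_vector
        assert np.all(np.abs(inner) <= 1e-8 * np.linalg.norm(m.hla.nas_vector))

    @pytest.mark.parametrize("method,A,kw", METHOD_CASES[:3])
    def test_repeated_fits_are_bit_identical(
        self, method, A, kw, X_noiseless, calib_design, pure
    ):
        y = calib_design.runs[:, 2]
        m1 = _fit(method, X_noiseless, y, A, kw, pure.absorbance[2])
        m2 = _fit(method, X_noiseless, y, A, kw, pure.absorbance[2])
        assert np.array_equal(m1.regression_vector, m2.regression_vector)

    def test_duplicate_samples_predict_identically(self, X_noiseless, calib_design):
        X2 = SpectraSet(
            grid=X_noiseless.grid,
            absorbance=np.vstack([X_noiseless.absorbance] * 2),
        )
        y2 = np.concatenate([calib_design.runs[:, 0]] * 2)
        m = fit_pcr(X2, y2, 3)
        p = predict(m, X2)
        # blocked matmul may differ by an ulp between rows; equality to
        # 1e-12 mg/L is the meaningful statement
        np.testing.assert_allclose(p[:15], p[15:], atol=1e-12)

    def test_pcr_at_full_rank_equals_ols_on_scores(self, calib_design, pure):
        from mvcal import default_three_drug_spec, simulate_mixtures

        spec = default_three_drug_spec(noise_sd=0.01, seed=5)
        X = simulate_mixtures(calib_design, pure, spec)
        y = calib_design.runs[:, 0]
        m = fit_pcr(X, y, 14)  # min(n-1, p) for 15 samples
        Xc = X.absorbance - X.absorbance.mean(axis=0)
        b_ols, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        np.testing.assert_allclose(
            predict(m, X), Xc @ b_ols + y.mean(), atol=1e-8
        )


class TestErrorsAndEdgeCases:
    def test_too_many_factors_raises_rank_error(self, X_noiseless, calib_design):
        with pytest.raises(RankError):
            fit_pls1(X_noiseless, calib_design.runs[:, 0], 15)
        with pytest.raises(RankError):
            fit_pcr(X_noiseless, calib_design.runs[:, 0], 4)  # rank-3 data

    def test_constant_target_raises(self, X_noiseless):
        with pytest.raises(DegenerateTargetError):
            fit_pls1(X_noiseless, np.full(15, 8.0), 2)

    def test_hla_degenerate_when_analyte_inside_interference_span(self):
        """A 'pure' spectrum built from the interferents leaves no NAS."""
        grid = WavelengthGrid(225, 1, 60)
        rng = np.random.default_rng(9)
        s1, s2 = rng.uniform(0.01, 0.1, (2, 60))
        C = rng.uniform(1, 10, (12, 2))
        X = SpectraSet(grid=grid, absorbance=C @ np.vstack([s1, s2]))
        y = C[:, 0]
        with pytest.raises(DegenerateNASError):
            fit_hla(X, y, 2, pure_spectrum=0.3 * s1 + 0.7 * s2)

    def test_hla_without_interferents_keeps_full_pure_spectrum(self):
        grid = WavelengthGrid(225, 1, 40)
        s = np.linspace(0.01, 0.08, 40)
        y = np.array([2.0, 5.0, 8.0, 11.0, 14.0])
        X = SpectraSet(grid=grid, absorbance=np.outer(y, s))
        m = fit_hla(X, y, 0, pure_spectrum=s)
        np.testing.assert_allclose(m.hla.nas_vector, s)
        np.testing.assert_allclose(predict(m, X), y, atol=1e-10)

    def test_centered_model_predicts_mean_for_mean_spectrum(
        self, X_noiseless, calib_design
    ):
        y = calib_design.runs[:, 0]
        m = fit_pls1(X_noiseless, y, 3)
        mean_spec = SpectraSet(
            grid=X_noiseless.grid,
            absorbance=X_noiseless.absorbance.mean(axis=0, keepdims=True),
        )
        np.testing.assert_allclose(predict(m, mean_spec), [y.mean()], atol=1e-10)

    def test_uncentered_hla_predicts_zero_for_blank(
        self, X_noiseless, calib_design, pure
    ):
        m = fit_hla(X_noiseless, calib_design.runs[:, 0], 2,
                    pure_spectrum=pure.absorbance[0])
        blank = SpectraSet(
            grid=X_noiseless.grid, absorbance=np.zeros((1, X_noiseless.n_points))
        )
        assert predict(m, blank)[0] == 0.0

    def test_grid_mismatch_raises(self, X_noiseless, calib_design):
        m = fit_pls1(X_noiseless, calib_design.runs[:, 0], 3)
        other = SpectraSet(
            grid=WavelengthGrid(200, 1, X_noiseless.n_points),
            absorbance=np.zeros((1, X_noiseless.n_points)),
        )
        with pytest.raises(GridError):
            predict(m, other)

    def test_serialization_roundtrip_preserves_predictions(
        self, X_noiseless, Xv_noiseless, calib_design, pure
    ):
        m = fit_hla(X_noiseless, calib_design.runs[:, 1], 2,
                    pure_spectrum=pure.absorbance[1], analyte="MKST")
        back = CalibrationModel.from_dict(m.to_dict())
        np.testing.assert_array_equal(
            predict(back, Xv_noiseless), predict(m, Xv_noiseless)
        )


class TestUnivariateFit:
    def test_exact_line(self):
        r = univariate_linear_fit([1, 2, 3], [0.1, 0.2, 0.3])
        assert r.slope == pytest.approx(0.1)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.correlation == pytest.approx(1.0)

    def test_sign_flipped_slope_gives_negative_correlation(self):
        r = univariate_linear_fit([1, 2, 3], [0.3, 0.2, 0.1])
        assert r.correlation == pytest.approx(-1.0)

    def test_noisy_line_slope_within_3_se(self):
        rng = np.random.default_rng(12)
        c = np.linspace(1, 25, 20)
        a = 0.05 * c + 0.01 + rng.normal(0, 0.004, 20)
        r = univariate_linear_fit(c, a)
        # closed-form OLS slope SE
        resid = a - (r.slope * c + r.intercept)
        se = np.sqrt(np.sum(resid**2) / 18 / np.sum((c - c.mean()) ** 2))
        assert abs(r.slope - 0.05) < 3 * se

    def test_constant_concentration_raises(self):
        with pytest.raises(DegenerateTargetError):
            univariate_linear_fit([5, 5, 5], [0.1, 0.2, 0.3])
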