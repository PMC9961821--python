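"""Quadratic response-surface fitting and the ANOVA diagnostic battery."""

import numpy as np
import pytest
import statsmodels.api as sm

import extractopt as eo
from extractopt.rsm import SingularDesignError, model_matrix

from conftest import random_ccd_response


class TestFit:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_statsmodels_ols(self, seed):
        """Independent oracle: coefficients and residual SS agree with statsmodels."""
        design, y = random_ccd_response(seed)
        model = eo.fit_quadratic(design, y)
        ref = sm.OLS(y, model_matrix(design.coded)).fit()
        assert np.allclose(model.coefficients, ref.params, rtol=1e-10)
        assert model.residual_ss == pytest.approx(ref.ssr, rel=1e-10)
        assert model.residual_df == int(ref.df_resid)

    def test_noiseless_surface_recovered_to_machine_precision(self):
        spec = eo.SurfaceSpec(sigma=0.0, seed=1)
        design, table = eo.generate_dataset(spec)
        model = eo.fit_quadratic(design, table.values[:, 0])
        assert np.allclose(model.coefficients, spec.coefficients, atol=1e-12)

    def test_fixture_interaction_coefficient(self, fitted_models):
        assert fitted_models["TFC"].coefficient("X1X2") == pytest.approx(0.1450, abs=1e-4)

    def test_singular_design_rejected(self):
        # factorial-only points: x_i^2 == 1 everywhere, collinear with intercept
        factors = (eo.FactorSpec("a", 0, 1), eo.FactorSpec("b", 0, 1))
        full = eo.build_ccd(factors, 1)
        fact = [t == "factorial" for t in full.run_type]
        bad = eo.DesignMatrix(
            factors=factors,
            natural=np.tile(full.natural[fact], (3, 1)),
            coded=np.tile(full.coded[fact], (3, 1)),
            run_type=["factorial"] * 12,
        )
        with pytest.raises(SingularDesignError):
            eo.fit_quadratic(bad, np.arange(12.0))


class TestPredict:
    def test_center_point_gives_intercept(self, fitted_models):
        for model in fitted_models.values():
            assert eo.predict(model, [50, 3, 60]) == pytest.approx(model.intercept)

    def test_natural_and_coded_agree(self, fitted_models):
        model = fitted_models["TPC"]
        assert eo.predict(model, [75, 3.7, 67]) == pytest.approx(
            eo.predict(model, [1.0, 0.7, 0.7], coded=True)
        )

    def test_batch_matches_scalar(self, fitted_models):
        model = fitted_models["DPPH"]
        pts = np.array([[75, 4, 70], [25, 2, 50], [50, 3, 60]], dtype=float)
        batch = eo.predict(model, pts)
        assert np.allclose(batch, [eo.predict(model, p) for p in pts])

    def test_dimension_mismatch(self, fitted_models):
        with pytest.raises(ValueError):
            eo.predict(fitted_models["TPC"], [1.0, 2.0])


class TestAnova:
    def test_ss_decomposition(self, anova_reports):
        """Model + lack-of-fit + pure-error SS account for the total corrected SS."""
        for rep in anova_reports.values():
            assert rep.model_ss + rep.lack_of_fit_ss + rep.pure_error_ss == pytest.approx(
                rep.total_ss, rel=1e-10
            )
            assert rep.pred_r2 <= rep.r2
            assert all(row.ss >= 0 for row in rep.terms)

    def test_orthogonal_term_ss(self, table1, fitted_models):
        """Linear/interaction columns are orthogonal: partial SS = b^2 * sum(x^2)."""
        design, responses = table1
        A = model_matrix(design.coded)
        rep = eo.anova(fitted_models["TFC"], design, responses.column("TFC"))
        names = fitted_models["TFC"].terms
        for term in ("X1", "X2", "X3", "X1X2", "X1X3", "X2X3"):
            j = names.index(term)
            expected = rep.term(term).coefficient ** 2 * np.sum(A[:, j] ** 2)
            assert rep.term(term).ss == pytest.approx(expected, rel=1e-10)

    def test_significance_flags_match_reported_pattern(self, anova_reports):
        """Terms reported significant in the study come out with p < 0.05 and vice versa."""
        reported = {
            "TPC": {"X1": True, "X2": False, "X3": True, "X1X2": True, "X1X3": False,
                    "X2X3": True, "X1^2": True, "X2^2": True, "X3^2": True},
            "TFC": {"X1": True, "X2": True, "X3": True, "X1X2": True, "X1X3": True,
                    "X2X3": False, "X1^2": False, "X2^2": True, "X3^2": True},
            "DPPH": {"X1": True, "X2": False, "X3": False, "X1X2": True, "X1X3": True,
                     "X2X3": True, "X1^2": True, "X2^2": True, "X3^2": True},
            "CUPRAC": {t: True for t in
                       ("X1", "X2", "X3", "X1X2", "X1X3", "X2X3", "X1^2", "X2^2", "X3^2")},
        }
        for resp, flags in reported.items():
            rep = anova_reports[resp]
            for term, expect in flags.items():
                assert rep.term(term).significant is expect, (resp, term)

    def test_order_invariance(self, table1):
        """Shuffling run order leaves every ANOVA statistic unchanged."""
        design, responses = table1
        perm = np.random.default_rng(3).permutation(design.n_runs)
        shuffled = eo.DesignMatrix(
            factors=design.factors,
            natural=design.natural[perm],
            coded=design.coded[perm],
            run_type=[design.run_type[i] for i in perm],
        )
        y = responses.column("DPPH")
        a = eo.anova(eo.fit_quadratic(design, y), design, y)
        b = eo.anova(eo.fit_quadratic(shuffled, y[perm]), shuffled, y[perm])
        assert b.r2 == pytest.approx(a.r2, rel=1e-12)
        assert b.press == pytest.approx(a.press, rel=1e-10)
        assert b.lack_of_fit_f == pytest.approx(a.lack_of_fit_f, rel=1e-10)
        assert b.term("X1X3").ss == pytest.approx(a.term("X1X3").ss, rel=1e-10)

    def test_no_replicates_flags_lack_of_fit_unavailable(self):
        design, table = eo.generate_dataset(eo.SurfaceSpec(sigma=0.05, n_center=1, seed=5))
        y = table.values[:, 0]
        rep = eo.anova(eo.fit_quadratic(design, y), design, y)
        assert not rep.has_lack_of_fit
        assert rep.lack_of_fit_f is None and rep.pure_error_ss is None


class TestPress:
    @pytest.mark.parametrize("seed", range(5))
    def test_hat_matrix_equals_brute_force_loo(self, seed):
        """Leverage shortcut equals literally refitting with each run left out."""
        design, y = random_ccd_response(seed, n_center=3)
        model = eo.fit_quadratic(design, y)
        press, _ = eo.press_and_predicted_r2(model, design, y)
        A = model_matrix(design.coded)
        brute = 0.0
        for i in range(design.n_runs):
            keep = np.arange(design.n_runs) != i
            beta = np.linalg.lstsq(A[keep], y[keep], rcond=None)[0]
            brute += (y[i] - A[i] @ beta) ** 2
        assert press == pytest.approx(brute, rel=1e-8)

    def test_press_dominates_residual_ss(self, table1, fitted_models):
        design, responses = table1
        for name, model in fitted_models.items():
            press, pred_r2 = eo.press_and_predicted_r2(design=design, model=model,
                                                       y=responses.column(name))
            assert press >= model.residual_ss
            assert pred_r2 <= 1.0


class TestInformationCriteria:
    def test_monotone_in_sse(self, fitted_models):
        model = fitted_models["DPPH"]
        aicc0, bic0 = eo.information_criteria(model)
        import dataclasses

        worse = dataclasses.replace(model, residual_ss=model.residual_ss * 2)
        aicc1, bic1 = eo.information_criteria(worse)
        assert aicc1 > aicc0 and bic1 > bic0

    def test_undefined_below_minimum_n(self, fitted_models):
        with pytest.raises(ValueError):
            eo.information_criteria(fitted_models["TPC"], n=11, p=10)


class TestAdequacy:
    def test_cv_scale_invariant(self, table1):
        design, responses = table1
        y = responses.column("TFC")
        cv1, _ = eo.adequacy_stats(eo.fit_quadratic(design, y), design, y)
        cv2, _ = eo.adequacy_stats(eo.fit_quadratic(design, 7.3 * y), design, 7.3 * y)
        assert cv2 == pytest.approx(cv1, rel=1e-10)

    def test_zero_mean_response_rejected(self, table1):
        design, responses = table1
        y = responses.column("TPC") - responses.column("TPC").mean()
        model = eo.fit_quadratic(design, y)
        with pytest.raises(ValueError):
            eo.adequacy_stats(model, design, y)
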