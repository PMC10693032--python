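"""ilr geometry, compositional OLS, multivariate F and the bootstrap."""

import numpy as np
import pytest

import placomp as pc
from placomp.compreg import (
    TRIMESTERS,
    bootstrap_inference,
    composition_effect,
    ilr_basis,
    ilr_inverse,
    ilr_transform,
    median_f_pvalue,
    multivariate_f,
)
from placomp.containers import closure
from placomp.design import ModelSpec

from helpers import standardize_exposures


@pytest.fixture(scope="module")
def seeded_fit():
    gam = np.array([0.3, -0.1, 0.05, 0.0, 0.2])
    cohort, truth = pc.generate_cohort(
        n=250, seed=42, effect_spec={"pm25_t1": gam}, composition_noise_sd=0.2
    )
    comp = pc.CellComposition(list(cohort["sample_id"]), truth.cell_types, truth.compositions)
    c2 = standardize_exposures(cohort)
    return pc.fit_compositional(comp, c2, ModelSpec()), comp, c2, gam


class TestIlrBasis:
    def test_two_part_closed_form(self):
        basis = ilr_basis(("a", "b"))
        np.testing.assert_allclose(basis.V, [[1 / np.sqrt(2)], [-1 / np.sqrt(2)]], atol=1e-15)

    @pytest.mark.parametrize("K", [2, 3, 6, 9])
    def test_orthonormal_with_zero_column_sums(self, K):
        basis = ilr_basis([f"p{i}" for i in range(K)])
        np.testing.assert_allclose(basis.V.T @ basis.V, np.eye(K - 1), atol=1e-12)
        np.testing.assert_allclose(basis.V.sum(axis=0), 0.0, atol=1e-12)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            ilr_basis(("a", "a", "b"))


class TestIlrTransform:
    def test_symmetric_two_part_maps_to_origin(self):
        basis = ilr_basis(("a", "b"))
        assert ilr_transform(np.array([[0.5, 0.5]]), basis)[0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_pivot_coordinate_closed_form(self):
        basis = ilr_basis(("a", "b"))
        z = ilr_transform(np.array([[0.8, 0.2]]), basis)[0, 0]
        assert z == pytest.approx(np.log(4.0) / np.sqrt(2.0), abs=1e-10)
        assert z == pytest.approx(0.98026, abs=1e-5)

    def test_round_trip_identity(self, rng):
        basis = ilr_basis([f"p{i}" for i in range(6)])
        X = rng.dirichlet(np.ones(6) * 3, size=50)
        np.testing.assert_allclose(ilr_inverse(ilr_transform(X, basis), basis), X, atol=1e-10)

    def test_scale_invariance_before_closure(self, rng):
        basis = ilr_basis([f"p{i}" for i in range(4)])
        raw = rng.uniform(0.1, 2.0, size=(20, 4))
        np.testing.assert_allclose(
            ilr_transform(closure(raw), basis),
            ilr_transform(closure(7.3 * raw), basis),
            atol=1e-12,
        )

    def test_nonpositive_composition_rejected(self):
        basis = ilr_basis(("a", "b", "c"))
        with pytest.raises(ValueError, match="replace_zeros"):
            ilr_transform(np.array([[0.5, 0.5, 0.0]]), basis)


class TestFitCompositional:
    def test_noiseless_coefficients_equal_injected_effects(self):
        gam = np.array([0.3, -0.1, 0.05, 0.0, 0.2])
        cohort, truth = pc.generate_cohort(
            n=200, seed=5, composition_noise_sd=0.0, effect_spec={"pm25_t1": gam}
        )
        comp = pc.CellComposition(
            list(cohort["sample_id"]), truth.cell_types, truth.compositions
        )
        fit = pc.fit_compositional(comp, standardize_exposures(cohort), ModelSpec())
        c = fit.design_columns.index("pm25_t1")
        np.testing.assert_allclose(fit.coefficients[c], gam, atol=1e-8)
        other = fit.design_columns.index("maternal_age")
        np.testing.assert_allclose(fit.coefficients[other], 0.0, atol=1e-8)

    def test_null_simulation_shows_no_spurious_signal(self):
        cohort, truth = pc.generate_cohort(n=500, seed=31)
        comp = pc.CellComposition(
            list(cohort["sample_id"]), truth.cell_types, truth.compositions
        )
        fit = pc.fit_compositional(comp, standardize_exposures(cohort), ModelSpec())
        for tri in TRIMESTERS:
            c = fit.design_columns.index(tri)
            se = np.sqrt(fit.xtx_inv[c, c] * np.diag(fit.residual_covariance))
            assert np.abs(fit.coefficients[c] / se).max() < 4.0

    def test_coefficient_recovery_within_three_ses(self):
        gam = np.array([0.3, -0.1, 0.05, 0.0, 0.2])
        hits = 0
        trials = 40
        for s in range(trials):
            cohort, truth = pc.generate_cohort(
                n=500, seed=300 + s, effect_spec={"pm25_t1": gam}, composition_noise_sd=0.3
            )
            comp = pc.CellComposition(
                list(cohort["sample_id"]), truth.cell_types, truth.compositions
            )
            fit = pc.fit_compositional(comp, standardize_exposures(cohort), ModelSpec())
            c = fit.design_columns.index("pm25_t1")
            se = np.sqrt(fit.xtx_inv[c, c] * np.diag(fit.residual_covariance))
            hits += bool(np.all(np.abs(fit.coefficients[c] - gam) <= 3 * se))
        assert hits >= int(0.90 * trials)

    def test_collinear_design_rejected(self, seeded_fit):
        _, comp, cohort, _ = seeded_fit
        bad = cohort.copy()
        bad["pm25_t2"] = bad["pm25_t1"]
        with pytest.raises(ValueError, match="collinear"):
            pc.fit_compositional(comp, bad, ModelSpec())


class TestCompositionEffect:
    def test_zero_coefficient_row_gives_zero_effect(self, seeded_fit):
        fit, *_ = seeded_fit
        c = fit.design_columns.index("pm25_t2")
        saved = fit.coefficients[c].copy()
        fit.coefficients[c] = 0.0
        np.testing.assert_allclose(composition_effect(fit, "pm25_t2"), 0.0, atol=1e-15)
        fit.coefficients[c] = saved

    def test_effects_sum_to_zero(self, seeded_fit):
        fit, *_ = seeded_fit
        for tri in TRIMESTERS:
            assert abs(composition_effect(fit, tri).sum()) < 1e-10

    def test_recovers_forward_simulated_truth(self):
        gam = np.array([0.25, -0.15, 0.05, 0.0, 0.1])
        base = closure(np.array([0.636, 0.091, 0.127, 0.099, 0.012, 0.036]))
        basis = ilr_basis(pc.PLACENTA_CELL_TYPES)
        eta0 = ilr_transform(base.reshape(1, -1), basis)
        truth_delta = (ilr_inverse(eta0 + gam, basis) - ilr_inverse(eta0, basis)).ravel()
        cohort, truth = pc.generate_cohort(
            n=2000, seed=8, effect_spec={"pm25_t1": gam}, composition_noise_sd=0.15,
            baseline_composition={"female": base, "male": base},
        )
        comp = pc.CellComposition(
            list(cohort["sample_id"]), truth.cell_types, truth.compositions
        )
        fit = pc.fit_compositional(comp, standardize_exposures(cohort), ModelSpec())
        np.testing.assert_allclose(
            composition_effect(fit, "pm25_t1"), truth_delta, atol=0.01
        )

    def test_unknown_trimester_rejected(self, seeded_fit):
        fit, *_ = seeded_fit
        with pytest.raises(ValueError):
            composition_effect(fit, "pm25_t9")


class TestMultivariateF:
    def test_two_part_reduces_to_squared_t(self, rng):
        # with a single ilr coordinate the Wilks test is the ordinary partial F
        n = 120
        cohort, truth = pc.generate_cohort(n=n, seed=14)
        y = rng.dirichlet((4, 6), size=n)
        comp = pc.CellComposition(list(cohort["sample_id"]), ("a", "b"), y)
        c2 = standardize_exposures(cohort)
        spec = ModelSpec()
        fit = pc.fit_compositional(comp, c2, spec, basis=ilr_basis(("a", "b")))
        F, df1, df2 = multivariate_f(fit, "pm25_t1")
        assert df1 == 1

        import statsmodels.api as sm
        from placomp.design import build_design

        X = build_design(c2, spec)
        z = ilr_transform(y, ilr_basis(("a", "b")))[:, 0]
        ols = sm.OLS(z, X).fit()
        assert F == pytest.approx(ols.tvalues["pm25_t1"] ** 2, abs=1e-10)
        p_wilks = 1 - __import__("scipy.stats", fromlist=["f"]).f.cdf(F, df1, df2)
        assert p_wilks == pytest.approx(ols.pvalues["pm25_t1"], abs=1e-10)

    def test_matches_statsmodels_manova(self, seeded_fit):
        from statsmodels.multivariate.manova import MANOVA
        from placomp.design import build_design

        fit, comp, cohort, _ = seeded_fit
        X = build_design(cohort, ModelSpec())
        Z = ilr_transform(comp, fit.basis)
        mv = MANOVA(Z, X.to_numpy())
        c = fit.design_columns.index("pm25_t1")
        contrast = np.zeros((1, X.shape[1]))
        contrast[0, c] = 1.0
        res = mv.mv_test(hypotheses=[("t1", contrast)])
        tab = res.results["t1"]["stat"]
        F, df1, df2 = multivariate_f(fit, "pm25_t1")
        assert F == pytest.approx(float(tab.loc["Wilks' lambda", "F Value"]), rel=1e-8)
        assert df2 == pytest.approx(float(tab.loc["Wilks' lambda", "Den DF"]))

    def test_null_p_values_uniform(self):
        from scipy import stats

        pvals = []
        for s in range(300):
            cohort, truth = pc.generate_cohort(n=150, seed=50_000 + s)
            comp = pc.CellComposition(
                list(cohort["sample_id"]), truth.cell_types, truth.compositions
            )
            fit = pc.fit_compositional(comp, standardize_exposures(cohort), ModelSpec())
            F, df1, df2 = multivariate_f(fit, "pm25_t1")
            pvals.append(stats.f.sf(F, df1, df2))
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.08

    def test_strong_effect_detected(self):
        gam = np.array([0.5, -0.3, 0.1, 0.0, 0.2])
        cohort, truth = pc.generate_cohort(
            n=500, seed=99, effect_spec={"pm25_t1": gam}, composition_noise_sd=0.2
        )
        comp = pc.CellComposition(
            list(cohort["sample_id"]), truth.cell_types, truth.compositions
        )
        fit = pc.fit_compositional(comp, standardize_exposures(cohort), ModelSpec())
        from scipy import stats

        F, df1, df2 = multivariate_f(fit, "pm25_t1")
        assert stats.f.sf(F, df1, df2) < 1e-4


class TestBasisInvariance:
    def test_effects_and_f_invariant_to_pivot_order(self, seeded_fit):
        fit, comp, cohort, _ = seeded_fit
        perm = [2, 5, 0, 3, 1, 4]
        comp_p = pc.CellComposition(
            list(comp.sample_ids),
            tuple(comp.cell_types[j] for j in perm),
            comp.values[:, perm],
        )
        fit_p = pc.fit_compositional(comp_p, cohort, ModelSpec())
        for tri in TRIMESTERS:
            d = composition_effect(fit, tri)
            d_p = composition_effect(fit_p, tri)
            np.testing.assert_allclose(d_p, d[perm], atol=1e-8)
            np.testing.assert_allclose(
                multivariate_f(fit_p, tri)[0], multivariate_f(fit, tri)[0], atol=1e-8
            )


class TestBootstrap:
    def test_fixed_seed_bit_identical(self, seeded_fit):
        _, comp, cohort, _ = seeded_fit
        kw = dict(B=100, seed=7)
        f1 = bootstrap_inference(comp, cohort, ModelSpec(), **kw)
        f2 = bootstrap_inference(comp, cohort, ModelSpec(), **kw)
        for tri in TRIMESTERS:
            np.testing.assert_array_equal(f1.ci_lower[tri], f2.ci_lower[tri])
            np.testing.assert_array_equal(f1.ci_upper[tri], f2.ci_upper[tri])
            assert f1.overall_p[tri] == f2.overall_p[tri]

    def test_ci_width_shrinks_with_sample_size(self):
        widths = {}
        for n in (100, 400):
            cohort, truth = pc.generate_cohort(n=n, seed=61, composition_noise_sd=0.2)
            comp = pc.CellComposition(
                list(cohort["sample_id"]), truth.cell_types, truth.compositions
            )
            fit = bootstrap_inference(
                comp, standardize_exposures(cohort), ModelSpec(), B=300, seed=3
            )
            widths[n] = np.mean(
                [np.mean(fit.ci_upper[t] - fit.ci_lower[t]) for t in TRIMESTERS]
            )
        ratio = widths[100] / widths[400]
        assert 1.7 < ratio < 2.3

    def test_median_f_pvalue_monotone_and_bounded(self):
        from scipy import stats

        central_median = stats.f.ppf(0.5, 5, 100)
        assert median_f_pvalue(0.9 * central_median, 5, 100) == 1.0  # no evidence
        p_mid = median_f_pvalue(5.0, 5, 100)
        p_large = median_f_pvalue(25.0, 5, 100)
        assert 0.0 <= p_large < p_mid < 1.0

    def test_small_B_rejected(self, seeded_fit):
        _, comp, cohort, _ = seeded_fit
        with pytest.raises(ValueError):
            bootstrap_inference(comp, cohort, ModelSpec(), B=50)
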