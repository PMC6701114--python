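"""Per-pair nested OLS, partial F-test, interaction t-tests, DFFITS, lines.

Every statistic is checked against at least one independent route: explicit
normal equations with quadrature tail probabilities (tests/oracles.py),
statsmodels, or brute-force leave-one-out refits.
"""

import numpy as np
import pytest

import omescreen as om
from omescreen.regress import _ordered_labels

import oracles


def _fit(d, **kw):
    return om.fit_pair(d["y"], d["x"], d["cohorts"], d["reference"], **kw)


class TestFitPairContracts:
    def test_constant_response_is_degenerate(self, pair10):
        with pytest.raises(om.DegenerateFitError) as exc:
            om.fit_pair(np.full(10, 0.3), pair10["x"], pair10["cohorts"], "A")
        assert exc.value.reason == "constant_response"

    def test_cohort_with_one_sample(self, pair10):
        cohorts = pair10["cohorts"].copy()
        cohorts[-1] = "C"
        with pytest.raises(om.InsufficientDataError, match="'C'"):
            om.fit_pair(pair10["y"], pair10["x"], cohorts, "A")

    def test_x_constant_in_every_cohort_is_singular(self):
        y = np.array([0.1, 0.2, 0.3, 0.15, 0.25, 0.35, 0.1, 0.3, 0.2, 0.4])
        x = np.ones(10)
        cohorts = np.array(["A"] * 5 + ["B"] * 5)
        with pytest.raises(om.DegenerateFitError) as exc:
            om.fit_pair(y, x, cohorts, "A")
        assert exc.value.reason == "singular_design"

    def test_too_few_samples_for_full_model(self):
        # 2 cohorts -> 4 parameters, need n >= 5
        y = np.array([0.1, 0.2, 0.3, 0.4])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        cohorts = np.array(["A", "A", "B", "B"])
        with pytest.raises(om.InsufficientDataError):
            om.fit_pair(y, x, cohorts, "A")

    def test_cohort_means_only_response_gives_null_f(self):
        # y depends only on cohort, exactly: nested models coincide
        cohorts = np.array(["A"] * 5 + ["B"] * 5)
        y = np.where(cohorts == "A", 0.25, 0.5)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 1.5, 2.5, 3.5, 4.5, 5.5])
        fit = om.fit_pair(y, x, cohorts, "A")
        assert fit.F == 0.0
        assert fit.p == 1.0

    def test_perfect_full_fit_flagged(self):
        # y exactly linear in x with cohort-specific slopes, no noise
        cohorts = np.array(["A"] * 5 + ["B"] * 5)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 1.5, 2.5, 3.5, 4.5, 5.5])
        y = np.where(cohorts == "A", 0.1 + 0.05 * x, 0.2 + 0.02 * x)
        fit = om.fit_pair(y, x, cohorts, "A")
        assert fit.degenerate_perfect
        assert fit.p == 0.0


class TestFitPairAgainstOracles:
    def test_beta_rss_f_p_match_normal_equations(self, pair10, fit10):
        labels = _ordered_labels(pair10["cohorts"], "A")
        X = oracles.full_design(pair10["x"], pair10["cohorts"], labels)
        beta_o, rss_full_o = oracles.ols_normal_equations(X, pair10["y"])
        _, rss_red_o = oracles.ols_normal_equations(X[:, :2], pair10["y"])
        n, K = 10, 2
        df_full, df_num = n - 2 * K, K
        F_o = ((rss_red_o - rss_full_o) / df_num) / (rss_full_o / df_full)
        p_o = oracles.f_upper_tail(F_o, df_num, df_full)

        np.testing.assert_allclose(fit10.beta, beta_o, rtol=1e-10)
        assert fit10.rss_full == pytest.approx(rss_full_o, rel=1e-10)
        assert fit10.rss_reduced == pytest.approx(rss_red_o, rel=1e-10)
        assert fit10.F == pytest.approx(F_o, rel=1e-10)
        assert fit10.p == pytest.approx(p_o, rel=1e-8)
        assert (fit10.df_full, fit10.df_reduced) == (6, 8)

    def test_matches_statsmodels(self, pair10, fit10):
        import statsmodels.api as sm

        labels = _ordered_labels(pair10["cohorts"], "A")
        X = oracles.full_design(pair10["x"], pair10["cohorts"], labels)
        full = sm.OLS(pair10["y"], X).fit()
        red = sm.OLS(pair10["y"], X[:, :2]).fit()
        F_sm, p_sm, _ = full.compare_f_test(red)
        np.testing.assert_allclose(fit10.beta, full.params, rtol=1e-9)
        assert fit10.F == pytest.approx(float(F_sm), rel=1e-9)
        assert fit10.p == pytest.approx(float(p_sm), rel=1e-9)


class TestInteractionPvalues:
    def test_reference_cohort_refused(self, fit10):
        with pytest.raises(om.ContractError, match="reference"):
            om.interaction_pvalue(fit10, "A")

    def test_identical_slopes_give_large_p(self):
        # both cohorts share slope 0.05; symmetric +-eps perturbation only
        rng = np.random.default_rng(11)
        n = 20
        x = np.concatenate([np.linspace(1, 6, 10), np.linspace(1, 6, 10)])
        cohorts = np.array(["A"] * 10 + ["B"] * 10)
        eps = rng.normal(0, 0.01, 10)
        noise = np.concatenate([eps, eps])  # same draw in both cohorts
        y = 0.1 + 0.05 * x + noise
        fit = om.fit_pair(y, x, cohorts, "A")
        assert fit.interaction_p["B"] > 0.5

    def test_three_cohort_fixture_matches_covariance_oracle(self):
        rng = np.random.default_rng(5)
        n_per = 8
        cohorts = np.repeat(["HC", "CD", "UC"], n_per)
        x = rng.lognormal(0, 0.5, size=3 * n_per)
        slopes = {"HC": 0.05, "CD": 0.25, "UC": -0.10}
        y = 0.2 + np.array([slopes[c] for c in cohorts]) * x \
            + rng.normal(0, 0.03, 3 * n_per)
        fit = om.fit_pair(y, x, cohorts, "HC")

        labels = _ordered_labels(cohorts, "HC")
        X = oracles.full_design(x, cohorts, labels)
        beta_o, rss_o = oracles.ols_normal_equations(X, y)
        cov = np.linalg.inv(X.T @ X) * (rss_o / fit.df_full)
        K = 3
        for j, cohort in enumerate(labels[1:], start=1):
            t = beta_o[K + j] / np.sqrt(cov[K + j, K + j])
            p_o = oracles.t_two_sided(float(t), fit.df_full)
            assert fit.interaction_p[cohort] == pytest.approx(p_o, rel=1e-8)

    def test_planted_strong_interaction_detected(self):
        rng = np.random.default_rng(2024)
        n = 40
        cohorts = np.array(["A"] * 20 + ["B"] * 20)
        x = rng.lognormal(0, 0.4, n)
        slope = np.where(cohorts == "A", 2.0, -2.0)
        y = 1.0 + slope * x + rng.normal(0, 0.2, n)
        fit = om.fit_pair(y, x, cohorts, "A")
        assert fit.interaction_p["B"] < 0.001


class TestDffits:
    def test_closed_form_equals_loo_refits(self, pair12, fit12):
        labels = _ordered_labels(pair12["cohorts"], "A")
        X = oracles.full_design(pair12["x"], pair12["cohorts"], labels)
        brute = oracles.loo_dffits(X, pair12["y"])
        np.testing.assert_allclose(fit12.dffits, brute, rtol=1e-10)
        assert fit12.max_influence == pytest.approx(np.max(np.abs(brute)),
                                                    rel=1e-10)

    def test_matches_statsmodels_influence(self, pair12, fit12):
        import statsmodels.api as sm
        from statsmodels.stats.outliers_influence import OLSInfluence

        labels = _ordered_labels(pair12["cohorts"], "A")
        X = oracles.full_design(pair12["x"], pair12["cohorts"], labels)
        infl = OLSInfluence(sm.OLS(pair12["y"], X).fit())
        np.testing.assert_allclose(fit12.dffits, infl.dffits[0], rtol=1e-9)

    def test_exchangeable_observations_equal_influence(self):
        # two observations with identical (x, cohort, y) must tie
        y = np.array([0.1, 0.2, 0.32, 0.32, 0.5, 0.12, 0.2, 0.33, 0.46, 0.5])
        x = np.array([1.0, 2.0, 3.0, 3.0, 5.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        cohorts = np.array(["A"] * 5 + ["B"] * 5)
        fit = om.fit_pair(y, x, cohorts, "A")
        assert abs(fit.dffits[2]) == pytest.approx(abs(fit.dffits[3]), rel=1e-12)

    def test_planted_extreme_point_attains_max(self, pair12):
        y, x = pair12["y"].copy(), pair12["x"].copy()
        y[5], x[5] = 10 * y[5], 10 * x[5]
        fit = om.fit_pair(y, x, pair12["cohorts"], "A")
        labels = _ordered_labels(pair12["cohorts"], "A")
        X = oracles.full_design(x, pair12["cohorts"], labels)
        brute = oracles.loo_dffits(X, y)
        assert int(np.argmax(np.abs(fit.dffits))) == 5
        assert int(np.argmax(np.abs(brute))) == 5
        np.testing.assert_allclose(fit.dffits, brute, rtol=1e-10)

    def test_minimal_residual_df_skips_diagnostics(self):
        # n = 5 with 2 cohorts: df_full = 1, deletion fit undefined
        y = np.array([0.1, 0.25, 0.3, 0.2, 0.45])
        x = np.array([1.0, 2.0, 3.0, 1.5, 3.5])
        cohorts = np.array(["A", "A", "A", "B", "B"])
        with pytest.warns(UserWarning, match="too few residual df"):
            fit = om.fit_pair(y, x, cohorts, "A")
        assert fit.dffits is None
        assert fit.max_influence is None


class TestCohortLines:
    def test_reference_line_is_base_coefficients(self, fit10):
        ln = fit10.cohort_lines[0]
        assert ln.cohort == "A"
        assert ln.intercept == pytest.approx(fit10.coefficient("intercept"))
        assert ln.slope == pytest.approx(fit10.coefficient("slope"))

    def test_nonreference_line_sums_offsets(self, fit10):
        ln = fit10.cohort_lines[1]
        assert ln.intercept == pytest.approx(
            fit10.coefficient("intercept") + fit10.coefficient("cohort:B"))
        assert ln.slope == pytest.approx(
            fit10.coefficient("slope") + fit10.coefficient("interaction:B"))

    def test_interaction_cancellation_gives_flat_line(self):
        # B's generating slope is 0 with no noise in B around its mean trend:
        # build data so beta_cx = -beta_x exactly by symmetry of the fit
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        cohorts = np.array(["A"] * 5 + ["B"] * 5)
        y = np.where(cohorts == "A", 0.1 + 0.08 * x, 0.4)
        # perturbation orthogonal to both the intercept and x, so the
        # fitted per-cohort slopes are unchanged
        y = y + np.tile([0.005, -0.005, 0.0, -0.005, 0.005], 2)
        fit = om.fit_pair(y, x, cohorts, "A")
        ln_b = fit.cohort_lines[1]
        assert ln_b.slope == pytest.approx(0.0, abs=1e-12)

    def test_segments_span_cohort_specific_ranges(self, fit10, pair10):
        for ln in fit10.cohort_lines:
            xs = pair10["x"][pair10["cohorts"] == ln.cohort]
            assert (ln.x_min, ln.x_max) == (xs.min(), xs.max())

    def test_glyph_matches_hand_computed_affine_map(self):
        lines = [
            om.CohortLine("A", intercept=0.0, slope=0.1, x_min=0.0, x_max=10.0),
            om.CohortLine("B", intercept=0.5, slope=-0.02, x_min=2.0, x_max=6.0),
        ]
        # pooled x range [0, 10]; endpoint fitted ys: A: 0, 1; B: 0.46, 0.38
        # pooled y range [0, 1] -> affine map is identity/10 on x, identity on y
        glyphs = om.glyph_segments(lines)
        ga, gb = glyphs
        assert (ga.x0, ga.x1) == (0.0, 1.0)
        assert (ga.y0, ga.y1) == (0.0, 1.0)
        assert gb.x0 == pytest.approx(0.2)
        assert gb.x1 == pytest.approx(0.6)
        assert gb.y0 == pytest.approx(0.46)
        assert gb.y1 == pytest.approx(0.38)

    def test_glyph_extremes_reach_unit_square_boundary(self, fit12):
        glyphs = om.glyph_segments(fit12.cohort_lines)
        xs = [v for g in glyphs for v in (g.x0, g.x1)]
        ys = [v for g in glyphs for v in (g.y0, g.y1)]
        assert min(xs) == pytest.approx(0.0) and max(xs) == pytest.approx(1.0)
        assert min(ys) == pytest.approx(0.0) and max(ys) == pytest.approx(1.0)
        assert all(0 <= v <= 1 for v in xs + ys)


class TestStatisticalProperties:
    def test_nesting_holds_on_simulated_pairs(self):
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(12, 40))
            k = int(rng.integers(2, 4))
            sizes = np.full(k, n // k)
            sizes[0] += n - sizes.sum()
            cohorts = np.repeat([f"C{i}" for i in range(k)], sizes)
            x = rng.lognormal(0, 0.5, n)
            y = rng.uniform(0, 1, n)
            try:
                fit = om.fit_pair(y, x, cohorts, "C0")
            except om.OmescreenError:
                continue
            assert fit.rss_reduced >= fit.rss_full

    def test_planted_slope_recovery_within_4se(self):
        """Fitted per-cohort slopes land within 4 standard errors of truth in
        at least 95% of 500 noisy replicates."""
        rng = np.random.default_rng(123)
        slopes = {"A": 0.3, "B": -0.2}
        n_per, sigma = 20, 0.04
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            cohorts = np.repeat(["A", "B"], n_per)
            x = rng.lognormal(-0.5, 0.6, 2 * n_per)
            y = 0.3 + np.array([slopes[c] for c in cohorts]) * x \
                + rng.normal(0, sigma, 2 * n_per)
            fit = om.fit_pair(y, x, cohorts, "A")
            # per-cohort slope ses from the unscaled covariance
            cov = fit._cov_unscaled * (fit.rss_full / fit.df_full)
            se_a = np.sqrt(cov[2, 2])
            se_b = np.sqrt(cov[2, 2] + cov[3, 3] + 2 * cov[2, 3])
            slope_a = fit.cohort_lines[0].slope
            slope_b = fit.cohort_lines[1].slope
            if (abs(slope_a - slopes["A"]) <= 4 * se_a
                    and abs(slope_b - slopes["B"]) <= 4 * se_b):
                hits += 1
        assert hits / n_rep >= 0.95
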