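"""Regression machinery: OLS, PGLS, LL4, AICc, LOO %PE, time calibration."""

import math

import numpy as np
import pytest

import plesiomass.allometry as al
from plesiomass.reference_predictors import get_equation
from plesiomass.synthetic_data import gen_phylo_dataset


class TestOLS:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = al.fit_log_linear_ols(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.method == "OLS"

    def test_noiseless_recovery_of_packaged_rib_equation(self):
        rec = get_equation("eq9")
        x = np.linspace(2.5, 3.5, 24)
        y = rec.coefficients["slope"] * x + rec.coefficients["intercept"]
        fit = al.fit_log_linear_ols(x, y)
        assert fit.slope == pytest.approx(1.0123, abs=1e-9)
        assert fit.intercept == pytest.approx(-0.5068, abs=1e-9)

    def test_order_invariance(self, rng):
        x = rng.normal(size=30)
        y = 1.5 * x - 0.3 + rng.normal(0, 0.1, 30)
        perm = rng.permutation(30)
        a = al.fit_log_linear_ols(x, y)
        b = al.fit_log_linear_ols(x[perm], y[perm])
        assert a.slope == pytest.approx(b.slope, abs=1e-12)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-12)

    def test_matches_normal_equations_and_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0, 2, 40)
        y = 0.8 * x + 0.1 + rng.normal(0, 0.05, 40)
        fit = al.fit_log_linear_ols(x, y)
        # closed-form normal equations
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        assert fit.slope == pytest.approx(sxy / sxx, abs=1e-10)
        assert fit.intercept == pytest.approx(y.mean() - fit.slope * x.mean(),
                                              abs=1e-10)
        sm_fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(sm_fit.params[1], abs=1e-10)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-8)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError):
            al.fit_log_linear_ols([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_slope_bias_small_under_lognormal_noise(self):
        # multiplicative noise sigma=0.05 at n=100: mean slope bias < 0.01
        slopes = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 1, 100)
            y = 2.9292 * x + 2.4367 + rng.normal(0, 0.05, 100)
            slopes.append(al.fit_log_linear_ols(x, y).slope)
        assert abs(np.mean(slopes) - 2.9292) < 0.01


class TestBrownianCovariance:
    def test_star_tree_is_diagonal(self):
        newick = "(a:7,b:7,c:7,d:7);"
        tree = al.DatedTree.from_newick(newick)
        C = al.brownian_covariance(tree, ["a", "b", "c", "d"])
        assert np.allclose(C, 7.0 * np.eye(4))

    def test_two_tip_path_lengths(self):
        # root at 10 Ma, MRCA of (a, b) at 4 Ma, all tips at 0
        tree = al.DatedTree.from_newick("((a:4,b:4):6,c:10);")
        C = al.brownian_covariance(tree, ["a", "b", "c"])
        assert np.allclose(np.diag(C), 10.0)
        assert C[0, 1] == pytest.approx(6.0)
        assert C[0, 2] == pytest.approx(0.0)

    def test_positive_semidefinite_on_random_trees(self):
        for seed in range(5):
            tree, traits = gen_phylo_dataset(12, seed=seed)
            C = al.brownian_covariance(tree, traits["taxon"].tolist())
            w = np.linalg.eigvalsh(C)
            assert w.min() > -1e-9 * w.max()
            assert np.allclose(C, C.T)

    def test_missing_tip_listed(self):
        tree = al.DatedTree.from_newick("(a:1,b:1);")
        with pytest.raises(ValueError, match="ghost"):
            al.brownian_covariance(tree, ["a", "ghost"])


class TestPGLS:
    def test_equals_ols_on_star_tree(self, rng):
        n = 12
        newick = "(" + ",".join(f"t{i}:5" for i in range(n)) + ");"
        tree = al.DatedTree.from_newick(newick)
        x = rng.normal(size=n)
        y = 1.2 * x + 0.4 + rng.normal(0, 0.2, n)
        ols = al.fit_log_linear_ols(x, y)
        pgls = al.fit_pgls(x, y, tree)
        assert pgls.slope == pytest.approx(ols.slope, abs=1e-8)
        assert pgls.intercept == pytest.approx(ols.intercept, abs=1e-8)

    def test_noiseless_recovery_on_any_tree(self):
        tree, traits = gen_phylo_dataset(15, seed=2,
                                         trait_params={"sigma2": 0.0})
        fit = al.fit_pgls(traits["x"], traits["y"], tree,
                          traits["taxon"].tolist())
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_statsmodels_gls(self):
        import statsmodels.api as sm

        tree, traits = gen_phylo_dataset(20, seed=9)
        taxa = traits["taxon"].tolist()
        C = al.brownian_covariance(tree, taxa)
        x = traits["x"].to_numpy()
        y = traits["y"].to_numpy()
        fit = al.fit_pgls(x, y, tree, taxa)
        gls = sm.GLS(y, sm.add_constant(x), sigma=C).fit()
        assert fit.slope == pytest.approx(gls.params[1], abs=1e-9)
        assert fit.intercept == pytest.approx(gls.params[0], abs=1e-9)

    def test_reml_and_ml_both_reported(self):
        tree, traits = gen_phylo_dataset(10, seed=4)
        fit = al.fit_pgls(traits["x"], traits["y"], tree,
                          traits["taxon"].tolist())
        assert fit.loglik_reml is not None
        assert np.isfinite(fit.loglik) and np.isfinite(fit.loglik_reml)


class TestLogLogistic:
    def test_noiseless_recovery_of_packaged_skullneck_curve(self):
        rec = get_equation("eq20")
        x = np.log10(np.arange(12, 77, dtype=float))
        y = np.array([rec.evaluate_log10(v) for v in x])
        fit = al.fit_log_logistic(x, y)
        assert fit.numerator == pytest.approx(1.3067, abs=1e-4)
        assert fit.scale == pytest.approx(1.5937, abs=1e-4)
        assert fit.exponent == pytest.approx(10.2847, abs=1e-4)
        assert fit.offset == pytest.approx(-1.4684, abs=1e-4)

    def test_noiseless_recovery_of_pruned_curve(self):
        rec = get_equation("eq18")
        x = np.log10(np.arange(12, 77, dtype=float))
        y = np.array([rec.evaluate_log10(v) for v in x])
        fit = al.fit_log_logistic(x, y)
        assert fit.exponent == pytest.approx(10.2843, abs=1e-3)
        assert fit.offset == pytest.approx(-1.4398, abs=1e-3)

    def test_constant_y_flags_degenerate(self):
        x = np.linspace(1.0, 2.0, 10)
        fit = al.fit_log_logistic(x, np.full(10, 3.0))
        assert fit.degenerate

    def test_affine_equivariance_in_y(self):
        rec = get_equation("eq20")
        x = np.log10(np.arange(15, 70, 3, dtype=float))
        y = np.array([rec.evaluate_log10(v) for v in x])
        base = al.fit_log_logistic(x, y)
        scaled = al.fit_log_logistic(x, 2.0 * y + 1.0)
        assert scaled.numerator == pytest.approx(2 * base.numerator, rel=1e-3)
        assert scaled.offset == pytest.approx(2 * base.offset + 1.0, rel=1e-3)
        assert scaled.exponent == pytest.approx(base.exponent, rel=1e-3)
        assert scaled.scale == pytest.approx(base.scale, rel=1e-3)

    def test_positive_x_required(self):
        with pytest.raises(ValueError):
            al.fit_log_logistic(np.array([-1.0, 1, 2, 3, 4, 5]),
                                np.zeros(6))


class TestAICc:
    def test_hand_arithmetic(self):
        assert al.aicc(-5.0, 3, 10) == pytest.approx(20.0)

    def test_k_zero(self):
        assert al.aicc(-7.0, 0, 50) == pytest.approx(14.0)

    def test_approaches_aic_for_large_n(self):
        n, k, ll = 10**5, 3, -100.0
        aic = -2 * ll + 2 * k
        assert abs(al.aicc(ll, k, n) - aic) < 1e-3

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            al.aicc(-5.0, 3, 4)


class TestLOOPredictionError:
    def test_collinear_data_zero_error(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 10.0 ** (0.5 * x + 1.0)
        s = al.loo_prediction_error(x, y, al.fit_log_linear_ols)
        assert s.mean_abs_pe == pytest.approx(0.0, abs=1e-10)
        assert s.sd_abs_pe == pytest.approx(0.0, abs=1e-10)

    def test_single_pe_formula(self):
        assert abs(110 - 100) / 100 * 100 == pytest.approx(10.0)

    def test_mean_and_sd_arithmetic(self):
        pes = np.array([10.0, 20.0])
        assert pes.mean() == pytest.approx(15.0)
        assert pes.std(ddof=1) == pytest.approx(7.0711, abs=1e-4)

    def test_matches_brute_force_oracle(self, rng):
        import statsmodels.api as sm

        for n in (8, 14, 20):
            x = rng.uniform(0, 2, n)
            y_obs = 10.0 ** (1.2 * x + 0.3 + rng.normal(0, 0.1, n))
            summary = al.loo_prediction_error(x, y_obs, al.fit_log_linear_ols)
            # independent oracle: explicit statsmodels refit per left-out row
            pes = []
            for i in range(n):
                mask = np.arange(n) != i
                res = sm.OLS(np.log10(y_obs[mask]),
                             sm.add_constant(x[mask])).fit()
                pred = 10.0 ** (res.params[0] + res.params[1] * x[i])
                pes.append(abs(y_obs[i] - pred) / pred * 100.0)
            assert summary.mean_abs_pe == pytest.approx(np.mean(pes),
                                                        abs=1e-10)
            assert summary.sd_abs_pe == pytest.approx(np.std(pes, ddof=1),
                                                      abs=1e-10)

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError):
            al.loo_prediction_error(np.arange(4.0), np.array([1.0, -2, 3, 4]),
                                    al.fit_log_linear_ols)


class TestPredictionInterval:
    def test_trunk_row_interval(self):
        pi = al.prediction_interval(1000.0, 17.73)
        assert pi.lower == pytest.approx(822.7)
        assert pi.upper == pytest.approx(1177.3)

    def test_zero_error_collapses(self):
        pi = al.prediction_interval(5.0, 0.0)
        assert pi.lower == pi.upper == pi.point == 5.0

    def test_midpoint_is_point(self):
        pi = al.prediction_interval(321.0, 23.4)
        assert 0.5 * (pi.lower + pi.upper) == pytest.approx(pi.point)


class TestTimeCalibrateMBL:
    def test_two_tip_push_back(self):
        dated = al.time_calibrate_mbl("(a,b);", {"a": 100.0, "b": 95.0},
                                      mbl=1.0, seed=0)
        lengths = sorted(
            e.length for e in dated.tree.preorder_edge_iter()
            if e.length is not None
        )
        assert lengths == pytest.approx([1.0, 6.0])

    def test_ladder_of_equal_ages_cascades(self):
        newick = "(a,(b,(c,(d,e))));"
        ages = {t: 50.0 for t in "abcde"}
        dated = al.time_calibrate_mbl(newick, ages, mbl=1.0, seed=0)
        root_age = 50.0 + max(
            leaf.distance_from_root() for leaf in dated.tree.leaf_node_iter()
        )
        assert root_age == pytest.approx(54.0)  # depth-4 ladder: 50 + 4 * mbl
        assert dated.min_branch_length() >= 1.0 - 1e-12

    def test_deterministic_polytomy_resolution(self):
        newick = "(a,b,c,d,e);"
        ages = {t: 80.0 for t in "abcde"}
        n1 = al.time_calibrate_mbl(newick, ages, seed=11).as_newick()
        n2 = al.time_calibrate_mbl(newick, ages, seed=11).as_newick()
        assert n1 == n2

    def test_missing_tip_age_rejected(self):
        with pytest.raises(ValueError, match="b"):
            al.time_calibrate_mbl("(a,b);", {"a": 100.0})

    def test_all_branches_at_least_mbl(self):
        newick = "((a,b),(c,(d,e)));"
        ages = {"a": 90.0, "b": 112.0, "c": 95.0, "d": 95.0, "e": 130.0}
        dated = al.time_calibrate_mbl(newick, ages, mbl=2.0, seed=1)
        assert dated.min_branch_length() >= 2.0 - 1e-12
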