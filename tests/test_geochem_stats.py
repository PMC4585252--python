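"""Zone classification, Fe:Cu regression, Spearman, rarefaction, CCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metalloprof import geochem_stats as gs
from metalloprof import synthetic_data as sd

from _oracles import (cca_one_constraint_eigenvalue, chi_square_over_total,
                      spearman_midrank_pearson, spearman_perm_p_enumerated)


class TestClassifyZone:
    @pytest.mark.parametrize("depth,o2,zone", [
        (30, 210, "upper_oxic"),
        (250, 2, "core_omz"),
        (60, 100, "upper_oxycline"),
        (100, 6, "upper_omz"),
        (800, 30, "lower_oxycline"),
        (30, 3, "unclassified"),    # shallow anoxia fits no box
        (400, 7, "unclassified"),   # depth gap between core and lower oxycline
    ])
    def test_examples(self, depth, o2, zone):
        assert gs.classify_zone(depth, o2) == zone

    def test_missing_input_unclassified_with_warning(self):
        with pytest.warns(UserWarning):
            assert gs.classify_zone(100, float("nan")) == "unclassified"

    def test_partition_no_point_maps_to_two_boxes(self):
        # exhaustive grid: each (depth, O2) satisfies at most one zone box
        for depth in np.arange(0, 1101, 12.5):
            for o2 in np.arange(0, 301, 2.5):
                matches = []
                for name, dlo, dhi, olo, ohi, strict in gs._ZONE_BOXES:
                    if dlo <= depth <= dhi and (
                            o2 > olo if strict
                            else olo <= o2 and (ohi is None or o2 < ohi)):
                        matches.append(name)
                assert len(matches) <= 1, (depth, o2, matches)
                expected = matches[0] if matches else "unclassified"
                assert gs.classify_zone(depth, o2) == expected


class TestFeCuRegression:
    def test_recovers_exact_line(self):
        o2 = np.linspace(67, 284, 30)
        df = pd.DataFrame({"o2": o2, "fe_cu_ratio": -0.006 * o2 + 1.8})
        fit = gs.fit_fe_cu_vs_o2(df)
        assert fit.slope == pytest.approx(-0.006, abs=1e-12)
        assert fit.intercept == pytest.approx(1.8, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_gives_zero_slope_and_r2(self):
        df = pd.DataFrame({"o2": [10, 50, 90, 200.0],
                           "fe_cu_ratio": [1.2] * 4})
        fit = gs.fit_fe_cu_vs_o2(df)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(0, 250, 50)
        y = -0.005 * x + 1.5 + rng.normal(0, 0.1, 50)
        fit = gs.fit_fe_cu_vs_o2(pd.DataFrame({"o2": x, "fe_cu_ratio": y}))
        X = np.column_stack([np.ones(50), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
        assert fit.slope == pytest.approx(beta[1], abs=1e-9)
        se = np.sqrt(np.sum((y - X @ beta) ** 2) / 48 /
                     np.sum((x - x.mean()) ** 2))
        assert abs(fit.slope - (-0.005)) < 4 * se

    def test_duplicated_points_leave_fit_unchanged(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(0, 200, 12)
        y = -0.004 * x + 1.1 + rng.normal(0, 0.05, 12)
        df = pd.DataFrame({"o2": x, "fe_cu_ratio": y})
        fit1 = gs.fit_fe_cu_vs_o2(df)
        fit3 = gs.fit_fe_cu_vs_o2(pd.concat([df] * 3))
        assert fit3.slope == pytest.approx(fit1.slope, abs=1e-12)
        assert fit3.intercept == pytest.approx(fit1.intercept, abs=1e-12)

    def test_degenerate_design_rejected(self):
        df = pd.DataFrame({"o2": [50.0, 50.0, 50.0],
                           "fe_cu_ratio": [1, 2, 3.0]})
        with pytest.raises(ValueError, match="degenerate"):
            gs.fit_fe_cu_vs_o2(df)


class TestPredictZeroOxygen:
    def test_negative_slope_returns_intercept(self):
        assert gs.predict_zero_oxygen(
            gs.LinearFit(-0.006, 1.8, 0.75, 40)) == pytest.approx(1.8)

    def test_slope_minus_one_intercept_zero(self):
        assert gs.predict_zero_oxygen(gs.LinearFit(-1.0, 0.0, 1.0, 5)) == 0.0

    def test_nonnegative_slope_flagged_not_a_maximum(self):
        with pytest.warns(UserWarning, match="not a maximum"):
            v = gs.predict_zero_oxygen(gs.LinearFit(0.01, 0.5, 0.2, 5))
        assert v == pytest.approx(0.5)


class TestSpearman:
    def test_monotone_increasing_is_plus_one(self):
        rho, p, n = gs.spearman_test([1, 2, 5, 9, 11], [2, 4, 8, 9, 30])
        assert rho == pytest.approx(1.0)

    def test_perfect_antitone_is_minus_one(self):
        rho, _, _ = gs.spearman_test([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_tied_fixture_matches_midrank_pearson_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0])
        rho, _, _ = gs.spearman_test(x, y)
        assert rho == pytest.approx(spearman_midrank_pearson(x, y), abs=1e-12)
        # and agrees with the scipy implementation
        assert rho == pytest.approx(sps.spearmanr(x, y).statistic, abs=1e-12)

    def test_exact_permutation_p_matches_enumeration_n6(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(size=6)
        y = rng.uniform(size=6)
        _, p, _ = gs.spearman_test(x, y)
        assert p == pytest.approx(spearman_perm_p_enumerated(x, y), abs=1e-12)

    def test_t_approximation_for_larger_n(self):
        rng = np.random.default_rng(16)
        x = rng.uniform(size=25)
        y = 0.8 * x + rng.normal(0, 0.3, 25)
        rho, p, n = gs.spearman_test(x, y)
        t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
        assert p == pytest.approx(2 * sps.t.sf(abs(t), n - 2), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gs.spearman_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_screen_shapes_and_bh_adjustment(self):
        rng = np.random.default_rng(17)
        idx = [f"s{i}" for i in range(12)]
        inv = pd.DataFrame({"famA": rng.uniform(size=12),
                            "famB": rng.uniform(size=12)}, index=idx)
        env = pd.DataFrame({"o2": rng.uniform(size=12),
                            "depth": rng.uniform(size=12),
                            "constant": 1.0}, index=idx)
        out = gs.spearman_screen(inv, env)
        assert set(out["x"]) == {"o2", "depth"}  # constant column skipped
        assert len(out) == 4
        from statsmodels.stats.multitest import multipletests
        assert out["q"].to_numpy() == pytest.approx(
            multipletests(out["p"], method="fdr_bh")[1])
        assert any("constant" in s for _, _, s in out.attrs["skipped"])


class TestRarefaction:
    def test_depth_equal_to_total_returns_matrix_unchanged(self):
        counts = pd.DataFrame({"a": [6], "b": [4]}, index=["s1"])
        out = gs.rarefy_matrix(counts, 10, reps=20, seed=1)
        assert out.loc["s1", "a"] == 6.0
        assert out.loc["s1", "b"] == 4.0

    def test_single_label_certainty(self):
        counts = pd.DataFrame({"a": [10], "b": [0]}, index=["s1"])
        out = gs.rarefy_matrix(counts, 5, reps=50, seed=2)
        assert out.loc["s1", "a"] == 5.0
        assert out.loc["s1", "b"] == 0.0

    def test_mean_near_hypergeometric_expectation(self):
        counts = pd.DataFrame({"a": [6], "b": [4]}, index=["s1"])
        reps = 999
        out = gs.rarefy_matrix(counts, 5, reps=reps, seed=3)
        # E[a] = 5 * 6/10 = 3; Var from the hypergeometric
        var = 5 * 0.6 * 0.4 * (10 - 5) / (10 - 1)
        se = np.sqrt(var / reps)
        assert abs(out.loc["s1", "a"] - 3.0) < 3 * se

    def test_excessive_depth_names_sample(self):
        counts = pd.DataFrame({"a": [3, 10]}, index=["shallow", "deep"])
        with pytest.raises(ValueError, match="shallow"):
            gs.rarefy_matrix(counts, 5)

    def test_seed_reproducibility(self):
        counts = pd.DataFrame({"a": [20, 7], "b": [11, 13]},
                              index=["s1", "s2"])
        a = gs.rarefy_matrix(counts, 10, reps=30, seed=7)
        b = gs.rarefy_matrix(counts, 10, reps=30, seed=7)
        pd.testing.assert_frame_equal(a, b)


def _random_community(rng, n=6, p=5):
    return pd.DataFrame(rng.integers(1, 40, size=(n, p)),
                        index=[f"s{i}" for i in range(n)],
                        columns=[f"f{j}" for j in range(p)])


class TestCca:
    def test_total_inertia_is_chi_square_over_grand_total(self):
        rng = np.random.default_rng(18)
        for _ in range(10):
            Y = _random_community(rng)
            X = pd.DataFrame({"env": rng.normal(size=6)}, index=Y.index)
            res = gs.partial_cca(Y, X)
            assert res.total_inertia == pytest.approx(
                chi_square_over_total(Y.to_numpy()), abs=1e-10)

    def test_constant_constraint_has_zero_constrained_inertia(self):
        rng = np.random.default_rng(19)
        Y = _random_community(rng)
        X = pd.DataFrame({"c": np.ones(6)}, index=Y.index)
        res = gs.partial_cca(Y, X)
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-12)

    def test_one_constraint_eigenvalue_matches_dense_eigen_oracle(self):
        rng = np.random.default_rng(20)
        Y = _random_community(rng)
        x = rng.integers(0, 2, 6).astype(float)
        x[0] = 1 - x[1]  # ensure non-constant
        res = gs.partial_cca(Y, pd.DataFrame({"bin": x}, index=Y.index))
        oracle = cca_one_constraint_eigenvalue(Y.to_numpy(), x)
        assert res.eigenvalues_constrained[0] == pytest.approx(oracle, abs=1e-8)

    def test_conditions_equal_constraints_full_partialling(self):
        rng = np.random.default_rng(21)
        Y = _random_community(rng)
        X = pd.DataFrame({"a": rng.normal(size=6), "b": rng.normal(size=6)},
                         index=Y.index)
        res = gs.partial_cca(Y, X, conditions=X)
        assert res.constrained_inertia == pytest.approx(0.0, abs=1e-10)

    def test_eigenvalues_nonincreasing_and_bounded_by_total(self):
        rng = np.random.default_rng(22)
        Y = _random_community(rng, n=8, p=6)
        X = pd.DataFrame(rng.normal(size=(8, 3)), index=Y.index,
                         columns=list("abc"))
        res = gs.partial_cca(Y, X)
        ev = res.eigenvalues_constrained
        assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(ev, ev[1:]))
        assert res.constrained_inertia <= res.total_inertia + 1e-10
        assert res.constrained_inertia + res.unconstrained_inertia == \
            pytest.approx(res.total_inertia, abs=1e-8)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(23)
        Y = _random_community(rng, n=7, p=5)
        X = pd.DataFrame({"e1": rng.normal(size=7), "e2": rng.normal(size=7)},
                         index=Y.index)
        res = gs.partial_cca(Y, X)
        perm = rng.permutation(7)
        Yp, Xp = Y.iloc[perm], X.iloc[perm]
        res_p = gs.partial_cca(Yp, Xp)
        assert res_p.eigenvalues_constrained == pytest.approx(
            res.eigenvalues_constrained, abs=1e-10)
        # site scores permute with the samples (up to axis sign)
        a = res.site_scores.loc[Yp.index].to_numpy()
        b = res_p.site_scores.to_numpy()
        for k in range(a.shape[1]):
            assert np.allclose(a[:, k], b[:, k], atol=1e-8) or \
                np.allclose(a[:, k], -b[:, k], atol=1e-8)

    def test_collinear_constraints_rejected_with_column_names(self):
        rng = np.random.default_rng(24)
        Y = _random_community(rng)
        x = rng.normal(size=6)
        X = pd.DataFrame({"a": x, "b": 2 * x}, index=Y.index)
        with pytest.raises(ValueError, match="collinear"):
            gs.partial_cca(Y, X)


class TestDirectionalRecovery:
    def test_fe_inventory_declines_and_oxidase_rises_with_o2(self):
        """The planted O2 gradient is recovered with the expected signs."""
        cfg = sd.SimConfig(seed=40)
        profiles = sd.simulate_profiles(cfg)
        counts, env = sd.simulate_community(cfg, profiles)
        fe_total = counts[[c for c in counts if c.startswith("Fe:")]].sum(axis=1)
        rho_fe, p_fe, _ = gs.spearman_test(env["o2"], fe_total)
        rho_cox, p_cox, _ = gs.spearman_test(env["o2"], counts["Cu:f.24.1.1"])
        assert rho_fe < 0 and p_fe < 0.05
        assert rho_cox > 0 and p_cox < 0.05
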