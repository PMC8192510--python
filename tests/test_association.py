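"""Association battery vs brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import immunosig as im
from immunosig.association import default_contrast_spec


class TestHoma:
    def test_normalizing_constant(self):
        assert im.homa_ir(22.5, 1.0) == 1.0
        assert im.homa_ir(5.0, 0.0) == 0.0
        assert im.homa_ir(5.58, 10.2) == pytest.approx(2.5296)

    def test_bilinear_and_vectorized(self):
        g = np.array([4.0, 6.0])
        i = np.array([8.0, 12.0])
        np.testing.assert_allclose(im.homa_ir(3 * g, i), 3 * im.homa_ir(g, i))
        np.testing.assert_allclose(im.homa_ir(g, 2 * i), 2 * im.homa_ir(g, i))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            im.homa_ir(-1.0, 5.0)


class TestGroupComparison:
    def test_identical_samples_give_p_one(self):
        gc = im.compare_groups([1, 2, 3, 4], [1, 2, 3, 4], method="t_test")
        assert gc.statistic == 0.0 and gc.p_value == 1.0

    def test_separated_groups(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)
        gc = im.compare_groups(a, b, method="t_test")
        assert gc.p_value < 1e-6

    def test_mann_whitney_exact_matches_permutation_oracle(self, rng):
        a = rng.normal(0.8, 1, 4)
        b = rng.normal(0.0, 1, 4)
        gc = im.compare_groups(a, b, method="mann_whitney")
        # oracle: enumerate all C(8,4) assignments of the pooled ranks
        pooled = np.concatenate([a, b])
        ranks = np.argsort(np.argsort(pooled)) + 1

        def u_stat(idx_a):
            r_a = ranks[list(idx_a)].sum()
            u1 = r_a - 4 * 5 / 2
            return max(u1, 4 * 4 - u1)

        observed = u_stat(range(4))
        count = sum(
            u_stat(idx) >= observed for idx in itertools.combinations(range(8), 4)
        )
        oracle_p = count / math.comb(8, 4)
        assert gc.p_value == pytest.approx(oracle_p, abs=1e-12)

    def test_auto_selects_mann_whitney_for_skewed_data(self, rng):
        a = rng.lognormal(0, 1.5, 60)
        b = rng.lognormal(0.2, 1.5, 60)
        assert im.compare_groups(a, b).method == "mann_whitney"
        assert im.compare_groups(rng.normal(0, 1, 60), rng.normal(0, 1, 60)).method == "t_test"

    def test_profile_vs_rest_planted_sign(self, planted_cohort):
        gc = im.compare_profile_vs_rest(planted_cohort, planted_cohort.true_profile, "scd163")
        assert gc.mean_a > gc.mean_b and gc.p_value < 0.01

    def test_empty_group_rejected(self, default_cohort):
        with pytest.raises(ValueError, match="empty"):
            im.compare_profile_vs_rest(default_cohort, default_cohort.true_profile,
                                       "insulinemia", profile=9)


class TestSpearman:
    def test_identity_and_reversal(self, rng):
        x = rng.normal(size=20)
        assert im.spearman(x, x).rho == pytest.approx(1.0)
        assert im.spearman(x, -x).rho == pytest.approx(-1.0)

    def test_rho_equals_pearson_on_midranks_with_ties(self, rng):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 7.0])
        y = rng.normal(size=8)
        from scipy.stats import pearsonr, rankdata

        oracle = pearsonr(rankdata(x), rankdata(y)).statistic
        assert im.spearman(x, y).rho == pytest.approx(oracle, abs=1e-12)

    def test_small_n_p_is_exact_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        res = im.spearman(x, y)
        # oracle: enumerate all 6! pairings of the rank vectors
        from scipy.stats import pearsonr

        rhos = [
            pearsonr(x, np.array(p)).statistic
            for p in itertools.permutations(y)
        ]
        oracle = np.mean(np.abs(rhos) >= abs(res.rho) - 1e-12)
        assert res.p_value == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=15)
        y = r.normal(size=15)
        base = im.spearman(x, y).rho
        assert im.spearman(np.exp(x), y).rho == pytest.approx(base, abs=1e-12)
        assert im.spearman(x, y**3).rho == pytest.approx(base, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            im.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            im.spearman([1.0, 2.0], [1.0, 2.0])


class TestCategorical:
    def test_printed_antihyperlipidemic_table(self):
        # default expected-count rule forces Fisher (min expected 4.4 < 5) ...
        auto = im.categorical_test([[8, 14], [22, 106]])
        assert auto.method == "fisher"
        # ... while chi-square without continuity correction gives p = 0.038
        forced = im.categorical_test([[8, 14], [22, 106]], method="chi2")
        assert forced.p_value == pytest.approx(0.038, abs=0.005)
        assert forced.proportions[0] == pytest.approx(8 / 22)
        assert forced.proportions[1] == pytest.approx(22 / 128)

    def test_perfect_independence(self):
        assert im.categorical_test([[10, 10], [10, 10]]).p_value == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_enumeration(self):
        table = np.array([[1, 9], [11, 3]])
        res = im.categorical_test(table, method="fisher")
        # oracle: point-probability rule over all tables with fixed margins
        r1, c1, n = table[0].sum(), table[:, 0].sum(), table.sum()

        def point_prob(a):
            return (
                math.comb(c1, a) * math.comb(n - c1, r1 - a) / math.comb(n, r1)
            )

        obs = point_prob(table[0, 0])
        p = sum(
            point_prob(a)
            for a in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
            if point_prob(a) <= obs * (1 + 1e-9)
        )
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_chi2_invariant_under_transposition(self):
        t = [[8, 14], [22, 106]]
        a = im.categorical_test(t, method="chi2")
        b = im.categorical_test(np.transpose(t), method="chi2")
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            im.categorical_test([[0, 0], [5, 3]])


class TestBattery:
    def test_planted_effect_has_positive_sign(self, planted_cohort):
        rep = im.run_association_battery(planted_cohort, planted_cohort.true_profile)
        row = rep[rep.variable == "scd163"].iloc[0]
        assert row.estimate > 0

    def test_unknown_variable_errors(self, default_cohort):
        spec = default_contrast_spec()
        spec.group_variables = ["not_a_marker"]
        with pytest.raises(KeyError):
            im.run_association_battery(default_cohort, default_cohort.true_profile, spec)

    def test_bh_column_is_monotone_in_raw_p(self, default_cohort):
        rep = im.run_association_battery(default_cohort, default_cohort.true_profile, bh=True)
        srt = rep.sort_values("p_value")
        assert (srt.p_bh.diff().dropna() >= -1e-12).all()
        assert (rep.p_bh >= rep.p_value - 1e-12).all()
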