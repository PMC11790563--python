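"""Inference layer against hand-evaluated formulas and resampling oracles."""

import numpy as np
import pandas as pd
import pytest

from cultfit import (InsufficientDataError, ParameterError, ValidationError,
                     compare_dependent_correlations, correlate_fits,
                     correlation_power, cronbach_alpha, detectable_r,
                     feature_compare, fit_between_compare, fit_within_compare)


def fit_table(rows):
    return pd.DataFrame(rows, columns=["participant", "culture", "situation",
                                       "measure", "target_culture", "r", "z"])


def paired_rows(pairs, culture="heritage", other="host", situation="pos_rel"):
    rows = []
    for i, (own, cross) in enumerate(pairs):
        for target, z in ((culture, own), (other, cross)):
            rows.append([f"p{i}", culture, situation, "emotion", target,
                         np.tanh(z), z])
    return fit_table(rows)


class TestFeatureCompare:
    def test_identical_groups(self):
        res = feature_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.estimate == 0.0

    def test_hand_evaluated_pooled_formula(self):
        # pooled variance 1, se = sqrt(2/3), t = -1/sqrt(2/3)
        res = feature_compare([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.t == pytest.approx(-np.sqrt(1.5))
        assert res.df == 4
        assert res.estimate == pytest.approx(-1.0)
        assert res.ci_low < -1.0 < res.ci_high

    def test_label_swap_negates_t_preserves_p(self):
        a, b = [1.0, 2.5, 3.0, 4.0], [2.0, 3.0, 4.5]
        r1, r2 = feature_compare(a, b), feature_compare(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_zero_pooled_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero pooled variance"):
            res = feature_compare([2.0, 2.0], [3.0, 3.0])
        assert res.degenerate and np.isnan(res.p)

    def test_welch_flag_changes_df(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [10.0, 30.0, 50.0]
        assert feature_compare(a, b, pooled=False).df != \
            feature_compare(a, b, pooled=True).df


class TestFitWithinCompare:
    def test_equal_directions_t_zero(self):
        table = paired_rows([(0.8, 0.8), (1.1, 1.1), (0.5, 0.5)])
        res = fit_within_compare(table, "heritage", "pos_rel")
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_hand_evaluated_paired_t(self):
        # diffs (0.2, 0.1, 0.4): mean 0.2333, sd 0.15275, t = 2.6458, df 2
        table = paired_rows([(1.2, 1.0), (0.9, 0.8), (1.1, 0.7)])
        res = fit_within_compare(table, "heritage", "pos_rel")
        assert res.design == "paired"
        assert res.t == pytest.approx(2.6457513, abs=1e-6)
        assert res.df == 2
        assert res.estimate == pytest.approx(0.7 / 3)

    def test_constant_shift_invariance(self):
        pairs = [(1.2, 1.0), (0.9, 0.8), (1.1, 0.7), (0.4, 0.9)]
        base = fit_within_compare(paired_rows(pairs), "heritage", "pos_rel")
        shifted = fit_within_compare(
            paired_rows([(a + 5, b + 5) for a, b in pairs]),
            "heritage", "pos_rel")
        assert shifted.t == pytest.approx(base.t)

    def test_listwise_deletion_of_missing(self):
        table = paired_rows([(1.2, 1.0), (0.9, 0.8), (1.1, 0.7)])
        table.loc[(table["participant"] == "p2")
                  & (table["target_culture"] == "host"), "z"] = np.nan
        res = fit_within_compare(table, "heritage", "pos_rel")
        assert res.n == (2,)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            fit_within_compare(paired_rows([(1.0, 0.5)]), "heritage", "pos_rel")


class TestFitBetweenCompare:
    def _two_culture_table(self, own_z, other_z):
        rows = []
        for i, z in enumerate(own_z):
            rows.append([f"h{i}", "host", "pos_rel", "emotion", "host",
                         np.tanh(z), z])
        for i, z in enumerate(other_z):
            rows.append([f"m{i}", "heritage", "pos_rel", "emotion", "host",
                         np.tanh(z), z])
        return fit_table(rows)

    def test_equal_groups_t_zero(self):
        table = self._two_culture_table([0.5, 0.7, 0.9], [0.5, 0.7, 0.9])
        res = fit_between_compare(table, "host", "pos_rel")
        assert res.t == pytest.approx(0.0)

    def test_members_minus_nonmembers_sign(self):
        table = self._two_culture_table([1.0, 1.2, 1.4], [0.2, 0.3, 0.4])
        res = fit_between_compare(table, "host", "pos_rel")
        assert res.estimate > 0 and res.t > 0
        assert res.df == 4

    def test_missing_side_rejected(self):
        table = self._two_culture_table([1.0, 1.2], [])
        with pytest.raises(InsufficientDataError):
            fit_between_compare(table, "host", "pos_rel")


class TestCronbachAlpha:
    def test_copied_columns_alpha_one(self):
        col = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        assert cronbach_alpha(np.column_stack([col, col, col])) == \
            pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        # item variances 3*5/3, total variance 41/3 -> alpha = 39/41
        mat = [[1, 2, 1], [2, 3, 2], [3, 4, 4], [4, 5, 3]]
        assert cronbach_alpha(mat) == pytest.approx(39 / 41)

    def test_column_constant_shift_invariance(self):
        rng = np.random.default_rng(0)
        mat = rng.normal(size=(20, 4))
        shifted = mat + np.array([10.0, -3.0, 0.5, 100.0])
        assert cronbach_alpha(shifted) == pytest.approx(cronbach_alpha(mat))

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        latent = rng.normal(size=(40, 1))
        mat = pd.DataFrame(latent + 0.8 * rng.normal(size=(40, 4)))
        expected = pingouin.cronbach_alpha(data=mat)[0]
        assert cronbach_alpha(mat) == pytest.approx(expected, abs=1e-10)

    def test_zero_total_variance_flagged(self):
        with pytest.warns(UserWarning, match="alpha undefined"):
            assert np.isnan(cronbach_alpha([[1, 2], [2, 1], [1, 2], [2, 1]]))

    def test_too_few_rows_or_columns(self):
        with pytest.raises(InsufficientDataError):
            cronbach_alpha([[1.0], [2.0], [3.0]])
        with pytest.raises(InsufficientDataError):
            cronbach_alpha([[1.0, 2.0], [2.0, 3.0]])


class TestCorrelateFits:
    def test_perfect_correlations(self):
        x = np.array([0.1, 0.4, 0.2, 0.9, 0.6])
        assert correlate_fits(x, x).r == pytest.approx(1.0)
        assert correlate_fits(x, -x).r == pytest.approx(-1.0)

    def test_fixed_pairs_against_permutation_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = 0.7 * x + 0.6 * rng.normal(size=10)
        res = correlate_fits(x, y)
        assert res.n == 10 and res.df == 8
        assert res.ci_low < res.r < res.ci_high
        # permutation p for the observed |r|
        def corr(a, b):
            return np.corrcoef(a, b)[0, 1]
        observed = abs(corr(x, y))
        perms = np.array([abs(corr(x, rng.permutation(y)))
                          for _ in range(10000)])
        perm_p = (perms >= observed - 1e-12).mean()
        assert res.p == pytest.approx(perm_p, abs=0.02)

    def test_ci_matches_fisher_formula(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        res = correlate_fits(x, y)
        half = 1.959963984540054 / np.sqrt(50 - 3)
        assert res.ci_low == pytest.approx(np.tanh(np.arctanh(res.r) - half))
        assert res.ci_high == pytest.approx(np.tanh(np.arctanh(res.r) + half))

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            res = correlate_fits([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res.degenerate and np.isnan(res.r)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            correlate_fits([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestDependentCorrelations:
    def test_symmetric_construction_zero_difference(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(200, 2))
        df = pd.DataFrame({"a": x[:, 0], "b": x[:, 1],
                           "c": x[:, 0], "d": x[:, 1]})
        res = compare_dependent_correlations(df, (("a", "b"), ("c", "d")))
        assert res.difference == pytest.approx(0.0)
        assert res.ci_low == pytest.approx(-res.ci_high)
        assert not res.significant

    def test_matches_bootstrap_oracle_within_002(self):
        S = np.array([[1, .5, .3, .2], [.5, 1, .2, .3],
                      [.3, .2, 1, .4], [.2, .3, .4, 1]])
        L = np.linalg.cholesky(S)
        rng = np.random.default_rng(42)
        X = rng.standard_normal((50, 4)) @ L.T
        df = pd.DataFrame(X, columns=list("abcd"))
        res = compare_dependent_correlations(df, (("a", "b"), ("c", "d")))
        boot = np.empty(20000)
        for i in range(20000):
            idx = rng.integers(0, 50, 50)
            c = np.corrcoef(X[idx], rowvar=False)
            boot[i] = c[0, 1] - c[2, 3]
        lo, hi = np.percentile(boot, [2.5, 97.5])
        assert res.ci_low == pytest.approx(lo, abs=0.02)
        assert res.ci_high == pytest.approx(hi, abs=0.02)

    def test_overlapping_pairing_rejected(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        with pytest.raises(ParameterError, match="overlapping"):
            compare_dependent_correlations(df, (("a", "b"), ("a", "c")))

    def test_too_few_rows(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        with pytest.raises(InsufficientDataError):
            compare_dependent_correlations(df, (("a", "b"), ("c", "d")))

    def test_unknown_column_rejected(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        with pytest.raises(ValidationError, match="x"):
            compare_dependent_correlations(df, (("a", "b"), ("c", "x")))


class TestDetectableR:
    def test_reference_sample_size(self):
        res = detectable_r(100, alpha=0.05, power=0.80)
        assert res.r_rounded == 0.27
        assert 0.26 < res.r < 0.28

    def test_strictly_decreasing_in_n(self):
        values = [detectable_r(n).r for n in (20, 50, 100, 200, 500)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_plug_back_recovers_target_power(self):
        for n in (30, 100, 250):
            res = detectable_r(n)
            assert correlation_power(res.r, n) == pytest.approx(0.80, abs=0.005)

    def test_monte_carlo_power_oracle_n30(self):
        """Simulate the fixed-score model the noncentral-t power describes."""
        from scipy import stats

        root = detectable_r(30).r
        rng = np.random.default_rng(12345)
        n, reps = 30, 100000
        x = rng.standard_normal(n)
        x = (x - x.mean()) / np.sqrt(((x - x.mean())**2).sum() / n)  # sum sq = n
        y = root * x + np.sqrt(1 - root**2) * rng.standard_normal((reps, n))
        xc = x - x.mean()
        yc = y - y.mean(axis=1, keepdims=True)
        r = (yc @ xc) / np.sqrt((xc @ xc) * (yc**2).sum(axis=1))
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        power = (np.abs(t) > stats.t.ppf(0.975, n - 2)).mean()
        assert 0.79 <= power <= 0.81

    def test_power_monotone_in_r(self):
        grid = np.linspace(0.05, 0.9, 18)
        powers = [correlation_power(r, 40) for r in grid]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_unattainable_power_rejected(self):
        with pytest.raises(ParameterError):
            detectable_r(50, alpha=0.05, power=0.04)
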