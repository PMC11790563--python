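"""Fit engine: Fisher transform, references, leave-one-out, invariances."""

import numpy as np
import pandas as pd
import pytest

from cultfit import (DEFAULT_EPS, InsufficientDataError, ParameterError,
                     ProfileFitModel, RatingDataset, SyntheticConfig,
                     compute_fit_scores, fisher_z, generate_ratings,
                     profile_fit, reference_profile)

from conftest import make_ratings_frame, random_profiles


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_maps_to_half_log_three(self):
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3))

    def test_odd_function_on_grid(self):
        grid = np.linspace(-0.99, 0.99, 41)
        np.testing.assert_allclose(fisher_z(-grid), -fisher_z(grid))

    def test_strictly_increasing(self):
        grid = np.linspace(-1, 1, 101)
        assert (np.diff(fisher_z(grid)) > 0).all()

    def test_clipping_keeps_extremes_finite(self):
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - DEFAULT_EPS))
        assert np.isfinite(fisher_z(-1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            fisher_z(1.5)

    def test_nan_passes_through(self):
        assert np.isnan(fisher_z(np.nan))


class TestReferenceProfile:
    def test_mean_of_two_after_exclusion(self):
        members = pd.DataFrame([[1, 2], [3, 4], [5, 6]],
                               index=["a", "b", "c"], columns=["x", "y"])
        ref = reference_profile(members, exclude="a")
        np.testing.assert_allclose(ref.to_numpy(), [4.0, 5.0])

    def test_identical_profiles_idempotent(self):
        members = pd.DataFrame([[2, 3, 4]] * 5, columns=["x", "y", "z"])
        np.testing.assert_allclose(reference_profile(members).to_numpy(),
                                   [2, 3, 4])

    def test_exclusion_below_two_members_rejected(self):
        members = pd.DataFrame([[1, 2], [3, 4]], index=["a", "b"])
        with pytest.raises(InsufficientDataError):
            reference_profile(members, exclude="a")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_group(self, seed):
        rng = np.random.default_rng(seed)
        members = pd.DataFrame(rng.normal(size=(25, 6)),
                               index=[f"p{i}" for i in range(25)])
        pick = f"p{rng.integers(25)}"
        got = reference_profile(members, exclude=pick)
        brute = members.drop(index=pick).to_numpy().mean(axis=0)
        np.testing.assert_array_equal(got.to_numpy(), brute)


class TestProfileFit:
    def test_identity_profile(self):
        ref = [1.0, 2.0, 3.0, 4.0]
        r, z = profile_fit(ref, ref)
        assert r == pytest.approx(1.0)
        assert z == pytest.approx(np.arctanh(1 - DEFAULT_EPS))

    def test_exact_anti_profile(self):
        r, _ = profile_fit([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_evaluated_product_moment(self):
        # centred cross-product 5, |x|^2 = 8.75, |y|^2 = 4 -> r = 5/sqrt(35)
        r, _ = profile_fit([1, 2, 3, 5], [2, 2, 4, 4])
        assert r == pytest.approx(5 / np.sqrt(35))
        assert r == pytest.approx(0.8452, abs=5e-5)

    def test_zero_variance_warns_and_is_missing(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r, z = profile_fit([3, 3, 3], [1, 2, 3])
        assert np.isnan(r) and np.isnan(z)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            profile_fit([1, 2, 3], [1, 2])


def brute_force_fit(profiles, participant, situation, target, features):
    """From-scratch oracle: rebuild the reference and correlate."""
    cell = profiles[profiles["situation"] == situation]
    members = cell[cell["culture"] == target].set_index("participant")
    row = cell[cell["participant"] == participant]
    own = row["culture"].iloc[0] == target
    pool = members.drop(index=participant) if own else members
    reference = pool[features].to_numpy(dtype=float).mean(axis=0)
    x = row[features].to_numpy(dtype=float)[0]
    xc, yc = x - x.mean(), reference - reference.mean()
    return float(np.clip(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)), -1, 1))


class TestComputeFitScores:
    def test_loo_applies_only_to_own_culture(self):
        rng = np.random.default_rng(0)
        profiles = random_profiles(rng, n_per_culture=6, n_features=5,
                                   situations=("pos_rel",))
        table = compute_fit_scores(profiles, feature_columns=[f"f{i}"
                                                              for i in range(5)])
        feats = [f"f{i}" for i in range(5)]
        for row in table.itertuples():
            expected = brute_force_fit(profiles, row.participant, row.situation,
                                       row.target_culture, feats)
            # continuous features: summation order may differ in the last ulp
            assert row.r == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_recomputation_everywhere(self, seed):
        rng = np.random.default_rng(100 + seed)
        config = SyntheticConfig(n_heritage=10, n_host=12, n_migrant=0,
                                 seed=int(rng.integers(2**31)))
        dataset, _ = generate_ratings(config)
        model = ProfileFitModel.from_ratings(dataset)
        table = model.fit().table
        profiles = dataset.profiles()
        feats = list(dataset.terms.active_terms)
        sample = table.sample(40, random_state=seed)
        for row in sample.itertuples():
            expected = brute_force_fit(profiles, row.participant, row.situation,
                                       row.target_culture, feats)
            assert row.r == expected

    def test_degenerate_identical_cultures_fit_near_one(self):
        config = SyntheticConfig(n_heritage=8, n_host=8, n_migrant=0,
                                 d_emotion=0.0, rating_noise_sd=1e-9, seed=4)
        dataset, _ = generate_ratings(config)
        table = ProfileFitModel.from_ratings(dataset).fit().table
        assert (table["r"] > 0.999).all()
        assert table["z"].max() <= np.arctanh(1 - DEFAULT_EPS) + 1e-12

    def test_small_cell_produces_missing_with_warning(self):
        rng = np.random.default_rng(1)
        profiles = random_profiles(rng, n_per_culture=5, n_features=4,
                                   situations=("pos_rel",))
        profiles = profiles[~((profiles["culture"] == "host")
                              & (profiles["participant"] != "hos0")
                              & (profiles["participant"] != "hos1"))]
        with pytest.warns(UserWarning, match="missing"):
            table = compute_fit_scores(profiles)
        toward_host = table[table["target_culture"] == "host"]
        assert toward_host["z"].isna().all()
        toward_heritage = table[table["target_culture"] == "heritage"]
        assert toward_heritage["z"].notna().all()

    def test_translation_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        profiles = random_profiles(rng, n_per_culture=6, n_features=6)
        feats = [f"f{i}" for i in range(6)]
        base = compute_fit_scores(profiles)
        shifted = profiles.copy()
        shifted[feats] = shifted[feats] * 2.5 + 7.0
        got = compute_fit_scores(shifted)
        np.testing.assert_allclose(got["r"], base["r"], atol=1e-12)

    def test_self_inclusion_inflates_own_fit_on_average(self):
        """Including the focal profile in the reference biases r upward."""
        loo_means, incl_means = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            group = rng.normal(size=(5, 8))
            loo, incl = [], []
            for i in range(5):
                ref_loo = np.delete(group, i, axis=0).mean(axis=0)
                ref_incl = group.mean(axis=0)
                loo.append(profile_fit(group[i], ref_loo)[0])
                incl.append(profile_fit(group[i], ref_incl)[0])
            loo_means.append(np.mean(loo))
            incl_means.append(np.mean(incl))
        assert np.mean(incl_means) > np.mean(loo_means)

    def test_duplicate_profile_rows_rejected(self):
        rng = np.random.default_rng(3)
        profiles = random_profiles(rng, n_per_culture=4)
        doubled = pd.concat([profiles, profiles.iloc[:1]], ignore_index=True)
        with pytest.raises(Exception, match="duplicate"):
            compute_fit_scores(doubled)


class TestComposite:
    def _results(self, config=None):
        config = config or SyntheticConfig(n_heritage=12, n_host=12,
                                           n_migrant=0, seed=9)
        dataset, _ = generate_ratings(config)
        return ProfileFitModel.from_ratings(dataset).fit()

    def test_composite_of_equal_scores_is_that_score(self):
        table = pd.DataFrame({
            "participant": ["p"] * 4, "culture": ["heritage"] * 4,
            "situation": ["pos_rel", "pos_auto", "neg_rel", "neg_auto"],
            "measure": ["emotion"] * 4, "target_culture": ["host"] * 4,
            "r": [0.5] * 4, "z": [0.7] * 4,
        })
        results = self._results()
        results.table = pd.concat([results.table, table], ignore_index=True)
        comp = results.composite("heritage", "host")
        row = comp.table[comp.table["participant"] == "p"].iloc[0]
        assert row["composite_z"] == pytest.approx(0.7)

    def test_missing_situation_averages_rest_and_flags(self):
        config = SyntheticConfig(n_heritage=12, n_host=12, n_migrant=0,
                                 missing_rate=0.15, seed=21)
        results = self._results(config)
        comp = results.composite("heritage", "heritage")
        mat = results.z_matrix("heritage", "heritage")
        incomplete = comp.table[comp.table["incomplete"]
                                & (comp.table["n_situations"] >= 2)]
        assert len(incomplete) > 0
        for row in incomplete.itertuples():
            expected = mat.loc[row.participant].mean(skipna=True)
            assert row.composite_z == pytest.approx(expected)

    def test_matches_column_mean_oracle(self):
        results = self._results()
        comp = results.composite("host", "heritage")
        mat = results.z_matrix("host", "heritage")
        np.testing.assert_allclose(comp.table["composite_z"].to_numpy(),
                                   mat.mean(axis=1).to_numpy())
        assert np.isfinite(comp.alpha)

    def test_summary_mentions_measure_and_comparisons(self):
        results = self._results()
        text = results.summary()
        assert "emotion" in text
        assert "Within-culture" in text
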