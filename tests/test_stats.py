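"""Normality-gated group comparisons, KS, Kruskal-Wallis + Dunn, two-way ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from calcohort import (
    InvalidInputError,
    InvalidParameterError,
    aggregate_per_animal,
    anova_binned_pairs,
    choose_test,
    compare_distance_bins,
    compare_group_means,
    compare_rate_distributions,
    dunn_test,
)


class TestChooseTest:
    def test_gaussian_samples_pass_gate(self, rng):
        hits = sum(
            choose_test(rng.normal(0, 1, 50), rng.normal(0, 1, 50)) == "parametric"
            for _ in range(100)
        )
        # each Shapiro falsely rejects with prob alpha; joint pass ~ (1-alpha)^2
        assert hits > 75

    def test_heavy_tails_fail_gate(self, rng):
        hits = sum(
            choose_test(rng.standard_cauchy(50), rng.normal(0, 1, 50))
            == "nonparametric"
            for _ in range(50)
        )
        assert hits > 45

    def test_tiny_or_degenerate_groups_fall_back(self):
        with pytest.warns(UserWarning):
            assert choose_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]) == "nonparametric"


class TestCompareGroupMeans:
    def test_extreme_separation_gives_u_zero(self):
        res = compare_group_means(
            [1.0, 2.0, 3.0, 4.0, 5.0], [10.0, 11.0, 12.0, 13.0, 14.0],
            force="nonparametric",
        )
        # U of the first sample against a uniformly larger second sample
        assert res.statistic == 0.0
        assert res.p_value < 0.01

    def test_exact_p_matches_permutation_enumeration(self):
        x = [1.2, 3.4, 5.1]
        y = [2.2, 4.0, 6.3, 7.7]
        res = compare_group_means(x, y, force="nonparametric")
        # enumerate all label assignments for the exact two-sided p
        pooled = np.array(x + y)
        u_obs = scipy.stats.mannwhitneyu(x, y, method="exact").statistic
        n1 = len(x)
        us = []
        for idx in itertools.combinations(range(pooled.size), n1):
            a = pooled[list(idx)]
            b = np.delete(pooled, list(idx))
            us.append(scipy.stats.mannwhitneyu(a, b, method="exact").statistic)
        us = np.array(us)
        mid = n1 * (pooled.size - n1) / 2
        p_exact = np.mean(np.abs(us - mid) >= abs(u_obs - mid) - 1e-12)
        assert res.p_value == pytest.approx(p_exact)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            compare_group_means([], [1.0, 2.0])

    def test_monotone_transform_invariance_of_mann_whitney(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 8)
        p1 = compare_group_means(x, y, force="nonparametric").p_value
        p2 = compare_group_means(np.exp(x), np.exp(y), force="nonparametric").p_value
        assert p1 == pytest.approx(p2)


class TestRateDistributions:
    def test_identical_samples(self):
        x = np.linspace(0, 1, 20)
        res = compare_rate_distributions(x, x.copy())
        assert res.statistic == pytest.approx(0.0)

    def test_disjoint_supports(self):
        res = compare_rate_distributions(np.arange(10.0), np.arange(100.0, 110.0))
        assert res.statistic == pytest.approx(1.0)

    def test_common_monotone_transform_invariance(self, rng):
        x, y = rng.normal(0, 1, 40), rng.normal(0.3, 1, 40)
        d1 = compare_rate_distributions(x, y).statistic
        d2 = compare_rate_distributions(np.tanh(x), np.tanh(y)).statistic
        assert d1 == pytest.approx(d2)


class TestKruskalDunn:
    def test_null_three_copies(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        omni, dunn = compare_distance_bins({"a": g, "b": g.copy(), "c": g.copy()})
        assert omni.statistic == pytest.approx(0.0, abs=1e-9)
        assert omni.p_value == pytest.approx(1.0)
        assert (dunn["p_adjusted"] > 0.9).all()

    def test_one_shifted_group_detected(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 40)
        c = rng.normal(3, 1, 40)
        omni, dunn = compare_distance_bins({"a": a, "b": b, "c": c})
        assert omni.p_value < 0.001
        sig = dunn[dunn["p_adjusted"] < 0.05]
        assert set(map(tuple, sig[["group_a", "group_b"]].values)) == {
            ("a", "c"),
            ("b", "c"),
        }

    def test_tie_corrected_h_matches_scipy(self, rng):
        # heavily tied integer data: our omnibus is scipy's tie-corrected H
        groups = {k: rng.integers(0, 4, 15).astype(float) for k in "abc"}
        omni, _ = compare_distance_bins(groups)
        h, p = scipy.stats.kruskal(*groups.values())
        assert omni.statistic == pytest.approx(h)

    def test_dunn_z_sign_reflects_rank_order(self):
        out = dunn_test({"low": np.arange(5.0), "high": np.arange(10.0, 15.0)})
        assert out.loc[0, "z"] < 0

    def test_fewer_than_three_groups_rejected(self):
        with pytest.raises(InvalidParameterError):
            compare_distance_bins({"a": [1.0, 2.0], "b": [3.0, 4.0]})


class TestAnova:
    def _frame(self, rng, shift=0.0, n=12):
        rows = []
        for b in ("b1", "b2", "b3"):
            for g in ("WT", "APP"):
                vals = rng.normal(shift if g == "APP" else 0.0, 1.0, n)
                rows += [{"bin": b, "genotype": g, "rho": v} for v in vals]
        return pd.DataFrame(rows)

    def test_additive_genotype_shift_detected(self, rng):
        table = anova_binned_pairs(self._frame(rng, shift=2.0))
        assert table.loc["genotype", "PR(>F)"] < 0.001
        assert table.loc["bin:genotype", "PR(>F)"] > 0.01

    def test_single_observation_per_cell_rejected(self, rng):
        df = self._frame(rng, n=1)
        with pytest.raises(InvalidParameterError):
            anova_binned_pairs(df)

    def test_empty_cell_rejected(self, rng):
        df = self._frame(rng)
        df = df[~((df["bin"] == "b1") & (df["genotype"] == "APP"))]
        with pytest.raises(InvalidParameterError):
            anova_binned_pairs(df)

    def test_missing_column_rejected(self):
        with pytest.raises(InvalidInputError):
            anova_binned_pairs(pd.DataFrame({"rho": [1.0]}))


class TestAggregatePerAnimal:
    def test_single_neuron_identity(self):
        df = pd.DataFrame({"animal_id": ["m1"], "rate_hz": [0.07], "genotype": ["WT"]})
        out = aggregate_per_animal(df)
        assert out.loc[0, "mean_rate_hz"] == pytest.approx(0.07)

    def test_invariant_to_row_order(self, rng):
        df = pd.DataFrame(
            {
                "animal_id": rng.choice(["m1", "m2", "m3"], 30),
                "rate_hz": rng.random(30),
            }
        )
        a = aggregate_per_animal(df)
        b = aggregate_per_animal(df.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(a, b)

    def test_neurons_pooled_equally_across_fovs(self):
        # equal neuron counts per FOV: pooled mean equals mean of FOV means
        df = pd.DataFrame(
            {
                "animal_id": ["m1"] * 4,
                "fov_id": ["f1", "f1", "f2", "f2"],
                "rate_hz": [0.1, 0.2, 0.3, 0.4],
            }
        )
        out = aggregate_per_animal(df)
        assert out.loc[0, "mean_rate_hz"] == pytest.approx(0.25)

    def test_missing_animal_tag_rejected(self):
        df = pd.DataFrame({"animal_id": ["m1", None], "rate_hz": [0.1, 0.2]})
        with pytest.raises(InvalidInputError):
            aggregate_per_animal(df)
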