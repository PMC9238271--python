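"""Alanine-scan ranking statistics and general effect-size helpers."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from entfkit.alascan import (
    BlotMeasurement,
    anova_lsd,
    bootstrap_median_diff,
    cohen_d,
    combined_pscore,
    compare_slopes,
    hedges_g,
    jenks_breaks,
    mann_whitney,
    normalize_blot,
    rank_positions,
)


class TestNormalizeBlot:
    def test_placebo_mean_anchored_at_100(self):
        lanes = [
            BlotMeasurement("placebo", 10, 10),
            BlotMeasurement("placebo", 20, 20),
            BlotMeasurement("treated", 6.2, 10),
        ]
        rel = normalize_blot(lanes)
        assert np.mean(rel["placebo"]) == pytest.approx(100.0)
        assert rel["treated"] == [pytest.approx(62.0)]

    def test_all_placebo_input(self):
        lanes = [BlotMeasurement("placebo", v, 1.0) for v in (9, 10, 11)]
        assert np.mean(normalize_blot(lanes)["placebo"]) == pytest.approx(100.0)

    def test_missing_placebo_group_rejected(self):
        with pytest.raises(ValueError):
            normalize_blot([BlotMeasurement("treated", 1, 1)])

    def test_zero_normalizer_rejected(self):
        with pytest.raises(ValueError):
            BlotMeasurement("placebo", 1.0, 0.0)


class TestAnovaLSD:
    def test_equal_means_give_p_one(self):
        table = anova_lsd({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 3.0]})
        assert table.p("a", "b") == pytest.approx(1.0)

    def test_matches_hand_computed_lsd(self):
        """{A:[1,2,3], B:[7,8,9], C:[4,5,6]}: MSE = 1, df = 6,
        t(A,B) = -6/sqrt(2/3), p from the t distribution."""
        from scipy.stats import t as tdist

        table = anova_lsd({"A": [1, 2, 3], "B": [7, 8, 9], "C": [4, 5, 6]})
        assert table.mse == pytest.approx(1.0)
        assert table.df_error == 6
        t_ab = -6.0 / math.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert table.p("A", "B") == pytest.approx(2 * tdist.sf(abs(t_ab), 6))

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            anova_lsd({"a": [1.0], "b": [1.0, 2.0]})

    def test_degenerate_zero_mse_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            anova_lsd({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_one_sided_alternatives_split_the_two_sided_p(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 7.0]}
        two = anova_lsd(groups).p("a", "b")
        less = anova_lsd(groups, alternative="less").p("a", "b")
        greater = anova_lsd(groups, alternative="greater").p("a", "b")
        assert less == pytest.approx(two / 2)
        assert less + greater == pytest.approx(1.0)


class TestCombinedPscore:
    @pytest.mark.parametrize("p_pbs, p_entf, expected", [
        (1.0, 0.7, 0.0),   # analog indistinguishable from placebo
        (0.0, 1.0, 1.0),   # analog behaves like the active peptide
        (0.2, 0.3, 0.24),
    ])
    def test_formula(self, p_pbs, p_entf, expected):
        assert combined_pscore(p_pbs, p_entf) == pytest.approx(expected)

    @pytest.mark.parametrize("p_pbs, p_entf", [(-0.1, 0.5), (0.5, 1.2)])
    def test_out_of_range_rejected(self, p_pbs, p_entf):
        with pytest.raises(ValueError):
            combined_pscore(p_pbs, p_entf)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone(self, p_pbs, p_entf, delta):
        s = combined_pscore(p_pbs, p_entf)
        assert 0.0 <= s <= 1.0
        # decreasing in p_pbs, increasing in p_entf
        assert combined_pscore(min(p_pbs + delta, 1.0), p_entf) <= s + 1e-12
        assert combined_pscore(p_pbs, min(p_entf + delta, 1.0)) >= s - 1e-12


def brute_force_jenks(values, k):
    """Enumerate all contiguous partitions of the sorted values."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    best, best_sse = None, math.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        sse = sum(
            float(np.sum((x[a:b] - x[a:b].mean()) ** 2))
            for a, b in zip(bounds[:-1], bounds[1:])
        )
        if sse < best_sse - 1e-12:
            best_sse, best = sse, bounds
    return best_sse


class TestJenks:
    def test_forced_two_class_split(self):
        assert jenks_breaks([1, 2, 10, 11], 2) == [1, 1, 2, 2]

    def test_single_class(self):
        assert jenks_breaks([3.0, 1.0, 2.0], 1) == [1, 1, 1]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            jenks_breaks([1.0, 2.0], 3)

    def test_classes_follow_value_order(self):
        classes = jenks_breaks([10.0, 1.0, 11.0, 2.0], 2)
        assert classes == [2, 1, 2, 1]

    @given(st.integers(0, 10_000), st.integers(5, 12), st.integers(2, 4))
    @settings(max_examples=40, deadline=None)
    def test_matches_partition_enumeration(self, seed, n, k):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 10, size=n)
        classes = np.asarray(jenks_breaks(values, k))
        sse = sum(
            float(np.sum((values[classes == c] - values[classes == c].mean()) ** 2))
            for c in range(1, k + 1)
        )
        assert sse == pytest.approx(brute_force_jenks(values, k), abs=1e-9)


class TestRankPositions:
    SPEC_SCORES = {
        1: 0.01, 2: 0.02, 10: 0.015, 3: 0.3, 9: 0.35,
        4: 0.82, 5: 0.88, 6: 0.91, 7: 0.85, 8: 0.95,
        11: 0.9, 12: 0.87, 13: 0.93, 14: 0.89, 15: 0.96,
    }

    def test_unambiguous_structure_recovered(self):
        ranking = rank_positions(self.SPEC_SCORES, k=5)
        assert ranking.positions_in_class(1) == {1, 2, 10}
        assert ranking.positions_in_class(2) == {3, 9}

    def test_multipliers_follow_classes(self):
        ranking = rank_positions(self.SPEC_SCORES, k=5)
        assert {p: m for p, m in ranking.multipliers.items() if m > 1} == {
            1: 3, 2: 3, 10: 3, 3: 2, 9: 2,
        }

    def test_all_equal_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            rank_positions({i: 0.5 for i in range(1, 8)}, k=5)

    def test_fewer_positions_than_classes_rejected(self):
        with pytest.raises(ValueError):
            rank_positions({1: 0.1, 2: 0.2}, k=5)

    def test_jenks_confirmation_reported(self):
        ranking = rank_positions(self.SPEC_SCORES, k=5)
        assert set(ranking.jenks_classes) == set(ranking.classes)
        for pos in ranking.jenks_disagreement:
            assert ranking.classes[pos] != ranking.jenks_classes[pos]


class TestEffectSizes:
    def test_unit_cohen_d(self):
        base = np.array([-1.5, -0.5, 0.5, 1.5])
        base = base / base.std(ddof=1)
        assert cohen_d(base + 1.0, base) == pytest.approx(1.0)

    def test_identical_samples_give_zero_d(self):
        x = [1.0, 2.0, 3.0]
        assert cohen_d(x, list(x)) == 0.0

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(5)
        x, y = rng.normal(1, 2, 12), rng.normal(0, 2, 9)
        assert cohen_d(x, y) == pytest.approx(
            pg.compute_effsize(x, y, eftype="cohen"), rel=1e-9
        )

    def test_hedges_correction_factor(self):
        # n = 20 pooled: g/d = 1 - 3/71
        base = np.linspace(-1, 1, 10)
        base = base / base.std(ddof=1)
        d = cohen_d(base + 1.0, base)
        g = hedges_g(base + 1.0, base)
        assert g / d == pytest.approx(1 - 3 / 71)
        assert g == pytest.approx(0.9577, abs=1e-4)

    def test_hedges_converges_to_cohen(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(1, 1, 4000), rng.normal(0, 1, 4000)
        assert hedges_g(x, y) == pytest.approx(cohen_d(x, y), rel=1e-3)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohen_d([1.0, 1.0], [2.0, 2.0])


class TestBootstrap:
    def test_identical_samples_ci_contains_zero(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        diff, (lo, hi) = bootstrap_median_diff(x, list(x), b=500, seed=0)
        assert diff == 0.0
        assert lo <= 0.0 <= hi

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(2, 1, 20), rng.normal(0, 1, 15)
        r1 = bootstrap_median_diff(x, y, b=300, seed=7)
        r2 = bootstrap_median_diff(x, y, b=300, seed=7)
        assert r1 == r2

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_median_diff([1, 2], [3, 4], b=10, seed=0)


class TestMannWhitney:
    def test_exact_p_for_separated_triples(self):
        # U = 0; two-sided exact p = 2 * 1/C(6,3) = 0.1
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_all_tied_gives_p_one(self):
        _, p = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(2)
        x = np.round(rng.normal(0, 1, 30), 1)
        y = np.round(rng.normal(0.5, 1, 25), 1)
        _, p = mann_whitney(x, y)
        assert 0.0 < p < 1.0


class TestCompareSlopes:
    def test_equal_noiseless_slopes(self):
        t = [0.0, 1.0, 2.0, 3.0]
        diff, p = compare_slopes(t, [0, 2, 4, 6], t, [1, 3, 5, 7])
        assert diff == pytest.approx(0.0)
        assert p == 1.0

    def test_matches_interaction_term_ols(self):
        """Slope-difference t-test equals the group-by-time interaction
        test in a pooled OLS fit (same pooled variance and df)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        ta, tb = np.arange(6.0), np.arange(7.0)
        ya = 1.0 + 0.8 * ta + rng.normal(0, 0.3, 6)
        yb = 0.5 + 0.2 * tb + rng.normal(0, 0.3, 7)
        diff, p = compare_slopes(ta, ya, tb, yb)
        x = np.concatenate([ta, tb])
        g = np.concatenate([np.zeros(6), np.ones(7)])
        X = sm.add_constant(np.column_stack([x, g, x * g]))
        fit = sm.OLS(np.concatenate([ya, yb]), X).fit()
        assert diff == pytest.approx(-fit.params[3], rel=1e-9)
        assert p == pytest.approx(fit.pvalues[3], rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            compare_slopes([0, 1], [0, 1], [0, 1, 2], [0, 1, 2])
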