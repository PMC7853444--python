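import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from copefr.allometry import (
    choose_and_run_test,
    length_to_mass,
    random_species_pairing,
    shapiro_wilk,
    welch_t,
    wilcoxon_rank_sum,
)
from copefr.trials import CopepodRecord


class TestLengthToMass:
    def test_unit_length_returns_coefficient(self):
        assert length_to_mass(1.0) == 0.055

    def test_printed_power_law(self):
        assert length_to_mass(2.0) == pytest.approx(0.055 * 2.0**2.73, rel=1e-15)

    def test_vanishes_at_zero_limit(self):
        assert length_to_mass(1e-9) == pytest.approx(0.0, abs=1e-20)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            length_to_mass(0.0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(a=st.floats(0.1, 5.0), b=st.floats(0.1, 5.0))
    def test_strictly_monotone(self, a, b):
        if a == b:
            return
        lo, hi = sorted([a, b])
        assert length_to_mass(lo) < length_to_mass(hi)


class TestShapiroWilk:
    def test_exact_normal_quantiles_look_normal(self):
        x = stats.norm.ppf((np.arange(1, 51) - 0.5) / 50)
        w, p = shapiro_wilk(x)
        assert w > 0.99
        assert p > 0.05

    def test_exponential_samples_rejected_in_majority_of_seeds(self):
        rejections = 0
        for seed in range(40):
            x = np.random.default_rng(seed).exponential(size=50)
            _, p = shapiro_wilk(x)
            rejections += p < 0.05
        assert rejections >= 32  # >= 80% power against this alternative

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0] * 10)


def _exact_rank_sum_p(x, y):
    """Two-sided Wilcoxon p by enumerating all rank assignments (no ties)."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in x)
    n = len(pooled)
    mean_w = len(x) * (n + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n + 1), len(x)):
        total += 1
        if abs(sum(combo) - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_identical_samples_give_p_near_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value > 0.9

    def test_fully_separated_samples_give_minimal_p(self):
        res = wilcoxon_rank_sum([1, 2, 3, 4], [10, 11, 12, 13])
        sep = res.p_value
        res2 = wilcoxon_rank_sum([1, 2, 3, 10], [4, 11, 12, 13])
        assert sep < res2.p_value
        assert sep < 0.05

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1.2, 3.4, 5.1, 2.2], [2.9, 4.4, 6.1, 7.3]),
            ([2, 4, 9, 12], [5, 7, 10, 14]),
            ([1, 2, 3, 4], [5, 6, 7, 8]),
        ],
    )
    def test_normal_approximation_close_to_exact_enumeration(self, x, y):
        res = wilcoxon_rank_sum(x, y)
        assert res.p_value == pytest.approx(_exact_rank_sum_p(list(x), list(y)), abs=0.02)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=12)
        y = rng.normal(0.5, size=10)
        r1 = wilcoxon_rank_sum(x, y)
        r2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
        assert r1.statistic == r2.statistic
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)


class TestWelch:
    def test_identical_samples_give_t_zero_p_one(self):
        res = welch_t([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_satterthwaite_reduces_to_pooled_df_for_equal_groups(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [11.0, 12.0, 13.0, 14.0]  # same variance
        res = welch_t(x, y)
        assert res.df == pytest.approx(len(x) + len(y) - 2)

    def test_matches_hand_computed_formulas(self):
        x, y = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        # hand oracle: means 2 and 3, both variances 1, n = 3 each
        se = math.sqrt(1 / 3 + 1 / 3)
        t_hand = (2 - 3) / se
        df_hand = (1 / 3 + 1 / 3) ** 2 / ((1 / 3) ** 2 / 2 + (1 / 3) ** 2 / 2)
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        res = welch_t(x, y)
        assert res.statistic == pytest.approx(t_hand, rel=1e-12)
        assert res.df == pytest.approx(df_hand, rel=1e-12)
        assert res.p_value == pytest.approx(p_hand, rel=1e-12)

    def test_both_samples_constant_rejected(self):
        with pytest.raises(ValueError):
            welch_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestGatedChoice:
    def test_clean_normal_samples_use_welch(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(0.3, size=40)
        res = choose_and_run_test(x, y)
        assert res.test_name == "welch_t"
        assert res.normality_gate is not None

    def test_heavy_skew_triggers_wilcoxon(self, rng):
        x = rng.exponential(size=40) ** 2
        y = rng.normal(size=40)
        res = choose_and_run_test(x, y)
        assert res.test_name == "wilcoxon_rank_sum"

    def test_alpha_zero_always_welch(self, rng):
        x = rng.exponential(size=40) ** 2
        y = rng.normal(size=40)
        res = choose_and_run_test(x, y, alpha=0.0)
        assert res.test_name == "welch_t"


def _records(species, n, experiment="FR", base=1.5):
    return [
        CopepodRecord(f"{species}{i}", species, experiment, base + 0.01 * i)
        for i in range(n)
    ]


class TestRandomPairing:
    def test_equal_groups_pair_everyone(self):
        s = random_species_pairing(_records("M_albidus", 80), _records("M_viridis", 80, base=2.0), seed=1)
        assert s.n_pairs == 80
        assert len(s.differences) == 80

    def test_unequal_groups_drop_surplus(self):
        s = random_species_pairing(
            _records("M_albidus", 23, "PE"), _records("M_viridis", 24, "PE", base=2.0),
            seed=1, experiment="PE",
        )
        assert s.n_pairs == 23

    def test_combined_designs_give_103_differences(self):
        fr = random_species_pairing(_records("M_albidus", 80), _records("M_viridis", 80, base=2.0), seed=3)
        pe = random_species_pairing(
            _records("M_albidus", 23, "PE"), _records("M_viridis", 24, "PE", base=2.0),
            seed=4, experiment="PE",
        )
        assert fr.n_pairs + pe.n_pairs == 103

    def test_single_pair_is_the_mass_difference(self):
        a = CopepodRecord("a", "M_albidus", "FR", 1.5)
        v = CopepodRecord("v", "M_viridis", "FR", 2.5)
        s = random_species_pairing([a], [v], seed=0)
        assert s.differences[0] == pytest.approx(v.mass_mg - a.mass_mg)

    def test_seed_reproducibility_and_count_invariance(self):
        alb, vir = _records("M_albidus", 30), _records("M_viridis", 40, base=2.0)
        s1 = random_species_pairing(alb, vir, seed=9)
        s2 = random_species_pairing(alb, vir, seed=9)
        s3 = random_species_pairing(alb, vir, seed=10)
        assert np.array_equal(s1.differences, s2.differences)
        assert s1.n_pairs == s3.n_pairs == 30
        assert not np.array_equal(s1.differences, s3.differences)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            random_species_pairing([], _records("M_viridis", 5), seed=0)
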