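import math
from itertools import combinations
from statistics import median

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ssctrn import deg, preprocess, simulate


# --- independent oracles -----------------------------------------------------


def welch_oracle(a, b):
    """Textbook Welch t-test: statistic, Satterthwaite df, two-sided p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return 2 * sps.t.sf(abs(t), df)


def median_ratio_oracle(a, b):
    """Exhaustive label enumeration of the cross-pair median statistic."""
    pooled = list(a) + list(b)
    n, n_a = len(pooled), len(a)
    obs = median(pooled[j] - pooled[i] for i in range(n_a) for j in range(n_a, n))
    count = 0
    total = 0
    for split in combinations(range(n), n_a):
        rest = [i for i in range(n) if i not in split]
        stat = median(pooled[j] - pooled[i] for i in split for j in rest)
        total += 1
        if abs(stat) >= abs(obs):
            count += 1
    return count / total


def bh_oracle(pvals):
    """All-cutoff brute force: adj_i = min over cutoffs t>=p_i of m*t/#{p<=t}."""
    p = list(pvals)
    m = len(p)
    out = []
    for pi in p:
        candidates = [
            m * t / sum(1 for q in p if q <= t) for t in p if t >= pi
        ]
        out.append(min(1.0, min(candidates)))
    return out


def stouffer_oracle(p1, p2):
    """Normal-CDF combination via erfc, independent of scipy.stats.norm."""
    z1 = math.sqrt(2) * _erfcinv(2 * p1)
    z2 = math.sqrt(2) * _erfcinv(2 * p2)
    z = (z1 + z2) / math.sqrt(2)
    return math.erfc(z / math.sqrt(2)) / 2


def _erfcinv(y):
    from scipy.special import erfcinv

    return float(erfcinv(y))


# --- ttest_p -----------------------------------------------------------------


class TestTTest:
    def test_degenerate_equal_constants(self):
        assert deg.ttest_p([5, 5, 5], [5, 5, 5]) == 1.0

    def test_identical_samples(self):
        assert deg.ttest_p([1, 2, 3], [1, 2, 3]) == 1.0

    def test_degenerate_unequal_constants_floored(self):
        assert deg.ttest_p([5, 5, 5], [7, 7, 7]) == pytest.approx(1e-300)

    def test_matches_textbook_welch(self):
        a = [10.1, 10.3, 10.2]
        b = [12.0, 12.2, 12.1]
        assert deg.ttest_p(a, b) == pytest.approx(welch_oracle(a, b), abs=1e-10)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            deg.ttest_p([1.0], [2.0, 3.0])


# --- median_ratio_p ----------------------------------------------------------


class TestMedianRatio:
    def test_null_case_p_one(self):
        assert deg.median_ratio_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_extreme_separation_minimum_p(self):
        # the identity split and its mirror are the only ones reaching |5|
        assert deg.median_ratio_p([0, 0, 0], [5, 5, 5]) == pytest.approx(2 / 20)

    def test_shift_invariance(self):
        a, b = [0.5, 1.0, 0.2], [2.0, 2.5, 1.8]
        assert deg.median_ratio_p(a, b) == deg.median_ratio_p(
            [x + 7 for x in a], [x + 7 for x in b]
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exhaustive_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 3), rng.normal(0.8, 1, 3)
        assert deg.median_ratio_p(a, b) == pytest.approx(median_ratio_oracle(a, b))

    def test_monte_carlo_path_reproducible(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)  # C(16,8)=12870 > n_perm
        p1 = deg.median_ratio_p(a, b, n_perm=200, seed=3)
        p2 = deg.median_ratio_p(a, b, n_perm=200, seed=3)
        assert p1 == p2
        assert p1 >= 1 / 201


# --- combine_p ---------------------------------------------------------------


class TestCombineP:
    def test_half_half(self):
        assert deg.combine_p(0.5, 0.5) == pytest.approx(0.5)

    def test_two_nominal_fives(self):
        # z = 2*1.6449/sqrt(2) = 2.3262 -> p ~ 0.0100
        assert deg.combine_p(0.05, 0.05) == pytest.approx(0.0100, abs=5e-4)
        assert deg.combine_p(0.05, 0.05) == pytest.approx(
            stouffer_oracle(0.05, 0.05), abs=1e-12
        )

    @pytest.mark.parametrize("p", [0.4, 0.2, 0.05, 0.001])
    def test_reinforcement_below_half(self, p):
        assert deg.combine_p(p, p) < p

    def test_symmetry(self):
        assert deg.combine_p(0.01, 0.3) == pytest.approx(deg.combine_p(0.3, 0.01))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            deg.combine_p(-0.1, 0.5)
        with pytest.raises(ValueError):
            deg.combine_p(0.5, 1.2)


# --- bh_adjust ---------------------------------------------------------------


class TestBH:
    def test_hand_computed_step_up(self):
        out = deg.bh_adjust([0.01, 0.04, 0.03, 0.002])
        assert np.allclose(out, [0.02, 0.04, 0.04, 0.008])

    def test_all_equal_unchanged(self):
        assert np.allclose(deg.bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_single_entry_unchanged(self):
        assert np.allclose(deg.bh_adjust([0.123]), 0.123)

    def test_empty(self):
        assert deg.bh_adjust([]).size == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_all_cutoff_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 13))
        assert np.allclose(deg.bh_adjust(p), bh_oracle(p), atol=1e-12)


# --- run_comparisons ---------------------------------------------------------


def _simulate(n_genes, fractions, seed, noise=0.3):
    config = simulate.SimulationConfig(
        n_genes=n_genes, group_fractions=fractions, seed=seed, noise_sd=noise
    )
    return simulate.simulate_expression(config)


class TestRunComparisons:
    def test_call_threshold_conjunction_invariant(self):
        matrix, stages, _ = _simulate(400, {2: 0.15, 8: 0.15}, seed=7)
        results = deg.run_comparisons(matrix, stages, seed=0)
        hit = results["call"] != 0
        assert (results.loc[hit, "p_adjusted"] < 0.05).all()
        assert (results.loc[hit, "log2fc"].abs() > 0.58).all()
        miss = results.loc[~hit]
        assert ((miss["p_adjusted"] >= 0.05) | (miss["log2fc"].abs() <= 0.58)).all()

    def test_full_effect_power(self, planted_run):
        # groups 2/8: early complete shift maintained -> |fc|=1.5 in the two
        # comparisons against SSC. Power is replicate-limited: the 3v3
        # comparison must call >=90% of planted genes; the 3v2 comparison
        # has intrinsically fewer degrees of freedom and a lower floor.
        matrix, stages, truth = planted_run
        normalized = preprocess.quantile_normalize(matrix)
        results = deg.run_comparisons(normalized, stages, seed=0)
        planted = set(truth.planted_genes())
        by_comp = {
            comp: (results[(results["comparison"] == comp) & results["gene"].isin(planted)]["call"] != 0).mean()
            for comp in ("iSSC-vs-SSC", "mSSC-vs-SSC")
        }
        assert by_comp["mSSC-vs-SSC"] >= 0.9
        assert by_comp["iSSC-vs-SSC"] >= 0.6

    def test_fold_change_below_threshold_never_called(self, planted_run):
        matrix, stages, _ = planted_run
        results = deg.run_comparisons(matrix, stages, seed=0)
        small_fc = results[results["log2fc"].abs() <= 0.58]
        assert (small_fc["call"] == 0).all()

    def test_stage_with_single_replicate_refused(self, small_matrix):
        stages = {c: c.split("_")[0] for c in small_matrix.columns}
        stages["iSSC_2"] = "other"
        with pytest.raises(ValueError, match="replicate"):
            deg.run_comparisons(small_matrix, stages)

    def test_reproducible_under_fixed_seed(self):
        matrix, stages, _ = _simulate(150, {1: 0.2}, seed=3)
        r1 = deg.run_comparisons(matrix, stages, seed=5)
        r2 = deg.run_comparisons(matrix, stages, seed=5)
        pd.testing.assert_frame_equal(r1, r2)

    def test_replicate_order_invariance(self):
        matrix, stages, _ = _simulate(100, {1: 0.2}, seed=4)
        shuffled = matrix[list(matrix.columns[::-1])]
        r1 = deg.run_comparisons(matrix, stages, seed=5)
        r2 = deg.run_comparisons(shuffled, stages, seed=5)
        merged = r1.merge(r2, on=["gene", "comparison"], suffixes=("_1", "_2"))
        assert np.allclose(merged["p_mr_1"], merged["p_mr_2"])
        assert np.allclose(merged["log2fc_1"], merged["log2fc_2"])
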