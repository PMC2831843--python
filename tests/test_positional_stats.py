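from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy import stats

from htract.genome_io import GeneRecord, GeneSet
from htract.ht_scan import ResiduePosition
from htract.positional_stats import (codon_position_test, codon_usage,
                                     first_fraction_enrichment, ladder_test,
                                     position_histogram, relative_location,
                                     residue_terminal_test,
                                     uniform_pseudo_null, wilcoxon_one_sided)


def brute_rank_sum_p_less(x, y):
    """Independent oracle: exhaustive enumeration of group labelings,
    ranks computed from scratch by sorting with mid-rank tie handling."""
    pooled = list(x) + list(y)
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for t in range(i, j):
            ranks[order[t]] = mid
        i = j
    n1 = len(x)
    w_obs = sum(ranks[:n1])
    hits = sum(1 for idx in combinations(range(len(pooled)), n1)
               if sum(ranks[i] for i in idx) <= w_obs + 1e-9)
    return hits / comb(len(pooled), n1)


def brute_fisher_greater(a, b, c, d):
    """One-sided Fisher p by direct hypergeometric enumeration."""
    n, row1, col1 = a + b + c + d, a + b, a + c
    denom = comb(n, row1)
    p = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        if x >= a:
            p += comb(col1, x) * comb(n - col1, row1 - x) / denom
    return p


class TestRelativeLocation:
    def test_worked_values(self):
        assert relative_location(1, 5, 100) == pytest.approx(0.03)
        assert relative_location(1, 7, 7) == pytest.approx(4 / 7)
        assert relative_location(7, 7, 7) == 1.0

    def test_midpoint_not_rounded(self):
        # midpoint (1+2)/2 = 1.5 kept exactly
        assert relative_location(1, 2, 3) == pytest.approx(0.5)

    def test_invalid_coordinates_rejected(self):
        for first, last, L in [(0, 5, 10), (6, 5, 10), (2, 11, 10)]:
            with pytest.raises(ValueError):
                relative_location(first, last, L)


class TestPseudoNull:
    def test_mean_and_range(self):
        u = uniform_pseudo_null(100_000, seed=1)
        assert abs(u.mean() - 0.5) < 3 * (1 / np.sqrt(12)) / np.sqrt(u.size)
        assert (u > 0).all() and (u < 1).all()

    def test_seed_reproducible(self):
        assert (uniform_pseudo_null(50, seed=9) ==
                uniform_pseudo_null(50, seed=9)).all()

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            uniform_pseudo_null(0)


class TestWilcoxon:
    def test_extreme_split_exact_sixth(self):
        assert wilcoxon_one_sided([0.1, 0.2], [0.8, 0.9]) == \
            pytest.approx(1 / 6)

    def test_identical_lists_no_shift(self):
        x = [0.2, 0.4, 0.6]
        assert ladder_test(x, x) >= 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_path_matches_brute_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 6, size=2)
        # discretised values force ties into the comparison
        x = np.round(rng.uniform(size=n1), 1)
        y = np.round(rng.uniform(size=n2), 1)
        assert wilcoxon_one_sided(x, y) == \
            pytest.approx(brute_rank_sum_p_less(x, y))

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_path_matches_scipy_when_tie_free(self, seed):
        rng = np.random.default_rng(100 + seed)
        x, y = rng.uniform(size=7), rng.uniform(size=8)
        _, p_ref = stats.mannwhitneyu(x, y, alternative="less",
                                      method="exact")
        assert wilcoxon_one_sided(x, y) == pytest.approx(p_ref)

    def test_large_sample_approximation_close_to_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=60) * 0.9
        y = rng.uniform(size=70)
        _, p_ref = stats.mannwhitneyu(x, y, alternative="less",
                                      method="asymptotic")
        assert wilcoxon_one_sided(x, y) == pytest.approx(p_ref, rel=0.05)

    def test_greater_is_mirror_of_less(self):
        rng = np.random.default_rng(4)
        x, y = rng.uniform(size=6), rng.uniform(size=5)
        assert wilcoxon_one_sided(x, y, "greater") == \
            pytest.approx(wilcoxon_one_sided(y, x, "less"))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_one_sided([], [1.0])

    def test_ladder_detects_five_prime_shift(self):
        rng = np.random.default_rng(5)
        rl_k = rng.beta(1, 9, size=500)
        rl_km1 = rng.uniform(size=500)
        assert ladder_test(rl_k, rl_km1) < 1e-3


class TestEnrichment:
    def test_cross_product_arithmetic(self):
        # fixed table [30,70;10,90] -> OR 3.857
        res = first_fraction_enrichment([0.05] * 30 + [0.5] * 70, seed=0)
        a, b, c, d = res.obs_in, res.obs_out, res.exp_in, res.exp_out
        assert (a, b) == (30, 70)
        assert res.odds_ratio == pytest.approx((a * d) / (b * c))

    @pytest.mark.parametrize("seed", range(6))
    def test_fisher_p_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        obs = rng.uniform(size=n)
        res = first_fraction_enrichment(obs, seed=seed)
        assert res.p == pytest.approx(
            brute_fisher_greater(res.obs_in, res.obs_out,
                                 res.exp_in, res.exp_out))

    def test_most_extreme_small_table(self):
        assert brute_fisher_greater(3, 0, 0, 3) == pytest.approx(1 / 20)
        _, p = stats.fisher_exact([[3, 0], [0, 3]], alternative="greater")
        assert p == pytest.approx(1 / 20)

    def test_zero_cell_haldane_correction(self):
        res = first_fraction_enrichment([0.05] * 10, seed=1)
        assert res.obs_out == 0
        assert np.isfinite(res.odds_ratio)
        assert np.isfinite(res.ci95[0]) and np.isfinite(res.ci95[1])

    def test_uniform_data_or_converges_to_one(self):
        res = first_fraction_enrichment(uniform_pseudo_null(100_000, seed=2),
                                        seed=3)
        assert abs(np.log(res.odds_ratio)) < 0.1

    def test_resampling_mode_stabilises_expected_cells(self):
        obs = uniform_pseudo_null(200, seed=4)
        single = [first_fraction_enrichment(obs, seed=s).exp_in
                  for s in range(30)]
        averaged = [first_fraction_enrichment(obs, seed=s, resamples=50).exp_in
                    for s in range(30)]
        assert np.std(averaged) < np.std(single)

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError):
            first_fraction_enrichment([])


class TestCodonAnalyses:
    def test_usage_fraction(self):
        gs = GeneSet("x", [GeneRecord("g", "AAAAAGAAA")])
        assert codon_usage(gs, ("AAA", "AAG")) == pytest.approx(2 / 3)

    def test_usage_zero_when_first_absent(self):
        gs = GeneSet("x", [GeneRecord("g", "AAG" * 5)])
        assert codon_usage(gs, ("AAA", "AAG")) == 0.0
        # the other synonym is 'preferred' under the >70% reading
        assert codon_usage(gs, ("AAG", "AAA")) > 0.7

    def test_absent_pair_rejected(self):
        gs = GeneSet("x", [GeneRecord("g", "CCCGGG")])
        with pytest.raises(ValueError, match="absent"):
            codon_usage(gs, ("AAA", "AAG"))

    def test_position_test_detects_planted_bias(self):
        rng = np.random.default_rng(6)
        genes = []
        for i in range(200):
            codons = ["GGC"] * 30
            codons[int(rng.integers(0, 3))] = "AAA"      # 5' decile
            codons[int(rng.integers(27, 30))] = "AAG"    # 3' decile
            genes.append(GeneRecord(f"g{i}", "".join(codons)))
        assert codon_position_test(GeneSet("x", genes), "AAA", "AAG") < 1e-3

    def test_position_test_null_when_identical_positions(self):
        genes = [GeneRecord(f"g{i}", "AAA" + "GGC" * 10 + "AAG" + "GGC" * 10)
                 for i in range(10)]
        # AAA always codon 1, AAG always codon 12: AAA genuinely 5' of AAG
        assert codon_position_test(GeneSet("x", genes), "AAG", "AAA") > 0.5


class TestResidueTests:
    @staticmethod
    def residues(positions, L, aa="K"):
        return [ResiduePosition("g", aa, p, L) for p in positions]

    def test_all_terminal_residues_minimal_p(self):
        res = self.residues([50] * 40, 50)
        assert residue_terminal_test(res, "K", "C", seed=0) < 1e-6

    def test_planted_c_terminal_excess(self):
        rng = np.random.default_rng(8)
        res = self.residues(rng.integers(381, 401, size=500), 400)
        assert residue_terminal_test(res, "K", "C", seed=1) < 1e-3

    def test_uniform_null_p_calibrated(self):
        rng = np.random.default_rng(9)
        ps = []
        for s in range(40):
            res = self.residues(rng.integers(1, 401, size=100), 400)
            ps.append(residue_terminal_test(res, "K", "C", seed=1000 + s))
        # under the null the p-values should be roughly uniform
        assert 0.2 < np.mean(ps) < 0.8
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError):
            residue_terminal_test(self.residues([1], 10), "W", "C")


class TestHistogram:
    def test_counts_sum_to_records(self):
        rls = uniform_pseudo_null(777, seed=10)
        counts = position_histogram(rls)
        assert counts.sum() == 777 and counts.size == 20

    def test_five_prime_mass_lands_in_first_bins(self):
        counts = position_histogram([0.01, 0.02, 0.04, 0.99])
        assert counts[0] == 3 and counts[-1] == 1
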