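"""Positional-bias statistics for runs, codons and residues.

The central quantity is the *relative location* of a feature within its
host gene (or protein): the midpoint of the feature divided by the gene
length, rl = ((first + last)/2) / L, which lies in (0, 1].  Values near 0
mean 5'/N-terminal placement.  Three families of tests operate on pooled
relative locations:

* the *ladder test*: one-sided Wilcoxon rank-sum comparing rl of length-k
  tracts against length-(k-1) tracts (are longer tracts closer to the 5'
  end?);
* the *first-fraction enrichment*: an odds ratio and one-sided Fisher
  exact test of observed counts in the 5'-most fraction t (default 10%)
  of genes against an equal-size pseudo-dataset of uniform draws;
* terminal tests for codons and amino acids against the uniform null.

The one-sided Wilcoxon rank-sum is exact (full enumeration of rank splits
with mid-ranks, which also handles ties exactly) for combined sample size
up to ``EXACT_N_MAX``; larger samples use the normal approximation with
tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

from .genome_io import GeneSet
from .ht_scan import CodonHit, HTRun, ResiduePosition, find_codons

__all__ = [
    "PositionRecord",
    "EnrichmentResult",
    "relative_location",
    "run_relative_locations",
    "uniform_pseudo_null",
    "wilcoxon_one_sided",
    "ladder_test",
    "first_fraction_enrichment",
    "codon_usage",
    "codon_position_test",
    "residue_terminal_test",
    "position_histogram",
]

#: combined-n bound below which the rank-sum test enumerates all splits
EXACT_N_MAX = 20


@dataclass(frozen=True)
class PositionRecord:
    """Relative location of one feature (run, codon or residue)."""

    gene_id: str
    kind: str  # ht_run | codon | residue
    first: int
    last: int
    L: int
    rl: float


@dataclass(frozen=True)
class EnrichmentResult:
    """First-fraction (5' t-quantile) enrichment against a uniform null."""

    threshold: float
    obs_in: int
    obs_out: int
    exp_in: int
    exp_out: int
    odds_ratio: float
    ci95: tuple[float, float]
    p: float


def relative_location(first: int, last: int, L: int) -> float:
    """Midpoint over length: ((first + last)/2) / L, in (0, 1].

    ``first`` and ``last`` are 1-based inclusive nt (or residue)
    coordinates; the midpoint may be a half-integer and is not rounded.
    """
    if not (1 <= first <= last <= L):
        raise ValueError(f"require 1 <= first <= last <= L, got {(first, last, L)}")
    return (first + last) / (2 * L)


def run_relative_locations(runs: list[HTRun], gene_lengths: dict[str, int],
                           base: str | None = None,
                           k: int | None = None) -> list[PositionRecord]:
    """PositionRecords for (optionally filtered) tract lists."""
    out = []
    for r in runs:
        if base is not None and r.base != base:
            continue
        if k is not None and r.k != k:
            continue
        L = gene_lengths[r.gene_id]
        out.append(PositionRecord(r.gene_id, "ht_run", r.start, r.end, L,
                                  relative_location(r.start, r.end, L)))
    return out


def uniform_pseudo_null(n: int, seed: int | None = None,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """n i.i.d. Uniform(0,1) pseudo relative locations, seed-reproducible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, size=n)


def _midranks_doubled(pooled: np.ndarray) -> np.ndarray:
    """Mid-ranks of the pooled sample, times 2 (exact integers even with ties)."""
    return np.asarray(2.0 * stats.rankdata(pooled, method="average"),
                      dtype=np.int64)


def _exact_rank_sum_p(ranks2: np.ndarray, n1: int, w2_obs: int) -> float:
    """P(rank-sum of a random n1-subset <= observed), by full enumeration."""
    values = ranks2.tolist()
    total = comb(len(values), n1)
    hits = sum(1 for combo in combinations(values, n1)
               if sum(combo) <= w2_obs)
    return hits / total


def wilcoxon_one_sided(x, y, alternative: str = "less") -> float:
    """One-sided Wilcoxon rank-sum p-value.

    ``alternative="less"`` tests whether x is stochastically smaller than
    y; ``"greater"`` the reverse.  Exact enumeration of all C(n, n1) rank
    splits (mid-ranks, ties included) for combined n <= EXACT_N_MAX,
    otherwise the normal approximation with tie-corrected variance and a
    0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative == "greater":
        return wilcoxon_one_sided(y, x, "less")
    if alternative != "less":
        raise ValueError("alternative must be 'less' or 'greater'")
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks2 = _midranks_doubled(pooled)
    w2_obs = int(ranks2[:n1].sum())
    if n <= EXACT_N_MAX:
        return _exact_rank_sum_p(ranks2, n1, w2_obs)
    w = w2_obs / 2.0
    mu = n1 * (n + 1) / 2.0
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t ** 3 - t).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values tied: no evidence of shift
        return 1.0
    z = (w + 0.5 - mu) / np.sqrt(var)
    return float(stats.norm.cdf(z))


def ladder_test(rl_k, rl_km1) -> float:
    """p for 'length-k tracts lie closer to the 5' end than length-(k-1)'."""
    return wilcoxon_one_sided(rl_k, rl_km1, alternative="less")


def _odds_ratio_ci(a: float, b: float, c: float, d: float
                   ) -> tuple[float, tuple[float, float]]:
    """Cross-product OR with 95% CI by the log-OR normal approximation;
    Haldane-Anscombe 0.5 added to every cell when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return float(or_), (float(lo), float(hi))


def first_fraction_enrichment(observed_rl, threshold: float = 0.10,
                              seed: int | None = None,
                              rng: np.random.Generator | None = None,
                              resamples: int = 1) -> EnrichmentResult:
    """Enrichment of observed relative locations in the 5'-most fraction.

    A pseudo-dataset of uniform draws of the same size as the observed
    list is generated (``resamples`` > 1 averages the expected cells over
    that many draws, rounding to the nearest integer count); the 2x2
    table [obs_in, obs_out; exp_in, exp_out] gives the odds ratio and a
    one-sided Fisher exact p-value for enrichment.
    """
    obs = np.asarray(observed_rl, dtype=float)
    if obs.size == 0:
        raise ValueError("observed list must be non-empty")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = obs.size
    obs_in = int((obs <= threshold).sum())
    obs_out = n - obs_in
    exp_in_draws = [
        int((uniform_pseudo_null(n, rng=rng) <= threshold).sum())
        for _ in range(max(1, resamples))
    ]
    exp_in = int(round(float(np.mean(exp_in_draws))))
    exp_out = n - exp_in
    or_, ci = _odds_ratio_ci(obs_in, obs_out, exp_in, exp_out)
    _, p = stats.fisher_exact([[obs_in, obs_out], [exp_in, exp_out]],
                              alternative="greater")
    return EnrichmentResult(threshold, obs_in, obs_out, exp_in, exp_out,
                            or_, ci, float(p))


def codon_usage(genes: GeneSet, codon_pair: tuple[str, str]) -> float:
    """Fraction of a synonymous pair attributable to the first codon.

    Returns count(pair[0]) / (count(pair[0]) + count(pair[1])) over
    in-frame occurrences pooled across genes; a codon is conventionally
    called 'preferred' above 0.5.
    """
    c1, c2 = (c.upper() for c in codon_pair)
    n1 = sum(len(find_codons(g, c1)) for g in genes if g.length >= 3)
    n2 = sum(len(find_codons(g, c2)) for g in genes if g.length >= 3)
    if n1 + n2 == 0:
        raise ValueError(f"codon pair {codon_pair} absent from gene set")
    return n1 / (n1 + n2)


def _codon_rls(genes: GeneSet, codon: str) -> list[float]:
    rls = []
    for g in genes:
        if g.length < 3:
            continue
        for hit in find_codons(g, codon):
            rls.append(relative_location(hit.start_nt, hit.start_nt + 2,
                                         g.length))
    return rls


def codon_position_test(genes: GeneSet, codon_a: str, codon_b: str) -> float:
    """p for 'codon_a lies closer to the 5' end than codon_b' (pooled)."""
    rl_a = _codon_rls(genes, codon_a)
    rl_b = _codon_rls(genes, codon_b)
    if not rl_a or not rl_b:
        raise ValueError("both codons must occur in the gene set")
    return wilcoxon_one_sided(rl_a, rl_b, alternative="less")


def residue_terminal_test(residues: list[ResiduePosition], amino_acid: str,
                          direction: str = "C",
                          seed: int | None = None,
                          rng: np.random.Generator | None = None) -> float:
    """Test whether an amino acid sits closer to one protein terminus than
    expected under uniform placement.

    rl = residue_index / protein_length; the comparison dataset is an
    equal-size uniform pseudo-null.  ``direction="N"`` tests proximity to
    the N-terminus (rl stochastically smaller than uniform), ``"C"`` the
    C-terminus.
    """
    rl = np.array([r.residue_index / r.protein_length for r in residues
                   if r.amino_acid == amino_acid])
    if rl.size == 0:
        raise ValueError(f"no {amino_acid!r} residues supplied")
    null = uniform_pseudo_null(rl.size, seed=seed, rng=rng)
    if direction == "N":
        return wilcoxon_one_sided(rl, null, alternative="less")
    if direction == "C":
        return wilcoxon_one_sided(rl, null, alternative="greater")
    raise ValueError("direction must be 'N' or 'C'")


def position_histogram(rls, bins: int = 20) -> np.ndarray:
    """Counts of relative locations over equal windows of (0, 1].

    The default 20 windows of 5% each reproduce the standard positional
    histogram; counts sum to the number of records.
    """
    rls = np.asarray(rls, dtype=float)
    counts, _ = np.histogram(rls, bins=bins, range=(0.0, 1.0))
    return counts
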