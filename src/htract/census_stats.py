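"""Expected tract counts under a composition null, and over-representation
Z-scores.

Model
-----
Under the null, coding sequence is i.i.d. nucleotides with per-base
frequencies f_i estimated from the gene set itself.  The expected number
of *maximal* runs of base i of exact length k in a gene of length L is

    E_gene = (L - k - 1) * f^k * (1-f)^2  +  2 * f^k * (1-f)     (L >= k+1)
    E_gene = f^k                                                  (L == k)
    E_gene = 0                                                    (L <  k)

(interior starts need two non-matching flanks; a run touching either gene
boundary needs only one).  Summed over a gene set with total length N and
n genes (all longer than k) this collapses to the aggregate closed form

    E = (N - n*(k+1)) * f^k * (1-f)^2  +  2*n * f^k * (1-f).

The observed count O is compared to E with a binomially-motivated normal
Z-score, Z = (O - E) / sqrt(N*q*(1-q)) with q = E/N; since q is tiny at
genome scale this is numerically (O - E)/sqrt(E) (the Poisson form, also
exposed).  Z > 1.64 is the one-sided 5% over-representation call and
|Z| > 1.96 the two-sided display cut-off.  Cells with E below a floor
(default 0.05) are 'untestable': under-representation cannot be detected
when almost no tracts are expected in the first place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import GeneSet
from .ht_scan import run_count_table
from .positional_stats import wilcoxon_one_sided

__all__ = [
    "GenomeComposition",
    "Z_ONE_SIDED",
    "Z_TWO_SIDED",
    "composition",
    "expected_count",
    "expected_count_per_gene",
    "z_score",
    "census",
    "grouped_census",
    "compare_group_zscores",
]

#: one-sided 5% critical value (over-representation call)
Z_ONE_SIDED = 1.64
#: two-sided 5% display cut-off
Z_TWO_SIDED = 1.96
#: cells with E below this are never called, in either direction
E_FLOOR = 0.05

BASES = "ACGT"


@dataclass(frozen=True)
class GenomeComposition:
    """Nucleotide frequencies over the non-N coding positions of a gene set."""

    freqs: dict[str, float]  # f_i for i in ACGT; sums to 1
    N: int                   # total coding length in nt (N bases included)
    n: int                   # number of coding genes

    @property
    def gc(self) -> float:
        return self.freqs["G"] + self.freqs["C"]


def composition(genes: GeneSet) -> GenomeComposition:
    """Estimate f_i, N and n from a gene set (Ns excluded from the
    frequency denominator but counted in N)."""
    if genes.n == 0:
        raise ValueError("empty GeneSet")
    counts = {b: 0 for b in BASES}
    for g in genes:
        for b in BASES:
            counts[b] += g.sequence.count(b)
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("gene set contains no A/C/G/T positions")
    freqs = {b: counts[b] / denom for b in BASES}
    return GenomeComposition(freqs, genes.N, genes.n)


def expected_count_per_gene(f: float, lengths, k: int) -> float:
    """Exact per-gene expectation summed over gene lengths (handles genes
    shorter than or equal to k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    L = np.asarray(lengths, dtype=float)
    fk = f ** k
    interior = np.clip(L - k - 1, 0.0, None) * fk * (1 - f) ** 2
    boundary = np.where(L >= k + 1, 2 * fk * (1 - f), 0.0)
    exact_fit = np.where(L == k, fk, 0.0)
    return float(np.where(L < k, 0.0, interior + boundary + exact_fit).sum())


def expected_count(comp: GenomeComposition, base: str, k: int,
                   gene_lengths=None) -> float:
    """Expected number E of maximal runs of ``base`` of exact length ``k``.

    Uses the aggregate closed form from (N, n); pass ``gene_lengths`` to
    apply per-gene boundary guards (the two differ only when genes of
    length <= k exist, negligible at genome scale).
    """
    if base not in BASES:
        raise ValueError(f"invalid base {base!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    f = comp.freqs[base]
    if gene_lengths is not None:
        return expected_count_per_gene(f, gene_lengths, k)
    return (comp.N - comp.n * (k + 1)) * f ** k * (1 - f) ** 2 \
        + 2 * comp.n * f ** k * (1 - f)


def z_score(O: float, E: float, N: int, variance: str = "binomial") -> float:
    """Standard score of the observed count against the null expectation.

    ``variance="binomial"`` uses N trial sites with per-site success
    probability q = E/N (variance N*q*(1-q)); ``"poisson"`` uses E.
    Requires E > 0 (cells with E = 0 are untestable, not scored).
    """
    if E <= 0:
        raise ValueError("z_score requires E > 0; cell is untestable")
    if variance == "binomial":
        q = E / N
        var = N * q * (1 - q)
    elif variance == "poisson":
        var = E
    else:
        raise ValueError("variance must be 'binomial' or 'poisson'")
    return (O - E) / np.sqrt(var)


def _call(Z: float | None, E: float, z_over: float, e_floor: float) -> str:
    if E < e_floor or Z is None:
        return "untestable"
    if Z > z_over:
        return "over"
    if Z < -z_over:
        return "under"
    return "ns"


def census(genes: GeneSet, k_min: int = 1, k_max: int = 20,
           bases: str = BASES, z_over: float = Z_ONE_SIDED,
           z_two: float = Z_TWO_SIDED, e_floor: float = E_FLOOR,
           variance: str = "binomial",
           per_gene_expectation: bool = False) -> pd.DataFrame:
    """Observed/expected census over bases x run lengths for one gene set.

    Returns one row per (base, k) with columns genome, base, k, f_i, gc,
    N, n, O, E, q, Z, call, signif_two_sided.
    """
    genes.validate()
    comp = composition(genes)
    counts = run_count_table(genes)
    lengths = [g.length for g in genes] if per_gene_expectation else None
    rows = []
    for base in bases:
        for k in range(k_min, k_max + 1):
            O = counts.get((base, k), 0)
            E = expected_count(comp, base, k, gene_lengths=lengths)
            Z = z_score(O, E, comp.N, variance) if E > 0 else None
            rows.append({
                "genome": genes.genome_id, "base": base, "k": k,
                "f_i": comp.freqs[base], "gc": comp.gc,
                "N": comp.N, "n": comp.n, "O": O, "E": E,
                "q": E / comp.N, "Z": Z if Z is not None else np.nan,
                "call": _call(Z, E, z_over, e_floor),
                "signif_two_sided": bool(Z is not None and abs(Z) > z_two),
            })
    return pd.DataFrame(rows)


def add_bh_correction(table: pd.DataFrame) -> pd.DataFrame:
    """Optional Benjamini-Hochberg adjustment of the one-sided
    over-representation p-values across a census table (off the default
    path: calls in :func:`census` are uncorrected)."""
    from scipy import stats as _st

    out = table.copy()
    p = _st.norm.sf(out["Z"].to_numpy(dtype=float))
    testable = ~np.isnan(p)
    p_adj = np.full(p.shape, np.nan)
    if testable.any():
        p_adj[testable] = _st.false_discovery_control(p[testable], method="bh")
    out["p_over"] = p
    out["p_over_bh"] = p_adj
    return out


def grouped_census(genes: GeneSet, k_min: int = 1, k_max: int = 20,
                   bases: str = BASES, **kwargs) -> pd.DataFrame:
    """Per-group census: composition, E, O and Z within each label's subset.

    Unlabelled genes participate only in whole-set analyses.  The role-
    category breakdown of a genome is the canonical use.
    """
    labels = genes.group_labels()
    if not labels:
        raise ValueError("no labelled genes in the gene set")
    frames = []
    for label in labels:
        sub = genes.subset(group_label=label)
        df = census(sub, k_min=k_min, k_max=k_max, bases=bases, **kwargs)
        df.insert(1, "group", label)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def compare_group_zscores(z_group_a, z_group_b,
                          alternative: str = "greater") -> float:
    """One-sided Wilcoxon rank-sum on per-genome Z-scores for a fixed
    (base, k) cell: are genomes in group A more over-represented than
    genomes in group B? (``alternative="greater"``: A shifted higher.)"""
    if alternative == "greater":
        return wilcoxon_one_sided(z_group_a, z_group_b, "greater")
    if alternative == "less":
        return wilcoxon_one_sided(z_group_a, z_group_b, "less")
    raise ValueError("alternative must be 'greater' or 'less'")
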