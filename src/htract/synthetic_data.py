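"""Synthetic gene sets and plating experiments for testing the pipeline.

Three generators cover the inputs every downstream stage needs:

* :func:`make_null_geneset` draws genes as i.i.d. nucleotides at a chosen
  composition (the exact null the tract-census expectation model
  assumes), so analytic expected counts can be checked against observed
  counts and false-positive rates calibrated;
* :func:`plant_hts` overwrites runs of a chosen base and length into
  existing genes at positions drawn from a configurable law — uniform,
  or a 5'-skewed Beta over relative position — with flanking bases
  forced to differ so every planted run is maximal and recoverable;
* :func:`simulate_plating` draws replicate plating experiments at a known
  true per-cell reversion frequency, including the two-component colony
  size mixture that exercises the large/small classifier and the
  sequencing-confirmation subsampling rule.

These emulate composition and placement only; real coding genes have
codon structure, ORF grammar and within-gene GC gradients that are
deliberately absent (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genome_io import GeneRecord, GeneSet
from .reversion import LARGE_COLONY_MIN_PX, PlatingExperiment

__all__ = [
    "CompositionSpec",
    "PlantSpec",
    "PlatingSimSpec",
    "make_null_geneset",
    "plant_hts",
    "simulate_plating",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CompositionSpec:
    """Target i.i.d. nucleotide composition for null gene sets."""

    f_A: float
    f_C: float
    f_G: float
    f_T: float

    def __post_init__(self):
        probs = self.as_array()
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")

    @classmethod
    def from_gc(cls, gc: float) -> "CompositionSpec":
        """Equal AT and GC splits at a target GC fraction."""
        return cls((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)

    def as_array(self) -> np.ndarray:
        return np.array([self.f_A, self.f_C, self.f_G, self.f_T])


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: runs of ``base`` of length ``k``, ``count_per_gene``
    per gene (fractional part realised as a Bernoulli draw), at relative
    midpoint positions drawn from ``position_law`` — "uniform" or
    ("beta", alpha, beta) with small alpha/large beta skewing 5'."""

    base: str
    k: int
    count_per_gene: float = 1.0
    position_law: str | tuple = "uniform"

    def __post_init__(self):
        if self.base not in "ACGT":
            raise ValueError(f"invalid base {self.base!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.count_per_gene < 0:
            raise ValueError("count_per_gene must be non-negative")
        if isinstance(self.position_law, tuple):
            tag, a, b = self.position_law
            if tag != "beta" or a <= 0 or b <= 0:
                raise ValueError("position_law tuple must be ('beta', a>0, b>0)")
        elif self.position_law != "uniform":
            raise ValueError("position_law must be 'uniform' or ('beta', a, b)")


@dataclass(frozen=True)
class PlatingSimSpec:
    """Ground truth and plating layout for simulated reversion assays."""

    true_freq: float                   # revertants per cell, phi
    culture_size: float = 2e10         # cells per culture
    culture_volume_ml: float = 5.0
    DF_total: float = 2e6              # dilution for viable counts
    DF_sel: float = 1.0                # dilution for selective plates
    VP: float = 0.1                    # ml plated (both platings)
    replicates: int = 3
    background_small_rate: float = 25.0  # non-revertant colonies/plate
    large_size_mean: float = 15.0      # px, revertant colony size law
    small_size_mean: float = 3.0       # px offset, background colonies
    max_sequenced: int = 10            # colonies sequenced when TC >= 20

    def __post_init__(self):
        if not 0 <= self.true_freq <= 1:
            raise ValueError("true_freq must be in [0, 1]")
        if self.culture_size < 1:
            raise ValueError("culture_size must be >= 1")
        if self.VP <= 0 or self.culture_volume_ml <= 0:
            raise ValueError("volumes must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def make_null_geneset(comp: CompositionSpec, n_genes: int,
                      length_law: int | Sequence[int] | Callable = 900,
                      seed: int | None = None,
                      genome_id: str = "null") -> GeneSet:
    """Gene set with i.i.d. bases at the given composition.

    ``length_law`` is a fixed length (nt), a per-gene length sequence, or
    a callable ``(rng, n_genes) -> lengths``.  Reproducible given seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    if callable(length_law):
        lengths = np.asarray(length_law(rng, n_genes), dtype=int)
    elif np.isscalar(length_law):
        lengths = np.full(n_genes, int(length_law))
    else:
        lengths = np.asarray(length_law, dtype=int)
        if lengths.size != n_genes:
            raise ValueError("length sequence must have n_genes entries")
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 nt")
    probs = comp.as_array()
    total = int(lengths.sum())
    draws = rng.choice(_BASES, size=total, p=probs)
    genes = []
    offset = 0
    for i, L in enumerate(lengths):
        chunk = draws[offset:offset + L]
        offset += L
        genes.append(GeneRecord(f"g{i + 1:05d}", chunk.tobytes().decode("ascii")))
    return GeneSet(genome_id, genes)


def _draw_rel_positions(law, n: int, rng: np.random.Generator) -> np.ndarray:
    if law == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    _, a, b = law
    return rng.beta(a, b, size=n)


def plant_hts(genes: GeneSet, spec: PlantSpec,
              seed: int | None = None) -> GeneSet:
    """Overwrite maximal runs into genes at law-driven relative positions.

    Each planted run of length k is written with both flanking bases
    forced to differ from the run base, the total gene length unchanged.
    The drawn relative position is the target *midpoint*; the realised
    start is clamped so the run plus flanks fits inside the gene and does
    not touch previously planted material.
    """
    rng = np.random.default_rng(seed)
    k = spec.k
    base_byte = ord(spec.base)
    others = np.array([b for b in _BASES if b != base_byte], dtype=np.uint8)
    new_genes = []
    for g in genes:
        L = g.length
        if spec.count_per_gene > 0 and L <= k + 2:
            raise ValueError(
                f"gene {g.gene_id!r} (L={L}) too short to plant a maximal "
                f"run of length {k}")
        want = int(spec.count_per_gene)
        if rng.uniform() < spec.count_per_gene - want:
            want += 1
        arr = np.frombuffer(g.sequence.encode("ascii"), dtype=np.uint8).copy()
        occupied: list[tuple[int, int]] = []  # 0-based [start-1, end+1] blocks
        planted = 0
        attempts = 0
        while planted < want and attempts < 100 * max(want, 1):
            attempts += 1
            rl = _draw_rel_positions(spec.position_law, 1, rng)[0]
            mid = rl * L
            start0 = int(round(mid - (k - 1) / 2.0)) - 1  # 0-based
            start0 = min(max(start0, 1), L - k - 1)
            block = (start0 - 1, start0 + k)
            if any(not (block[1] < lo or block[0] > hi)
                   for lo, hi in occupied):
                continue
            arr[start0:start0 + k] = base_byte
            arr[start0 - 1] = rng.choice(others)
            arr[start0 + k] = rng.choice(others)
            occupied.append(block)
            planted += 1
        if planted < want:
            raise ValueError(
                f"could not place {want} runs of length {k} in gene "
                f"{g.gene_id!r} (L={L})")
        new_genes.append(GeneRecord(g.gene_id, arr.tobytes().decode("ascii"),
                                    g.group_label))
    return GeneSet(genes.genome_id, new_genes)


def _colony_sizes(n_large_law: int, mean: float, minimum: int,
                  rng: np.random.Generator) -> np.ndarray:
    sizes = rng.poisson(mean, size=n_large_law)
    return np.maximum(sizes, minimum)


def simulate_plating(spec: PlatingSimSpec,
                     seed: int | None = None) -> list[PlatingExperiment]:
    """Draw replicate plating experiments at a known reversion frequency.

    Per replicate: revertant cells per culture are Poisson(phi * culture
    size); plated revertants are a binomial thinning by the plated
    fraction VP / (culture volume * DF_sel); revertant colonies draw
    sizes from a Poisson law around ``large_size_mean`` px and background
    non-revertant colonies (rate ``background_small_rate``) around
    ``small_size_mean`` + 1 px, so a small fraction of each class crosses
    the 8 px boundary.  Large colonies are sequenced per the assay rule
    (all when fewer than 20, else ``max_sequenced``), and confirmations
    follow the hypergeometric draw of true revertants among sequenced
    large colonies.
    """
    rng = np.random.default_rng(seed)
    exps = []
    density = spec.culture_size / spec.culture_volume_ml  # cells/ml
    plated_frac_sel = spec.VP / (spec.culture_volume_ml * spec.DF_sel)
    if plated_frac_sel > 1:
        raise ValueError("selective plating would plate more than the culture")
    for rep in range(spec.replicates):
        cfu = int(rng.poisson(density * spec.VP / spec.DF_total))
        revertant_cells = int(rng.poisson(spec.true_freq * spec.culture_size))
        rev_plated = int(rng.binomial(revertant_cells, plated_frac_sel))
        rev_sizes = rng.poisson(spec.large_size_mean, size=rev_plated)
        rev_sizes = np.maximum(rev_sizes, 1)
        n_bg = int(rng.poisson(spec.background_small_rate))
        bg_sizes = 1 + rng.poisson(spec.small_size_mean, size=n_bg)
        sizes = np.concatenate([rev_sizes, bg_sizes]).astype(int)
        is_rev = np.concatenate([np.ones(rev_plated, bool),
                                 np.zeros(n_bg, bool)])
        large_mask = sizes >= LARGE_COLONY_MIN_PX
        tc = int(large_mask.sum())
        n_true_large = int((large_mask & is_rev).sum())
        cs = tc if tc < 20 else min(spec.max_sequenced, tc)
        r = int(rng.hypergeometric(n_true_large, tc - n_true_large, cs)) \
            if cs > 0 else 0
        exps.append(PlatingExperiment(
            replicate_id=f"rep{rep + 1}", CFU=float(cfu),
            DF_total=spec.DF_total, VP=spec.VP, DF_sel=spec.DF_sel,
            TC=tc, CS=cs, R=r, colony_sizes=tuple(int(s) for s in sizes),
        ))
    return exps
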