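"""Detection of homopolymeric tracts, in-frame codons, and residue positions.

A homopolymeric tract (HT) is a *maximal* run of one nucleotide: a run of
exact length k is flanked by a different base or by a gene boundary, so a
run of 8 As is one A8 tract and contributes nothing to the A7 or A6 counts.
Detection is by run-length encoding of the byte sequence, which partitions
every non-N position of a gene into exactly one maximal run.

Codon scanning is in-frame only (frame fixed by nt 1 of the record) and
translation uses the standard genetic code with the first codon translated
literally; genes with internal stop codons are flagged and excluded from
residue-position analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .genome_io import GeneRecord, GeneSet

__all__ = [
    "HTRun",
    "CodonHit",
    "ResiduePosition",
    "TranslationResult",
    "find_runs",
    "scan_geneset",
    "count_runs",
    "find_codons",
    "translate",
]

_N_BYTE = ord("N")


@dataclass(frozen=True)
class HTRun:
    """One maximal mononucleotide run (1-based inclusive coordinates)."""

    gene_id: str
    base: str
    k: int
    start: int
    end: int

    def __post_init__(self):
        assert self.end - self.start + 1 == self.k


@dataclass(frozen=True)
class CodonHit:
    """An in-frame occurrence of a codon; start_nt = 3*(codon_index-1)+1."""

    gene_id: str
    codon: str
    codon_index: int
    start_nt: int


@dataclass(frozen=True)
class ResiduePosition:
    """Position of one amino acid within its translated protein."""

    gene_id: str
    amino_acid: str
    residue_index: int
    protein_length: int


@dataclass(frozen=True)
class TranslationResult:
    gene_id: str
    protein: str
    residues: list[ResiduePosition]
    has_internal_stop: bool


def _run_bounds(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start and (exclusive) end indices of maximal equal-value runs."""
    if arr.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    return starts, ends


def find_runs(gene: GeneRecord, k_min: int = 1, k_max: int = 20) -> list[HTRun]:
    """All maximal mononucleotide runs of length >= ``k_min``.

    Runs longer than ``k_max`` are still reported with their true length
    (so the run partition of the gene is complete); ``k_max`` is the
    census range, not a detection cap.  N positions belong to no run.
    """
    if k_min < 1 or k_max < k_min:
        raise ValueError("require 1 <= k_min <= k_max")
    if not gene.sequence:
        raise ValueError(f"gene {gene.gene_id!r} has an empty sequence")
    arr = np.frombuffer(gene.sequence.encode("ascii"), dtype=np.uint8)
    starts, ends = _run_bounds(arr)
    bases = arr[starts]
    out: list[HTRun] = []
    for s, e, b in zip(starts, ends, bases):
        if b == _N_BYTE:
            continue
        k = int(e - s)
        if k >= k_min:
            out.append(HTRun(gene.gene_id, chr(b), k, int(s) + 1, int(e)))
    return out


def scan_geneset(genes: GeneSet, k_min: int = 1, k_max: int = 20) -> list[HTRun]:
    """find_runs over every gene, in gene order."""
    out: list[HTRun] = []
    for g in genes:
        out.extend(find_runs(g, k_min=k_min, k_max=k_max))
    return out


def count_runs(genes: GeneSet, base: str, k: int) -> int:
    """Observed number O of maximal runs of ``base`` of exactly length ``k``.

    Vectorised over the whole gene set: genes are concatenated with a
    separator byte so runs cannot bridge gene boundaries, then run-length
    encoded in one pass.
    """
    if base not in "ACGT":
        raise ValueError(f"invalid base {base!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = run_count_table(genes)
    return int(counts.get((base, k), 0))


def run_count_table(genes: GeneSet) -> dict[tuple[str, int], int]:
    """Counts of maximal runs for every (base, exact length) in one pass."""
    blob = "\0".join(g.sequence for g in genes)
    if not blob:
        return {}
    arr = np.frombuffer(blob.encode("ascii"), dtype=np.uint8)
    starts, ends = _run_bounds(arr)
    bases = arr[starts]
    lengths = ends - starts
    keep = (bases != 0) & (bases != _N_BYTE)
    table: dict[tuple[str, int], int] = {}
    if not keep.any():
        return table
    b = bases[keep].astype(np.int64)
    ln = lengths[keep].astype(np.int64)
    stride = int(ln.max()) + 1
    uniq, cnt = np.unique(b * stride + ln, return_counts=True)
    for key, c in zip(uniq, cnt):
        table[(chr(int(key) // stride), int(key) % stride)] = int(c)
    return table


def find_codons(gene: GeneRecord, codon: str) -> list[CodonHit]:
    """In-frame occurrences of ``codon``; trailing 1-2 nt are ignored."""
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError("codon must be a 3-mer")
    if gene.length < 3:
        raise ValueError(f"gene {gene.gene_id!r} shorter than one codon")
    seq = gene.sequence
    hits = []
    for idx in range(gene.length // 3):
        start = 3 * idx
        if seq[start:start + 3] == codon:
            hits.append(CodonHit(gene.gene_id, codon, idx + 1, start + 1))
    return hits


def translate(gene: GeneRecord) -> TranslationResult:
    """Translate a full CDS (standard code, first codon literal).

    The terminal stop is dropped; an internal stop sets
    ``has_internal_stop`` and such genes should be excluded from
    residue-position analyses (the caller decides; residues up to the
    internal stop are still returned for inspection).
    """
    if gene.length < 3:
        raise ValueError(f"gene {gene.gene_id!r} shorter than one codon")
    trimmed = gene.sequence[: 3 * (gene.length // 3)]
    aa = str(Seq(trimmed).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    internal = "*" in aa
    protein = aa.split("*")[0] if internal else aa
    residues = [
        ResiduePosition(gene.gene_id, res, i + 1, len(protein))
        for i, res in enumerate(protein)
    ]
    return TranslationResult(gene.gene_id, protein, residues, internal)


def residue_positions(genes: GeneSet) -> list[ResiduePosition]:
    """Pooled residue positions over all stop-free genes of a set.

    Genes shorter than a codon or containing an internal stop (or an X
    from an N base) are skipped, mirroring the exclusion rule above.
    """
    out: list[ResiduePosition] = []
    for g in genes:
        if g.length < 3:
            continue
        tr = translate(g)
        if tr.has_internal_stop:
            continue
        out.extend(tr.residues)
    return out
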