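"""Reading, writing and validation of coding-sequence gene sets.

A :class:`GeneSet` is the unit every downstream analysis operates on: an
ordered collection of coding sequences (one record per gene, given 5'->3'),
optionally annotated with free-text group labels (e.g. functional role
categories) supplied as a TSV sidecar.

Conventions
-----------
* Sequences are normalised to upper case over the alphabet {A, C, G, T, N};
  ``U`` is mapped to ``T``.
* ``N`` bases are retained verbatim but never extend a homopolymer run and
  are excluded from nucleotide-frequency denominators.
* All coordinates in this package are 1-based and inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneRecord",
    "GeneSet",
    "read_gene_fasta",
    "write_gene_fasta",
    "read_group_labels",
]

_VALID = set("ACGTN")
# IUPAC one-letter ambiguity codes other than N
_AMBIGUOUS = set("RYSWKMBDHV")

AmbiguityPolicy = Literal["strict", "map-to-n"]


@dataclass(frozen=True)
class GeneRecord:
    """One coding gene: an identifier, its nucleotide sequence and an
    optional group label used by per-group (role-category style) analyses."""

    gene_id: str
    sequence: str
    group_label: str | None = None

    @property
    def length(self) -> int:
        """Gene length L in nucleotides."""
        return len(self.sequence)


@dataclass
class GeneSet:
    """Ordered collection of :class:`GeneRecord` forming one 'genome'
    (more precisely: the coding complement analysed as a unit)."""

    genome_id: str
    genes: list[GeneRecord] = field(default_factory=list)

    @property
    def n(self) -> int:
        """Number of coding genes."""
        return len(self.genes)

    @property
    def N(self) -> int:
        """Total length of the coding genes, in nt (N bases included)."""
        return sum(g.length for g in self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def validate(self) -> None:
        """Raise ``ValueError`` on duplicate ids, empty sequences or
        characters outside {A,C,G,T,N}."""
        if self.n == 0:
            raise ValueError(f"GeneSet {self.genome_id!r} is empty")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if not g.sequence:
                raise ValueError(f"gene {g.gene_id!r} has an empty sequence")
            bad = set(g.sequence) - _VALID
            if bad:
                raise ValueError(
                    f"gene {g.gene_id!r} contains non-nucleotide characters {sorted(bad)}"
                )

    def subset(self, gene_ids: Iterable[str] | None = None,
               group_label: str | None = None) -> "GeneSet":
        """Restrict to named genes and/or one group label."""
        genes = self.genes
        if gene_ids is not None:
            wanted = set(gene_ids)
            genes = [g for g in genes if g.gene_id in wanted]
        if group_label is not None:
            genes = [g for g in genes if g.group_label == group_label]
        return GeneSet(self.genome_id, list(genes))

    def group_labels(self) -> list[str]:
        """Distinct non-null labels, in first-appearance order."""
        out: list[str] = []
        for g in self.genes:
            if g.group_label is not None and g.group_label not in out:
                out.append(g.group_label)
        return out


def normalize_sequence(seq: str, ambiguous: AmbiguityPolicy = "strict") -> str:
    """Upper-case, map U->T, and resolve IUPAC ambiguity codes.

    ``strict`` rejects any character outside {A,C,G,T,N,U}; ``map-to-n``
    maps the IUPAC ambiguity codes (R, Y, S, W, K, M, B, D, H, V) to N.
    """
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if not bad:
        return s
    if ambiguous == "map-to-n" and bad <= _AMBIGUOUS:
        return s.translate(str.maketrans({c: "N" for c in _AMBIGUOUS}))
    raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")


def read_group_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``gene_id<TAB>group_label`` (header required)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "gene_id" not in reader.fieldnames \
                or "group_label" not in reader.fieldnames:
            raise ValueError(
                f"{path}: expected header columns 'gene_id' and 'group_label', "
                f"got {reader.fieldnames}"
            )
        return {row["gene_id"]: row["group_label"] for row in reader}


def read_gene_fasta(path: str | Path,
                    labels: str | Path | None = None,
                    genome_id: str | None = None,
                    ambiguous: AmbiguityPolicy = "strict") -> GeneSet:
    """Read a multi-FASTA of coding sequences into a :class:`GeneSet`.

    Parameters
    ----------
    path:
        Multi-record FASTA, one record per gene.
    labels:
        Optional TSV sidecar mapping gene_id to a free-text group label.
    genome_id:
        Identifier for the gene set; defaults to the file stem.
    ambiguous:
        How to treat IUPAC ambiguity codes other than N (see
        :func:`normalize_sequence`).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    label_map = read_group_labels(labels) if labels is not None else {}
    genes = [
        GeneRecord(
            gene_id=rec.id,
            sequence=normalize_sequence(str(rec.seq), ambiguous),
            group_label=label_map.get(rec.id),
        )
        for rec in records
    ]
    gs = GeneSet(genome_id or path.stem, genes)
    gs.validate()
    return gs


def write_gene_fasta(genes: GeneSet, path: str | Path) -> None:
    """Write a GeneSet as multi-FASTA; read(write(x)) round-trips exactly."""
    genes.validate()
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description="")
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def attach_labels(genes: GeneSet, label_map: dict[str, str]) -> GeneSet:
    """Return a copy with group labels joined by gene_id."""
    return GeneSet(
        genes.genome_id,
        [replace(g, group_label=label_map.get(g.gene_id, g.group_label))
         for g in genes],
    )
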