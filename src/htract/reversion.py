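"""Frameshift-reversion frequency estimation from plating experiments.

A selection assay grows cultures of a reporter strain in which a
slipped-strand event at a homopolymeric tract restores the reading frame
of an antibiotic-resistance fusion.  Appropriate dilutions are plated on
non-selective medium (total viable counts) and selective medium
(revertant counts).  Colonies on selective plates fall into two size
classes; large colonies (> 8 px in plate images) are mostly true
revertants and a subset is sequenced for confirmation, while small
colonies (< 9 px) are slow-growing non-revertants and are excluded.

Estimators (per replicate)::

    OCD = CFU * DF_total / VP          original cell density  [cells/ml]
    RD  = TC * (R / CS) * DF_sel / VP  revertant density      [revertants/ml]
    FR  = RD / OCD                     reversion frequency    [dimensionless]

where CFU is the mean colony count per non-selective plate, VP the
volume plated (ml), DF the dilution factors, TC the total large-colony
count on selective plates, CS the number of large colonies sequenced and
R the number confirmed as revertants.  The multi-replicate summary is
the arithmetic mean of replicate FRs.  When no revertant is confirmed in
any replicate, the detection limit is the frequency that a single
revertant colony among all cells effectively screened would have
implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PlatingExperiment",
    "ReversionEstimate",
    "LARGE_COLONY_MIN_PX",
    "classify_colonies",
    "original_cell_density",
    "revertant_density",
    "reversion_frequency",
    "summarize_replicates",
    "detection_limit",
    "fold_vs_reference",
    "read_plating_tsv",
    "write_plating_tsv",
]

#: smallest pixel size counted as a large colony (> 8 px rule)
LARGE_COLONY_MIN_PX = 9


@dataclass(frozen=True)
class PlatingExperiment:
    """Raw counts for one biological replicate of a plating assay."""

    replicate_id: str
    CFU: float          # mean colonies per non-selective plate
    DF_total: float     # dilution factor, non-selective plating
    VP: float           # volume plated, ml (same for both platings)
    TC: int             # total large colonies on selective plates
    CS: int             # large colonies sequenced
    R: int              # sequenced colonies confirmed as revertants
    DF_sel: float = 1.0  # dilution factor, selective plating
    colony_sizes: tuple[int, ...] = field(default_factory=tuple)  # px

    def __post_init__(self):
        if not 0 <= self.R <= self.CS <= self.TC:
            raise ValueError("require 0 <= R <= CS <= TC")
        if self.VP <= 0:
            raise ValueError("VP must be positive")
        if self.DF_total < 1 or self.DF_sel < 1:
            raise ValueError("dilution factors must be >= 1")


@dataclass(frozen=True)
class ReversionEstimate:
    replicate_id: str
    OCD: float                      # cells/ml of undiluted culture
    RD: float                       # confirmed revertants/ml
    FR: float                       # RD / OCD
    detection_limit: float | None   # set when R = 0


def classify_colonies(sizes) -> tuple[int, int]:
    """Partition pixel sizes into (large, small): >= 9 px is large."""
    sizes = np.asarray(list(sizes), dtype=float)
    if sizes.size and ((sizes < 0).any() or (sizes % 1 != 0).any()):
        raise ValueError("colony sizes must be non-negative integers (px)")
    large = int((sizes >= LARGE_COLONY_MIN_PX).sum())
    return large, int(sizes.size) - large


def original_cell_density(CFU: float, VP: float, DF: float) -> float:
    """OCD = CFU * DF / VP, in cells per ml of undiluted culture."""
    if VP <= 0:
        raise ValueError("VP must be positive")
    return CFU * DF / VP


def revertant_density(TC: int, CS: int, R: int, VP: float,
                      DF: float = 1.0) -> float:
    """RD = TC * (R/CS) * DF / VP: total large colonies scaled by the
    sequencing-confirmed revertant fraction."""
    if VP <= 0:
        raise ValueError("VP must be positive")
    if TC == 0:
        return 0.0
    if CS < 1:
        raise ValueError("TC > 0 requires CS >= 1 to estimate the "
                         "confirmed fraction")
    if R > CS:
        raise ValueError("R cannot exceed CS")
    return TC * (R / CS) * DF / VP


def _cells_screened(exp: PlatingExperiment) -> float:
    """Cells effectively subjected to selection in one replicate."""
    ocd = original_cell_density(exp.CFU, exp.VP, exp.DF_total)
    return ocd * exp.VP / exp.DF_sel


def reversion_frequency(exp: PlatingExperiment) -> ReversionEstimate:
    """Per-replicate FR = RD / OCD (with a one-colony detection limit
    attached when no revertant was confirmed)."""
    ocd = original_cell_density(exp.CFU, exp.VP, exp.DF_total)
    if ocd <= 0:
        raise ValueError("OCD must be positive (no viable-count colonies?)")
    rd = revertant_density(exp.TC, exp.CS, exp.R, exp.VP, exp.DF_sel)
    fr = rd / ocd
    limit = 1.0 / _cells_screened(exp) if exp.R == 0 else None
    return ReversionEstimate(exp.replicate_id, ocd, rd, fr, limit)


def summarize_replicates(exps: list[PlatingExperiment],
                         center: str = "mean") -> float:
    """Multi-replicate FR summary: arithmetic mean of replicate FRs
    (median exposed as an option)."""
    frs = [reversion_frequency(e).FR for e in exps]
    if center == "mean":
        return float(np.mean(frs))
    if center == "median":
        return float(np.median(frs))
    raise ValueError("center must be 'mean' or 'median'")


def detection_limit(exps: list[PlatingExperiment]) -> float:
    """Upper bound on FR when no replicate confirmed a revertant: the
    frequency one revertant colony among all pooled screened cells would
    have implied."""
    if not exps:
        raise ValueError("need at least one replicate")
    if any(e.R > 0 for e in exps):
        raise ValueError("detection limit is defined only when R = 0 "
                         "in every replicate")
    return 1.0 / sum(_cells_screened(e) for e in exps)


def fold_vs_reference(FR: float, reference_freq: float,
                      sig_figs: int | None = None) -> float:
    """FR over a reference frequency, optionally rounded to significant
    figures (e.g. comparing a tract reversion frequency with the average
    point-mutation frequency)."""
    if reference_freq <= 0:
        raise ValueError("reference frequency must be positive")
    fold = FR / reference_freq
    if sig_figs is not None:
        if fold == 0:
            return 0.0
        exponent = int(np.floor(np.log10(abs(fold))))
        factor = 10.0 ** (exponent - sig_figs + 1)
        fold = round(fold / factor) * factor
    return float(fold)


_PLATING_COLUMNS = ["replicate", "CFU", "DF_total", "VP", "DF_selective",
                    "TC", "CS", "R", "colony_sizes"]


def write_plating_tsv(exps: list[PlatingExperiment], path: str | Path) -> None:
    """Write replicates as TSV (colony sizes comma-joined)."""
    rows = [{
        "replicate": e.replicate_id, "CFU": e.CFU, "DF_total": e.DF_total,
        "VP": e.VP, "DF_selective": e.DF_sel, "TC": e.TC, "CS": e.CS,
        "R": e.R, "colony_sizes": ",".join(map(str, e.colony_sizes)),
    } for e in exps]
    pd.DataFrame(rows, columns=_PLATING_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_plating_tsv(path: str | Path) -> list[PlatingExperiment]:
    """Read the plating TSV schema written by :func:`write_plating_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"replicate": str,
                                            "colony_sizes": str})
    missing = [c for c in _PLATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plating TSV missing column(s): {missing}")
    exps = []
    for _, row in df.iterrows():
        sizes_field = row["colony_sizes"]
        sizes = tuple(
            int(s) for s in str(sizes_field).split(",") if s
        ) if pd.notna(sizes_field) and str(sizes_field) else ()
        exps.append(PlatingExperiment(
            replicate_id=str(row["replicate"]), CFU=float(row["CFU"]),
            DF_total=float(row["DF_total"]), VP=float(row["VP"]),
            DF_sel=float(row["DF_selective"]), TC=int(row["TC"]),
            CS=int(row["CS"]), R=int(row["R"]), colony_sizes=sizes,
        ))
    return exps
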