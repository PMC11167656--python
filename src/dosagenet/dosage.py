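"""Relative dosage scores from indel intervals and cis-effect neutralization.

In an irradiated-pollen indel population every line carries zero or more
large chromosomal deletions or insertions. A gene overlapped by a deletion
in a given line is present at roughly half dose, a gene overlapped by an
insertion at roughly 1.5x dose. This module turns per-line indel intervals
into a three-level relative dosage score (RDS) per (gene, line) —
0.5 (deleted), 1.0 (unaltered), 1.5 (inserted) — and can neutralize the
cis effect of dosage on expression by replacing affected values with the
mean over unaltered lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "IndelEvent",
    "DosageMap",
    "compute_gene_dosage",
    "indel_normalize_expression",
]

RDS_DELETION = 0.5
RDS_NEUTRAL = 1.0
RDS_INSERTION = 1.5


@dataclass(frozen=True)
class IndelEvent:
    """A large deletion or insertion carried by one line.

    Coordinates are 1-based inclusive (GFF convention).
    """

    line: str
    chromosome: str
    start: int
    end: int
    type: Literal["deletion", "insertion"]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"indel start {self.start} > end {self.end}")
        if self.type not in ("deletion", "insertion"):
            raise ValueError(f"unknown indel type {self.type!r}")

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        return (
            self.chromosome == chromosome
            and self.start <= end
            and start <= self.end
        )

    def contains(self, chromosome: str, start: int, end: int) -> bool:
        return (
            self.chromosome == chromosome
            and self.start <= start
            and end <= self.end
        )


class DosageMap:
    """Per (gene, line) relative dosage score.

    Backed by a dense genes x lines frame; every entry is one of
    {0.5, 1.0, 1.5}, defaulting to 1.0.
    """

    def __init__(self, rds: pd.DataFrame):
        values = rds.to_numpy()
        if not np.isin(values, [RDS_DELETION, RDS_NEUTRAL, RDS_INSERTION]).all():
            raise ValueError("RDS values must be in {0.5, 1.0, 1.5}")
        self.rds = rds

    @property
    def genes(self) -> pd.Index:
        return self.rds.index

    @property
    def lines(self) -> pd.Index:
        return self.rds.columns

    def get(self, gene: str, line: str) -> float:
        return float(self.rds.at[gene, line])

    def affected_genes(self) -> pd.Index:
        """Genes whose dosage differs from 1.0 in at least one line."""
        mask = (self.rds != RDS_NEUTRAL).any(axis=1)
        return self.rds.index[mask]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DosageMap):
            return NotImplemented
        return self.rds.equals(other.rds)


def compute_gene_dosage(
    annotation: pd.DataFrame,
    indels: Iterable[IndelEvent],
    lines: Iterable[str] | None = None,
    overlap_policy: Literal["any", "contained"] = "any",
) -> DosageMap:
    """Assign an RDS to every (gene, line) pair from indel intervals.

    Parameters
    ----------
    annotation
        Frame indexed by gene id with columns ``chromosome``, ``start``,
        ``end`` (1-based inclusive).
    indels
        Indel events; a line may carry several on different chromosomes.
    lines
        Lines to include as columns. Defaults to the lines appearing in
        ``indels`` — pass the full genotype list to also get all-1.0
        columns for lesion-free lines.
    overlap_policy
        ``"any"``: any positive overlap between gene and event interval
        confers the event's dosage. ``"contained"``: the gene must lie
        fully inside the event interval.

    Raises
    ------
    ValueError
        If a gene overlaps both a deletion and an insertion in the same
        line (dosage would be ill-defined beyond the three-level score).
    """
    indels = list(indels)
    if lines is None:
        line_index = pd.Index(sorted({e.line for e in indels}), name="line")
    else:
        line_index = pd.Index(list(lines), name="line")
    rds = pd.DataFrame(
        RDS_NEUTRAL, index=annotation.index.copy(), columns=line_index
    )
    hit = {"deletion": RDS_DELETION, "insertion": RDS_INSERTION}
    for event in indels:
        if event.line not in rds.columns:
            continue
        chrom_genes = annotation[annotation["chromosome"] == event.chromosome]
        for gene, row in chrom_genes.iterrows():
            if overlap_policy == "contained":
                match = event.contains(event.chromosome, row["start"], row["end"])
            else:
                match = event.overlaps(event.chromosome, row["start"], row["end"])
            if not match:
                continue
            current = rds.at[gene, event.line]
            new = hit[event.type]
            if current != RDS_NEUTRAL and current != new:
                raise ValueError(
                    f"gene {gene} overlapped by both a deletion and an "
                    f"insertion in line {event.line}: dosage conflict"
                )
            rds.at[gene, event.line] = new
    return DosageMap(rds)


def indel_normalize_expression(
    expression: pd.DataFrame,
    dosage_map: DosageMap,
    library_to_line: pd.Series | None = None,
    reference: Literal["non_indel", "all_other"] = "non_indel",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace cis-dosage-affected expression values with a reference mean.

    For every (gene, column) whose line has RDS != 1.0 at that gene, the
    expression value is replaced by the mean of that gene's values over
    reference lines, removing the cis effect of the indel while leaving
    trans signal in unaffected lines untouched.

    Parameters
    ----------
    expression
        Genes x columns frame. Columns are lines, or libraries when
        ``library_to_line`` maps each column to its line.
    dosage_map
        RDS per (gene, line); genes absent from the map are left unchanged.
    library_to_line
        Optional map column -> line for library-level matrices.
    reference
        ``"non_indel"`` (default) averages over columns whose line has
        RDS == 1.0 at the gene, so other indel lines cannot reintroduce a
        cis effect; ``"all_other"`` averages over every other column.

    Returns
    -------
    (normalized, log)
        A new frame, plus a replacement log with columns
        gene, column, line, rds, old, new.

    Raises
    ------
    ValueError
        If a gene has RDS != 1.0 in every line (no reference values).
    """
    if library_to_line is None:
        col_lines = pd.Series(expression.columns, index=expression.columns)
    else:
        missing = expression.columns.difference(library_to_line.index)
        if len(missing):
            raise ValueError(f"columns without a line mapping: {list(missing)}")
        col_lines = library_to_line.reindex(expression.columns)

    out = expression.copy()
    records: list[dict] = []
    shared_genes = expression.index.intersection(dosage_map.genes)
    for gene in shared_genes.intersection(dosage_map.affected_genes()):
        gene_rds = dosage_map.rds.loc[gene]
        col_rds = col_lines.map(gene_rds)
        affected = out.columns[(col_rds != RDS_NEUTRAL) & col_rds.notna()]
        if len(affected) == 0:
            continue
        if reference == "non_indel":
            ref_cols = out.columns[col_rds == RDS_NEUTRAL]
            if len(ref_cols) == 0:
                raise ValueError(
                    f"gene {gene} has no line with RDS 1.0; cannot normalize"
                )
            replacement = float(expression.loc[gene, ref_cols].mean())
            for col in affected:
                old = float(expression.at[gene, col])
                out.at[gene, col] = replacement
                records.append(
                    {
                        "gene": gene,
                        "column": col,
                        "line": col_lines[col],
                        "rds": float(col_rds[col]),
                        "old": old,
                        "new": replacement,
                    }
                )
        else:  # literal "all other lines" reading
            for col in affected:
                others = [c for c in out.columns if c != col]
                replacement = float(expression.loc[gene, others].mean())
                old = float(expression.at[gene, col])
                out.at[gene, col] = replacement
                records.append(
                    {
                        "gene": gene,
                        "column": col,
                        "line": col_lines[col],
                        "rds": float(col_rds[col]),
                        "old": old,
                        "new": replacement,
                    }
                )
    log = pd.DataFrame(
        records, columns=["gene", "column", "line", "rds", "old", "new"]
    )
    if reference == "all_other" and len(log):
        warnings.warn(
            "all_other reference averages over other indel lines and may "
            "retain part of the cis effect",
            stacklevel=2,
        )
    return out, log
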