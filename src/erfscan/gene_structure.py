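"""Intron counting and per-family structural summaries.

Reproduces the roster-level statistics: per-family gene counts, gene-length
and residue ranges, and intron-count histograms.  Intron count is simply
``#exons - 1`` of the (single) annotated isoform, strand-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_formats import GeneRecord

GLOBAL_LABEL = "ALL"


@dataclass
class FamilySummary:
    family: str
    n_genes: int
    min_length_bp: int
    max_length_bp: int
    min_residues: int
    max_residues: int
    intron_histogram: dict[int, int]

    def __post_init__(self) -> None:
        if sum(self.intron_histogram.values()) != self.n_genes:
            raise ValueError("intron histogram does not total n_genes")
        if self.min_length_bp > self.max_length_bp:
            raise ValueError("min length > max length")


def count_introns(gene: GeneRecord) -> int:
    """Number of introns = number of exons − 1."""
    if not gene.exons:
        raise ValueError(f"{gene.gene_id}: no exons annotated")
    return len(gene.exons) - 1


def _summary(family: str, sub: pd.DataFrame) -> FamilySummary:
    hist = sub["n_introns"].value_counts().sort_index()
    return FamilySummary(
        family=family,
        n_genes=len(sub),
        min_length_bp=int(sub["gene_length_bp"].min()),
        max_length_bp=int(sub["gene_length_bp"].max()),
        min_residues=int(sub["n_residues"].min()),
        max_residues=int(sub["n_residues"].max()),
        intron_histogram={int(k): int(v) for k, v in hist.items()},
    )


def summarize_families(roster: pd.DataFrame) -> list[FamilySummary]:
    """One :class:`FamilySummary` per classification label, plus a global
    summary labelled :data:`GLOBAL_LABEL`."""
    if roster.empty:
        raise ValueError("empty roster")
    out = [
        _summary(label, sub)
        for label, sub in roster.groupby("classification", sort=True)
    ]
    out.append(_summary(GLOBAL_LABEL, roster))
    return out


def summaries_frame(summaries: list[FamilySummary]) -> pd.DataFrame:
    """Tabular view of summaries (histogram rendered as ``k:n`` pairs)."""
    return pd.DataFrame(
        {
            "family": s.family,
            "n_genes": s.n_genes,
            "min_length_bp": s.min_length_bp,
            "max_length_bp": s.max_length_bp,
            "min_residues": s.min_residues,
            "max_residues": s.max_residues,
            "introns": ",".join(
                f"{k}:{v}" for k, v in sorted(s.intron_histogram.items())
            ),
        }
        for s in summaries
    )
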