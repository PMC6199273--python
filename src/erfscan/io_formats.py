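"""Readers and writers for every external representation the pipeline touches.

Protein FASTA (Biopython), gene models in GFF3 (gffutils), the packaged
roster transcription, tabular hit/expression/Cq files (pandas TSV) and
newick trees (scikit-bio containers, local serializer for controlled
branch-length formatting).

Coordinates are 1-based inclusive throughout, matching GFF3 and the
convention in which a gene's length in bp is ``end - start + 1``.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode


class FormatError(ValueError):
    """A file violates the format contract (duplicate ids, bad bounds, ...)."""


#: Classification labels admitted in roster files, as printed in the source
#: summary table.
ROSTER_CLASSIFICATIONS = (
    "RAV family",
    "AP2 family",
    "ERF subfamily",
    "DREB Subfamily",
    "Soloist",
)


@dataclass
class GeneRecord:
    """One gene model: coordinates, exon chain and (optionally) its protein.

    ``exons`` are (start, end) pairs, 1-based inclusive, sorted and
    non-overlapping.  ``protein_seq`` may be empty for records built from
    annotation alone; attach the translation later if needed.
    """

    gene_id: str
    seq_region: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    protein_seq: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"{self.gene_id}: end < start")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if e < s:
                raise FormatError(f"{self.gene_id}: exon end < start")
            if s < self.start or e > self.end:
                raise FormatError(
                    f"{self.gene_id}: exon ({s},{e}) outside gene span "
                    f"({self.start},{self.end})"
                )
            if prev_end is not None and s <= prev_end:
                raise FormatError(f"{self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def gene_length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def n_residues(self) -> int:
        return len(self.protein_seq)


@dataclass(frozen=True)
class DomainHit:
    """A located domain on a protein, hmmscan-table shaped."""

    protein_id: str
    domain_name: str  # "AP2", "B3" or other
    start: int  # 1-based inclusive residue positions
    end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise FormatError(f"{self.protein_id}: domain end < start")
        if self.e_value < 0:
            raise FormatError(f"{self.protein_id}: negative E-value")


@dataclass(frozen=True)
class TabularHit:
    """A BLAST-style pairwise hit."""

    query_id: str
    subject_id: str
    bit_score: float
    e_value: float
    percent_match: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_match <= 100.0:
            raise FormatError("percent_match outside [0, 100]")
        if self.e_value < 0:
            raise FormatError("negative E-value")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA into (id, uppercased sequence) pairs.

    Order is preserved.  Duplicate ids raise :class:`FormatError`; an empty
    file returns ``[]`` with a warning.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"{path}: no FASTA records", stacklevel=2)
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(path: str | Path) -> list[GeneRecord]:
    """Read gene/mRNA/exon features from GFF3 into :class:`GeneRecord`\\ s.

    Exons are grouped under their gene via Parent attributes.  When a gene
    carries several isoforms, the one with the longest summed exon span is
    kept (one model per locus in practice).  An exon outside its gene's span
    raises :class:`FormatError`.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[GeneRecord] = []
    for gene in db.features_of_type("gene", order_by="start"):
        best_exons: list[tuple[int, int]] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = [(e.start, e.end) for e in db.children(mrna, featuretype="exon")]
            if sum(e - s + 1 for s, e in exons) > sum(e - s + 1 for s, e in best_exons):
                best_exons = exons
        if not best_exons:  # exons attached directly to the gene
            best_exons = [(e.start, e.end) for e in db.children(gene, featuretype="exon")]
        for s, e in best_exons:
            if s < gene.start or e > gene.end:
                raise FormatError(
                    f"{gene.id}: exon ({s},{e}) outside gene span "
                    f"({gene.start},{gene.end})"
                )
        out.append(
            GeneRecord(
                gene_id=gene.id,
                seq_region=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                exons=sorted(best_exons),
            )
        )
    return out


def _roster_frame(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    required = [
        "classification",
        "gene_name",
        "gene_id",
        "gene_length_bp",
        "n_residues",
        "n_introns",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{origin}: missing roster columns {missing}")
    bad = set(df["classification"]) - set(ROSTER_CLASSIFICATIONS)
    if bad:
        raise FormatError(f"{origin}: unknown classification labels {sorted(bad)}")
    return df[required].reset_index(drop=True)


def read_roster(path: str | Path) -> pd.DataFrame:
    """Read a roster TSV (classification, name, id, length, residues, introns).

    Lines starting with ``#`` are comments.  Classification labels outside
    :data:`ROSTER_CLASSIFICATIONS` raise :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    return _roster_frame(df, str(path))


def packaged_roster() -> pd.DataFrame:
    """The bundled 119-gene jujube AP2/ERF superfamily roster."""
    with resources.as_file(
        resources.files("erfscan.data").joinpath("table1_roster.tsv")
    ) as p:
        return read_roster(p)


def packaged_motif_table() -> pd.DataFrame:
    """The bundled ERF/DREB conserved-motif consensus table."""
    with resources.as_file(
        resources.files("erfscan.data").joinpath("table2_motifs.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t", comment="#", keep_default_na=False)


def _fmt_length(x: float | None) -> str:
    if x is None:
        return ""
    return f":{float(f'{x:.6g}'):g}"


def _newick_node(node: TreeNode) -> str:
    if node.is_tip():
        return f"{node.name or ''}{_fmt_length(node.length)}"
    inner = ",".join(_newick_node(c) for c in node.children)
    return f"({inner}){node.name or ''}{_fmt_length(node.length)}"


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to newick with branch lengths at 6 significant digits."""
    n_nodes = sum(1 for _ in tree.traverse())
    if n_nodes > 4 * max(1, tree.count(tips=True)):  # defensive: malformed graph
        raise FormatError("tree structure is not a tree")
    return _newick_node(tree) + ";"


def read_newick(text_or_path: str | Path) -> TreeNode:
    """Parse newick from a string or a file path into a skbio TreeNode."""
    s = str(text_or_path)
    if s.strip().endswith(";"):
        return TreeNode.read(io.StringIO(s), format="newick")
    return TreeNode.read(s, format="newick")


def read_hits_tsv(path: str | Path) -> list[TabularHit]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        TabularHit(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            bit_score=float(r.bit_score),
            e_value=float(r.e_value),
            percent_match=float(r.percent_match),
        )
        for r in df.itertuples()
    ]


def read_domain_hits_tsv(path: str | Path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        DomainHit(
            protein_id=str(r.protein_id),
            domain_name=str(r.domain_name),
            start=int(r.start),
            end=int(r.end),
            e_value=float(r.e_value),
            bit_score=float(r.bit_score),
        )
        for r in df.itertuples()
    ]
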