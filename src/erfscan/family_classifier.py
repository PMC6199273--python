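"""Family and subfamily assignment from domain architecture.

The superfamily splits on domain content: AP2 + B3 -> RAV; two or more AP2
domains (or a curated override, standing in for a phylogeny-based rescue of
single-domain members) -> AP2 family; a curated soloist id, or high identity
to the soloist reference -> soloist; a single AP2 domain -> ERF family,
which is further divided into ERF and DREB subfamilies by diagnostic
residues read through a global alignment onto a reference AP2-domain frame
(Ala/Asp for ERF, Val/Glu for DREB).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import config
from ._align import fraction_identical_aligned, global_align
from .io_formats import DomainHit, TabularHit


@dataclass
class FamilyAssignment:
    gene_id: str
    family: str  # RAV | AP2 | ERF | soloist | rejected
    subfamily: str = "none"  # ERF | DREB | none | unresolved
    n_ap2_domains: int = 0
    has_b3: bool = False
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.family != "ERF" and self.subfamily not in ("none",):
            raise ValueError("subfamily is defined only for the ERF family")
        if (self.family == "rejected") != (self.n_ap2_domains == 0):
            raise ValueError("rejected iff no AP2 domain")


@dataclass(frozen=True)
class DiagnosticRule:
    """Expected residues at two positions of the reference domain frame."""

    positions: tuple[int, int]
    residues: tuple[str, str]

    def __post_init__(self) -> None:
        if not self.positions[0] < self.positions[1]:
            raise ValueError("diagnostic positions must be increasing")
        valid = set("ACDEFGHIKLMNPQRSTVWY")
        if not set(self.residues) <= valid:
            raise ValueError("diagnostic residues must be amino acids")


@dataclass(frozen=True)
class DiagnosticResidues:
    """The ERF-vs-DREB residue rules, configurable per alignment frame."""

    erf: DiagnosticRule = DiagnosticRule(
        tuple(config.DIAGNOSTICS_DEFAULT["erf"]["positions"]),
        tuple(config.DIAGNOSTICS_DEFAULT["erf"]["residues"]),
    )
    dreb: DiagnosticRule = DiagnosticRule(
        tuple(config.DIAGNOSTICS_DEFAULT["dreb"]["positions"]),
        tuple(config.DIAGNOSTICS_DEFAULT["dreb"]["residues"]),
    )


def filter_blast_hits(
    hits: list[TabularHit],
    min_bits: float = config.MIN_BIT_SCORE,
    max_e: float = config.MAX_EVALUE,
) -> list[TabularHit]:
    """Keep hits with bit score strictly > ``min_bits`` and E-value strictly
    < ``max_e``; input order is preserved."""
    for h in hits:
        if h.e_value < 0:
            raise ValueError(f"{h.query_id}: negative E-value")
    return [h for h in hits if h.bit_score > min_bits and h.e_value < max_e]


def classify_family(
    domain_hits: list[DomainHit],
    gene_id: str | None = None,
    soloist_ids: frozenset[str] | set[str] = frozenset(),
    ap2_override_ids: frozenset[str] | set[str] = frozenset(),
) -> FamilyAssignment:
    """Assign one protein to RAV / AP2 / ERF / soloist from its domain hits.

    Decision order: no AP2 domain -> rejected; curated soloist -> soloist;
    AP2 + B3 -> RAV; >=2 AP2 domains or curated override -> AP2; else ERF.
    All hits must belong to a single protein.
    """
    ids = {h.protein_id for h in domain_hits}
    if len(ids) > 1:
        raise ValueError(f"hits for multiple proteins: {sorted(ids)}")
    if gene_id is None:
        if not ids:
            raise ValueError("no hits and no gene_id given")
        gene_id = next(iter(ids))
    elif ids and ids != {gene_id}:
        raise ValueError(f"hits belong to {ids}, not {gene_id!r}")

    n_ap2 = sum(h.domain_name == "AP2" for h in domain_hits)
    has_b3 = any(h.domain_name == "B3" for h in domain_hits)
    ev = [f"{n_ap2} AP2 domain(s)"] + (["B3 domain present"] if has_b3 else [])

    if n_ap2 == 0:
        return FamilyAssignment(gene_id, "rejected", evidence=ev + ["no AP2 domain"])
    if gene_id in soloist_ids:
        return FamilyAssignment(
            gene_id, "soloist", n_ap2_domains=n_ap2, has_b3=has_b3,
            evidence=ev + ["curated soloist id"],
        )
    if has_b3:
        return FamilyAssignment(
            gene_id, "RAV", n_ap2_domains=n_ap2, has_b3=True,
            evidence=ev + ["AP2 + B3 architecture"],
        )
    if n_ap2 >= 2 or gene_id in ap2_override_ids:
        why = "repeated AP2 domains" if n_ap2 >= 2 else "phylogeny override"
        return FamilyAssignment(
            gene_id, "AP2", n_ap2_domains=n_ap2, evidence=ev + [why]
        )
    return FamilyAssignment(
        gene_id, "ERF", n_ap2_domains=n_ap2, evidence=ev + ["single AP2 domain"]
    )


def align_to_reference(domain_seq: str, reference_domain: str) -> dict[int, str | None]:
    """Map each 1-based reference position to the aligned query residue.

    Positions the query does not cover (deletions) map to ``None``.
    """
    if not domain_seq or not reference_domain:
        raise ValueError("empty sequence")
    # reference first so its coordinates index the alignment rows
    gref, gquery = global_align(reference_domain, domain_seq)
    mapping: dict[int, str | None] = {}
    ref_pos = 0
    for r, q in zip(gref, gquery):
        if r != "-":
            ref_pos += 1
            mapping[ref_pos] = None if q == "-" else q
    return mapping


def discriminate_subfamily(
    domain_seq: str,
    reference_domain: str,
    diag: DiagnosticResidues | None = None,
    min_coverage: float = config.MIN_ALIGNMENT_COVERAGE,
) -> str:
    """Call ERF vs DREB from the diagnostic residues; ties -> ``unresolved``.

    The domain must align to the reference with at least ``min_coverage`` of
    reference positions matched by a residue, otherwise a ValueError is
    raised (the call would not be reading a homologous frame).
    """
    diag = diag or DiagnosticResidues()
    mapping = align_to_reference(domain_seq, reference_domain)
    covered = sum(v is not None for v in mapping.values()) / len(mapping)
    if covered < min_coverage:
        raise ValueError(
            f"alignment covers only {covered:.0%} of the reference frame"
        )

    def rule_fires(rule: DiagnosticRule) -> bool:
        return all(
            mapping.get(pos) == res
            for pos, res in zip(rule.positions, rule.residues)
        )

    erf, dreb = rule_fires(diag.erf), rule_fires(diag.dreb)
    if erf and not dreb:
        return "ERF"
    if dreb and not erf:
        return "DREB"
    return "unresolved"


def assign_soloist_by_reference(
    protein_seq: str,
    reference_soloist_seq: str,
    min_identity: float = config.MIN_SOLOIST_IDENTITY,
) -> bool:
    """True iff global identity to the soloist reference is >= ``min_identity``."""
    if not protein_seq or not reference_soloist_seq:
        raise ValueError("empty sequence")
    ga, gb = global_align(protein_seq, reference_soloist_seq)
    identity = sum(x == y for x, y in zip(ga, gb)) / len(ga)
    return identity >= min_identity


def derive_ap2_overrides(tree, family_map: dict[str, str], k: int = 3) -> set[str]:
    """Single-AP2-domain genes rescued into the AP2 family by tree context.

    A gene currently called ERF whose ``k`` nearest leaves are majority AP2
    is flagged for override — the in-silico analogue of reassigning
    single-domain members that sit inside the AP2 clade.
    """
    from .phylogeny import nearest_leaf_families

    overrides = set()
    for leaf in tree.tips():
        name = leaf.name
        if family_map.get(name) != "ERF":
            continue
        if nearest_leaf_families(tree, name, k=k, family_map=family_map) == "AP2":
            overrides.add(name)
    return overrides
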