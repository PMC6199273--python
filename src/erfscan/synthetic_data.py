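"""Seeded generators for every fixture the pipeline's tests exercise.

The generators emulate the study conditions, never real jujube data:

* ``gen_proteome`` — proteins with implanted AP2/B3 domain blocks (copied
  from bundled synthetic reference blocks with seeded point mutations) and
  EAR / zinc-finger motifs at recorded positions;
* ``gen_dup_layout`` (fixture ``F-dup``) — a gene-order map with 18 planted
  paralog pairs: 5 tandem (0–4 intervening loci on a shared linkage group)
  and 13 segmental (farther apart or on different groups);
* ``gen_expression`` (fixture ``F-expr119``) — a 119-gene x 3-tissue RPKM
  matrix with exactly 85 genes expressed somewhere, exactly 2 of them
  fruit-specific, and four planted expression clades;
* ``gen_ripening`` (fixture ``F-ripen``) — 44 fruit-expressed genes with
  planted five-stage trajectories (15 up, 23 down, 6 flat), ethylene qPCR
  responses (6 up, 16 down) and EAR flags, such that the screen yields
  exactly 2 activators and 2 repressors.

Counts that mirror the published tallies are planted BY CONSTRUCTION; runs
on these fixtures verify the pipeline's rule engines, not the biology.
All generators are deterministic under a fixed seed; noise defaults to
zero (the deterministic mode used for acceptance runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .io_formats import DomainHit, packaged_roster
from .motif_scan import scan_ear, scan_zinc_finger

#: Background alphabet excludes C and D so that random background can never
#: form an EAR (needs D) or zinc-finger (needs C) motif by accident.
BACKGROUND_ALPHABET = "AEFGHIKLMNPQRSTVWY"

#: Synthetic 60-residue AP2-domain reference block (ERF-type frame):
#: Ala at position 33 and Asp at position 43, the ERF-subfamily diagnostic
#: residues; positions 21/26 deliberately non-DREB (Ile/Arg).  Composed for
#: this package — not a database sequence.
REFERENCE_AP2_DOMAIN = (
    "MYRGVRQRPWGKYAAEIRDP" "IRNGARVWLG" "TFATAEEAAR" "AYDRAAFGAK" "FSLENFPAAE"
)

#: DREB-type variant of the same frame: Val-21 and Glu-26, with the ERF
#: diagnostics (33/43) replaced.
DREB_AP2_DOMAIN = (
    "MYRGVRQRPWGKYAAEIRDP" "VRNGAEVWLG" "TFSTAEEAAR" "AYNRAAFGAK" "FSLENFPAAE"
)

#: Synthetic B3 domain block (stand-in; only its located hit matters).
REFERENCE_B3_DOMAIN = "GSSKYLRLSLQWNKFVEENGLKEGGSVTLWSFRNNGVLGFAL"

#: Synthetic soloist reference protein (stand-in for the At4g13040 homology
#: anchor; constructed, not a database sequence).
REFERENCE_SOLOIST = "".join(
    BACKGROUND_ALPHABET[(i * 7 + i // 9) % len(BACKGROUND_ALPHABET)] for i in range(110)
)

EAR_INSERT = "LDLNL"
ZNF_INSERT = "CAACAAAACAAC"

#: Positions (1-based, within the domain frame) never touched by mutation.
_PROTECTED_DOMAIN_POSITIONS = (21, 26, 33, 43)


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one fixture; same spec -> same bytes."""

    name: str
    seed: int
    parameters: dict[str, Any] = field(default_factory=dict)


def _background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BACKGROUND_ALPHABET), size=n))


def _mutate_block(rng: np.random.Generator, block: str, n_mut: int,
                  protected: tuple[int, ...] = ()) -> str:
    """Seeded point mutations drawn from the background alphabet."""
    seq = list(block)
    candidates = [i for i in range(len(seq)) if (i + 1) not in protected]
    for i in rng.choice(candidates, size=min(n_mut, len(candidates)), replace=False):
        choices = [c for c in BACKGROUND_ALPHABET if c != seq[i]]
        seq[i] = rng.choice(choices)
    return "".join(seq)


# ---------------------------------------------------------------------------
# proteome fixture
# ---------------------------------------------------------------------------

@dataclass
class ProteomeFixture:
    spec: FixtureSpec
    records: list[tuple[str, str]]
    domain_hits: list[DomainHit]
    truth: pd.DataFrame  # gene_id, family, subfamily, n_ear, n_znf, flags


DEFAULT_PROTEOME_PARAMS: dict[str, Any] = {
    "families": {"RAV": 2, "AP2": 3, "ERF": 5, "DREB": 4, "soloist": 1},
    "n_ap2_single": 1,  # AP2-family members with a single domain (override set)
    "n_ear": 2,  # ERF members carrying an EAR motif
    "n_znf": 1,  # ERF members carrying a zinc-finger motif
    "n_mutations": 2,  # point mutations per implanted domain block
    "flank": (30, 60),  # background flank length range
}


def gen_proteome(spec: FixtureSpec | None = None) -> ProteomeFixture:
    """Proteins with implanted domains and motifs, plus the truth table.

    Planted motif positions are re-verified with the scanners before
    returning, so the background is guaranteed motif-free.
    """
    spec = spec or FixtureSpec("F-proteome", seed=1)
    params = {**DEFAULT_PROTEOME_PARAMS, **spec.parameters}
    rng = np.random.default_rng(spec.seed)
    records: list[tuple[str, str]] = []
    hits: list[DomainHit] = []
    rows = []

    def flank(lo_hi=params["flank"]) -> str:
        return _background(rng, int(rng.integers(*lo_hi)))

    def add_protein(gene_id: str, family: str, subfamily: str, blocks: list[str],
                    ear: int = 0, znf: int = 0, override: bool = False,
                    soloist: bool = False) -> None:
        parts = [flank()]
        domain_spans = []
        for block in blocks:
            name = "B3" if block is REFERENCE_B3_DOMAIN else "AP2"
            mutated = _mutate_block(
                rng, block, params["n_mutations"], _PROTECTED_DOMAIN_POSITIONS
            ) if name == "AP2" else block
            start = sum(len(p) for p in parts) + 1
            parts.append(mutated)
            domain_spans.append((name, start, start + len(mutated) - 1))
            parts.append(flank())
        for _ in range(ear):
            start = sum(len(p) for p in parts) + 1
            parts.append(EAR_INSERT)
            parts.append(flank())
        for _ in range(znf):
            parts.append(ZNF_INSERT)
            parts.append(flank())
        seq = "".join(parts)
        records.append((gene_id, seq))
        for name, s, e in domain_spans:
            hits.append(DomainHit(gene_id, name, s, e,
                                  e_value=10.0 ** -int(rng.integers(20, 60)),
                                  bit_score=float(rng.integers(80, 300))))
        n_ear_found = len(scan_ear(seq, gene_id))
        n_znf_found = len(scan_zinc_finger(seq, gene_id))
        if n_ear_found != ear or n_znf_found != znf:
            raise RuntimeError(
                f"{gene_id}: planted {ear} EAR/{znf} ZnF, scanners found "
                f"{n_ear_found}/{n_znf_found}"
            )
        rows.append({
            "gene_id": gene_id, "family": family, "subfamily": subfamily,
            "n_ear": ear, "n_znf": znf, "is_override": override,
            "is_soloist": soloist,
        })

    fams = params["families"]
    for i in range(fams.get("RAV", 0)):
        add_protein(f"SYN_RAV{i+1}", "RAV", "none",
                    [REFERENCE_AP2_DOMAIN, REFERENCE_B3_DOMAIN])
    n_single = params["n_ap2_single"]
    for i in range(fams.get("AP2", 0)):
        single = i < n_single
        add_protein(f"SYN_AP2_{i+1}", "AP2", "none",
                    [REFERENCE_AP2_DOMAIN] * (1 if single else 2),
                    override=single)
    ear_left, znf_left = params["n_ear"], params["n_znf"]
    for i in range(fams.get("ERF", 0)):
        ear = 1 if ear_left > 0 else 0
        znf = 1 if ear == 0 and znf_left > 0 else 0
        ear_left -= ear
        znf_left -= znf
        add_protein(f"SYN_ERF{i+1}", "ERF", "ERF", [REFERENCE_AP2_DOMAIN],
                    ear=ear, znf=znf)
    for i in range(fams.get("DREB", 0)):
        add_protein(f"SYN_DREB{i+1}", "ERF", "DREB", [DREB_AP2_DOMAIN])
    for i in range(fams.get("soloist", 0)):
        gene_id = f"SYN_SOLOIST{i+1}"
        mutated_core = _mutate_block(rng, REFERENCE_SOLOIST, 5)
        seq = mutated_core + REFERENCE_AP2_DOMAIN
        records.append((gene_id, seq))
        hits.append(DomainHit(gene_id, "AP2", len(mutated_core) + 1,
                              len(seq), 1e-25, 120.0))
        rows.append({
            "gene_id": gene_id, "family": "soloist", "subfamily": "none",
            "n_ear": 0, "n_znf": 0, "is_override": False, "is_soloist": True,
        })

    return ProteomeFixture(spec, records, hits, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# duplication fixture (F-dup)
# ---------------------------------------------------------------------------

@dataclass
class DupFixture:
    spec: FixtureSpec
    gene_order: dict[str, list[str]]  # region -> ordered locus ids
    proteome: dict[str, str]
    pairs: pd.DataFrame  # gene_a, gene_b, spacing, expected_type


#: (kind, region_a, region_b_or_None, intervening loci) for the 18 pairs:
#: 5 tandem (spacings 0..4, covering the "four or fewer" boundary),
#: 8 same-region segmental (spacing 5 probes the rule's complement),
#: 5 cross-region segmental.
DEFAULT_DUP_LAYOUT = [
    ("tandem", "LG01", None, 0),
    ("tandem", "LG01", None, 1),
    ("tandem", "LG04", None, 2),
    ("tandem", "LG06", None, 3),
    ("tandem", "LG07", None, 4),
    ("segmental", "LG02", None, 5),
    ("segmental", "LG03", None, 6),
    ("segmental", "LG05", None, 7),
    ("segmental", "LG08", None, 9),
    ("segmental", "LG09", None, 11),
    ("segmental", "LG10", None, 14),
    ("segmental", "LG11", None, 17),
    ("segmental", "LG12", None, 21),
    ("segmental", "LG01", "LG02", None),
    ("segmental", "LG03", "LG04", None),
    ("segmental", "LG05", "LG06", None),
    ("segmental", "LG07", "LG08", None),
    ("segmental", "LG09", "LG10", None),
]

DEFAULT_DUP_PARAMS: dict[str, Any] = {
    "layout": DEFAULT_DUP_LAYOUT,
    "protein_length": 120,
    "mutation_range": (12, 36),  # per-pair mutated positions -> 70-90% similarity
}


def gen_dup_layout(spec: FixtureSpec | None = None) -> DupFixture:
    """Fixture F-dup: 18 planted paralog pairs on a 12-linkage-group map."""
    spec = spec or FixtureSpec("F-dup", seed=1)
    params = {**DEFAULT_DUP_PARAMS, **spec.parameters}
    rng = np.random.default_rng(spec.seed)
    regions: dict[str, list[str]] = {f"LG{i:02d}": [] for i in range(1, 13)}
    filler_count = 0

    def filler(region: str, n: int) -> None:
        nonlocal filler_count
        for _ in range(n):
            filler_count += 1
            regions[region].append(f"LOC{filler_count:04d}")

    proteome: dict[str, str] = {}
    rows = []
    L = params["protein_length"]
    for idx, (kind, ra, rb, spacing) in enumerate(params["layout"], start=1):
        a, b = f"DUPA{idx:02d}", f"DUPB{idx:02d}"
        base = _background(rng, L)
        n_mut = int(rng.integers(*params["mutation_range"]))
        proteome[a] = base
        proteome[b] = _mutate_block(rng, base, n_mut)
        if rb is None:
            filler(ra, int(rng.integers(1, 4)))
            regions[ra].append(a)
            filler(ra, spacing)
            regions[ra].append(b)
            filler(ra, int(rng.integers(1, 4)))
        else:
            filler(ra, int(rng.integers(1, 4)))
            regions[ra].append(a)
            filler(rb, int(rng.integers(1, 4)))
            regions[rb].append(b)
        rows.append({
            "gene_a": a, "gene_b": b, "region_a": ra,
            "region_b": rb or ra, "spacing": spacing,
            "expected_type": kind,
        })
    return DupFixture(spec, regions, proteome, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# tissue expression fixture (F-expr119)
# ---------------------------------------------------------------------------

@dataclass
class ExpressionFixture:
    spec: FixtureSpec
    values: pd.DataFrame  # genes x samples (RPKM)
    design: pd.DataFrame  # sample -> tissue, replicate
    truth: pd.DataFrame  # gene_id, clade, expressed, specific
    similarity_cut: float  # cut recovering the planted clades in noise-free mode


TISSUES = ("leaf", "flower", "fruit")

#: Planted mean profiles (leaf, flower, fruit) per clade; scaling a profile
#: per gene leaves within-clade correlation at exactly 1 in noise-free mode.
CLADE_PROFILES = {
    "I": (1.5, 2.5, 25.0),  # fruit-dominant
    "I-fruit-specific": (0.2, 0.3, 30.0),
    "II": (18.0, 3.0, 0.6),  # leaf-dominant
    "III": (4.0, 9.0, 0.4),  # flower > leaf, silent in fruit
    "IV": (1.6, 22.0, 0.4),  # flower-dominant
    "IV-flower-specific": (0.3, 22.0, 0.4),
}

DEFAULT_EXPR_PARAMS: dict[str, Any] = {
    "clade_sizes": {"I": 8, "II": 12, "III": 17, "IV": 48},  # 85 expressed
    "n_fruit_specific": 2,
    "n_flower_specific": 17,
    "noise_sd": 0.0,  # multiplicative log-normal noise; 0 = deterministic mode
    "scale_range": (0.8, 1.25),
    "similarity_cut": 0.99,
}


def gen_expression(spec: FixtureSpec | None = None) -> ExpressionFixture:
    """Fixture F-expr119: 119 genes x 3 tissues with planted structure.

    Exactly 85 genes have at least one tissue mean >= 1.0 RPKM (the other
    34 stay below the gate everywhere), exactly 2 are fruit-specific, and
    the expressed genes fall into four clades whose within-clade profiles
    are exact scalings of each other in noise-free mode.
    """
    spec = spec or FixtureSpec("F-expr119", seed=1)
    params = {**DEFAULT_EXPR_PARAMS, **spec.parameters}
    rng = np.random.default_rng(spec.seed)
    roster = packaged_roster()
    genes = roster["gene_name"].tolist()

    sizes = params["clade_sizes"]
    fruit_specific = ["ZjDREB12", "ZjDREB17"][: params["n_fruit_specific"]]
    pool = [g for g in genes if g not in fruit_specific]
    assignments: dict[str, tuple[str, str]] = {}  # gene -> (clade, profile key)
    for g in fruit_specific:
        assignments[g] = ("I", "I-fruit-specific")
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = pool[cursor : cursor + n]
        cursor += n
        return out

    for g in take(sizes["I"] - len(fruit_specific)):
        assignments[g] = ("I", "I")
    for g in take(sizes["II"]):
        assignments[g] = ("II", "II")
    for g in take(sizes["III"]):
        assignments[g] = ("III", "III")
    n_fs = params["n_flower_specific"]
    for i, g in enumerate(take(sizes["IV"])):
        assignments[g] = ("IV", "IV-flower-specific" if i < n_fs else "IV")
    # the rest stay silent everywhere

    values = np.zeros((len(genes), len(TISSUES)))
    rows = []
    for i, g in enumerate(genes):
        if g in assignments:
            clade, key = assignments[g]
            scale = rng.uniform(*params["scale_range"])
            profile = np.array(CLADE_PROFILES[key]) * scale
        else:
            clade = "silent"
            profile = rng.uniform(0.0, 0.8, size=len(TISSUES))
        if params["noise_sd"] > 0:
            profile = profile * np.exp(
                rng.normal(0.0, params["noise_sd"], size=len(TISSUES))
            )
        values[i] = profile
        expressed_in = [t for t, v in zip(TISSUES, profile) if v >= 1.0]
        rows.append({
            "gene_id": g,
            "clade": clade,
            "expressed": bool(expressed_in),
            "specific": expressed_in[0] if len(expressed_in) == 1 else "",
        })
    vdf = pd.DataFrame(values, index=genes, columns=list(TISSUES))
    design = pd.DataFrame(
        {"tissue": list(TISSUES), "replicate": [1] * len(TISSUES)},
        index=list(TISSUES),
    )
    return ExpressionFixture(
        spec, vdf, design, pd.DataFrame(rows), params["similarity_cut"]
    )


# ---------------------------------------------------------------------------
# ripening / ethylene fixture (F-ripen)
# ---------------------------------------------------------------------------

@dataclass
class RipeningFixture:
    spec: FixtureSpec
    stage_profiles: pd.DataFrame  # genes x (YF, WM, BR, HR, FR)
    qpcr: pd.DataFrame  # gene, group, replicate, cq_target, cq_reference
    ear_flags: dict[str, bool]
    truth: pd.DataFrame  # gene, ripening, ethylene, has_ear, expected_verdict


RIPENING_UP = [
    "ZjAP2.1", "ZjAP2.4", "ZjAP2.5", "ZjERF11", "ZjERF23", "ZjERF24",
    "ZjERF27", "ZjERF28", "ZjERF35", "ZjERF37", "ZjERF42", "ZjERF53",
    "ZjERF54", "ZjDREB1", "ZjDREB39",
]
RIPENING_DOWN = [
    "ZjRAV1", "ZjRAV5", "ZjAP2.14", "ZjERF8", "ZjERF13", "ZjERF21",
    "ZjERF25", "ZjERF26", "ZjERF33", "ZjERF36", "ZjERF44", "ZjERF45",
    "ZjDREB2", "ZjDREB12", "ZjDREB17", "ZjDREB18", "ZjDREB22", "ZjDREB26",
    "ZjDREB27", "ZjDREB31", "ZjDREB32", "ZjDREB34", "ZjDREB36",
]
RIPENING_FLAT = ["ZjERF5", "ZjERF9", "ZjERF12", "ZjDREB21", "ZjDREB23", "ZjDREB24"]

ETHYLENE_UP = ["ZjERF54", "ZjDREB39", "ZjRAV5", "ZjERF21", "ZjERF33", "ZjERF5"]
ETHYLENE_DOWN = [
    "ZjAP2.1", "ZjAP2.4", "ZjAP2.5", "ZjERF53", "ZjAP2.14", "ZjERF25",
    "ZjERF36", "ZjDREB18", "ZjDREB22", "ZjDREB26", "ZjDREB27", "ZjDREB31",
    "ZjDREB34", "ZjERF9", "ZjERF12", "ZjDREB21",
]
#: EAR-motif carriers among the fruit-expressed genes.
EAR_GENES = ["ZjERF21", "ZjERF23", "ZjERF24", "ZjERF25", "ZjERF36"]

_TRAJECTORIES = {
    "up": (1.0, 1.0, 2.0, 4.0, 8.0),
    "down": (8.0, 6.0, 3.0, 1.5, 1.0),
    "none": (3.0, 3.0, 3.0, 3.0, 3.0),
}

DEFAULT_RIPEN_PARAMS: dict[str, Any] = {
    "noise_sd": 0.0,  # stage-profile noise; 0 = deterministic mode
    "scale_range": (0.5, 2.0),
    "cq_reference": 20.0,
    "cq_base": 24.0,
    "ethylene_fold": 4.0,  # treated/control relative-expression fold
    "replicate_offsets": (-0.05, 0.0, 0.05),  # fixed within-group Cq spread
}


def gen_ripening(spec: FixtureSpec | None = None) -> RipeningFixture:
    """Fixture F-ripen: 44 genes with planted trajectories and responses."""
    spec = spec or FixtureSpec("F-ripen", seed=1)
    params = {**DEFAULT_RIPEN_PARAMS, **spec.parameters}
    rng = np.random.default_rng(spec.seed)

    classes = (
        [(g, "up") for g in RIPENING_UP]
        + [(g, "down") for g in RIPENING_DOWN]
        + [(g, "none") for g in RIPENING_FLAT]
    )
    genes = [g for g, _ in classes]
    if len(set(genes)) != len(genes):
        raise ValueError("trajectory classes overlap")

    profiles = {}
    for g, cls in classes:
        scale = rng.uniform(*params["scale_range"])
        prof = np.array(_TRAJECTORIES[cls]) * scale
        if params["noise_sd"] > 0:
            prof = prof * np.exp(rng.normal(0.0, params["noise_sd"], size=5))
        profiles[g] = prof
    stage_df = pd.DataFrame.from_dict(
        profiles, orient="index", columns=["YF", "WM", "BR", "HR", "FR"]
    )

    log2_fold = np.log2(params["ethylene_fold"])
    qrows = []
    for g in genes:
        if g in ETHYLENE_UP:
            shift = -log2_fold
        elif g in ETHYLENE_DOWN:
            shift = +log2_fold
        else:
            shift = 0.0
        for group, delta in (("control", 0.0), ("treated", shift)):
            for rep, off in enumerate(params["replicate_offsets"], start=1):
                qrows.append({
                    "gene": g, "group": group, "replicate": rep,
                    "cq_target": params["cq_base"] + delta + off,
                    "cq_reference": params["cq_reference"],
                })
    qpcr = pd.DataFrame(qrows)

    ear_flags = {g: g in EAR_GENES for g in genes}
    truth_rows = []
    for g, cls in classes:
        eth = "up" if g in ETHYLENE_UP else "down" if g in ETHYLENE_DOWN else "none"
        if cls == "up" and eth == "up":
            verdict = "activator"
        elif cls == "down" and eth == "down" and ear_flags[g]:
            verdict = "repressor"
        else:
            verdict = "other"
        truth_rows.append({
            "gene": g, "ripening": cls, "ethylene": eth,
            "has_ear": ear_flags[g], "expected_verdict": verdict,
        })
    return RipeningFixture(spec, stage_df, qpcr, ear_flags, pd.DataFrame(truth_rows))
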