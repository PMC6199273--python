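"""Default thresholds, alignment parameters and diagnostic-residue frames.

Every threshold that drives a decision anywhere in the pipeline lives here so
a run manifest can snapshot them, and so a YAML config file can override them.
"""

from __future__ import annotations

from typing import Any

import yaml

#: BLAST-style candidate retention: keep hits with bit score strictly above
#: this and E-value strictly below MAX_EVALUE.
MIN_BIT_SCORE = 200.0
MAX_EVALUE = 1e-3

#: Homolog pairing: hits under this percent match are ignored.
MIN_PERCENT_MATCH = 50.0

#: Duplication typing: a pair is a duplication at all only above this percent
#: similarity; tandem additionally requires at most MAX_INTERVENING_LOCI
#: annotated loci between the two genes on the same linkage group.
MIN_DUP_SIMILARITY = 40.0
MAX_INTERVENING_LOCI = 4

#: Expression gate: mean RPKM below this is "no expression".
RPKM_THRESHOLD = 1.0

#: Ethylene response: two-sided Welch t-test significance level.
ALPHA = 0.05

#: Ripening direction: late-stage mean must exceed early-stage mean by this
#: fold (and vice versa for downregulation).
RIPENING_FOLD = 2.0

#: Global pairwise alignment (protein): substitution matrix and gap costs
#: used for every alignment in the pipeline.
SUBSTITUTION_MATRIX = "BLOSUM62"
GAP_OPEN = 10.0
GAP_EXTEND = 0.5

#: Subfamily discrimination requires at least this fraction of reference
#: positions covered by the alignment.
MIN_ALIGNMENT_COVERAGE = 0.5

#: Soloist assignment: minimum global identity to the soloist reference.
MIN_SOLOIST_IDENTITY = 0.5

#: Diagnostic residues within the aligned AP2-domain frame.  The default
#: frame numbers Ala/Asp at 33/43 for the ERF subfamily and Val/Glu at 21/26
#: for the DREB subfamily; the classical 14/19 frame is provided as an
#: alternative (same residue identities, different alignment numbering).
DIAGNOSTICS_DEFAULT: dict[str, Any] = {
    "erf": {"positions": (33, 43), "residues": ("A", "D")},
    "dreb": {"positions": (21, 26), "residues": ("V", "E")},
}
DIAGNOSTICS_CLASSICAL: dict[str, Any] = {
    "erf": {"positions": (14, 19), "residues": ("A", "D")},
    "dreb": {"positions": (14, 19), "residues": ("V", "E")},
}


def defaults() -> dict[str, Any]:
    """Snapshot of every default threshold, for manifests and overrides."""
    return {
        "min_bit_score": MIN_BIT_SCORE,
        "max_evalue": MAX_EVALUE,
        "min_percent_match": MIN_PERCENT_MATCH,
        "min_dup_similarity": MIN_DUP_SIMILARITY,
        "max_intervening_loci": MAX_INTERVENING_LOCI,
        "rpkm_threshold": RPKM_THRESHOLD,
        "alpha": ALPHA,
        "ripening_fold": RIPENING_FOLD,
        "substitution_matrix": SUBSTITUTION_MATRIX,
        "gap_open": GAP_OPEN,
        "gap_extend": GAP_EXTEND,
        "min_alignment_coverage": MIN_ALIGNMENT_COVERAGE,
        "min_soloist_identity": MIN_SOLOIST_IDENTITY,
        "diagnostics": DIAGNOSTICS_DEFAULT,
    }


def load_config(path: str | None = None) -> dict[str, Any]:
    """Defaults, optionally overridden by a YAML mapping at ``path``."""
    cfg = defaults()
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        if not isinstance(overrides, dict):
            raise ValueError("config file must contain a YAML mapping")
        unknown = set(overrides) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(overrides)
    return cfg
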