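"""Shared global protein alignment (Needleman–Wunsch via Bio.Align).

One fixed parameterization for the whole pipeline: BLOSUM62, gap open 10,
gap extend 0.5 (see :mod:`erfscan.config`).  The first optimal alignment
reported by Biopython is used, which is deterministic for fixed inputs.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from . import config


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(config.SUBSTITUTION_MATRIX)
    aligner.open_gap_score = -config.GAP_OPEN
    aligner.extend_gap_score = -config.GAP_EXTEND
    return aligner


def global_align(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Globally align two protein sequences; return the gapped strings."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    alignment = _aligner().align(seq_a, seq_b)[0]
    return str(alignment[0]), str(alignment[1])


def percent_similarity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity over the full alignment length.

    100 x (identical columns) / (alignment columns, gaps included).
    Arguments are ordered canonically first so the measure is symmetric
    even when co-optimal alignments exist.
    """
    if seq_a > seq_b:
        seq_a, seq_b = seq_b, seq_a
    ga, gb = global_align(seq_a, seq_b)
    ident = sum(x == y for x, y in zip(ga, gb))
    return 100.0 * ident / len(ga)


def fraction_identical_aligned(seq_a: str, seq_b: str) -> float:
    """Fraction of identical residues over aligned (both non-gap) columns.

    Symmetric in its arguments (canonical ordering, as above).
    """
    if seq_a > seq_b:
        seq_a, seq_b = seq_b, seq_a
    ga, gb = global_align(seq_a, seq_b)
    both = [(x, y) for x, y in zip(ga, gb) if x != "-" and y != "-"]
    if not both:
        return 0.0
    return sum(x == y for x, y in both) / len(both)
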