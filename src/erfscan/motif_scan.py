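"""Deterministic scanning of functionally annotated protein motifs.

Two built-in patterns drive the biology downstream:

* the EAR repression motif, core ``(L/F) D L N (L/P)`` — its presence marks
  candidate transcriptional repressors;
* the putative zinc-finger Cys spacing ``C x2 C x4 C x2~4 C``.

In pattern notation ``X``/``x`` means "any of the 20 standard amino acids";
a literal ``X`` in an input sequence is rejected.  A third scanner matches a
printed consensus string within a Hamming-distance budget, replacing de-novo
motif discovery (consensus strings are inputs here, not outputs).
"""

from __future__ import annotations

from dataclasses import dataclass

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PatternElement:
    """One slot of a motif pattern: an allowed-residue set with a repeat range.

    ``allowed=None`` is the wildcard (any standard amino acid).
    """

    allowed: frozenset[str] | None
    min_repeat: int = 1
    max_repeat: int = 1

    def __post_init__(self) -> None:
        if self.min_repeat < 0 or self.min_repeat > self.max_repeat:
            raise ValueError("repeat range must satisfy 0 <= min <= max")
        if self.allowed is not None and not self.allowed <= AMINO_ACIDS:
            raise ValueError("allowed residues must be standard amino acids")


@dataclass(frozen=True)
class MotifPattern:
    name: str
    elements: tuple[PatternElement, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("empty pattern")


@dataclass(frozen=True)
class MotifMatch:
    protein_id: str
    motif: str
    start: int  # 1-based
    matched: str


def _x(n: int, m: int | None = None) -> PatternElement:
    return PatternElement(None, n, m if m is not None else n)


def _any_of(chars: str) -> PatternElement:
    return PatternElement(frozenset(chars))


EAR_PATTERN = MotifPattern(
    "EAR",
    (_any_of("LF"), _any_of("D"), _any_of("L"), _any_of("N"), _any_of("LP")),
)

ZINC_FINGER_PATTERN = MotifPattern(
    "ZnF",
    (
        _any_of("C"), _x(2), _any_of("C"), _x(4), _any_of("C"), _x(2, 4), _any_of("C"),
    ),
)

PATTERN_REGISTRY = {"EAR": EAR_PATTERN, "ZnF": ZINC_FINGER_PATTERN}


def _check_sequence(seq: str) -> None:
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")


def _match_here(seq: str, i: int, elements: tuple[PatternElement, ...]) -> int | None:
    """Shortest match of ``elements`` anchored at index ``i``; returns end index."""
    if not elements:
        return i
    el, rest = elements[0], elements[1:]
    for n in range(el.min_repeat, el.max_repeat + 1):
        j = i + n
        if j > len(seq):
            break
        window = seq[i:j]
        if el.allowed is not None and any(c not in el.allowed for c in window):
            break  # fixed residues: a longer repeat cannot recover
        end = _match_here(seq, j, rest)
        if end is not None:
            return end
    return None


def scan_pattern(
    seq: str, pattern: MotifPattern, protein_id: str = "", overlapping: bool = True
) -> list[MotifMatch]:
    """All matches of ``pattern``; shortest stretch per start position.

    ``overlapping=False`` reports non-overlapping matches leftmost-greedily.
    """
    if not seq:
        raise ValueError("empty sequence")
    _check_sequence(seq)
    matches: list[MotifMatch] = []
    i = 0
    while i < len(seq):
        end = _match_here(seq, i, pattern.elements)
        if end is not None:
            matches.append(MotifMatch(protein_id, pattern.name, i + 1, seq[i:end]))
            i = end if not overlapping else i + 1
        else:
            i += 1
    return matches


def scan_ear(seq: str, protein_id: str = "") -> list[MotifMatch]:
    """Non-overlapping, leftmost-first matches of the EAR core (L/F)DLN(L/P)."""
    return scan_pattern(seq, EAR_PATTERN, protein_id, overlapping=False)


def scan_zinc_finger(seq: str, protein_id: str = "") -> list[MotifMatch]:
    """Matches of C x2 C x4 C x2~4 C; one (shortest) match per start position."""
    return scan_pattern(seq, ZINC_FINGER_PATTERN, protein_id, overlapping=True)


def scan_consensus(
    seq: str, consensus: str, max_mismatches: int = 0, protein_id: str = ""
) -> list[MotifMatch]:
    """All windows of ``seq`` within ``max_mismatches`` Hamming distance of
    ``consensus``.

    Letters are compared literally (MEME consensus strings may carry
    ambiguity letters such as Z or J), so no alphabet check is applied.
    """
    if not consensus:
        raise ValueError("empty consensus")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    k = len(consensus)
    out = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if sum(a != b for a, b in zip(window, consensus)) <= max_mismatches:
            out.append(MotifMatch(protein_id, f"consensus:{consensus[:10]}", i + 1, window))
    return out
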