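"""Pairwise similarity, homolog pairing and tandem-vs-segmental typing.

Pairing uses a percent-similarity floor (hits under 50% are ignored) plus
reciprocal best hit across genomes.  Duplication typing then applies the
positional rule: a pair above 40% similarity is tandem when both genes sit
on the same linkage group with at most four annotated loci between them,
and segmental otherwise.  Similarity exactly 40.0 is not a duplication
(the rule is strictly "greater than 40%"); an intervening count of exactly
4 is tandem ("four or fewer"); genes on different regions can never be
tandem.  Note the spacing-5 case is assigned to segmental as the complement
of the tandem rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from . import config
from ._align import percent_similarity

pairwise_similarity = percent_similarity


class GeneOrderMap:
    """Ordinal positions of ALL annotated loci per seq region.

    Indices are consecutive from 1 within each region; the map must cover
    every locus, not only superfamily members, because the tandem rule
    counts intervening annotated genes.
    """

    def __init__(self, regions: dict[str, list[str]]):
        self._index: dict[str, tuple[str, int]] = {}
        self.regions = {r: list(genes) for r, genes in regions.items()}
        for region, genes in self.regions.items():
            for i, g in enumerate(genes, start=1):
                if g in self._index:
                    raise ValueError(f"gene {g!r} appears twice in the order map")
                self._index[g] = (region, i)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def locate(self, gene_id: str) -> tuple[str, int]:
        if gene_id not in self._index:
            raise KeyError(f"gene {gene_id!r} absent from the order map")
        return self._index[gene_id]

    def intervening_loci(self, gene_a: str, gene_b: str) -> int | None:
        """Annotated loci strictly between the two genes, or None when the
        genes lie on different regions."""
        ra, ia = self.locate(gene_a)
        rb, ib = self.locate(gene_b)
        if ra != rb:
            return None
        return abs(ia - ib) - 1


@dataclass
class ParalogPair:
    gene_a: str
    gene_b: str
    percent_similarity: float
    same_region: bool
    intervening_loci: int | None  # None when on different regions
    dup_type: str = "none"  # tandem | segmental | none

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_similarity <= 100.0:
            raise ValueError("percent_similarity outside [0, 100]")
        if self.dup_type == "tandem" and not self.same_region:
            raise ValueError("tandem requires both genes on one region")


def classify_duplication(
    pair: ParalogPair,
    order: GeneOrderMap,
    max_intervening: int = config.MAX_INTERVENING_LOCI,
    min_similarity: float = config.MIN_DUP_SIMILARITY,
) -> str:
    """Type a qualifying pair as tandem or segmental (or ``none``)."""
    spacing = order.intervening_loci(pair.gene_a, pair.gene_b)
    if pair.percent_similarity <= min_similarity:
        return "none"
    if spacing is not None and spacing <= max_intervening:
        return "tandem"
    return "segmental"


def make_pair(gene_a: str, gene_b: str, similarity: float, order: GeneOrderMap,
              **kwargs) -> ParalogPair:
    """Build a :class:`ParalogPair` with its duplication type filled in."""
    spacing = order.intervening_loci(gene_a, gene_b)
    pair = ParalogPair(
        gene_a=gene_a,
        gene_b=gene_b,
        percent_similarity=similarity,
        same_region=spacing is not None,
        intervening_loci=spacing,
    )
    pair.dup_type = classify_duplication(pair, order, **kwargs)
    return pair


def find_homolog_pairs(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str] | None = None,
    min_percent_match: float = config.MIN_PERCENT_MATCH,
) -> dict[str, list[tuple[str, str, float]]]:
    """Within-genome paralogs and (optionally) cross-genome co-orthologs.

    Returns ``{"paralogs_a": [...], "paralogs_b": [...], "co_orthologs":
    [...]}`` of (id, id, similarity) triples.  Within-genome pairs qualify
    at similarity >= ``min_percent_match``; cross-genome pairs must
    additionally be reciprocal best hits.
    """
    proteome_b = proteome_b or {}
    collisions = set(proteome_a) & set(proteome_b)
    if collisions:
        raise ValueError(f"ids present in both proteomes: {sorted(collisions)}")

    def within(proteome: dict[str, str]) -> list[tuple[str, str, float]]:
        out = []
        for a, b in itertools.combinations(sorted(proteome), 2):
            sim = percent_similarity(proteome[a], proteome[b])
            if sim >= min_percent_match:
                out.append((a, b, sim))
        return out

    result = {
        "paralogs_a": within(proteome_a),
        "paralogs_b": within(proteome_b),
        "co_orthologs": [],
    }
    if proteome_a and proteome_b:
        sims = {
            (a, b): percent_similarity(sa, sb)
            for a, sa in proteome_a.items()
            for b, sb in proteome_b.items()
        }
        best_ab = {
            a: max((b for b in proteome_b), key=lambda b: (sims[(a, b)], b))
            for a in proteome_a
        }
        best_ba = {
            b: max((a for a in proteome_a), key=lambda a: (sims[(a, b)], a))
            for b in proteome_b
        }
        for a in sorted(proteome_a):
            b = best_ab[a]
            if best_ba[b] == a and sims[(a, b)] >= min_percent_match:
                result["co_orthologs"].append((a, b, sims[(a, b)]))
    return result
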