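"""Expression quantification, gating, clustering and response testing.

RPKM normalization; the "expressed" gate at mean RPKM >= 1.0 per tissue
(strictly below 1.0 counts as no expression); row z-scoring (population
standard deviation); agglomerative clustering with Pearson distance
d = 1 − r and average linkage over all pairs, with dendrogram nodes
reported on the similarity scale 1 − merge distance (a correlation-scale
value in [−1, 1]); clade cutting at a similarity level; qPCR relative
expression by 2^−ΔCt against a reference gene; and a two-sided Welch
t-test for ethylene response at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from scipy.stats import ttest_ind

from . import config


@dataclass
class ExpressionMatrix:
    """Genes x samples abundances plus a sample design (tissue, replicate)."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    design: pd.DataFrame  # index: sample ids; columns: tissue, replicate

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative abundances")
        if set(self.values.columns) != set(self.design.index):
            raise ValueError("samples in values and design differ")
        if "tissue" not in self.design.columns:
            raise ValueError("design must declare a tissue per sample")

    def tissue_means(self) -> pd.DataFrame:
        """Genes x tissues, averaging replicates."""
        groups = self.design["tissue"]
        return self.values.T.groupby(groups).mean().T


def rpkm(read_count: float, exon_model_length_bp: float, mapped_reads_total: float) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if exon_model_length_bp <= 0:
        raise ValueError("exon model length must be positive")
    if mapped_reads_total <= 0:
        raise ValueError("library size must be positive")
    if read_count < 0:
        raise ValueError("negative read count")
    return read_count / (exon_model_length_bp / 1e3 * mapped_reads_total / 1e6)


def gate_expressed(
    matrix: ExpressionMatrix, threshold: float = config.RPKM_THRESHOLD
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression flags from tissue means.

    Returns (expressed_in_tissue: genes x tissues bool, expressed_overall:
    bool per gene).  A gene is expressed in a tissue iff its mean RPKM is
    >= ``threshold`` (strictly below the threshold is "no expression"), and
    expressed overall iff expressed in at least one tissue.
    """
    means = matrix.tissue_means()
    in_tissue = means >= threshold
    return in_tissue, in_tissue.any(axis=1)


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize to mean 0, population standard deviation 1."""
    sd = values.std(axis=1, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant expression rows: {constant}")
    return values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over genes with correlation-scale heights."""

    labels: list[str]
    merges: np.ndarray  # scipy linkage matrix (n-1, 4); heights are 1 - r

    @property
    def merge_similarities(self) -> np.ndarray:
        """1 − merge distance for each internal node, root last."""
        return 1.0 - self.merges[:, 2]


@dataclass
class CladeAssignment:
    clades: dict[str, int]  # gene id -> clade label (1-based)
    merge_similarities: list[float] = field(default_factory=list)

    @property
    def n_clades(self) -> int:
        return len(set(self.clades.values()))


def cluster_genes(values: pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering with d = 1 − Pearson r, average linkage."""
    if len(values) < 2:
        raise ValueError("need at least 2 genes to cluster")
    sd = values.std(axis=1, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant expression rows: {constant}")
    dists = pdist(values.values, metric="correlation")
    return Dendrogram(list(values.index), linkage(dists, method="average"))


def cut_clades(dendrogram: Dendrogram, similarity_cut: float) -> CladeAssignment:
    """Clades = connected components after removing merges whose similarity
    (1 − height) is <= ``similarity_cut``."""
    if not -1.0 <= similarity_cut <= 1.0:
        raise ValueError("similarity_cut must lie in [-1, 1]")
    n = len(dendrogram.labels)
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, (a, b, height, _size) in enumerate(dendrogram.merges):
        if 1.0 - height > similarity_cut:  # keep this merge
            node = n + idx
            parent[find(int(a))] = node
            parent[find(int(b))] = node

    roots: dict[int, int] = {}
    clades: dict[str, int] = {}
    for i, label in enumerate(dendrogram.labels):
        r = find(i)
        roots.setdefault(r, len(roots) + 1)
        clades[label] = roots[r]
    return CladeAssignment(
        clades=clades,
        merge_similarities=[float(s) for s in dendrogram.merge_similarities],
    )


def relative_expression_2ddct(cq_target: float, cq_reference: float) -> float:
    """Relative qPCR expression, 2^−(Cq_target − Cq_reference)."""
    if not (math.isfinite(cq_target) and math.isfinite(cq_reference)):
        raise ValueError("non-finite Cq value")
    return 2.0 ** (-(cq_target - cq_reference))


def ethylene_response_test(
    control: list[float] | np.ndarray,
    treated: list[float] | np.ndarray,
    alpha: float = config.ALPHA,
) -> tuple[str, float]:
    """Two-sided Welch t-test; returns ({'up','down','none'}, p-value).

    ``up`` when significant with treated mean above control, ``down`` when
    significant below, ``none`` otherwise.  Degenerate zero-variance groups
    are handled: equal means give p = 1, unequal means with no within-group
    variance give p = 0.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if len(control) < 2 or len(treated) < 2:
        raise ValueError("need at least 2 replicates per group")
    diff = treated.mean() - control.mean()
    if control.std() == 0 and treated.std() == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(ttest_ind(treated, control, equal_var=False).pvalue)
        if math.isnan(p):
            p = 1.0
    if p < alpha and diff > 0:
        return "up", p
    if p < alpha and diff < 0:
        return "down", p
    return "none", p


def tissue_specific_calls(expressed_in_tissue: pd.DataFrame) -> pd.Series:
    """Per-gene specificity from the gate's genes x tissues flags.

    Genes expressed in exactly one tissue get ``"<tissue>-specific"``;
    multi-tissue genes get ``"none"``; all-silent genes are excluded.
    """
    counts = expressed_in_tissue.sum(axis=1)
    kept = expressed_in_tissue.loc[counts > 0]
    labels = {}
    for gene, row in kept.iterrows():
        tissues = row[row].index.tolist()
        labels[gene] = f"{tissues[0]}-specific" if len(tissues) == 1 else "none"
    return pd.Series(labels, dtype="object")
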