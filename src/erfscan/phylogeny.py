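"""Distance matrices and neighbor-joining trees.

Distances come from pairwise global alignments (d = 1 − fraction identical
over aligned columns, gap columns excluded).  The NJ implementation is the
standard Q-criterion agglomeration with deterministic tie-breaking on the
smallest (i, j) index pair; negative branch lengths are clamped to zero and
the clamped deficit is recorded on the tree.  Trees are scikit-bio
``TreeNode`` objects, so newick round-tripping and path-length queries come
for free.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from ._align import fraction_identical_aligned


@dataclass
class DistanceMatrix:
    labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.data), 0.0):
            raise ValueError("nonzero diagonal")
        if (self.data < -1e-12).any():
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.labels)


def distance_from_alignment(sequences: dict[str, str]) -> DistanceMatrix:
    """Pairwise alignment distances: 1 − identity over aligned columns."""
    labels = list(sequences)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dist = 1.0 - fraction_identical_aligned(sequences[labels[i]], sequences[labels[j]])
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbor joining; deterministic given the tie rule.

    Agglomerates until three nodes remain, then joins them at an unrooted
    (trifurcating) root with closed-form pendant lengths.  Negative branch
    lengths are clamped to 0; the summed deficit is stored on the root as
    ``negative_length_deficit``.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    d = dm.data.astype(float).copy()
    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        # Q(i, j) = (m - 2) d_ij - r_i - r_j ; pick smallest Q, ties -> smallest (i, j)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = clamp(0.5 * dij + (r[a] - r[b]) / (2 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))))
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])

        # distances from the new node to every other active node
        new_idx = i
        for c in active:
            if c in (i, j):
                continue
            d_new = 0.5 * (d[i, c] + d[j, c] - dij)
            d[new_idx, c] = d[c, new_idx] = max(d_new, 0.0)
        nodes[new_idx] = parent
        active.remove(j)

    # join the last three nodes at a trifurcating root
    i, j, k = active
    root = TreeNode()
    nodes[i].length = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    nodes[j].length = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    nodes[k].length = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root.extend([nodes[i], nodes[j], nodes[k]])
    root.negative_length_deficit = deficit
    return root


def tree_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree."""
    skdm = tree.tip_tip_distances()
    labels = list(skdm.ids)
    return DistanceMatrix(labels, np.asarray(skdm.data))


def nearest_leaf_families(
    tree: TreeNode, leaf: str, k: int = 3, family_map: dict[str, str] | None = None
) -> str:
    """Majority family among the ``k`` nearest leaves by path length.

    Distance ties are broken by leaf name for determinism; a tied majority
    returns ``"unresolved"``.
    """
    family_map = family_map or {}
    try:
        target = next(t for t in tree.tips() if t.name == leaf)
    except StopIteration:
        raise KeyError(f"leaf {leaf!r} not in tree") from None
    skdm = tree.tip_tip_distances()
    dists = sorted(
        ((skdm[leaf, other.name], other.name) for other in tree.tips()
         if other.name != leaf),
    )
    nearest = [name for _, name in dists[:k]]
    votes: dict[str, int] = {}
    for name in nearest:
        fam = family_map.get(name, "unknown")
        votes[fam] = votes.get(fam, 0) + 1
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "unresolved"
    return ranked[0][0]
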