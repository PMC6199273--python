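import itertools

import numpy as np
import pandas as pd
import pytest

from erfscan.expression import (
    Dendrogram,
    ExpressionMatrix,
    cluster_genes,
    cut_clades,
    ethylene_response_test,
    gate_expressed,
    relative_expression_2ddct,
    rpkm,
    tissue_specific_calls,
    zscore_rows,
)


def matrix(values: dict, tissues=("leaf", "flower", "fruit")) -> ExpressionMatrix:
    vdf = pd.DataFrame(values, index=list(tissues)).T
    design = pd.DataFrame(
        {"tissue": list(tissues), "replicate": [1] * len(tissues)},
        index=list(tissues),
    )
    return ExpressionMatrix(vdf, design)


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [
            (10, 1000, 1e6, 10.0),
            (0, 1000, 1e6, 0.0),
            (5, 500, 2e6, 5.0),  # 5 / (0.5 kb x 2 M) by hand
        ],
    )
    def test_unit_cases(self, count, length, total, expected):
        assert rpkm(count, length, total) == pytest.approx(expected)

    @pytest.mark.parametrize("length,total", [(0, 1e6), (1000, 0)])
    def test_degenerate_denominators_rejected(self, length, total):
        with pytest.raises(ValueError):
            rpkm(10, length, total)


class TestGate:
    def test_strictly_below_threshold_is_silent(self):
        m = matrix({"g1": [0.99, 0.5, 0.2], "g2": [1.0, 0.0, 0.0]})
        in_tissue, overall = gate_expressed(m)
        assert not overall["g1"]  # 0.99 < 1.0: no expression
        assert overall["g2"]  # boundary: exactly 1.0 is expressed

    def test_replicates_averaged_before_gating(self):
        vdf = pd.DataFrame({"s1": [0.4], "s2": [1.8]}, index=["g1"])
        design = pd.DataFrame(
            {"tissue": ["leaf", "leaf"], "replicate": [1, 2]}, index=["s1", "s2"]
        )
        in_tissue, overall = gate_expressed(ExpressionMatrix(vdf, design))
        assert overall["g1"]  # mean 1.1 >= 1.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(23)
        m = matrix({f"g{i}": rng.uniform(0, 3, size=3) for i in range(30)})
        previous = None
        for t in (0.5, 1.0, 1.5, 2.0):
            _, overall = gate_expressed(m, threshold=t)
            n = int(overall.sum())
            if previous is not None:
                assert n <= previous  # raising the gate never adds genes
            previous = n

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            matrix({"g1": [-1.0, 0.0, 0.0]})


class TestZscore:
    def test_hand_computed_row(self):
        z = zscore_rows(pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]},
                                     index=["g"]))
        assert np.allclose(z.loc["g"], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_idempotent_on_standardized_rows(self):
        row = np.array([-1.2247448, 0.0, 1.2247448])
        df = pd.DataFrame([row], index=["g"], columns=list("abc"))
        assert np.allclose(zscore_rows(df).values, df.values, atol=1e-6)

    def test_constant_row_error_names_gene(self):
        df = pd.DataFrame({"a": [1.0, 5.0], "b": [1.0, 6.0], "c": [1.0, 7.0]},
                          index=["flatgene", "ok"])
        with pytest.raises(ValueError, match="flatgene"):
            zscore_rows(df)


def brute_force_average_linkage(values: np.ndarray, labels):
    """Oracle: agglomerate by average of ALL inter-cluster pairs, d = 1 - r."""

    def pearson_distance(x, y):
        return 1.0 - np.corrcoef(x, y)[0, 1]

    base = {
        (i, j): pearson_distance(values[i], values[j])
        for i, j in itertools.combinations(range(len(labels)), 2)
    }
    clusters = {i: frozenset([i]) for i in range(len(labels))}
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean([
                base[(min(i, j), max(i, j))]
                for i in clusters[a] for j in clusters[b]
            ])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        merges.append(d)
        new_key = max(clusters) + 1
        clusters[new_key] = clusters.pop(a) | clusters.pop(b)
    return sorted(merges)


class TestClusterGenes:
    def test_identical_rows_merge_at_similarity_one(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]],
                          index=["a", "b"], columns=list("xyz"))
        dend = cluster_genes(df)
        assert dend.merge_similarities[0] == pytest.approx(1.0)

    def test_anticorrelated_rows_merge_at_similarity_minus_one(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
                          index=["a", "b"], columns=list("xyz"))
        dend = cluster_genes(df)
        assert dend.merge_similarities[0] == pytest.approx(-1.0)

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(29)
        for n in (3, 5, 8):
            for _ in range(5):
                values = rng.normal(size=(n, 6))
                df = pd.DataFrame(values, index=[f"g{i}" for i in range(n)])
                dend = cluster_genes(df)
                got = sorted(dend.merges[:, 2])
                want = brute_force_average_linkage(values, df.index)
                assert np.allclose(got, want, atol=1e-10)

    def test_constant_row_rejected(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            cluster_genes(df)


@pytest.fixture(scope="module")
def planted():
    # four clades of scaled copies of distinct profiles
    profiles = {
        "A": [10.0, 1.0, 1.0, 1.0], "B": [1.0, 10.0, 1.0, 1.0],
        "C": [1.0, 1.0, 10.0, 1.0], "D": [1.0, 1.0, 1.0, 10.0],
    }
    rows, truth = {}, {}
    for clade, profile in profiles.items():
        for i, scale in enumerate((0.5, 1.0, 2.0)):
            g = f"{clade}{i}"
            rows[g] = [v * scale for v in profile]
            truth[g] = clade
    return pd.DataFrame(rows).T, truth


class TestCutClades:
    def test_cut_below_lowest_merge_gives_one_clade(self, planted):
        df, _ = planted
        clades = cut_clades(cluster_genes(df), similarity_cut=-1.0)
        assert clades.n_clades == 1

    def test_cut_above_highest_merge_gives_singletons(self, planted):
        df, _ = planted
        clades = cut_clades(cluster_genes(df), similarity_cut=1.0)
        assert clades.n_clades == len(df)

    def test_planted_four_clade_structure_recovered(self, planted):
        df, truth = planted
        clades = cut_clades(cluster_genes(df), similarity_cut=0.99)
        assert clades.n_clades == 4
        # clade labels must be constant within each planted group
        by_truth = {}
        for gene, label in clades.clades.items():
            by_truth.setdefault(truth[gene], set()).add(label)
        assert all(len(s) == 1 for s in by_truth.values())

    def test_out_of_range_cut_rejected(self):
        dend = Dendrogram(["a", "b"], np.array([[0, 1, 0.5, 2]], float))
        with pytest.raises(ValueError):
            cut_clades(dend, 1.5)


class TestQpcr:
    @pytest.mark.parametrize(
        "dct,expected",
        [(0.0, 1.0), (1.0, 0.5), (3.3219, 0.1000)],
    )
    def test_two_power_minus_delta_ct(self, dct, expected):
        assert relative_expression_2ddct(20.0 + dct, 20.0) == pytest.approx(
            expected, abs=1e-4)

    def test_monotone_in_target_and_reference(self):
        base = relative_expression_2ddct(24.0, 20.0)
        assert relative_expression_2ddct(25.0, 20.0) < base  # more cycles = less
        assert relative_expression_2ddct(24.0, 21.0) > base

    def test_non_finite_cq_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            relative_expression_2ddct(float("nan"), 20.0)


class TestEthyleneResponse:
    def test_identical_groups_not_significant(self):
        direction, p = ethylene_response_test([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert direction == "none" and p == pytest.approx(1.0)

    def test_clear_induction_called_up(self):
        direction, p = ethylene_response_test([1.0, 1.1, 0.9], [5.0, 5.2, 4.8])
        assert direction == "up" and p < 0.05

    def test_clear_suppression_called_down(self):
        direction, p = ethylene_response_test([5.0, 5.2, 4.8], [1.0, 1.1, 0.9])
        assert direction == "down" and p < 0.05

    def test_zero_variance_groups_with_shift(self):
        direction, p = ethylene_response_test([1.0, 1.0], [2.0, 2.0])
        assert direction == "up" and p == 0.0

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            ethylene_response_test([1.0], [2.0, 2.1])


class TestTissueSpecific:
    def test_specificity_labels(self):
        m = matrix({
            "fruit_only": [0.2, 0.3, 30.0],
            "broad": [5.0, 5.0, 5.0],
            "silent": [0.1, 0.1, 0.1],
        })
        in_tissue, _ = gate_expressed(m)
        calls = tissue_specific_calls(in_tissue)
        assert calls["fruit_only"] == "fruit-specific"
        assert calls["broad"] == "none"
        assert "silent" not in calls.index
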