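"""t-score matrix assembly, clustering and specificity classification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from trexkit.errors import ConfigurationError
from trexkit.regional import (
    assemble_tscore_matrix,
    bin_tscores,
    classify_region_specificity,
    cluster_tscores,
)


def frame(rows):
    """Build an enrichment-style frame from {protein: (d_stat, significant)}."""
    return pd.DataFrame(
        {"difference": [v[0] for v in rows.values()],
         "d_stat": [v[0] for v in rows.values()],
         "p": 0.01, "q": 0.01,
         "significant": [v[1] for v in rows.values()]},
        index=list(rows))


class TestAssemble:
    def test_union_of_significant_proteins(self):
        results = {
            "A": frame({"P1": (5.0, True), "P2": (1.0, False)}),
            "B": frame({"P2": (6.0, True), "P3": (0.5, False)}),
        }
        mat = assemble_tscore_matrix(results)
        assert set(mat.proteins) == {"P1", "P2"}  # P3 significant nowhere
        assert mat.tscores.loc["P1", "A"] == 5.0
        # P1 absent from region B -> 0 with absence mask
        assert mat.tscores.loc["P1", "B"] == 0.0
        assert bool(mat.absent.loc["P1", "B"])
        assert not bool(mat.absent.loc["P2", "B"])

    def test_retained_count_equals_set_union_oracle(self, rng):
        regions = {}
        sig_sets = []
        for r in range(4):
            ids = [f"P{i}" for i in rng.choice(100, size=40, replace=False)]
            sig = rng.random(40) < 0.3
            regions[f"R{r}"] = frame(
                {p: (float(rng.normal()), bool(s)) for p, s in zip(ids, sig)})
            sig_sets.append({p for p, s in zip(ids, sig) if s})
        mat = assemble_tscore_matrix(regions)
        assert set(mat.proteins) == set.union(*sig_sets)

    def test_retained_set_invariant_under_region_reordering(self):
        a = frame({"P1": (5.0, True)})
        b = frame({"P2": (4.0, True)})
        m1 = assemble_tscore_matrix({"A": a, "B": b})
        m2 = assemble_tscore_matrix({"B": b, "A": a})
        assert set(m1.proteins) == set(m2.proteins)

    def test_needs_two_regions(self):
        with pytest.raises(ConfigurationError):
            assemble_tscore_matrix({"A": frame({"P1": (1.0, True)})})


def planted_matrix(rng, n_per_cluster=30, noise=0.3):
    """Two orthogonal profiles: hot in region A only vs region B only."""
    rows, labels = [], []
    for i in range(n_per_cluster):
        rows.append([8.0 + rng.normal(0, noise), rng.normal(0, noise), 0.0])
        labels.append(0)
    for i in range(n_per_cluster):
        rows.append([rng.normal(0, noise), 8.0 + rng.normal(0, noise), 0.0])
        labels.append(1)
    results = {}
    ids = [f"P{i:03d}" for i in range(len(rows))]
    for j, region in enumerate(["A", "B", "C"]):
        results[region] = frame(
            {p: (rows[i][j], rows[i][j] > 4) for i, p in enumerate(ids)})
    mat = assemble_tscore_matrix(results)
    truth = pd.Series(labels, index=ids).loc[mat.proteins]
    return mat, truth


class TestClustering:
    def test_recovers_planted_partition(self, rng):
        mat, truth = planted_matrix(rng)
        cluster_tscores(mat, kmeans_pre_k=10, n_clusters=2, seed=0)
        assert adjusted_rand_score(truth, mat.cluster_ids) == 1.0
        assert set(mat.cluster_ids) == {1, 2}
        sil = silhouette_score(mat.tscores, mat.cluster_ids)
        assert sil >= 0.5

    def test_gap_heuristic_finds_two_clusters(self, rng):
        mat, truth = planted_matrix(rng)
        cluster_tscores(mat, kmeans_pre_k=10, seed=0)
        assert adjusted_rand_score(truth, mat.cluster_ids) == 1.0

    def test_row_order_permutation_invariance(self, rng):
        mat, _ = planted_matrix(rng)
        ids1 = cluster_tscores(mat, kmeans_pre_k=8, n_clusters=2,
                               seed=3).cluster_ids
        perm = rng.permutation(len(mat.proteins))
        mat2, _ = planted_matrix(np.random.default_rng(1234))
        mat2.tscores = mat2.tscores.iloc[perm]
        mat2.significant = mat2.significant.iloc[perm]
        mat2.absent = mat2.absent.iloc[perm]
        ids2 = cluster_tscores(mat2, kmeans_pre_k=8, n_clusters=2,
                               seed=3).cluster_ids
        common = ids1.index
        assert adjusted_rand_score(ids1[common], ids2[common]) == 1.0

    def test_single_row_single_cluster(self):
        mat = assemble_tscore_matrix({
            "A": frame({"P1": (5.0, True)}),
            "B": frame({"P1": (0.1, False)}),
        })
        cluster_tscores(mat, seed=0)
        assert mat.cluster_ids.tolist() == [1]

    def test_pre_k_above_n_raises(self, rng):
        mat, _ = planted_matrix(rng, n_per_cluster=3)
        with pytest.raises(ConfigurationError):
            cluster_tscores(mat, kmeans_pre_k=50)

    def test_deterministic_per_seed(self, rng):
        mat, _ = planted_matrix(rng)
        a = cluster_tscores(mat, kmeans_pre_k=12, n_clusters=2, seed=7
                            ).cluster_ids.copy()
        b = cluster_tscores(mat, kmeans_pre_k=12, n_clusters=2, seed=7
                            ).cluster_ids
        pd.testing.assert_series_equal(a, b)


class TestSpecificity:
    def make_matrix(self):
        results = {
            "A": frame({"P1": (9.0, True), "P2": (3.0, True), "P3": (2.0, True)}),
            "B": frame({"P1": (1.0, False), "P2": (4.0, True), "P3": (7.0, True)}),
            "C": frame({"P2": (5.0, True), "P3": (0.2, False)}),
            "D": frame({"P2": (2.5, True)}),
        }
        return assemble_tscore_matrix(results)

    def test_classification_rules(self):
        mat = self.make_matrix()
        spec = classify_region_specificity(mat)
        assert spec.loc["P1", "specificity"] == "region_specific"
        assert spec.loc["P1", "primary_region"] == "A"
        assert spec.loc["P2", "specificity"] == "multiregional"  # 4 regions
        assert pd.isna(spec.loc["P2", "primary_region"])
        assert spec.loc["P3", "specificity"] == "region_specific"  # 2 regions
        assert spec.loc["P3", "primary_region"] == "B"

    def test_counts_partition_retained_set(self):
        mat = self.make_matrix()
        spec = classify_region_specificity(mat)
        counts = spec["specificity"].value_counts()
        assert counts.sum() == len(mat.proteins)

    def test_ties_break_by_region_order(self):
        results = {
            "A": frame({"P1": (5.0, True)}),
            "B": frame({"P1": (5.0, True)}),
        }
        mat = assemble_tscore_matrix(results)
        spec = classify_region_specificity(mat)
        assert spec.loc["P1", "primary_region"] == "A"
        assert bool(spec.loc["P1", "tie"])


class TestBins:
    def test_fixed_edges(self):
        results = {
            "A": frame({"P1": (-1.0, True), "P2": (3.0, True)}),
            "B": frame({"P1": (1.0, False), "P2": (15.0, True)}),
        }
        mat = assemble_tscore_matrix(results)
        bins = bin_tscores(mat)
        assert bins.loc["P1", "A"] == "le0"
        assert bins.loc["P1", "B"] == "0-2"
        assert bins.loc["P2", "A"] == "2-6"
        assert bins.loc["P2", "B"] == "ge10"
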