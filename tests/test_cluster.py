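"""kNN + Louvain clustering and disease-cluster identification."""

import numpy as np
import pandas as pd
import pytest

from cgps.cluster import (ClusterResult, cluster_cells,
                          identify_disease_cluster, rank_cluster_markers)
from cgps.simulate import (CANDIDATE_MARKERS, DISEASE_TEMPLATE, SimConfig,
                           generate_cohort)
from cgps.io import scale_and_regress
from cgps.stats import wilcoxon_rank_sum

from conftest import make_cohort, make_sample


def blob_cohort(rng, centers, n_each=20, sd=0.3):
    """One sample containing well-separated Gaussian blobs."""
    blocks = [c + rng.normal(0, sd, (n_each, len(c))) for c in centers]
    values = np.vstack(blocks)
    markers = [f"M{j}" for j in range(values.shape[1])]
    sample = make_sample(values, markers, sid="s0")
    return make_cohort([sample], ["HD"]), np.repeat(
        np.arange(len(centers)), n_each)


class TestClusterCells:
    def test_recovers_three_well_separated_blobs(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        cohort, truth = blob_cohort(rng, centers, n_each=20)
        res = cluster_cells(cohort, k_neighbors=10, seed=0)
        assert len(res.cluster_ids) == 3
        # oracle: nearest-centroid assignment must agree within each cluster
        oracle = np.argmin(
            ((res.cells[:, None, :] - centers[None]) ** 2).sum(-1), axis=1)
        for c in res.cluster_ids:
            assert len(set(oracle[res.labels == c])) == 1
        # and each blob is one whole cluster
        assert len(set(zip(res.labels, truth))) == 3

    def test_same_seed_gives_identical_labels(self, rng):
        cohort, _ = blob_cohort(rng, np.array([[0.0, 0], [8, 0], [0, 8]]))
        a = cluster_cells(cohort, k_neighbors=10, seed=4)
        b = cluster_cells(cohort, k_neighbors=10, seed=4)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_single_blob_collapses_at_vanishing_resolution(self, rng):
        cohort, _ = blob_cohort(rng, np.array([[0.0, 0.0]]), n_each=60)
        res = cluster_cells(cohort, k_neighbors=10, resolution=1e-3, seed=0)
        assert len(res.cluster_ids) == 1

    def test_k_at_least_n_cells_is_an_error(self, rng):
        cohort, _ = blob_cohort(rng, np.array([[0.0, 0.0]]), n_each=5)
        with pytest.raises(ValueError, match="k_neighbors"):
            cluster_cells(cohort, k_neighbors=5, seed=0)

    def test_composition_counts_conserve_group_totals(self, rng):
        cohort, _ = blob_cohort(rng, np.array([[0.0, 0], [9, 0]]))
        res = cluster_cells(cohort, k_neighbors=8, seed=0)
        assert res.composition["count"].sum() == len(res.labels)
        frac_sums = res.composition.groupby("cluster")["fraction"].sum()
        np.testing.assert_allclose(frac_sums, 1.0, atol=1e-9)


def composition_result(fracs, counts):
    comp = pd.DataFrame([
        {"cluster": c, "group": "cGVHD", "count": counts[c],
         "fraction": fracs[c]}
        for c in fracs])
    dummy = np.zeros((1, 1))
    return ClusterResult(labels=np.zeros(1, dtype=int), cells=dummy,
                         meta=pd.DataFrame({"sample_id": ["s"],
                                            "group": ["cGVHD"]}),
                         k_neighbors=1, resolution=1.0, composition=comp)


class TestIdentifyDiseaseCluster:
    def test_selects_the_dominated_cluster(self):
        res = composition_result({0: 0.50, 1: 0.40, 2: 0.82},
                                 {0: 500, 1: 400, 2: 1748})
        assert identify_disease_cluster(res, min_fraction=0.75) == 2

    def test_no_cluster_above_floor_is_an_error(self):
        res = composition_result({0: 0.5, 1: 0.5}, {0: 100, 1: 100})
        with pytest.raises(ValueError, match="no disease-associated"):
            identify_disease_cluster(res, min_fraction=0.75)

    def test_exact_fraction_tie_broken_by_cell_count(self):
        res = composition_result({0: 0.80, 1: 0.80}, {0: 100, 1: 500})
        assert identify_disease_cluster(res, min_fraction=0.75) == 1

    def test_missing_group_is_an_error(self):
        res = composition_result({0: 0.9}, {0: 50})
        with pytest.raises(ValueError, match="no group"):
            identify_disease_cluster(res, disease_group="XX")

    def test_relabeling_clusters_returns_the_same_cell_set(self, rng):
        cohort, _ = blob_cohort(rng, np.array([[0.0, 0], [9, 0]]), n_each=30)
        res = cluster_cells(cohort, k_neighbors=8, seed=0)
        res.meta["group"] = np.where(res.labels == res.labels[0],
                                     "cGVHD", "HD")
        from cgps.cluster import _composition_table
        res.composition = _composition_table(res.labels, res.meta["group"])
        c = identify_disease_cluster(res, min_fraction=0.6)
        cells_before = set(np.flatnonzero(res.labels == c))
        # cyclically permute cluster ids
        ids = sorted(set(res.labels))
        relabel = {a: b for a, b in zip(ids, ids[1:] + ids[:1])}
        res2 = ClusterResult(
            labels=np.array([relabel[v] for v in res.labels]),
            cells=res.cells, meta=res.meta, k_neighbors=8, resolution=0.8)
        res2.composition = _composition_table(res2.labels,
                                              res2.meta["group"])
        c2 = identify_disease_cluster(res2, min_fraction=0.6)
        assert set(np.flatnonzero(res2.labels == c2)) == cells_before


class TestMarkerRanking:
    def _clustered_synthetic(self, seed=0):
        cfg = SimConfig(n_subjects={"HD": 3, "cGVHD_DP": 3},
                        cells_per_subject=1500, seed=seed)
        cohort = generate_cohort(cfg)
        scaled = scale_and_regress(cohort, ["batch"])
        res = cluster_cells(scaled, k_neighbors=15, seed=seed)
        cluster = identify_disease_cluster(res, min_fraction=0.75)
        truth = np.concatenate([cohort.cell_truth[s.sample_id]
                                for s in cohort.samples])
        # rank on the arcsinh axis, as the model does
        values, _ = cohort.pooled()
        return cohort, res, cluster, truth, values

    def test_planted_markers_are_the_top_eight_by_effect(self):
        cohort, res, cluster, truth, values = self._clustered_synthetic()
        in_cluster = res.cluster_mask(cluster)
        # sanity: the cluster is the planted population
        assert (truth[in_cluster] == DISEASE_TEMPLATE).mean() > 0.95
        ranking = rank_cluster_markers(cohort, res, cluster, values=values)
        assert set(ranking.selected) == set(CANDIDATE_MARKERS)

    def test_identical_marker_has_p_one_and_is_not_selected(self, rng):
        values = np.column_stack([
            np.concatenate([np.full(40, 3.0), np.full(60, 0.5)])
            + rng.normal(0, 0.3, 100),           # separates the cluster
            np.full(100, 1.25),                  # identical in/out
        ])
        sample = make_sample(values, ["GOOD", "FLAT"], sid="s0")
        cohort = make_cohort([sample], ["cGVHD"])
        res = cluster_cells(cohort, k_neighbors=10, seed=0)
        # the cluster holding the GOOD-high cells (first 40 rows)
        cluster = int(np.bincount(res.labels[:40]).argmax())
        ranking = rank_cluster_markers(cohort, res, cluster, alpha=0.01)
        flat = ranking.table.set_index("marker").loc["FLAT"]
        assert flat["p_value"] == pytest.approx(1.0)
        assert "FLAT" not in ranking.selected
        assert "GOOD" in ranking.selected

    def test_rank_sum_p_matches_exact_enumeration_at_small_n(self):
        # complete separation at n=5 vs 5 -> exact two-sided p = 2/252
        res = wilcoxon_rank_sum([10, 11, 12, 13, 14], [1, 2, 3, 4, 5],
                                mode="exact")
        assert res.p_value == pytest.approx(2 / 252)

    def test_tiny_cluster_is_an_error(self, rng):
        cohort, _ = blob_cohort(rng, np.array([[0.0, 0], [9, 0]]), n_each=20)
        res = cluster_cells(cohort, k_neighbors=8, seed=0)
        with pytest.raises(ValueError, match="does not exist"):
            rank_cluster_markers(cohort, res, cluster=99)
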