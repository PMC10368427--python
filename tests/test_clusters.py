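"""Consensus-cluster algorithm: thresholding, overlap, components, filters."""

import numpy as np
import pytest

from cortasym.asymmetry import AIMap, mean_ai_map
from cortasym.clusters import (
    ClusterError,
    build_overlap_map,
    delineate_clusters,
    extract_cluster_values,
    jaccard,
    proportion_lateralized,
)
from cortasym.simulate import simulate_datasets


def _maps_from_vertex_values(values_per_dataset, metric="area"):
    return [
        AIMap(ai=np.asarray(v, dtype=float), metric=metric,
              dataset_id=f"d{i}", n_subjects=10)
        for i, v in enumerate(values_per_dataset)
    ]


class TestOverlapMap:
    def test_hand_count_with_closed_threshold(self, mesh_tiny):
        # effect sizes at one vertex across 7 datasets; >= 0.05 counts
        vals = [0.06, 0.07, 0.06, 0.05, 0.06, 0.06, 0.04]
        maps = _maps_from_vertex_values(
            [np.full(mesh_tiny.n_vertices, v) for v in vals]
        )
        overlap = build_overlap_map(maps, threshold=0.05)
        assert overlap.leftward[0] == 6
        assert overlap.rightward[0] == 0

    def test_all_zero_maps_give_zero_counts(self, mesh_tiny):
        maps = _maps_from_vertex_values([np.zeros(42)] * 3)
        overlap = build_overlap_map(maps, threshold=0.05)
        assert overlap.leftward.sum() == 0 and overlap.rightward.sum() == 0

    def test_directions_separated(self, mesh_tiny):
        maps = _maps_from_vertex_values([np.full(42, 0.1), np.full(42, -0.1)])
        overlap = build_overlap_map(maps, threshold=0.05)
        assert overlap.leftward[0] == 1 and overlap.rightward[0] == 1

    def test_mesh_mismatch_rejected(self, mesh_tiny):
        maps = _maps_from_vertex_values([np.zeros(42), np.zeros(43)])
        with pytest.raises(ClusterError):
            build_overlap_map(maps, threshold=0.05)


def _flood_fill_oracle(mesh, members):
    """Brute-force connected components by repeated neighbour expansion."""
    members = set(int(v) for v in members)
    edges = mesh.edges()
    adj = {}
    for a, b in edges:
        adj.setdefault(int(a), set()).add(int(b))
        adj.setdefault(int(b), set()).add(int(a))
    comps = []
    unseen = set(members)
    while unseen:
        stack = [unseen.pop()]
        comp = {stack[0]}
        while stack:
            v = stack.pop()
            for u in adj.get(v, ()):
                if u in members and u not in comp:
                    comp.add(u)
                    stack.append(u)
        unseen -= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestDelineate:
    def test_matches_flood_fill_oracle_on_small_mesh(self, mesh_small):
        rng = np.random.default_rng(3)
        for _ in range(5):
            field = np.where(rng.random(mesh_small.n_vertices) < 0.3, 0.2, 0.0)
            maps = _maps_from_vertex_values([field] * 3)
            overlap = build_overlap_map(maps, threshold=0.05)
            cset = delineate_clusters(overlap, mesh_small, min_overlap=3,
                                      min_area=0.0)
            got = {
                frozenset(int(v) for v in c.vertices)
                for c in cset
                if c.direction == "leftward"
            }
            expected = _flood_fill_oracle(
                mesh_small, np.flatnonzero(field >= 0.05)
            )
            assert got == expected

    def test_recovers_two_planted_patches(self, mesh_default, consensus_run):
        datasets, truth = consensus_run
        maps = [mean_ai_map(obs)[0] for obs in datasets]
        overlap = build_overlap_map(maps, threshold=0.05)
        cset = delineate_clusters(overlap, mesh_default, 6, 200.0)
        assert len(cset) == 2
        tl = np.flatnonzero(truth.patches[0]["field"] >= 0.05)
        tr = np.flatnonzero(truth.patches[1]["field"] <= -0.05)
        left = next(c for c in cset if c.direction == "leftward")
        right = next(c for c in cset if c.direction == "rightward")
        assert jaccard(left.vertices, tl) >= 0.9
        assert jaccard(right.vertices, tr) >= 0.9

    def test_five_of_seven_patch_excluded(self, mesh_default, consensus_run):
        datasets, truth = consensus_run
        maps = [mean_ai_map(obs)[0] for obs in datasets]
        overlap = build_overlap_map(maps, threshold=0.05)
        cset = delineate_clusters(overlap, mesh_default, 6, 200.0)
        partial = np.flatnonzero(truth.patches[2]["field"] >= 0.05)
        for c in cset:
            assert jaccard(c.vertices, partial) < 0.1

    def test_small_patch_dropped_by_area_filter(self, mesh_default,
                                                consensus_run):
        datasets, truth = consensus_run
        maps = [mean_ai_map(obs)[0] for obs in datasets]
        overlap = build_overlap_map(maps, threshold=0.05)
        # without the size filter the small patch survives the overlap rule
        unfiltered = delineate_clusters(overlap, mesh_default, 6, 0.0)
        small = np.flatnonzero(truth.patches[3]["field"] >= 0.05)
        hits = [c for c in unfiltered if jaccard(c.vertices, small) > 0.3]
        assert len(hits) == 1
        assert hits[0].area_mm2 < 200.0
        filtered = delineate_clusters(overlap, mesh_default, 6, 200.0)
        assert all(jaccard(c.vertices, small) < 0.3 for c in filtered)

    def test_monotone_in_min_overlap_and_min_area(self, mesh_default,
                                                  consensus_run):
        datasets, _ = consensus_run
        maps = [mean_ai_map(obs)[0] for obs in datasets]
        overlap = build_overlap_map(maps, threshold=0.05)
        prev_total = None
        for min_overlap in (4, 5, 6, 7):
            cset = delineate_clusters(overlap, mesh_default, min_overlap, 0.0)
            total = sum(len(c.vertices) for c in cset)
            if prev_total is not None:
                assert total <= prev_total
            prev_total = total
        n_loose = len(delineate_clusters(overlap, mesh_default, 6, 0.0))
        n_tight = len(delineate_clusters(overlap, mesh_default, 6, 500.0))
        assert n_tight <= n_loose

    def test_empty_supra_threshold_returns_empty_set(self, mesh_tiny):
        maps = _maps_from_vertex_values([np.zeros(42)] * 3)
        overlap = build_overlap_map(maps, threshold=0.05)
        cset = delineate_clusters(overlap, mesh_tiny, 3, 0.0)
        assert len(cset) == 0


class TestExtractAndProportion:
    def test_constant_map_and_single_vertex_cluster(self, mesh_small):
        from cortasym.clusters import Cluster, ConsensusClusterSet
        from cortasym.simulate import VertexObservation

        obs = VertexObservation(
            "s1", "d0", 1, 30.0, 0, "sc", 1.5e6,
            lh_map=np.full(mesh_small.n_vertices, 3.0),
            rh_map=np.full(mesh_small.n_vertices, 2.0),
        )
        cset = ConsensusClusterSet(
            clusters=[
                Cluster("L1", "leftward", np.array([0, 1, 2]), 10.0),
                Cluster("L2", "leftward", np.array([5]), 3.0),
            ],
            mesh=mesh_small,
        )
        table = extract_cluster_values(cset, [obs])
        assert (table["lh_mean"] == 3.0).all()
        assert (table["rh_mean"] == 2.0).all()
        np.testing.assert_allclose(table["ai"], 2 * (3 - 2) / 5)

    def test_vectorized_equals_per_vertex_loop(self, mesh_small):
        datasets, _ = simulate_datasets(
            mesh_small, n_datasets=2, n_subjects_per_dataset=3, seed=8
        )
        from cortasym.clusters import Cluster, ConsensusClusterSet

        verts = np.array([4, 9, 17, 30])
        cset = ConsensusClusterSet(
            [Cluster("L1", "leftward", verts, 1.0)], mesh_small
        )
        table = extract_cluster_values(cset, datasets[0][:2])
        for i, obs in enumerate(datasets[0][:2]):
            acc = 0.0
            for v in verts:
                acc += obs.lh_map[v]
            assert table["lh_mean"].iloc[i] == pytest.approx(
                acc / len(verts), abs=1e-12
            )

    def test_proportion_noiseless_and_sign_flip(self, mesh_small):
        datasets, _ = simulate_datasets(
            mesh_small, n_datasets=2, n_subjects_per_dataset=10,
            noise_sd=0.0, seed=9,
        )
        from cortasym.clusters import Cluster, ConsensusClusterSet

        # vertices inside the first (leftward) default patch
        from cortasym.simulate import DEFAULT_PATCHES, patch_field

        field = patch_field(mesh_small, DEFAULT_PATCHES[0])
        verts = np.flatnonzero(field >= 0.05)
        cset = ConsensusClusterSet(
            [Cluster("L1", "leftward", verts, 1.0)], mesh_small
        )
        table = extract_cluster_values(cset, datasets[0])
        props = proportion_lateralized(table, {"L1": "leftward"})
        assert (props["proportion"] == 1.0).all()
        flipped = table.copy()
        flipped["ai"] = -flipped["ai"]
        props_f = proportion_lateralized(flipped, {"L1": "leftward"})
        assert (props_f["proportion"] == 0.0).all()

    def test_empty_cluster_rejected(self, mesh_small):
        from cortasym.clusters import Cluster, ConsensusClusterSet
        from cortasym.simulate import VertexObservation

        obs = VertexObservation(
            "s1", "d0", 1, 30.0, 0, "sc", 1.5e6,
            lh_map=np.ones(mesh_small.n_vertices),
            rh_map=np.ones(mesh_small.n_vertices),
        )
        cset = ConsensusClusterSet(
            [Cluster("L1", "leftward", np.array([], dtype=int), 0.0)],
            mesh_small,
        )
        with pytest.raises(ClusterError):
            extract_cluster_values(cset, [obs])
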