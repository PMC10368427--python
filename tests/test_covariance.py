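"""Interregional covariance: residualization, Mantel, geodesics, global factor."""

import numpy as np
import pandas as pd
import pytest

from cortasym.covariance import (
    AsymCorrMatrix,
    CovarianceError,
    correlation_matrix,
    distance_correlation_test,
    flag_multivariate_outliers,
    geodesic_cluster_distance,
    global_structure,
    mantel_test,
    residualize_ai,
)


def _cluster_table(rng, n=400, clusters=("L1", "L2", "R1"), rho=0.0,
                   directions=None):
    """Cross-sectional cluster table with an optional shared latent factor."""
    g = rng.standard_normal(n)
    age = rng.uniform(20, 80, n)
    sex = rng.integers(0, 2, n)
    rows = []
    for cid in clusters:
        base = 0.1 if cid.startswith("L") else -0.1
        ai = (
            base
            + np.sqrt(rho) * g * (1 if cid.startswith("L") else 1)
            + np.sqrt(1 - rho) * rng.standard_normal(n)
        )
        ai = ai + 0.002 * age + 0.05 * sex  # covariate structure to remove
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"s{i}",
                    "dataset_id": "d0",
                    "timepoint": 1,
                    "age": age[i],
                    "sex": int(sex[i]),
                    "scanner": "sc0",
                    "icv": 1.5e6,
                    "cluster_id": cid,
                    "ai": ai[i],
                }
            )
    return pd.DataFrame(rows)


class TestResidualize:
    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(0)
        tab = _cluster_table(rng)
        res = residualize_ai(tab)
        merged = res.merge(
            tab[tab.cluster_id == "L1"][["subject_id", "age", "sex"]],
            on="subject_id",
        )
        for cov in ("age", "sex"):
            r = np.corrcoef(merged["L1"], merged[cov].astype(float))[0, 1]
            assert abs(r) < 1e-10

    def test_rightward_inversion_makes_mean_positive(self):
        rng = np.random.default_rng(1)
        tab = _cluster_table(rng)
        res = residualize_ai(tab, directions={"R1": "rightward"})
        raw = residualize_ai(tab)
        np.testing.assert_allclose(res["R1"], -raw["R1"], atol=1e-12)

    def test_longitudinal_mixed_residualization_recovers_covariance(self):
        # repeated visits with a subject intercept: the planted cross-
        # cluster correlation must survive residualization + averaging
        rng = np.random.default_rng(2)
        n = 300
        g = rng.standard_normal(n)
        rows = []
        for i in range(n):
            b = {c: 0.5 * g[i] + 0.5 * rng.standard_normal()
                 for c in ("L1", "L2")}
            for t in range(2):
                age = 30 + 10 * t + rng.uniform(0, 3)
                for cid in ("L1", "L2"):
                    rows.append(
                        {
                            "subject_id": f"s{i}", "dataset_id": "d0",
                            "timepoint": t + 1, "age": age, "sex": i % 2,
                            "scanner": "sc0", "icv": 1.5e6,
                            "cluster_id": cid,
                            "ai": 0.1 + 0.003 * age + b[cid]
                            + 0.3 * rng.standard_normal(),
                        }
                    )
        res = residualize_ai(pd.DataFrame(rows))
        m = correlation_matrix(res)
        # planted subject-level correlation is 0.25/sqrt(0.5*0.5)=0.5,
        # attenuated by residual noise
        assert m.matrix[0, 1] > 0.3

    def test_constant_covariate_dropped_not_fatal(self):
        rng = np.random.default_rng(3)
        tab = _cluster_table(rng)
        tab["sex"] = 1
        res = residualize_ai(tab)
        assert res.notna().all().all()


class TestCorrelationMatrix:
    def test_duplicated_cluster_gives_unit_offdiagonal(self):
        rng = np.random.default_rng(4)
        res = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(50)],
                "dataset_id": "d0",
                "A": rng.standard_normal(50),
            }
        )
        res["B"] = res["A"]
        m = correlation_matrix(res)
        assert m.matrix[0, 1] == pytest.approx(1.0)

    def test_planted_latent_factor_recovered(self):
        rng = np.random.default_rng(5)
        tab = _cluster_table(rng, n=2000, clusters=("L1", "L2"), rho=0.4)
        res = residualize_ai(tab)
        m = correlation_matrix(res)
        assert m.matrix[0, 1] == pytest.approx(0.4, abs=0.05)

    def test_independent_clusters_near_zero(self):
        rng = np.random.default_rng(6)
        tab = _cluster_table(rng, n=1000, rho=0.0)
        res = residualize_ai(tab)
        m = correlation_matrix(res)
        off = m.matrix[np.triu_indices(3, 1)]
        assert np.mean(np.abs(off)) < 3 / np.sqrt(1000)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(7)
        tab = _cluster_table(rng, n=200)
        res = residualize_ai(tab)
        scaled = res.copy()
        scaled["L1"] = 5.0 * scaled["L1"] + 2.0
        m1 = correlation_matrix(res)
        m2 = correlation_matrix(scaled)
        np.testing.assert_allclose(m1.matrix, m2.matrix, atol=1e-12)


class TestMantel:
    @staticmethod
    def _random_corr(rng, k=4, p=5):
        return np.corrcoef(rng.standard_normal((k, p)))

    def test_identical_matrices_attain_minimum_p_exhaustive(self):
        rng = np.random.default_rng(8)
        m = self._random_corr(rng, k=4)
        res = mantel_test(m, m, exhaustive=True)
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0 / 24)  # only the identity ties

    def test_identical_matrices_sampled_p_is_one_over_nperm_plus_one(self):
        rng = np.random.default_rng(9)
        m = self._random_corr(rng, k=10, p=12)
        res = mantel_test(m, m, n_perm=999, seed=1)
        assert res["p"] == pytest.approx(1.0 / 1000)

    def test_joint_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        a = self._random_corr(rng, k=6)
        b = self._random_corr(rng, k=6)
        perm = rng.permutation(6)
        r1 = mantel_test(a, b, n_perm=200, seed=3)["r"]
        r2 = mantel_test(a[np.ix_(perm, perm)], b[np.ix_(perm, perm)],
                         n_perm=200, seed=3)["r"]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(CovarianceError):
            mantel_test(np.eye(4), np.eye(5), n_perm=99)

    def test_minimum_permutations_enforced(self):
        with pytest.raises(CovarianceError):
            mantel_test(np.eye(4), np.eye(4), n_perm=10)


class TestGeodesics:
    def test_adjacent_single_vertex_clusters(self, mesh_tiny):
        from cortasym.clusters import Cluster, ConsensusClusterSet

        e = mesh_tiny.edges()[0]
        cset = ConsensusClusterSet(
            [
                Cluster("A", "leftward", np.array([e[0]]), 1.0),
                Cluster("B", "rightward", np.array([e[1]]), 1.0),
            ],
            mesh_tiny,
        )
        gd = geodesic_cluster_distance(cset)
        expected = np.linalg.norm(
            mesh_tiny.vertex_coords[e[0]] - mesh_tiny.vertex_coords[e[1]]
        )
        assert gd.matrix[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_matches_networkx_oracle(self, mesh_tiny):
        import networkx as nx

        from cortasym.clusters import Cluster, ConsensusClusterSet

        G = nx.Graph()
        for a, b in mesh_tiny.edges():
            w = np.linalg.norm(
                mesh_tiny.vertex_coords[a] - mesh_tiny.vertex_coords[b]
            )
            G.add_edge(int(a), int(b), weight=w)
        va, vb = np.array([0, 1]), np.array([20, 30])
        cset = ConsensusClusterSet(
            [
                Cluster("A", "leftward", va, 1.0),
                Cluster("B", "rightward", vb, 1.0),
            ],
            mesh_tiny,
        )
        gd = geodesic_cluster_distance(cset)
        expected = np.mean(
            [
                nx.shortest_path_length(G, int(i), int(j), weight="weight")
                for i in va
                for j in vb
            ]
        )
        assert gd.matrix[0, 1] == pytest.approx(expected, abs=1e-9)


class TestDistanceCorrelation:
    def _setup(self, rng, decay):
        k = 12
        ids = [f"L{i}" for i in range(6)] + [f"R{i}" for i in range(6)]
        directions = {c: ("leftward" if c.startswith("L") else "rightward")
                      for c in ids}
        dist = np.zeros((k, k))
        corr = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                d = rng.uniform(10, 150)
                dist[i, j] = dist[j, i] = d
                r = np.tanh(decay * (1 - d / 150) + 0.05 * rng.standard_normal())
                corr[i, j] = corr[j, i] = r
        return (
            AsymCorrMatrix(ids, corr),
            type("GD", (), {"cluster_ids": ids, "matrix": dist})(),
            directions,
        )

    def test_planted_decay_detected(self):
        rng = np.random.default_rng(11)
        corr, dist, directions = self._setup(rng, decay=0.8)
        res = distance_correlation_test(corr, dist, directions, "opposite")
        assert res["rho"] < 0
        assert res["p"] < 0.05
        assert res["n_pairs"] == 36

    def test_too_few_pairs_rejected(self):
        rng = np.random.default_rng(12)
        corr, dist, directions = self._setup(rng, decay=0.0)
        only_two = {c: d for c, d in list(directions.items())}
        for c in list(only_two):
            if c not in ("L0", "L1"):
                only_two[c] = "leftward" if c == "L0" else only_two[c]
        with pytest.raises(CovarianceError):
            # same-rightward pairs among just 2 rightward clusters: 1 pair
            small = AsymCorrMatrix(["R0", "R1"], np.eye(2))
            gd = type("GD", (), {"cluster_ids": ["R0", "R1"],
                                 "matrix": np.ones((2, 2))})()
            distance_correlation_test(
                small, gd, {"R0": "rightward", "R1": "rightward"},
                "same-rightward",
            )


class TestGlobalStructure:
    @staticmethod
    def _residuals(rng, n=2000, k_left=5, k_right=5, load=0.0):
        cols = {}
        g = rng.standard_normal(n)
        ids = []
        for i in range(k_left):
            cols[f"L{i}"] = load * g + np.sqrt(1 - load**2) * rng.standard_normal(n)
            ids.append(f"L{i}")
        for i in range(k_right):
            # global factor loads on raw AI in the same direction; after
            # rightward inversion the sign flips
            cols[f"R{i}"] = -(
                load * g + np.sqrt(1 - load**2) * rng.standard_normal(n)
            )
            ids.append(f"R{i}")
        df = pd.DataFrame(cols)
        df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
        df.insert(1, "dataset_id", "d0")
        directions = {c: ("leftward" if c.startswith("L") else "rightward")
                      for c in ids}
        areas = {c: 100.0 + 10 * i for i, c in enumerate(ids)}
        return df, directions, areas

    def test_planted_factor_share_recovered(self):
        rng = np.random.default_rng(13)
        load = 0.55
        df, directions, areas = self._residuals(rng, load=load)
        res = global_structure(df, directions, areas)
        expected = (10 * load**2 + (1 - load**2)) / 10
        assert res["pc1_variance_share"] == pytest.approx(expected, abs=0.03)

    def test_anticorrelated_left_right_factor(self):
        rng = np.random.default_rng(14)
        df, directions, areas = self._residuals(rng, load=0.55)
        res = global_structure(df, directions, areas)
        assert res["left_right_corr_weighted"] < 0
        assert res["left_right_p_weighted"] < 1e-6
        assert res["left_right_corr_unweighted"] < 0

    def test_insufficient_clusters_rejected(self):
        rng = np.random.default_rng(15)
        df, directions, areas = self._residuals(rng, k_right=1)
        with pytest.raises(CovarianceError):
            global_structure(df, directions, areas)


def test_multivariate_outlier_flagging():
    rng = np.random.default_rng(16)
    df = pd.DataFrame(rng.standard_normal((500, 3)), columns=["A", "B", "C"])
    df.insert(0, "subject_id", [f"s{i}" for i in range(500)])
    df.insert(1, "dataset_id", "d0")
    df.loc[0, ["A", "B", "C"]] = [15.0, -15.0, 15.0]
    flags = flag_multivariate_outliers(df)
    assert flags[0]
    assert flags.sum() <= 5
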