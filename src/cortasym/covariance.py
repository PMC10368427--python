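"""Interregional asymmetry covariance: correlation matrices, Mantel
replication tests, geodesic-distance analysis, and the global single-factor
analysis.

Per-cluster asymmetry indices are first sign-aligned (AIs in clusters with
rightward mean asymmetry are inverted so positive values always mean "more
asymmetric in the population direction"), residualized for age, sex and
scanner — with a subject random intercept where subjects repeat — and
reduced to one value per subject.  Pairwise Pearson correlations over
subjects give the cluster-cluster matrix; replication between datasets is
assessed with a one-sided Mantel permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import ConsensusClusterSet
from .mesh import SurfaceMesh


class CovarianceError(ValueError):
    pass


@dataclass
class AsymCorrMatrix:
    cluster_ids: list[str]
    matrix: np.ndarray
    inverted_rightward: bool = True

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.cluster_ids),) * 2:
            raise CovarianceError("matrix shape does not match cluster ids")
        self.matrix = m


@dataclass
class GeodesicDistances:
    cluster_ids: list[str]
    matrix: np.ndarray  # mean cross-cluster vertex-pair distance, mm


# --------------------------------------------------------------------------
# residualization
# --------------------------------------------------------------------------


def _covariate_design(df: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(df))]
    for cov in covariates:
        if cov == "scanner":
            levels = pd.unique(df["scanner"])
            for lev in levels[1:]:
                col = (df["scanner"].to_numpy() == lev).astype(float)
                if col.std() > 0:
                    cols.append(col)
        else:
            col = df[cov].to_numpy(dtype=float)
            if col.std() > 0:  # constant covariates dropped, not fatal
                cols.append(col)
    return np.column_stack(cols)


def residualize_ai(
    table: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "scanner"),
    directions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Covariate-residualized, sign-aligned AI per subject per cluster.

    Fits, per cluster, a collated model of AI on the covariates; when any
    subject has repeated observations a subject random intercept is added
    (statsmodels MixedLM), otherwise plain OLS.  Residuals retain the
    subject-level deviation (only fixed covariate effects are removed),
    are averaged within subject, and rightward clusters' values are
    multiplied by −1.

    Returns a frame with subject_id, dataset_id and one column per cluster.
    """
    out = None
    for cid, grp in table.groupby("cluster_id", sort=True):
        X = _covariate_design(grp, covariates)
        y = grp["ai"].to_numpy(dtype=float)
        has_repeats = grp["subject_id"].duplicated().any()
        if has_repeats:
            import statsmodels.api as sm

            model = sm.MixedLM(y, X, groups=grp["subject_id"].to_numpy())
            fit = model.fit(reml=True, method="lbfgs")
            resid = y - X @ fit.fe_params
        else:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
        if directions and directions.get(cid) == "rightward":
            resid = -resid
        part = (
            pd.DataFrame(
                {
                    "subject_id": grp["subject_id"].to_numpy(),
                    "dataset_id": grp["dataset_id"].to_numpy(),
                    cid: resid,
                }
            )
            .groupby(["subject_id", "dataset_id"], sort=True)
            .mean()
            .reset_index()
        )
        out = part if out is None else out.merge(
            part, on=["subject_id", "dataset_id"], how="outer"
        )
    return out


def correlation_matrix(
    residuals: pd.DataFrame, dataset_id: str | None = None
) -> AsymCorrMatrix:
    """Pairwise Pearson correlation of residual AIs over subjects."""
    df = residuals
    if dataset_id is not None:
        df = df[df["dataset_id"] == dataset_id]
    cluster_cols = [
        c for c in df.columns if c not in ("subject_id", "dataset_id")
    ]
    if len(cluster_cols) < 2 or len(df) < 3:
        raise CovarianceError("need >= 2 clusters and >= 3 subjects")
    vals = df[cluster_cols].to_numpy(dtype=float)
    sd = vals.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.corrcoef(vals, rowvar=False)
    m[sd == 0, :] = np.nan
    m[:, sd == 0] = np.nan
    np.fill_diagonal(m, np.where(sd == 0, np.nan, 1.0))
    return AsymCorrMatrix(cluster_ids=cluster_cols, matrix=m)


# --------------------------------------------------------------------------
# Mantel replication test
# --------------------------------------------------------------------------


def _lower(m: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def mantel_test(
    m1: AsymCorrMatrix | np.ndarray,
    m2: AsymCorrMatrix | np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    exhaustive: bool = False,
) -> dict:
    """One-sided Mantel permutation test between two square matrices.

    r is the Pearson correlation of the lower-triangle entries; the null
    distribution permutes one matrix's row/column labels jointly, and
    p = (#{permuted r >= observed} + 1) / (n_perm + 1).  With
    ``exhaustive=True`` (feasible for small matrices) all k! label
    permutations are enumerated instead and p = #{r_perm >= r_obs} / k!,
    the identity permutation included.
    """
    a = m1.matrix if isinstance(m1, AsymCorrMatrix) else np.asarray(m1, float)
    b = m2.matrix if isinstance(m2, AsymCorrMatrix) else np.asarray(m2, float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise CovarianceError("matrices must be square and of equal size")
    if (
        isinstance(m1, AsymCorrMatrix)
        and isinstance(m2, AsymCorrMatrix)
        and m1.cluster_ids != m2.cluster_ids
    ):
        raise CovarianceError("cluster sets differ between matrices")
    if n_perm < 99:
        raise CovarianceError("n_perm must be at least 99")
    k = a.shape[0]
    va = _lower(a)
    va = (va - va.mean()) / va.std()
    vb = _lower(b)
    r_obs = float(np.corrcoef(va, _standardize(vb))[0, 1])

    if exhaustive:
        from itertools import permutations as _perms
        from math import factorial

        perms = np.array(list(_perms(range(k))))
        i, j = np.tril_indices(k, k=-1)
        flat = b[perms[:, i], perms[:, j]]
        flat = (flat - flat.mean(axis=1, keepdims=True)) / flat.std(
            axis=1, keepdims=True
        )
        r_perm = flat @ va / len(va)
        p = np.sum(r_perm >= r_obs - 1e-12) / factorial(k)
        return {"r": r_obs, "p": float(p), "n_perm": factorial(k)}

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(k) for _ in range(n_perm)])
    i, j = np.tril_indices(k, k=-1)
    # permuted lower triangles of b, gathered in one shot
    pi, pj = perms[:, i], perms[:, j]
    flat = b[pi, pj]  # (n_perm, n_pairs)
    flat = (flat - flat.mean(axis=1, keepdims=True)) / flat.std(
        axis=1, keepdims=True
    )
    r_perm = flat @ va / len(va)
    p = (np.sum(r_perm >= r_obs - 1e-12) + 1) / (n_perm + 1)
    return {"r": r_obs, "p": float(p), "n_perm": n_perm}


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


# --------------------------------------------------------------------------
# geodesic distances and distance-correlation analysis
# --------------------------------------------------------------------------


def geodesic_cluster_distance(
    cluster_set: ConsensusClusterSet, mesh: SurfaceMesh | None = None
) -> GeodesicDistances:
    """Mean geodesic distance (mm) between all cross-cluster vertex pairs.

    Geodesics are shortest paths on the mesh edge graph weighted by
    Euclidean edge length (Dijkstra).
    """
    mesh = mesh or cluster_set.mesh
    ids = [c.cluster_id for c in cluster_set]
    verts = {c.cluster_id: c.vertices for c in cluster_set}
    n = len(ids)
    out = np.zeros((n, n))
    dist_rows = {
        cid: mesh.geodesic_from(verts[cid]) for cid in ids
    }
    for i in range(n):
        for j in range(i + 1, n):
            block = dist_rows[ids[i]][:, verts[ids[j]]]
            if not np.all(np.isfinite(block)):
                raise CovarianceError("mesh is disconnected: unreachable vertex")
            out[i, j] = out[j, i] = float(block.mean())
    return GeodesicDistances(cluster_ids=ids, matrix=out)


def distance_correlation_test(
    corr: AsymCorrMatrix,
    dist: GeodesicDistances,
    directions: dict[str, str],
    pair_filter: str = "opposite",
) -> dict:
    """Spearman correlation of cluster-pair distance with Fisher-z correlation.

    ``pair_filter`` selects which cluster pairs enter: 'opposite'
    (leftward-rightward pairs), 'same-leftward', or 'same-rightward'.
    """
    if set(corr.cluster_ids) != set(dist.cluster_ids):
        raise CovarianceError("cluster sets differ between inputs")
    ids = corr.cluster_ids
    if dist.cluster_ids != ids:  # align the distance matrix by id
        order = [dist.cluster_ids.index(c) for c in ids]
        dist = GeodesicDistances(ids, dist.matrix[np.ix_(order, order)])
    want = {
        "opposite": {"leftward", "rightward"},
        "same-leftward": {"leftward"},
        "same-rightward": {"rightward"},
    }[pair_filter]
    xs, ys = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            pair_dirs = {directions[ids[i]], directions[ids[j]]}
            if pair_dirs != want:
                continue
            r = corr.matrix[i, j]
            if np.isfinite(r):
                xs.append(dist.matrix[i, j])
                ys.append(np.arctanh(np.clip(r, -0.999999, 0.999999)))
    if len(xs) < 4:
        raise CovarianceError("fewer than 4 cluster pairs after filtering")
    rho, p = stats.spearmanr(xs, ys)
    return {"rho": float(rho), "p": float(p), "n_pairs": len(xs)}


# --------------------------------------------------------------------------
# global structure
# --------------------------------------------------------------------------


def global_structure(
    residuals: pd.DataFrame,
    directions: dict[str, str],
    cluster_areas: dict[str, float],
) -> dict:
    """Global single-factor summary of (sign-aligned) residual asymmetries.

    Reports the variance share of the first principal component of the
    z-scored residual AIs, the correlation between the (cluster-area
    weighted and unweighted) mean asymmetry across leftward clusters and
    across rightward clusters, and the correlation of the two blocks'
    first principal components.
    """
    cluster_cols = [
        c for c in residuals.columns if c not in ("subject_id", "dataset_id")
    ]
    left = [c for c in cluster_cols if directions[c] == "leftward"]
    right = [c for c in cluster_cols if directions[c] == "rightward"]
    if len(left) < 2 or len(right) < 2:
        raise CovarianceError("need >= 2 clusters of each direction")
    vals = residuals[cluster_cols].to_numpy(dtype=float)
    ok = np.all(np.isfinite(vals), axis=1)
    vals = vals[ok]
    if vals.shape[0] < 3:
        raise CovarianceError("fewer than 3 complete subjects")
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0)
    eigvals = np.linalg.eigvalsh(np.corrcoef(z, rowvar=False))[::-1]
    pc1_share = float(eigvals[0] / eigvals.sum())

    def weighted_mean(cols, weights):
        idx = [cluster_cols.index(c) for c in cols]
        w = np.asarray(weights, dtype=float)
        return vals[:, idx] @ (w / w.sum())

    def pc1_scores(cols):
        idx = [cluster_cols.index(c) for c in cols]
        block = z[:, idx]
        _, _, vt = np.linalg.svd(block - block.mean(axis=0), full_matrices=False)
        return block @ vt[0]

    results = {"pc1_variance_share": pc1_share, "n": int(vals.shape[0])}
    for label, wl, wr in (
        ("weighted", [cluster_areas[c] for c in left],
         [cluster_areas[c] for c in right]),
        ("unweighted", np.ones(len(left)), np.ones(len(right))),
    ):
        r, p = stats.pearsonr(weighted_mean(left, wl), weighted_mean(right, wr))
        results[f"left_right_corr_{label}"] = float(r)
        results[f"left_right_p_{label}"] = float(p)
    r, p = stats.pearsonr(pc1_scores(left), pc1_scores(right))
    results["pc1_left_vs_right_corr"] = float(r)
    results["pc1_left_vs_right_p"] = float(p)
    return results


def flag_multivariate_outliers(
    residuals: pd.DataFrame, quantile: float = 0.999
) -> np.ndarray:
    """Robust-distance outlier flags (squared Mahalanobis > χ² quantile).

    Optional screen (off by default in the pipeline) mirroring ad-hoc
    removal of extreme multivariate observations before correlation.
    """
    cols = [c for c in residuals.columns if c not in ("subject_id", "dataset_id")]
    x = residuals[cols].to_numpy(dtype=float)
    mu = np.nanmean(x, axis=0)
    xc = x - mu
    cov = np.cov(xc, rowvar=False)
    d2 = np.einsum("ij,jk,ik->i", xc, np.linalg.pinv(cov), xc)
    return d2 > stats.chi2.ppf(quantile, df=len(cols))
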