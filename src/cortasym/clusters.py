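"""Cross-dataset consensus delineation of asymmetric surface regions.

Per-dataset mean AI maps are thresholded by absolute effect size
(conventionally 0.05 for surface area, 0.01 for thickness), binarized per
direction, and summed across datasets.  Vertices exceeding the threshold in
at least ``min_overlap`` datasets (6 of 7 in the reference configuration)
are partitioned into edge-connected components, and components smaller than
``min_area`` (200 mm²) are dropped.  The surviving components are the
robust asymmetry clusters from which per-subject values are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .asymmetry import AIMap, compute_ai
from .mesh import SurfaceMesh
from .simulate import VertexObservation

DIRECTIONS = ("leftward", "rightward")


class ClusterError(ValueError):
    pass


@dataclass
class OverlapMap:
    """Per-direction count of datasets exceeding the AI threshold."""

    leftward: np.ndarray
    rightward: np.ndarray
    n_datasets: int
    threshold: float


@dataclass
class Cluster:
    cluster_id: str
    direction: str
    vertices: np.ndarray
    area_mm2: float
    metric: str = "area"


@dataclass
class ConsensusClusterSet:
    clusters: list[Cluster]
    mesh: SurfaceMesh

    def __iter__(self):
        return iter(self.clusters)

    def __len__(self):
        return len(self.clusters)

    def by_id(self, cluster_id: str) -> Cluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)


def build_overlap_map(ai_maps: Sequence[AIMap], threshold: float) -> OverlapMap:
    """Binarize each map at ±threshold (closed at the threshold) and sum.

    A dataset contributes at most one direction per vertex; undefined (NaN)
    vertices contribute to neither.
    """
    if threshold <= 0:
        raise ClusterError("threshold must be positive")
    shapes = {m.ai.shape for m in ai_maps}
    if len(shapes) != 1:
        raise ClusterError("AI maps are not on a common mesh")
    stack = np.vstack([m.ai for m in ai_maps])
    with np.errstate(invalid="ignore"):
        left = (stack >= threshold).sum(axis=0)
        right = (stack <= -threshold).sum(axis=0)
    return OverlapMap(
        leftward=left.astype(int),
        rightward=right.astype(int),
        n_datasets=len(ai_maps),
        threshold=threshold,
    )


def _connected_components(mesh: SurfaceMesh, members: np.ndarray) -> list[np.ndarray]:
    """Edge-connected components of a vertex subset, via the subgraph."""
    if members.size == 0:
        return []
    sub = mesh.adjacency().tocsr()[members][:, members]
    n, labels = connected_components(sub, directed=False)
    return [members[labels == k] for k in range(n)]


def delineate_clusters(
    overlap: OverlapMap,
    mesh: SurfaceMesh,
    min_overlap: int = 6,
    min_area: float = 200.0,
    metric: str = "area",
) -> ConsensusClusterSet:
    """Extract robust clusters from an overlap map.

    Pipeline order: apply the overlap rule per direction, split the
    supra-threshold vertex set into edge-connected components, then drop
    components whose summed vertex area falls below ``min_area`` mm².
    Returns an empty set (not an error) when nothing survives.
    """
    if min_overlap > overlap.n_datasets:
        raise ClusterError("min_overlap exceeds the number of datasets")
    if min_area < 0:
        raise ClusterError("min_area must be non-negative")
    clusters: list[Cluster] = []
    for direction in DIRECTIONS:
        counts = getattr(overlap, direction)
        if counts.shape[0] != mesh.n_vertices:
            raise ClusterError("overlap map does not match the mesh")
        members = np.flatnonzero(counts >= min_overlap)
        comps = _connected_components(mesh, members)
        # deterministic ordering: largest area first, then lowest vertex id
        comps.sort(key=lambda v: (-mesh.vertex_area[v].sum(), v.min()))
        for comp in comps:
            area = float(mesh.vertex_area[comp].sum())
            if area < min_area:
                continue
            clusters.append(
                Cluster(
                    cluster_id=f"{direction[0].upper()}{len(clusters) + 1}",
                    direction=direction,
                    vertices=np.sort(comp),
                    area_mm2=area,
                    metric=metric,
                )
            )
    return ConsensusClusterSet(clusters=clusters, mesh=mesh)


def extract_cluster_values(
    cluster_set: ConsensusClusterSet,
    observations: Sequence[VertexObservation],
) -> pd.DataFrame:
    """Per-observation cluster table: hemispheric means and recomputed AI.

    lh_mean/rh_mean are unweighted means over a cluster's member vertices;
    the AI is recomputed from the means (not averaged over vertex AIs).
    """
    n_vert = cluster_set.mesh.n_vertices
    rows = []
    for cl in cluster_set:
        if cl.vertices.size == 0:
            raise ClusterError(f"cluster {cl.cluster_id} is empty")
    for obs in observations:
        if obs.lh_map.shape[0] != n_vert:
            raise ClusterError("observation not on the clusters' mesh")
        for cl in cluster_set:
            lh = float(obs.lh_map[cl.vertices].mean())
            rh = float(obs.rh_map[cl.vertices].mean())
            rows.append(
                {
                    "subject_id": obs.subject_id,
                    "dataset_id": obs.dataset_id,
                    "timepoint": obs.timepoint,
                    "age": obs.age,
                    "sex": obs.sex,
                    "scanner": obs.scanner_id,
                    "icv": obs.icv,
                    "cluster_id": cl.cluster_id,
                    "lh_mean": lh,
                    "rh_mean": rh,
                    "ai": compute_ai(lh, rh),
                }
            )
    return pd.DataFrame(rows)


def proportion_lateralized(
    table: pd.DataFrame, directions: dict[str, str]
) -> pd.DataFrame:
    """Proportion of subjects lateralized in each cluster's consensus direction.

    Uses each subject's first timepoint; an AI of exactly 0 counts as
    non-matching.  Returns one row per (dataset, cluster).
    """
    first = (
        table.sort_values("timepoint")
        .groupby(["dataset_id", "cluster_id", "subject_id"], sort=True)
        .first()
        .reset_index()
    )
    out = []
    for (ds, cid), grp in first.groupby(["dataset_id", "cluster_id"], sort=True):
        want = directions[cid]
        match = grp["ai"] > 0 if want == "leftward" else grp["ai"] < 0
        out.append(
            {
                "dataset_id": ds,
                "cluster_id": cid,
                "direction": want,
                "n": len(grp),
                "proportion": float(match.mean()),
            }
        )
    return pd.DataFrame(out)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap of two vertex index sets."""
    sa, sb = set(map(int, a)), set(map(int, b))
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)
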