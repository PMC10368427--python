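"""Plain-text serialization: TSV tables, per-vertex maps, YAML summaries.

Meshes travel as ASCII PLY (see :mod:`cortasym.mesh`); observations and all
derived tables as TSV with a header row; genotype dosages as a subjects ×
SNPs TSV matrix (with a minimal GT-only VCF reader as an alternative
input); ground truth as YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .clusters import Cluster, ConsensusClusterSet
from .mesh import SurfaceMesh
from .simulate import GenotypePanel, VertexObservation


def write_vertex_map(values: np.ndarray, path, extra: dict | None = None):
    df = pd.DataFrame({"vertex_index": np.arange(len(values)), "value": values})
    for k, v in (extra or {}).items():
        df[k] = v
    df.to_csv(path, sep="\t", index=False)


def read_vertex_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_observations(obs_list: Sequence[VertexObservation], path) -> None:
    """One TSV per dataset: metadata columns then v0..vN per hemisphere."""
    rows = []
    for o in obs_list:
        row = {
            "subject_id": o.subject_id,
            "dataset_id": o.dataset_id,
            "timepoint": o.timepoint,
            "age": o.age,
            "sex": o.sex,
            "scanner_id": o.scanner_id,
            "icv": o.icv,
            "metric": o.metric,
        }
        row.update({f"lh_v{i}": v for i, v in enumerate(o.lh_map)})
        row.update({f"rh_v{i}": v for i, v in enumerate(o.rh_map)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_observations(path) -> list[VertexObservation]:
    df = pd.read_csv(path, sep="\t")
    lh_cols = sorted(
        (c for c in df.columns if c.startswith("lh_v")),
        key=lambda c: int(c[4:]),
    )
    rh_cols = sorted(
        (c for c in df.columns if c.startswith("rh_v")),
        key=lambda c: int(c[4:]),
    )
    return [
        VertexObservation(
            subject_id=str(r["subject_id"]),
            dataset_id=str(r["dataset_id"]),
            timepoint=int(r["timepoint"]),
            age=float(r["age"]),
            sex=int(r["sex"]),
            scanner_id=str(r["scanner_id"]),
            icv=float(r["icv"]),
            lh_map=r[lh_cols].to_numpy(dtype=float),
            rh_map=r[rh_cols].to_numpy(dtype=float),
            metric=str(r["metric"]),
        )
        for _, r in df.iterrows()
    ]


def write_clusters(cluster_set: ConsensusClusterSet, tsv_path, yaml_path=None):
    rows = [
        {"cluster_id": c.cluster_id, "direction": c.direction, "vertex_index": v}
        for c in cluster_set
        for v in c.vertices
    ]
    pd.DataFrame(rows, columns=["cluster_id", "direction", "vertex_index"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    if yaml_path is not None:
        summary = {
            "n_clusters": len(cluster_set),
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "direction": c.direction,
                    "n_vertices": int(len(c.vertices)),
                    "area_mm2": float(c.area_mm2),
                }
                for c in cluster_set
            ],
        }
        Path(yaml_path).write_text(yaml.safe_dump(summary, sort_keys=False))


def read_clusters(tsv_path, mesh: SurfaceMesh, metric="area") -> ConsensusClusterSet:
    df = pd.read_csv(tsv_path, sep="\t")
    clusters = []
    for (cid, direction), grp in df.groupby(
        ["cluster_id", "direction"], sort=True
    ):
        verts = np.sort(grp["vertex_index"].to_numpy(dtype=np.int64))
        clusters.append(
            Cluster(
                cluster_id=str(cid),
                direction=str(direction),
                vertices=verts,
                area_mm2=float(mesh.vertex_area[verts].sum()),
                metric=metric,
            )
        )
    return ConsensusClusterSet(clusters=clusters, mesh=mesh)


def write_dosage(panel: GenotypePanel, path) -> None:
    df = pd.DataFrame(
        panel.dosage,
        columns=[f"snp{i}" for i in range(panel.n_snps)],
    )
    df.insert(0, "subject_id", [f"s{i}" for i in range(panel.n_subjects)])
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    dosage = df.drop(columns=["subject_id"]).to_numpy(dtype=float)
    freq = np.nanmean(dosage, axis=0) / 2.0
    return GenotypePanel(dosage=dosage, allele_freq=freq)


def read_vcf_gt(path) -> GenotypePanel:
    """Minimal VCF reader: diploid GT field only, '.' treated as missing."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            fmt = parts[8].split(":")
            gi = fmt.index("GT")
            snp = []
            for sample in parts[9:]:
                gt = sample.split(":")[gi].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    snp.append(np.nan)
                else:
                    snp.append(float(sum(int(a) > 0 for a in alleles)))
            rows.append(snp)
    dosage = np.asarray(rows, dtype=float).T  # subjects x SNPs
    freq = np.nanmean(dosage, axis=0) / 2.0
    return GenotypePanel(dosage=dosage, allele_freq=freq)


def write_ground_truth(truth, path) -> None:
    """YAML dump of a GroundTruth's scalar/array fields (arrays as lists)."""

    def convert(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, dict):
            return {k: convert(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [convert(x) for x in v]
        if isinstance(v, pd.DataFrame):
            return v.to_dict(orient="list")
        return v

    payload = {}
    for name in ("asym_field", "dataset_fields", "true_peak_age", "true_h2",
                 "true_rG", "outlier_flags"):
        val = getattr(truth, name, None)
        if val is not None:
            payload[name] = convert(val)
    extras = {
        k: convert(v)
        for k, v in getattr(truth, "extras", {}).items()
        if not callable(v)
    }
    if extras:
        payload["extras"] = extras
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
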