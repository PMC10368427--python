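"""Synthetic-data generators with planted, recoverable ground truth.

Every downstream stage of the pipeline (consensus asymmetry clusters,
lifespan trajectory models, asymmetry covariance, heritability, association
screens) is exercised on data produced here, where the truth — planted
asymmetry fields, hemispheric age curves, heritabilities, genetic
correlations, outliers, covariate effects — is known and returned alongside
the data so recovery can be scored directly.

All generators draw from ``numpy.random.default_rng`` seeded by the caller;
identical seeds give identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .mesh import SurfaceMesh


class SimulationError(ValueError):
    """Invalid generator parameters."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class VertexObservation:
    """One subject-timepoint's left/right per-vertex maps plus metadata."""

    subject_id: str
    dataset_id: str
    timepoint: int
    age: float
    sex: int
    scanner_id: str
    icv: float
    lh_map: np.ndarray
    rh_map: np.ndarray
    metric: str = "area"

    def __post_init__(self) -> None:
        self.lh_map = np.asarray(self.lh_map, dtype=float)
        self.rh_map = np.asarray(self.rh_map, dtype=float)
        if self.lh_map.shape != self.rh_map.shape:
            raise SimulationError("lh_map and rh_map must have equal length")
        if self.metric == "area" and (
            np.any(self.lh_map <= 0) or np.any(self.rh_map <= 0)
        ):
            raise SimulationError("area-metric values must be strictly positive")


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulation output.

    Only the fields relevant to the generating call are populated.
    """

    asym_field: np.ndarray | None = None
    dataset_fields: np.ndarray | None = None
    patches: list[dict] | None = None
    hemi_curves: dict | None = None
    true_peak_age: float | None = None
    true_h2: float | tuple | None = None
    true_rG: float | None = None
    outlier_flags: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


@dataclass
class FamilyData:
    """Family-structured phenotypes for twin/sibling variance decomposition.

    ``table`` has one row per family member: family_id, member_id,
    relation_class (MZ / DZ / SIB, optionally with a ``+SIB`` suffix for
    twin+sibling trios), age, sex, and one or two phenotype columns
    (y1[, y2]).  ``kinship_matrix`` maps a family's relation class to the
    expected additive-genetic correlation matrix K (1 on the diagonal, 1 for
    MZ co-twins, 0.5 for DZ co-twins and siblings).
    """

    table: pd.DataFrame
    n_traits: int = 1

    @staticmethod
    def kinship_matrix(relation_class: str) -> np.ndarray:
        base = {"MZ": 1.0, "DZ": 0.5, "SIB": 0.5}
        if relation_class in base:
            r = base[relation_class]
            return np.array([[1.0, r], [r, 1.0]])
        if relation_class in ("MZ+SIB", "DZ+SIB"):
            r = base[relation_class[:2]]
            return np.array([[1.0, r, 0.5], [r, 1.0, 0.5], [0.5, 0.5, 1.0]])
        raise SimulationError(f"unknown relation class {relation_class!r}")

    def family_blocks(self, traits: Sequence[str] | None = None):
        """Yield (family_id, K, values) per family; values is (m, n_traits)."""
        if traits is None:
            traits = ["y1"] if self.n_traits == 1 else ["y1", "y2"]
        for fam_id, grp in self.table.groupby("family_id", sort=True):
            K = self.kinship_matrix(grp["relation_class"].iloc[0])
            yield fam_id, K, grp[list(traits)].to_numpy(dtype=float)


@dataclass
class GenotypePanel:
    """SNP dosages (0/1/2, NaN = missing) with generative truth."""

    dosage: np.ndarray
    allele_freq: np.ndarray
    causal_idx: np.ndarray | None = None
    causal_beta: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]


@dataclass(frozen=True)
class PatchSpec:
    """A smooth signed asymmetry patch: geodesic cap with cosine falloff.

    ``center`` is a unit direction (the nearest mesh vertex anchors the
    patch), ``radius_mm`` the geodesic extent, ``magnitude`` the peak AI
    (positive = leftward), ``present_in`` an optional tuple of dataset
    indices carrying the patch (None = all datasets).
    """

    center: tuple[float, float, float]
    radius_mm: float
    magnitude: float
    present_in: tuple[int, ...] | None = None


#: Default planted configuration for the consensus analysis: a large
#: leftward and a large rightward patch present in every dataset, a patch
#: present in only five datasets (to be rejected by a 6-dataset overlap
#: rule), and a small patch whose supra-threshold extent (~100 mm² on the
#: default mesh) falls under the 200 mm² size filter.
DEFAULT_PATCHES: tuple[PatchSpec, ...] = (
    PatchSpec((1.0, 0.0, 0.0), 30.0, +0.12),
    PatchSpec((-1.0, 0.0, 0.0), 30.0, -0.12),
    PatchSpec((0.0, 1.0, 0.0), 30.0, +0.12, present_in=(0, 1, 2, 3, 4)),
    PatchSpec((0.0, 0.0, 1.0), 11.0, +0.12),
)


# --------------------------------------------------------------------------
# cross-sectional multi-dataset surface maps
# --------------------------------------------------------------------------


def patch_field(mesh: SurfaceMesh, patch: PatchSpec) -> np.ndarray:
    """Evaluate one patch's AI contribution at every vertex."""
    center = np.asarray(patch.center, dtype=float)
    center = center / np.linalg.norm(center)
    # anchor at the mesh vertex closest to the requested direction
    vi = int(np.argmax(mesh.vertex_coords @ center))
    g = mesh.geodesic_from(np.array([vi]))[0]
    out = np.zeros(mesh.n_vertices)
    inside = g < patch.radius_mm
    out[inside] = patch.magnitude * 0.5 * (
        1.0 + np.cos(np.pi * g[inside] / patch.radius_mm)
    )
    return out


def simulate_datasets(
    mesh: SurfaceMesh,
    n_datasets: int = 7,
    n_subjects_per_dataset: int = 30,
    asym_field_spec: Sequence[PatchSpec] = DEFAULT_PATCHES,
    noise_sd: float | Sequence[float] = 0.03,
    dataset_offsets: Sequence[float] | None = None,
    metric: str = "area",
    age_range: tuple[float, float] = (20.0, 90.0),
    seed: int | np.random.Generator = 0,
) -> tuple[list[list[VertexObservation]], GroundTruth]:
    """Simulate D independent adult samples of LH/RH surface maps.

    Each subject's maps are constructed so the expected vertex-wise
    asymmetry index AI = 2(L−R)/(L+R) equals the planted field: with
    baseline map μ(v) (per-vertex area for the area metric, constant 2.5 mm
    for thickness) and planted field a(v),

        L(v) = μ(v)(1 + a(v)/2) + ε_L,   R(v) = μ(v)(1 − a(v)/2) + ε_R,

    with ε ~ N(0, (noise_sd·μ)²) i.i.d. over vertices and hemispheres.
    ``noise_sd`` may be per-dataset; ``dataset_offsets`` adds a constant
    per-dataset shift to the planted field (default none).
    """
    if n_datasets < 2:
        raise SimulationError("need at least 2 datasets")
    rng = np.random.default_rng(seed)
    noise = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_datasets,))
    if np.any(noise < 0):
        raise SimulationError("noise_sd must be non-negative")
    offsets = (
        np.zeros(n_datasets)
        if dataset_offsets is None
        else np.asarray(dataset_offsets, dtype=float)
    )

    patch_fields = [patch_field(mesh, p) for p in asym_field_spec]
    full_field = np.sum(patch_fields, axis=0) if patch_fields else np.zeros(
        mesh.n_vertices
    )
    dataset_fields = np.empty((n_datasets, mesh.n_vertices))
    for d in range(n_datasets):
        f = np.zeros(mesh.n_vertices)
        for p, pf in zip(asym_field_spec, patch_fields):
            if p.present_in is None or d in p.present_in:
                f += pf
        dataset_fields[d] = f + offsets[d]
    if np.any(np.abs(dataset_fields) >= 2.0):
        raise SimulationError(
            "patch magnitudes imply non-positive hemispheric values (|AI| >= 2)"
        )

    mu = mesh.vertex_area if metric == "area" else np.full(mesh.n_vertices, 2.5)
    datasets: list[list[VertexObservation]] = []
    for d in range(n_datasets):
        obs_list: list[VertexObservation] = []
        a = dataset_fields[d]
        lh_mean = mu * (1.0 + a / 2.0)
        rh_mean = mu * (1.0 - a / 2.0)
        for s in range(n_subjects_per_dataset):
            eps = rng.normal(0.0, 1.0, size=(2, mesh.n_vertices)) * (
                noise[d] * mu
            )
            lh = lh_mean + eps[0]
            rh = rh_mean + eps[1]
            if metric == "area":
                floor = 1e-6 * mu
                lh = np.maximum(lh, floor)
                rh = np.maximum(rh, floor)
            obs_list.append(
                VertexObservation(
                    subject_id=f"d{d}s{s}",
                    dataset_id=f"dataset{d}",
                    timepoint=1,
                    age=float(rng.uniform(*age_range)),
                    sex=int(rng.integers(0, 2)),
                    scanner_id=f"scanner{d}",
                    icv=float(rng.normal(1.5e6, 1.5e5)),
                    lh_map=lh,
                    rh_map=rh,
                    metric=metric,
                )
            )
        datasets.append(obs_list)

    truth = GroundTruth(
        asym_field=full_field,
        dataset_fields=dataset_fields,
        patches=[
            {
                "field": pf,
                "present_in": (
                    tuple(range(n_datasets))
                    if p.present_in is None
                    else p.present_in
                ),
                "spec": p,
            }
            for p, pf in zip(asym_field_spec, patch_fields)
        ],
    )
    return datasets, truth


# --------------------------------------------------------------------------
# longitudinal lifespan cohorts
# --------------------------------------------------------------------------


def peaked_difference(
    age: np.ndarray, peak_age: float = 24.3, shape: float = 3.0
) -> np.ndarray:
    """Unimodal lifespan curve, 1 at ``peak_age``, gamma-density shape.

    Emulates developmental asymmetry increase to an early-adult peak
    followed by slow decline.
    """
    x = np.asarray(age, dtype=float) / peak_age
    return (x * np.exp(1.0 - x)) ** shape


def default_hemi_curves(
    baseline: float = 2.5,
    slope: float = -0.008,
    asym_offset: float = 0.05,
    asym_peak: float = 0.2,
    peak_age: float = 24.3,
) -> tuple[Callable, Callable]:
    """Thickness-like hemispheric curves whose difference peaks at ``peak_age``.

    Both hemispheres thin linearly with age; the left additionally carries a
    constant offset plus a unimodal developmental asymmetry component.
    """

    def f_right(age):
        return baseline + slope * (np.asarray(age, dtype=float) - 4.0)

    def f_left(age):
        return (
            f_right(age)
            + asym_offset
            + asym_peak * peaked_difference(age, peak_age=peak_age)
        )

    return f_left, f_right


def simulate_lifespan(
    cluster_ids: Sequence[str] = ("cluster1",),
    n_subjects: int = 500,
    visit_probs: Sequence[float] = (0.5, 0.3, 0.2),
    hemi_curves: dict[str, tuple[Callable, Callable]] | None = None,
    subj_sd: float = 0.05,
    resid_sd: float = 0.1,
    sex_effect: float = 0.02,
    scanner_effects: Sequence[float] = (0.0, 0.03),
    icv_effect: float = 5e-8,
    age_range: tuple[float, float] = (4.0, 90.0),
    outlier_spec: Sequence[dict] | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a longitudinal cohort of per-cluster hemispheric values.

    Each observation of hemisphere h is

        y = f_h(age) + sex_effect·sex + scanner_effect + icv_effect·(icv−mean)
            + b_subject + ε,

    with b ~ N(0, subj_sd²) shared across a subject's visits and hemispheres
    and ε ~ N(0, resid_sd²) i.i.d.  ``visit_probs[k]`` is the probability of
    k+1 visits; inter-visit intervals are uniform on 1–4 years.

    ``outlier_spec`` plants gross errors: each entry is a dict with keys
    ``n`` (count), ``offset`` (in units of resid_sd) and ``hemi`` ('L'/'R');
    a planted observation's value is set to the deterministic mean (no
    subject effect, no noise) plus exactly offset·resid_sd, so its distance
    from the population trajectory in residual-SD units is known.
    """
    rng = np.random.default_rng(seed)
    default_curves = hemi_curves is None
    if default_curves:
        hemi_curves = {cid: default_hemi_curves() for cid in cluster_ids}
    if subj_sd < 0 or resid_sd < 0:
        raise SimulationError("variance components must be non-negative")

    rows = []
    n_visits = rng.choice(
        np.arange(1, len(visit_probs) + 1), size=n_subjects, p=visit_probs
    )
    b_subj = rng.normal(0.0, subj_sd, size=n_subjects)
    sexes = rng.integers(0, 2, size=n_subjects)
    scanners = rng.integers(0, len(scanner_effects), size=n_subjects)
    icvs = rng.normal(1.5e6, 1.5e5, size=n_subjects)
    base_age = rng.uniform(age_range[0], age_range[1] - 8.0, size=n_subjects)
    for i in range(n_subjects):
        age = base_age[i]
        for t in range(n_visits[i]):
            if t > 0:
                age = age + rng.uniform(1.0, 4.0)
            mean_cov = (
                sex_effect * sexes[i]
                + scanner_effects[scanners[i]]
                + icv_effect * (icvs[i] - 1.5e6)
            )
            for cid in cluster_ids:
                f_l, f_r = hemi_curves[cid]
                det_l = float(f_l(age)) + mean_cov
                det_r = float(f_r(age)) + mean_cov
                if not (np.isfinite(det_l) and np.isfinite(det_r)):
                    raise SimulationError("hemispheric curve evaluated non-finite")
                lh = det_l + b_subj[i] + rng.normal(0.0, resid_sd)
                rh = det_r + b_subj[i] + rng.normal(0.0, resid_sd)
                rows.append(
                    {
                        "subject_id": f"s{i}",
                        "dataset_id": "synthetic",
                        "timepoint": t + 1,
                        "age": age,
                        "sex": int(sexes[i]),
                        "scanner": f"scanner{scanners[i]}",
                        "icv": icvs[i],
                        "cluster_id": cid,
                        "lh_mean": lh,
                        "rh_mean": rh,
                        "det_lh": det_l,
                        "det_rh": det_r,
                        "outlier_lh": False,
                        "outlier_rh": False,
                        "outlier_offset": 0.0,
                    }
                )
    table = pd.DataFrame(rows)

    if outlier_spec:
        eligible = np.arange(len(table))
        for spec in outlier_spec:
            n_out = int(spec["n"])
            offset = float(spec["offset"])
            hemi = spec.get("hemi", "L").upper()
            idx = rng.choice(eligible, size=n_out, replace=False)
            eligible = np.setdiff1d(eligible, idx)
            col = "lh_mean" if hemi == "L" else "rh_mean"
            det = "det_lh" if hemi == "L" else "det_rh"
            flag = "outlier_lh" if hemi == "L" else "outlier_rh"
            table.loc[idx, col] = table.loc[idx, det] + offset * resid_sd
            table.loc[idx, flag] = True
            table.loc[idx, "outlier_offset"] = offset

    from .asymmetry import compute_ai  # local import avoids cycle

    table["ai"] = compute_ai(
        table["lh_mean"].to_numpy(), table["rh_mean"].to_numpy()
    )
    outflags = table[["subject_id", "timepoint", "cluster_id",
                      "outlier_lh", "outlier_rh", "outlier_offset"]].copy()
    table = table.drop(columns=["det_lh", "det_rh", "outlier_offset"])
    truth = GroundTruth(
        hemi_curves=hemi_curves,
        true_peak_age=24.3 if default_curves else None,
        outlier_flags=outflags,
        extras={"subj_sd": subj_sd, "resid_sd": resid_sd,
                "sex_effect": sex_effect, "icv_effect": icv_effect},
    )
    return table, truth


# --------------------------------------------------------------------------
# families (twin / sibling)
# --------------------------------------------------------------------------


def simulate_families(
    n_mz: int = 500,
    n_dz: int = 500,
    n_sib: int = 0,
    a2: float | tuple[float, float] = 0.5,
    e2: float | tuple[float, float] = 0.5,
    rG: float | None = None,
    n_trio_mz: int = 0,
    n_trio_dz: int = 0,
    age_range: tuple[float, float] = (22.0, 37.0),
    seed: int | np.random.Generator = 0,
) -> tuple[FamilyData, GroundTruth]:
    """Simulate MZ/DZ/sibling families with known additive-genetic variance.

    Phenotypes follow the AE model: within a family with kinship matrix K,
    the genetic parts have covariance a2·K and the environmental parts are
    independent N(0, e2).  With ``rG`` given, two traits are generated whose
    genetic components correlate rG within member (cross-member scaled by K)
    and whose environments are independent.  Twin pairs are same-sex.
    """
    a2_t = np.atleast_1d(np.asarray(a2, dtype=float))
    e2_t = np.atleast_1d(np.asarray(e2, dtype=float))
    bivariate = rG is not None
    n_traits = 2 if bivariate else 1
    if bivariate:
        if not -1.0 <= rG <= 1.0:
            raise SimulationError("rG must lie in [-1, 1]")
        a2_t = np.broadcast_to(a2_t, (2,)).astype(float)
        e2_t = np.broadcast_to(e2_t, (2,)).astype(float)
    if np.any(a2_t < 0) or np.any(e2_t <= 0) or np.any(a2_t + e2_t == 0):
        raise SimulationError("need a2 >= 0 and e2 > 0")

    if bivariate:
        cg = rG * np.sqrt(a2_t[0] * a2_t[1])
        sigma_g = np.array([[a2_t[0], cg], [cg, a2_t[1]]])
        sigma_e = np.diag(e2_t)
    else:
        sigma_g = np.array([[a2_t[0]]])
        sigma_e = np.array([[e2_t[0]]])
    # numerically safe square root of the genetic trait covariance
    w, q = np.linalg.eigh(sigma_g)
    g_half = q @ np.diag(np.sqrt(np.maximum(w, 0.0))) @ q.T
    e_half = np.sqrt(sigma_e)

    rng = np.random.default_rng(seed)
    rows = []
    fam = 0
    classes = (
        ["MZ"] * n_mz + ["DZ"] * n_dz + ["SIB"] * n_sib
        + ["MZ+SIB"] * n_trio_mz + ["DZ+SIB"] * n_trio_dz
    )
    for rel in classes:
        K = FamilyData.kinship_matrix(rel)
        m = K.shape[0]
        wk, qk = np.linalg.eigh(K)  # MZ blocks are singular: eigen sqrt
        L = qk @ np.diag(np.sqrt(np.maximum(wk, 0.0)))
        z = rng.standard_normal((m, n_traits))
        genetic = L @ z @ g_half.T
        env = rng.standard_normal((m, n_traits)) @ e_half.T
        y = genetic + env
        sex = int(rng.integers(0, 2))  # same-sex twin pairs
        ages = rng.uniform(*age_range, size=m)
        for j in range(m):
            row = {
                "family_id": f"f{fam}",
                "member_id": f"f{fam}m{j}",
                "relation_class": rel,
                "age": ages[j],
                "sex": sex,
                "y1": y[j, 0],
            }
            if bivariate:
                row["y2"] = y[j, 1]
            rows.append(row)
        fam += 1

    data = FamilyData(table=pd.DataFrame(rows), n_traits=n_traits)
    truth = GroundTruth(
        true_h2=(
            tuple(a2_t / (a2_t + e2_t)) if bivariate
            else float(a2_t[0] / (a2_t[0] + e2_t[0]))
        ),
        true_rG=rG,
        extras={"a2": a2, "e2": e2},
    )
    return data, truth


# --------------------------------------------------------------------------
# genotypes + phenotypes
# --------------------------------------------------------------------------


def simulate_genotype_phenotypes(
    n_subjects: int = 1000,
    n_snps: int = 2000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    h2: float = 0.5,
    n_causal: int = 200,
    related_pairs: int = 0,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[GenotypePanel, np.ndarray, GroundTruth]:
    """Simulate a SNP panel and a phenotype with known SNP heritability.

    Dosages are Binomial(2, p) with p uniform on ``maf_range``.  The genetic
    score is built from ``n_causal`` SNPs with N(0,1) effects on true-
    frequency-standardized dosages, then rescaled so its in-sample variance
    is exactly h2; environmental noise has variance 1−h2.  ``related_pairs``
    duplicates genomes (the last k subjects copy the first k) to exercise
    the kinship cutoff.  Missing dosages are planted completely at random.
    """
    if not 0.0 <= h2 < 1.0:
        raise SimulationError("h2 must lie in [0, 1)")
    if n_causal > n_snps:
        raise SimulationError("n_causal cannot exceed n_snps")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise SimulationError("maf_range must be within (0, 0.5]")
    if 2 * related_pairs > n_subjects:
        raise SimulationError("too many related pairs")

    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)
    dosage = rng.binomial(2, p, size=(n_subjects, n_snps)).astype(float)
    if related_pairs:
        dosage[n_subjects - related_pairs:] = dosage[:related_pairs]

    causal_idx = rng.choice(n_snps, size=n_causal, replace=False)
    beta = rng.standard_normal(n_causal)
    std = (dosage[:, causal_idx] - 2 * p[causal_idx]) / np.sqrt(
        2 * p[causal_idx] * (1 - p[causal_idx])
    )
    score = std @ beta
    if h2 > 0:
        sv = score.var()
        if sv == 0:
            raise SimulationError("degenerate genetic score")
        genetic = score * np.sqrt(h2 / sv)
    else:
        genetic = np.zeros(n_subjects)
    phenotype = genetic + rng.normal(0.0, np.sqrt(1.0 - h2), size=n_subjects)

    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = np.nan

    panel = GenotypePanel(
        dosage=dosage, allele_freq=p, causal_idx=causal_idx, causal_beta=beta
    )
    truth = GroundTruth(
        true_h2=h2,
        extras={
            "genetic_component": genetic,
            "related_pairs": [
                (i, n_subjects - related_pairs + i) for i in range(related_pairs)
            ],
        },
    )
    return panel, phenotype, truth


def simulate_bivariate_phenotypes(
    panel: GenotypePanel,
    h2: tuple[float, float] = (0.5, 0.5),
    rG: float = 0.8,
    n_causal: int = 200,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two phenotypes with SNP-based genetic components correlating at rG.

    Two disjoint causal scores z1, z2 are built from the panel's observed
    dosages; trait 1's genetic part is z1 and trait 2's is
    rG·z1 + √(1−rG²)·z2, each rescaled to its h2 in-sample.  Environmental
    noise is independent with variance 1−h2 per trait.
    """
    if not -1.0 <= rG <= 1.0:
        raise SimulationError("rG must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    x = np.asarray(panel.dosage, dtype=float)
    p = np.nanmean(x, axis=0) / 2.0
    ok = np.flatnonzero((p > 0.01) & (p < 0.99))
    if len(ok) < 2 * n_causal:
        raise SimulationError("too few polymorphic SNPs for two causal sets")
    pick = rng.choice(ok, size=2 * n_causal, replace=False)
    xs = np.where(np.isnan(x), 2 * p, x)

    def score(idx):
        w = (xs[:, idx] - 2 * p[idx]) / np.sqrt(2 * p[idx] * (1 - p[idx]))
        s = w @ rng.standard_normal(len(idx))
        return (s - s.mean()) / s.std()

    z1 = score(pick[:n_causal])
    z2 = score(pick[n_causal:])
    g1 = np.sqrt(h2[0]) * z1
    raw2 = rG * z1 + np.sqrt(1 - rG**2) * z2
    g2 = np.sqrt(h2[1]) * (raw2 - raw2.mean()) / raw2.std()
    n = panel.n_subjects
    y1 = g1 + rng.normal(0, np.sqrt(1 - h2[0]), n)
    y2 = g2 + rng.normal(0, np.sqrt(1 - h2[1]), n)
    truth = GroundTruth(true_h2=h2, true_rG=rG,
                        extras={"g1": g1, "g2": g2})
    return y1, y2, truth


# --------------------------------------------------------------------------
# cognition battery / handedness / ICV covariates
# --------------------------------------------------------------------------

BATTERY_COLUMNS = (
    "reaction_time",
    "numeric_memory",
    "fluid_reasoning",
    "matrix_completion",
    "tower_rearranging",
    "symbol_digit",
    "paired_associate",
    "prospective_memory",
    "pairs_matching",
    "trail_making_a",
    "trail_making_b",
)

#: loading for which an equal-loading one-factor battery has a PC1 variance
#: share of 0.392 (the share the study's composite explained):
#: share = (11λ² + (1−λ²)) / 11  →  λ² = (11·0.392 − 1)/10.
DEFAULT_LOADING = float(np.sqrt((11 * 0.392 - 1) / 10))


def onefactor_pc1_share(loading: float, unique_var: float | None = None,
                        n_vars: int = 11) -> float:
    """Closed-form PC1 variance share of an equal-loading one-factor model.

    For n standardized indicators x_j = λ g + e_j with Var(e_j) = u, the
    correlation matrix is (λ²/(λ²+u))·J off the diagonal, whose top
    eigenvalue is 1 + (n−1)·λ²/(λ²+u); the share divides by n.
    """
    u = 1.0 - loading**2 if unique_var is None else unique_var
    rho = loading**2 / (loading**2 + u)
    return (1.0 + (n_vars - 1) * rho) / n_vars


def simulate_covariates_battery(
    n_subjects: int = 2000,
    loading: float | Sequence[float] = DEFAULT_LOADING,
    missing_rate: float = 0.1,
    handed_left_rate: float = 0.1,
    handed_mixed_rate: float = 0.01,
    age_cognition_corr: float = -0.39,
    cluster_ids: Sequence[str] = (),
    cluster_directions: Sequence[str] = (),
    effects_spec: dict | None = None,
    ai_noise_sd: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the 11-test cognition battery plus covariates and cluster AIs.

    The battery follows a one-factor model: test_j = λ_j·g + √(1−λ_j²)·e_j
    with g standard normal and correlated with age at
    ``age_cognition_corr``.  Missingness is completely at random.  If
    ``cluster_ids`` are given, per-subject cluster AI values are generated
    with planted linear effects from ``effects_spec``, a mapping
    {(cluster_id, predictor): beta} with predictors in
    {"cognition", "handedness", "sex", "icv"}; betas act on standardized
    predictors (g itself for cognition; 0/1 codes for handedness [left=1]
    and sex [male=1]; z-scored ICV).
    """
    lam = np.broadcast_to(np.atleast_1d(np.asarray(loading, float)), (11,))
    if np.any(np.abs(lam) >= 1):
        raise SimulationError("|loading| must be < 1 for standardized tests")
    if not 0.0 <= missing_rate < 0.5:
        raise SimulationError("missing_rate must lie in [0, 0.5)")
    if not 0.0 < handed_left_rate < 0.5:
        raise SimulationError("handed_left_rate must lie in (0, 0.5)")

    rng = np.random.default_rng(seed)
    age = rng.uniform(45.0, 80.0, size=n_subjects)
    z_age = (age - age.mean()) / age.std()
    r = age_cognition_corr
    g = r * z_age + np.sqrt(1 - r**2) * rng.standard_normal(n_subjects)
    tests = g[:, None] * lam[None, :] + rng.standard_normal(
        (n_subjects, 11)
    ) * np.sqrt(1 - lam**2)[None, :]

    mask = rng.random(tests.shape) < missing_rate
    tests_obs = tests.copy()
    tests_obs[mask] = np.nan

    sex = rng.integers(0, 2, size=n_subjects)
    icv = rng.normal(1.5e6, 1.5e5, size=n_subjects)
    handed = rng.choice(
        np.array(["right", "left", "mixed"]),
        size=n_subjects,
        p=[1 - handed_left_rate - handed_mixed_rate, handed_left_rate,
           handed_mixed_rate],
    )

    table = pd.DataFrame(tests_obs, columns=list(BATTERY_COLUMNS))
    table.insert(0, "subject_id", [f"s{i}" for i in range(n_subjects)])
    table["age"] = age
    table["sex"] = sex
    table["icv"] = icv
    table["handedness"] = handed

    effects_spec = effects_spec or {}
    z_icv = (icv - icv.mean()) / icv.std()
    left = (handed == "left").astype(float)
    predictor_values = {
        "cognition": g,
        "handedness": left,
        "sex": sex.astype(float),
        "icv": z_icv,
    }
    for cid, direction in zip(cluster_ids, cluster_directions):
        base = 0.1 if direction == "leftward" else -0.1
        ai = np.full(n_subjects, base)
        for (ecid, pred), beta in effects_spec.items():
            if ecid == cid:
                ai = ai + beta * predictor_values[pred]
        table[f"ai_{cid}"] = ai + rng.normal(0, ai_noise_sd, size=n_subjects)

    truth = GroundTruth(
        extras={
            "g": g,
            "complete_tests": tests,
            "missing_mask": mask,
            "loading": lam,
            "pc1_share": onefactor_pc1_share(float(lam[0]))
            if np.allclose(lam, lam[0])
            else None,
            "effects_spec": dict(effects_spec),
            "cluster_directions": dict(zip(cluster_ids, cluster_directions)),
        }
    )
    return table, truth
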