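"""Vertex-wise asymmetry indices and per-dataset mean AI maps.

The asymmetry index at a vertex with left value L and right value R is

    AI = (L − R) / ((L + R) / 2) = 2(L − R)/(L + R),

positive for leftward lateralization and bounded in (−2, 2) for positive
inputs.  Vertices with L + R = 0 have no defined AI and are carried as NaN
through every map statistic rather than being zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .simulate import VertexObservation


class AsymmetryError(ValueError):
    pass


@dataclass
class AIMap:
    """Across-subject mean asymmetry-index map for one dataset."""

    ai: np.ndarray
    metric: str
    dataset_id: str
    n_subjects: int


@dataclass
class HemiEffectMap:
    """Per-vertex hemisphere main-effect statistics (paired design)."""

    estimate: np.ndarray
    se: np.ndarray
    stat: np.ndarray
    p: np.ndarray
    df: float


def compute_ai(lh, rh):
    """Asymmetry index 2(L−R)/(L+R); NaN where L+R = 0.

    Accepts scalars or arrays; antisymmetric in its arguments and invariant
    to positive rescaling of both.
    """
    lh = np.asarray(lh, dtype=float)
    rh = np.asarray(rh, dtype=float)
    if not (np.all(np.isfinite(lh)) and np.all(np.isfinite(rh))):
        raise AsymmetryError("non-finite input to compute_ai")
    denom = lh + rh
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom == 0.0, np.nan, 2.0 * (lh - rh) / denom)
    if out.ndim == 0:
        return float(out)
    return out


def _subject_ai_matrix(
    observations: Sequence[VertexObservation],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Within-subject averaged AI and paired L−R differences.

    Returns (ai, diff, age, sex): one row per subject, longitudinal
    timepoints averaged within subject first.
    """
    subjects: dict[str, list[VertexObservation]] = {}
    for obs in observations:
        subjects.setdefault(obs.subject_id, []).append(obs)
    n_vert = observations[0].lh_map.shape[0]
    ai = np.empty((len(subjects), n_vert))
    diff = np.empty((len(subjects), n_vert))
    age = np.empty(len(subjects))
    sex = np.empty(len(subjects))
    for i, (sid, obs_list) in enumerate(sorted(subjects.items())):
        for obs in obs_list:
            if obs.lh_map.shape[0] != n_vert:
                raise AsymmetryError("observation not on the common mesh")
        ai[i] = np.nanmean(
            [compute_ai(o.lh_map, o.rh_map) for o in obs_list], axis=0
        )
        diff[i] = np.mean([o.lh_map - o.rh_map for o in obs_list], axis=0)
        age[i] = np.mean([o.age for o in obs_list])
        sex[i] = obs_list[0].sex
    return ai, diff, age, sex


def mean_ai_map(
    observations: Sequence[VertexObservation],
    covariates: tuple[str, ...] = ("age", "sex"),
) -> tuple[AIMap, HemiEffectMap]:
    """Mean AI map plus vertex-wise hemisphere-effect inference.

    The AI map is the across-subject mean of subject-level vertex AIs
    (multiple timepoints averaged within subject first).  The hemisphere
    main effect is tested by the paired-difference reduction of the
    two-row mixed model: within-subject L−R differences are regressed on
    an intercept plus (centered) covariates; the intercept is the
    hemisphere effect at sample-mean covariates.  With both hemispheres
    observed for every row this is exactly the mixed model's hemisphere
    inference — subject intercepts cancel in the difference.
    """
    if len({o.subject_id for o in observations}) < 2:
        raise AsymmetryError("need at least two subjects")
    ai, diff, age, sex = _subject_ai_matrix(observations)
    n = ai.shape[0]

    cols = [np.ones(n)]
    if "age" in covariates:
        cols.append(age - age.mean())
    if "sex" in covariates and np.ptp(sex) > 0:
        cols.append(sex - sex.mean())
    x = np.column_stack(cols)
    p_par = x.shape[1]
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ (x.T @ diff)  # (p, V)
    resid = diff - x @ beta
    dof = n - p_par
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(xtx_inv[0, 0] * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta[0] / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof)

    ref = observations[0]
    ai_map = AIMap(
        ai=np.nanmean(ai, axis=0),
        metric=ref.metric,
        dataset_id=ref.dataset_id,
        n_subjects=n,
    )
    return ai_map, HemiEffectMap(beta[0], se, tstat, pval, float(dof))


def map_correlation(map_a: AIMap, map_b: AIMap) -> float:
    """Pearson correlation between two AI maps over jointly defined vertices."""
    a, b = map_a.ai, map_b.ai
    if a.shape != b.shape:
        raise AsymmetryError("maps are not on the same mesh")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise AsymmetryError("fewer than 3 jointly defined vertices")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise AsymmetryError("zero variance map: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
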