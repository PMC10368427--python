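"""General-cognition composite and the cluster-wise association screen.

The cognition composite is the first principal component of an 11-test
battery, with missing scores completed by iterative low-rank PCA
imputation (EM on the reconstruction: missing cells are repeatedly
replaced by their rank-r reconstruction until the fit stabilizes; the rank
is chosen by cross-validated reconstruction error).  PC1 is sign-fixed to
correlate non-positively with age so higher values mean better cognition.

The screen fits, per cluster, two ordinary-least-squares model families on
sign-aligned asymmetry indices: cognition PC1 as predictor (age, sex, ICV
controlled) and handedness + sex + ICV jointly (age controlled; mixed-
handed participants excluded).  Significance is Bonferroni-corrected at
alpha_base / (n_clusters × 4 predictors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import BATTERY_COLUMNS


class AssociationError(ValueError):
    pass


PREDICTORS = ("cognition_pc1", "handedness", "sex", "icv")


@dataclass
class CognitionPC1:
    scores: np.ndarray
    variance_share: float
    completed: np.ndarray
    rank: int
    n_iter: int
    sign_flipped: bool


# --------------------------------------------------------------------------
# iterative PCA imputation
# --------------------------------------------------------------------------


def _svd_reconstruct(x: np.ndarray, rank: int) -> np.ndarray:
    mu = x.mean(axis=0)
    u, s, vt = np.linalg.svd(x - mu, full_matrices=False)
    return mu + (u[:, :rank] * s[:rank]) @ vt[:rank]


def impute_pca(
    x: np.ndarray,
    rank: int,
    tol: float = 1e-5,
    max_iter: int = 2000,
    strict: bool = True,
) -> tuple[np.ndarray, int]:
    """Iterative rank-r PCA imputation of missing entries.

    Missing cells start at column means and are repeatedly replaced by the
    rank-r SVD reconstruction of the completed matrix until the relative
    change in imputed values falls below ``tol``.  Observed entries are
    never altered.  Convergence is geometric at a rate set by the trailing
    eigengap, so ranks that mostly fit noise converge slowly; with
    ``strict=False`` the current iterate is returned at ``max_iter``
    instead of raising.
    """
    x = np.asarray(x, dtype=float)
    mask = np.isnan(x)
    if not mask.any():
        return x.copy(), 0
    filled = x.copy()
    col_mean = np.nanmean(x, axis=0)
    filled[mask] = np.take(col_mean, np.where(mask)[1])
    scale = float(np.nanstd(x)) or 1.0
    trace = []
    for it in range(1, max_iter + 1):
        recon = _svd_reconstruct(filled, rank)
        new_vals = recon[mask]
        change = np.sqrt(np.mean((new_vals - filled[mask]) ** 2)) / scale
        trace.append(change)
        filled[mask] = new_vals
        if change < tol:
            return filled, it
    if strict:
        raise AssociationError(
            f"PCA imputation did not converge in {max_iter} iterations; "
            f"relative-change trace tail {['%.1e' % c for c in trace[-3:]]}"
        )
    return filled, max_iter


def _cv_select_rank(
    x: np.ndarray, ranks, n_folds: int = 5, seed: int = 0
) -> int:
    """Rank with the lowest cross-validated reconstruction error.

    Observed cells are split into folds; each fold is masked in turn,
    imputed, and scored against the held-out values.
    """
    rng = np.random.default_rng(seed)
    obs = np.argwhere(~np.isnan(x))
    fold = rng.integers(0, n_folds, size=len(obs))
    errors = {r: 0.0 for r in ranks}
    for f in range(n_folds):
        xm = x.copy()
        held = obs[fold == f]
        truth = x[held[:, 0], held[:, 1]]
        xm[held[:, 0], held[:, 1]] = np.nan
        if np.any(np.all(np.isnan(xm), axis=0)):
            continue
        for r in ranks:
            filled, _ = impute_pca(xm, r, tol=1e-4, max_iter=200,
                                   strict=False)
            pred = filled[held[:, 0], held[:, 1]]
            errors[r] += float(np.sum((pred - truth) ** 2))
    return min(errors, key=errors.get)


def cognition_pc1(
    battery: pd.DataFrame,
    age: np.ndarray | None = None,
    rank: int | None = None,
    ranks=(1, 2, 3, 4, 5),
    tol: float = 1e-6,
    max_iter: int = 500,
) -> CognitionPC1:
    """General-cognition composite: PC1 of the (imputed) 11-test battery.

    ``battery`` holds the test columns (NaN = missing); columns are
    centered/scaled before imputation and PCA.  The component is inverted
    if it correlates positively with ``age``.
    """
    cols = [c for c in BATTERY_COLUMNS if c in battery.columns]
    if not cols:
        cols = list(battery.columns)
    x = battery[cols].to_numpy(dtype=float)
    n, m = x.shape
    if n < 3:
        raise AssociationError("need at least 3 subjects")
    frac_missing = np.isnan(x).mean(axis=0)
    if np.any(frac_missing >= 0.5):
        raise AssociationError("a battery variable is >= 50% missing")
    mu = np.nanmean(x, axis=0)
    sd = np.nanstd(x, axis=0)
    if np.any(sd == 0):
        raise AssociationError("constant battery variable")
    z = (x - mu) / sd

    if np.isnan(z).any():
        if rank is None:
            rank = _cv_select_rank(z, ranks)
        completed, n_iter = impute_pca(z, rank, tol=tol, max_iter=max_iter)
    else:
        rank = rank or 0
        completed, n_iter = z.copy(), 0

    cov = np.cov(completed, rowvar=False)
    w, v = np.linalg.eigh(cov)
    share = float(w[-1] / w.sum())
    pc1 = completed @ v[:, -1]
    flipped = False
    if age is not None:
        r = np.corrcoef(pc1, np.asarray(age, float))[0, 1]
        if r > 0:
            pc1 = -pc1
            flipped = True
    return CognitionPC1(
        scores=pc1,
        variance_share=share,
        completed=completed,
        rank=int(rank),
        n_iter=n_iter,
        sign_flipped=flipped,
    )


# --------------------------------------------------------------------------
# association screen
# --------------------------------------------------------------------------


def _ols(y, X):
    """OLS with (beta, se, p) for every column of X."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return beta, se, p, dof


def fit_associations(
    ai_table: pd.DataFrame,
    covars: pd.DataFrame,
    directions: dict[str, str] | None = None,
    alpha_base: float = 0.01,
    n_clusters_total: int | None = None,
) -> pd.DataFrame:
    """Cluster-wise association screen for cognition, handedness, sex, ICV.

    ``ai_table`` has one row per subject with one ``ai_<cluster>`` column
    per cluster (or is a long cluster table with cluster_id/ai columns);
    ``covars`` supplies subject_id, age, sex, icv, handedness and
    cognition_pc1.  Rightward clusters' AIs are inverted before modeling.
    Two model families are fitted per cluster: cognition PC1 controlling
    age/sex/ICV, and handedness+sex+ICV jointly controlling age
    (mixed-handers excluded).  The Bonferroni threshold is
    alpha_base / (n_clusters_total × 4).
    """
    if "cluster_id" in ai_table.columns:  # long cluster-table form
        wide = ai_table.pivot_table(
            index="subject_id", columns="cluster_id", values="ai"
        )
        wide.columns = [f"ai_{c}" for c in wide.columns]
        ai_table = wide.reset_index()
    df = covars.merge(ai_table, on="subject_id", how="inner")
    ai_cols = [c for c in df.columns if c.startswith("ai_")]
    if not ai_cols:
        raise AssociationError("no cluster AI columns found")
    n_clusters = n_clusters_total or len(ai_cols)
    alpha = alpha_base / (n_clusters * len(PREDICTORS))

    age = df["age"].to_numpy(dtype=float)
    sex = df["sex"].to_numpy(dtype=float)
    icv = df["icv"].to_numpy(dtype=float)
    rows = []
    for col in ai_cols:
        cid = col[3:]
        y = df[col].to_numpy(dtype=float)
        if directions and directions.get(cid) == "rightward":
            y = -y

        # family 1: cognition PC1, controlling age, sex, ICV
        if "cognition_pc1" in df.columns:
            pc1 = df["cognition_pc1"].to_numpy(dtype=float)
            ok = np.isfinite(pc1)
            X = np.column_stack(
                [np.ones(ok.sum()), pc1[ok], age[ok], sex[ok], icv[ok]]
            )
            beta, se, p, _ = _ols(y[ok], X)
            rows.append(
                _result_row(cid, "cognition_pc1", beta[1], se[1], p[1],
                            int(ok.sum()), alpha)
            )

        # family 2: handedness + sex + ICV jointly, controlling age
        if "handedness" in df.columns:
            hand = df["handedness"].astype(str).to_numpy()
            ok = hand != "mixed"
            h01 = (hand[ok] == "left").astype(float)  # right handers coded 0
            X = np.column_stack(
                [np.ones(ok.sum()), h01, sex[ok], icv[ok], age[ok]]
            )
            beta, se, p, _ = _ols(y[ok], X)
            for k, pred in ((1, "handedness"), (2, "sex"), (3, "icv")):
                rows.append(
                    _result_row(cid, pred, beta[k], se[k], p[k],
                                int(ok.sum()), alpha)
                )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_alpha"] = alpha
    return out


def _result_row(cid, predictor, beta, se, p, n, alpha):
    return {
        "cluster_id": cid,
        "predictor": predictor,
        "beta": float(beta),
        "se": float(se),
        "ci_low": float(beta - 1.96 * se),
        "ci_high": float(beta + 1.96 * se),
        "p": float(p),
        "n": n,
        "sig_bonferroni": bool(p < alpha),
    }


def association_bonferroni_alpha(
    n_clusters: int, n_predictors: int = 4, alpha_base: float = 0.01
) -> float:
    """Per-test threshold for the association screen (alpha / (clusters × predictors))."""
    if n_clusters < 1 or n_predictors < 1:
        raise AssociationError("counts must be positive")
    return alpha_base / (n_clusters * n_predictors)
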