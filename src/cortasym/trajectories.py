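"""Factor-smooth penalized-spline mixed models for hemispheric age trajectories.

The model for a cluster's hemispheric value y (one row per scan per
hemisphere) is

    y = β₀ + β_H·h + β_a·a + β_aH·a·h + covariates
        + s_L(age)·[hemi = L] + s_R(age)·[hemi = R] + b_subject + ε,

with h = ±1/2 hemisphere coding, a the standardized age, s_L/s_R penalized
spline smooths, b ~ N(0, σ_b²) a subject random intercept and ε ~ N(0, σ²).

The smooths use a cubic B-spline basis with k = 6 basis functions (knots at
age quantiles) under a second-order difference penalty, in the mixed-model
reparametrization: the basis is sum-to-zero constrained, its penalty null
space (the linear-in-age trend) is carried by the explicit β_a/β_aH columns,
and the remaining "wiggly" directions are whitened so the penalty is λ·I.
Smoothing parameters and the subject variance ratio are chosen by profiled
REML; as λ → ∞ each smooth therefore vanishes and the fit degenerates to
the hemisphere-specific linear model.

The asymmetry difference trajectory d(age) is the difference of the
demeaned hemispheric age-curves plus the hemisphere offset, with pointwise
Bayesian credible intervals from the penalized-coefficient posterior
covariance, evaluated through the model's linear predictor matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace


class DesignError(ValueError):
    pass


class ExtrapolationError(ValueError):
    pass


# --------------------------------------------------------------------------
# basis construction
# --------------------------------------------------------------------------


@dataclass
class _SmoothBasis:
    """Whitened wiggly B-spline basis shared by both hemisphere smooths."""

    knots: np.ndarray
    transform: np.ndarray  # (k, r): B(x) @ transform = wiggly columns
    rank: int
    age_min: float
    age_max: float

    def evaluate(self, ages: np.ndarray) -> np.ndarray:
        x = np.asarray(ages, dtype=float)
        x = np.clip(x, self.age_min, self.age_max)
        B = BSpline.design_matrix(x, self.knots, 3).toarray()
        return B @ self.transform


def _build_basis(ages: np.ndarray, k: int) -> _SmoothBasis:
    if k < 4:
        raise DesignError("need at least 4 basis functions for a cubic basis")
    a0, a1 = float(ages.min()), float(ages.max())
    if a1 <= a0:
        raise DesignError("ages must span a positive range")
    n_interior = k - 4
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(ages, qs) if n_interior else np.array([])
    knots = np.concatenate([[a0] * 4, interior, [a1] * 4])
    B = BSpline.design_matrix(ages, knots, 3).toarray()
    # sum-to-zero over the fitting ages
    c = B.mean(axis=0)
    q, _ = np.linalg.qr(np.column_stack([c, np.eye(k)[:, :-1]]))
    Z = q[:, 1:]  # (k, k-1), orthogonal complement of c
    D2 = np.diff(np.eye(k), n=2, axis=0)
    S = Z.T @ (D2.T @ D2) @ Z
    w, U = np.linalg.eigh(S)
    keep = w > w.max() * 1e-10
    transform = Z @ U[:, keep] / np.sqrt(w[keep])
    return _SmoothBasis(knots, transform, int(keep.sum()), a0, a1)


# --------------------------------------------------------------------------
# model fit container
# --------------------------------------------------------------------------


@dataclass
class TrajectoryFit:
    basis: _SmoothBasis
    coef: np.ndarray
    coef_cov: np.ndarray  # posterior covariance of all coefficients
    col_names: list[str]
    slices: dict  # name -> slice into coef for each block
    lambdas: dict  # smoothing parameters {"L", "R", "subject"}
    sigma2: float  # residual variance
    subject_var: float
    reml: float  # maximized restricted log-likelihood (-0.5 * criterion)
    reml_trace: np.ndarray
    converged: bool
    age_mean: float
    age_sd: float
    scanner_levels: list
    include_icv: bool
    icv_mean: float
    sex_mean: float
    subject_levels: list
    k: int
    n_obs: int
    design: np.ndarray | None = None  # full penalized design (rows = obs)
    response: np.ndarray | None = None

    @property
    def age_range(self) -> tuple[float, float]:
        return self.basis.age_min, self.basis.age_max

    # -- linear predictor rows ------------------------------------------------

    def _rows(self, ages: np.ndarray, hemi: str, *, with_intercept=True):
        """Linear-functional rows L with L @ coef = predicted trajectory.

        Covariates-of-no-interest are held at reference values: sex at the
        sample proportion, scanner at its first level, ICV at the sample
        mean; the subject random effect is zero.
        """
        ages = np.asarray(ages, dtype=float)
        h = 0.5 if hemi == "L" else -0.5
        a = (ages - self.age_mean) / self.age_sd
        L = np.zeros((len(ages), len(self.coef)))
        if with_intercept:
            L[:, self.slices["intercept"]] = 1.0
            L[:, self.slices["hemi"]] = h
        L[:, self.slices["age"]] = a[:, None]
        L[:, self.slices["age_hemi"]] = (a * h)[:, None]
        W = self.basis.evaluate(ages)
        L[:, self.slices["smooth_L" if hemi == "L" else "smooth_R"]] = W
        return L

    def predict(self, ages, hemi: str):
        """Reference-covariate trajectory for one hemisphere with SE."""
        L = self._rows(np.asarray(ages, float), hemi)
        mu = L @ self.coef
        se = np.sqrt(np.einsum("ij,jk,ik->i", L, self.coef_cov, L))
        return mu, se

    def fitted_marginal(self, data: pd.DataFrame, hemi: str) -> np.ndarray:
        """Population-level prediction at each row's observed covariates."""
        X, _, _ = _design_rows(self, data, hemi)
        return X @ self.coef


@dataclass
class DifferenceTrajectory:
    ages: np.ndarray
    d: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray = field(init=False)
    ci_high: np.ndarray = field(init=False)
    p_nonzero: float = np.nan
    p_change: float = np.nan

    def __post_init__(self):
        half = 1.96 * self.se
        self.ci_low = self.d - half
        self.ci_high = self.d + half


# --------------------------------------------------------------------------
# design assembly
# --------------------------------------------------------------------------


def _long_format(data: pd.DataFrame) -> pd.DataFrame:
    """Two rows (hemispheres) per scan from a cluster-table slice."""
    keep = ["subject_id", "age", "sex", "scanner", "icv"]
    rows = []
    for hemi, col in (("L", "lh_mean"), ("R", "rh_mean")):
        part = data[keep].copy()
        part["hemi"] = hemi
        part["y"] = data[col].to_numpy()
        rows.append(part)
    return pd.concat(rows, ignore_index=True)


def _design_rows(fit: TrajectoryFit, data: pd.DataFrame, hemi: str) -> tuple:
    """Design rows for observed covariates (no subject effect)."""
    n = len(data)
    ages = data["age"].to_numpy(dtype=float)
    L = fit._rows(ages, hemi)
    sx = data["sex"].to_numpy(dtype=float)
    L[:, fit.slices["sex"]] = (sx - fit.sex_mean)[:, None]
    for j, lev in enumerate(fit.scanner_levels[1:]):
        L[:, fit.slices["scanner"].start + j] = (
            data["scanner"].to_numpy() == lev
        ).astype(float)
    if fit.include_icv:
        L[:, fit.slices["icv"]] = (
            data["icv"].to_numpy(dtype=float) - fit.icv_mean
        )[:, None]
    return L, ages, n


def fit_factor_smooth(
    data: pd.DataFrame,
    k: int = 6,
    include_icv: bool = False,
    max_iter: int = 600,
    tol: float = 1e-8,
) -> TrajectoryFit:
    """Fit the factor-smooth penalized-spline mixed model to one cluster.

    ``data`` is a cluster-table slice (one cluster) with columns
    subject_id, age, sex, scanner, icv, lh_mean, rh_mean.  Smoothing
    parameters for the two hemisphere smooths and the subject-intercept
    variance ratio are selected by profiled REML (Nelder–Mead on the log
    scale); convergence requires the relative REML change to fall below
    ``tol`` within ``max_iter`` evaluations of the profiled criterion.
    """
    long = _long_format(data)
    n = len(long)
    if n < 10 * k:
        raise DesignError(f"need at least {10 * k} observations, got {n}")
    ages = long["age"].to_numpy(dtype=float)
    basis = _build_basis(ages, k)
    r = basis.rank

    age_mean, age_sd = float(ages.mean()), float(ages.std())
    a = (ages - age_mean) / age_sd
    h = np.where(long["hemi"].to_numpy() == "L", 0.5, -0.5)
    sex = long["sex"].to_numpy(dtype=float)
    scanner_levels = sorted(pd.unique(long["scanner"]))
    icv = long["icv"].to_numpy(dtype=float)
    icv_mean = float(icv.mean())

    cols = {
        "intercept": np.ones(n),
        "hemi": h,
        "age": a,
        "age_hemi": a * h,
        "sex": sex - sex.mean(),
    }
    scanner_block = np.column_stack(
        [
            (long["scanner"].to_numpy() == lev).astype(float)
            for lev in scanner_levels[1:]
        ]
    ) if len(scanner_levels) > 1 else np.empty((n, 0))
    icv_block = (
        (icv - icv_mean)[:, None] if include_icv else np.empty((n, 0))
    )

    W = basis.evaluate(ages)
    WL = W * (h > 0)[:, None]
    WR = W * (h < 0)[:, None]
    subjects = sorted(pd.unique(long["subject_id"]))
    subj_idx = pd.Categorical(
        long["subject_id"], categories=subjects
    ).codes
    n_subj = len(subjects)
    Zs = np.zeros((n, n_subj))
    Zs[np.arange(n), subj_idx] = 1.0

    fixed = np.column_stack(list(cols.values()) + [scanner_block, icv_block])
    p_fixed = fixed.shape[1]
    if np.linalg.matrix_rank(fixed) < p_fixed:
        raise DesignError("rank-deficient covariate design")

    C = np.column_stack([fixed, WL, WR, Zs])
    p_tot = C.shape[1]
    slices = {
        "intercept": slice(0, 1),
        "hemi": slice(1, 2),
        "age": slice(2, 3),
        "age_hemi": slice(3, 4),
        "sex": slice(4, 5),
        "scanner": slice(5, 5 + scanner_block.shape[1]),
    }
    pos = 5 + scanner_block.shape[1]
    if include_icv:
        slices["icv"] = slice(pos, pos + 1)
        pos += 1
    else:
        slices["icv"] = slice(pos, pos)
    slices["smooth_L"] = slice(pos, pos + r)
    slices["smooth_R"] = slice(pos + r, pos + 2 * r)
    slices["subject"] = slice(pos + 2 * r, pos + 2 * r + n_subj)

    y = long["y"].to_numpy(dtype=float)
    CtC = C.T @ C
    Cty = C.T @ y
    yty = float(y @ y)
    p0 = p_fixed  # penalty null-space dimension
    pen_idx = np.arange(p_fixed, p_tot)

    sl_L, sl_R, sl_s = slices["smooth_L"], slices["smooth_R"], slices["subject"]

    def criterion(log_lam, want_fit=False):
        lam = np.exp(np.clip(log_lam, -25.0, 25.0))
        A = CtC.copy()
        diag = np.zeros(p_tot)
        diag[sl_L] = lam[0]
        diag[sl_R] = lam[1]
        diag[sl_s] = lam[2]
        A[np.arange(p_tot), np.arange(p_tot)] += diag
        cf = cho_factor(A, lower=True)
        theta = cho_solve(cf, Cty)
        rss = yty - 2 * theta @ Cty + theta @ (CtC @ theta)
        pen = float(theta[pen_idx] ** 2 @ diag[pen_idx])
        sig2 = max(rss + pen, 1e-300) / (n - p0)
        logdet_A = 2.0 * np.log(np.diag(cf[0])).sum()
        logdet_S = (
            r * np.log(lam[0]) + r * np.log(lam[1]) + n_subj * np.log(lam[2])
        )
        crit = (
            (n - p0) * (np.log(2 * np.pi * sig2) + 1.0)
            + logdet_A
            - logdet_S
        )
        if want_fit:
            return crit, theta, sig2, cf
        return crit

    trace: list[float] = []

    def wrapped(x):
        c = criterion(x)
        trace.append(min(c, trace[-1]) if trace else c)
        return c

    res = optimize.minimize(
        wrapped,
        x0=np.zeros(3),
        method="Nelder-Mead",
        options={"maxfev": max_iter, "fatol": 1e-6, "xatol": 1e-4},
    )
    if not res.success:  # restart with a fresh simplex at the current best
        res = optimize.minimize(
            wrapped,
            x0=res.x,
            method="Nelder-Mead",
            options={"maxfev": max_iter, "fatol": 1e-6, "xatol": 1e-4},
        )

    def _plateaued(rel_tol):
        return len(trace) > 20 and abs(trace[-1] - trace[-21]) < rel_tol * (
            1 + abs(trace[-1])
        )

    # converged if the optimizer met its tolerances or the best criterion
    # value plateaued; the looser plateau (1e-6 relative over 20
    # evaluations) absorbs slow crawling along flat smoothing-parameter
    # ridges at the boundary, where the fit itself is unchanged
    converged = bool(res.success) or _plateaued(tol) or _plateaued(1e-6)
    if not converged:
        raise ConvergenceError(
            "REML optimization did not converge", trace=np.asarray(trace)
        )

    crit, theta, sig2, cf = criterion(res.x, want_fit=True)
    lam = np.exp(np.clip(res.x, -25.0, 25.0))
    coef_cov = sig2 * cho_solve(cf, np.eye(p_tot))
    col_names = (
        ["intercept", "hemi", "age", "age_hemi", "sex"]
        + [f"scanner[{lev}]" for lev in scanner_levels[1:]]
        + (["icv"] if include_icv else [])
        + [f"sL{i}" for i in range(r)]
        + [f"sR{i}" for i in range(r)]
        + [f"subj[{s}]" for s in subjects]
    )
    return TrajectoryFit(
        basis=basis,
        coef=theta,
        coef_cov=coef_cov,
        col_names=col_names,
        slices=slices,
        lambdas={"L": lam[0], "R": lam[1], "subject": lam[2]},
        sigma2=float(sig2),
        subject_var=float(sig2 / lam[2]),
        reml=-0.5 * crit,
        reml_trace=np.asarray(trace),
        converged=converged,
        age_mean=age_mean,
        age_sd=age_sd,
        scanner_levels=scanner_levels,
        include_icv=include_icv,
        icv_mean=icv_mean,
        sex_mean=float(sex.mean()),
        subject_levels=subjects,
        k=k,
        n_obs=n,
        design=C,
        response=y,
    )


# --------------------------------------------------------------------------
# derived quantities
# --------------------------------------------------------------------------


def _wald_truncated(d: np.ndarray, cov: np.ndarray) -> float:
    """Wald χ² p-value with rank-truncated covariance pseudo-inverse."""
    w, U = np.linalg.eigh((cov + cov.T) / 2)
    keep = w > max(w.max(), 0.0) * 1e-8
    if not keep.any():
        return 1.0
    z = U[:, keep].T @ d
    statv = float(np.sum(z**2 / w[keep]))
    return float(stats.chi2.sf(statv, df=int(keep.sum())))


def difference_trajectory(
    fit: TrajectoryFit, grid: np.ndarray
) -> DifferenceTrajectory:
    """Asymmetry trajectory d(age) with pointwise 95% CIs and Wald tests.

    d(age) is the difference of the grid-demeaned hemispheric age-curves
    plus the hemisphere offset; its covariance follows from the linear
    predictor matrix and the coefficient posterior.  Two tests are
    reported: d ≡ 0 anywhere (asymmetry somewhere in life) and
    d non-constant (asymmetry changes with age).
    """
    grid = np.asarray(grid, dtype=float)
    a0, a1 = fit.age_range
    if grid.min() < a0 - 1e-9 or grid.max() > a1 + 1e-9:
        raise ExtrapolationError("grid extends outside the fitted age range")
    G = len(grid)
    L_L = fit._rows(grid, "L", with_intercept=False)
    L_R = fit._rows(grid, "R", with_intercept=False)
    M = np.eye(G) - 1.0 / G
    Ld = M @ (L_L - L_R)
    Ld[:, fit.slices["hemi"]] = 1.0
    d = Ld @ fit.coef
    cov = Ld @ fit.coef_cov @ Ld.T
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    p_nonzero = _wald_truncated(d, cov)
    p_change = _wald_truncated(M @ d, M @ cov @ M.T)
    return DifferenceTrajectory(
        ages=grid, d=d, se=se, p_nonzero=p_nonzero, p_change=p_change
    )


def peak_asymmetry_age(
    fit: TrajectoryFit, grid_resolution: float = 0.25
) -> tuple[float | None, pd.DataFrame]:
    """Age where the hemispheric trajectories' CIs are maximally non-overlapping.

    On a dense age grid, gap(age) = lower CI bound of the larger-valued
    hemisphere minus the upper CI bound of the smaller.  The peak is the
    earliest argmax of the gap; None if the CIs overlap everywhere.
    """
    if grid_resolution > 0.5:
        raise ValueError("grid_resolution must be <= 0.5 years")
    a0, a1 = fit.age_range
    grid = np.arange(a0, a1 + grid_resolution / 2, grid_resolution)
    mu_l, se_l = fit.predict(grid, "L")
    mu_r, se_r = fit.predict(grid, "R")
    lo_l, hi_l = mu_l - 1.96 * se_l, mu_l + 1.96 * se_l
    lo_r, hi_r = mu_r - 1.96 * se_r, mu_r + 1.96 * se_r
    gap = np.where(mu_l >= mu_r, lo_l - hi_r, lo_r - hi_l)
    diag = pd.DataFrame({"age": grid, "gap": gap})
    if np.all(gap <= 0):
        return None, diag
    return float(grid[int(np.argmax(gap))]), diag


def detect_and_refit_outliers(
    data: pd.DataFrame,
    fit: TrajectoryFit,
    sd_threshold: float = 6.0,
    **fit_kwargs,
) -> tuple[pd.DataFrame, TrajectoryFit, pd.DataFrame]:
    """Remove scans >``sd_threshold`` residual SDs from either hemisphere's
    trajectory and refit once.

    Residuals are taken against the population-level fitted trajectory at
    each scan's observed covariates (no subject effect) and scaled by the
    model's residual SD, so a gross error of k residual SDs measures ≈ k.
    A scan is removed if either hemisphere exceeds the threshold.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    sd = np.sqrt(fit.sigma2)
    log_rows = []
    keep = np.ones(len(data), dtype=bool)
    for hemi, col in (("L", "lh_mean"), ("R", "rh_mean")):
        pred = fit.fitted_marginal(data, hemi)
        z = (data[col].to_numpy(dtype=float) - pred) / sd
        bad = np.abs(z) > sd_threshold
        keep &= ~bad
        for i in np.flatnonzero(bad):
            log_rows.append(
                {
                    "subject_id": data["subject_id"].iloc[i],
                    "timepoint": data["timepoint"].iloc[i]
                    if "timepoint" in data
                    else 1,
                    "hemi": hemi,
                    "residual_sd": float(z[i]),
                }
            )
    cleaned = data.loc[keep].reset_index(drop=True)
    log = pd.DataFrame(
        log_rows, columns=["subject_id", "timepoint", "hemi", "residual_sd"]
    )
    if cleaned.empty:
        raise DesignError("outlier removal emptied the data")
    refit = fit_factor_smooth(
        cleaned, k=fit.k, include_icv=fit.include_icv, **fit_kwargs
    )
    return cleaned, refit, log


def relative_change(
    fit: TrajectoryFit, grid: np.ndarray
) -> pd.DataFrame:
    """Hemispheric trajectories scaled by their prediction at the minimum age.

    Requires an ICV-adjusted fit.  Each hemisphere's reference-covariate
    trajectory is divided by its own value at the youngest fitted age, so
    the relative value there is exactly 1; SEs follow by the delta method.
    """
    if not fit.include_icv:
        raise DesignError("relative_change requires a fit with the ICV covariate")
    grid = np.asarray(grid, dtype=float)
    a0, a1 = fit.age_range
    if grid.min() < a0 - 1e-9 or grid.max() > a1 + 1e-9:
        raise ExtrapolationError("grid extends outside the fitted age range")
    out = {"age": grid}
    for hemi in ("L", "R"):
        Lg = fit._rows(grid, hemi)
        L0 = fit._rows(np.array([a0]), hemi)
        mu = Lg @ fit.coef
        mu0 = float((L0 @ fit.coef)[0])
        if mu0 <= 0:
            raise DesignError("non-positive baseline prediction")
        rel = mu / mu0
        grad = Lg / mu0 - np.outer(rel / mu0, L0[0])
        se = np.sqrt(
            np.maximum(
                np.einsum("ij,jk,ik->i", grad, fit.coef_cov, grad), 0.0
            )
        )
        out[f"rel_{hemi}"] = rel
        out[f"se_{hemi}"] = se
    return pd.DataFrame(out)
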