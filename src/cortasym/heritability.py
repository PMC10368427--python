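"""Heritability of asymmetry: GRM construction, GREML, twin AE models.

SNP heritability follows the GREML approach: a genetic relationship matrix
(GRM) from frequency-standardized dosages, relatedness pruning, and
restricted maximum likelihood on V = σ²_g·A + σ²_e·I with the top GRM
eigenvectors as fixed effects controlling population structure.  The REML
maximization is average-information (AI) REML with an EM warm start,
carried out in the GRM eigenbasis where every iteration is O(n·p).

Twin heritability uses AE variance decomposition on family blocks: within
a family with expected additive-genetic correlation matrix K (1 for MZ
co-twins, 0.5 for DZ co-twins and siblings), phenotypes have covariance
a²·K + e²·I.  Bivariate versions estimate the genetic correlation rG with
a Cholesky parametrization of the genetic and environmental trait
covariance blocks; significance comes from likelihood-ratio tests (the
0.5·χ²₀ + 0.5·χ²₁ boundary mixture for variance tests, χ²₁ for covariance
tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import FamilyData, GenotypePanel


class HeritabilityError(ValueError):
    pass


class RemlError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace


@dataclass
class GRM:
    """Genetic relationship matrix with lazily cached eigendecomposition."""

    matrix: np.ndarray
    n_snps: int
    _eig: tuple | None = field(default=None, repr=False)

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    def eig(self):
        if self._eig is None:
            w, q = np.linalg.eigh(self.matrix)
            self._eig = (w, q)
        return self._eig

    def subset(self, idx: np.ndarray) -> "GRM":
        return GRM(self.matrix[np.ix_(idx, idx)], self.n_snps)


@dataclass
class HeritabilityEstimate:
    method: str  # "SNP" or "twin"
    var_genetic: float
    var_env: float
    h2: float
    se: float
    p: float
    loglik: float
    null_loglik: float
    converged: bool
    n: int
    n_iter: int = 0


@dataclass
class GeneticCorrelationEstimate:
    method: str
    rG: float
    se: float
    p: float
    var_genetic: tuple
    var_env: tuple
    loglik: float
    null_loglik: float
    n: int


# --------------------------------------------------------------------------
# phenotype preparation
# --------------------------------------------------------------------------


def adjust_phenotype(y, age, sex) -> np.ndarray:
    """Regress age and sex out of a phenotype and z-score the residuals."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(y), np.asarray(age, float),
                         np.asarray(sex, float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    sd = r.std()
    if sd == 0:
        raise HeritabilityError("phenotype has zero residual variance")
    return r / sd


# --------------------------------------------------------------------------
# GRM construction and pruning
# --------------------------------------------------------------------------


def compute_grm(panel: GenotypePanel, maf_min: float = 0.01) -> GRM:
    """GRM from frequency-standardized dosages.

    A_jk = (1/M) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1−p_i)) over SNPs
    with sample minor allele frequency ≥ ``maf_min``; missing dosages are
    mean-imputed per SNP; p_i is the sample allele frequency.
    """
    x = np.asarray(panel.dosage, dtype=float)
    if x.shape[0] < 2:
        raise HeritabilityError("need at least 2 subjects")
    p = np.nanmean(x, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min
    if not keep.any():
        raise HeritabilityError("all SNPs removed by the MAF filter")
    x = x[:, keep]
    p = p[keep]
    x = np.where(np.isnan(x), 2.0 * p, x)  # mean imputation
    w = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m = w.shape[1]
    return GRM(matrix=(w @ w.T) / m, n_snps=m)


def prune_related(grm: GRM, cutoff: float = 0.025) -> np.ndarray:
    """Greedy relatedness pruning: indices of subjects kept.

    While any off-diagonal relatedness exceeds ``cutoff``, remove the
    individual involved in the most such pairs (lowest index on ties), so
    exactly one member of an isolated related pair is dropped.
    """
    if cutoff <= 0:
        raise HeritabilityError("cutoff must be positive")
    a = grm.matrix.copy()
    np.fill_diagonal(a, 0.0)
    alive = np.ones(a.shape[0], dtype=bool)
    over = a > cutoff
    while True:
        counts = np.where(alive, (over & alive[None, :]).sum(axis=1), -1)
        if counts.max() <= 0:
            break
        alive[int(np.argmax(counts))] = False
    return np.flatnonzero(alive)


def grm_pcs(grm: GRM, n_pcs: int = 10) -> np.ndarray:
    """Top eigenvectors of the GRM (genetic population-structure axes)."""
    w, q = grm.eig()
    return q[:, ::-1][:, :n_pcs]


# --------------------------------------------------------------------------
# univariate GREML (AI-REML in the GRM eigenbasis)
# --------------------------------------------------------------------------


def _reml_parts(yt, xt, lam, sg, se_):
    """REML log-likelihood pieces in the eigenbasis (constants dropped)."""
    v = sg * lam + se_
    if np.any(v <= 0):
        return None
    vinv = 1.0 / v
    xtv = xt * vinv[:, None]
    B = xt.T @ xtv
    sign, logdet_b = np.linalg.slogdet(B)
    if sign <= 0:
        return None
    binv_xty = np.linalg.solve(B, xtv.T @ yt)
    py = yt * vinv - xtv @ binv_xty
    quad = float(yt @ py)
    ll = -0.5 * (np.log(v).sum() + logdet_b + quad)
    return ll, v, vinv, B, py, xtv


def greml(
    y: np.ndarray,
    grm: GRM,
    covariates: np.ndarray | None = None,
    n_pcs: int = 10,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> HeritabilityEstimate:
    """SNP heritability by AI-REML under V = σ²_g·A + σ²_e·I.

    Fixed effects are an intercept, the top ``n_pcs`` GRM eigenvectors,
    and any extra ``covariates`` columns.  Variance components are floored
    at 1e-6 of the phenotypic variance; the p-value tests σ²_g = 0 by LRT
    against the 0.5·χ²₀ + 0.5·χ²₁ boundary mixture.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != grm.n_subjects:
        raise HeritabilityError("phenotype/GRM size mismatch")
    lam, q = grm.eig()
    X = [np.ones((n, 1))]
    if n_pcs:
        X.append(grm_pcs(grm, n_pcs))
    if covariates is not None:
        X.append(np.atleast_2d(np.asarray(covariates, float).T).T)
    X = np.hstack(X)
    p = X.shape[1]
    yt, xt = q.T @ y, q.T @ X

    vary = float(y.var())
    floor = 1e-6 * vary
    sg, se_ = 0.5 * vary, 0.5 * vary

    # EM warm start
    for _ in range(2):
        parts = _reml_parts(yt, xt, lam, sg, se_)
        if parts is None:
            break
        _, v, vinv, B, py, xtv = parts
        tr_p_lam = float((lam * vinv).sum()) - float(
            np.trace(np.linalg.solve(B, xtv.T @ (xt * (lam * vinv**2)[:, None])))
        )
        tr_p = float(vinv.sum()) - float(
            np.trace(np.linalg.solve(B, xtv.T @ (xt * (vinv**2)[:, None])))
        )
        sg = max(sg + sg**2 * (float(py @ (lam * py)) - tr_p_lam) / n, floor)
        se_ = max(se_ + se_**2 * (float(py @ py) - tr_p) / n, floor)

    trace = []
    ll = -np.inf
    ai_inv = np.eye(2)
    converged = False
    for it in range(max_iter):
        parts = _reml_parts(yt, xt, lam, sg, se_)
        if parts is None:
            raise RemlError("non-positive-definite V", trace=trace)
        ll_new, v, vinv, B, py, xtv = parts
        trace.append(ll_new)
        if it > 0 and abs(ll_new - ll) < tol * (1 + abs(ll_new)):
            ll = ll_new
            converged = True
            break
        ll = ll_new

        def p_apply(u):
            return u * vinv - xtv @ np.linalg.solve(B, xtv.T @ u)

        u_g = lam * py
        u_e = py
        pu_g, pu_e = p_apply(u_g), p_apply(u_e)
        ai = 0.5 * np.array(
            [
                [float(u_g @ pu_g), float(u_g @ pu_e)],
                [float(u_e @ pu_g), float(u_e @ pu_e)],
            ]
        )
        tr_p_lam = float((lam * vinv).sum()) - float(
            np.trace(np.linalg.solve(B, xtv.T @ (xt * (lam * vinv**2)[:, None])))
        )
        tr_p = float(vinv.sum()) - float(
            np.trace(np.linalg.solve(B, xtv.T @ (xt * (vinv**2)[:, None])))
        )
        score = 0.5 * np.array(
            [float(py @ u_g) - tr_p_lam, float(py @ u_e) - tr_p]
        )
        try:
            ai_inv = np.linalg.inv(ai)
        except np.linalg.LinAlgError:
            ai_inv = np.linalg.pinv(ai)
        delta = ai_inv @ score
        step = 1.0
        cur = np.array([sg, se_])
        accepted = False
        for _ in range(30):  # step-halving to stay feasible and ascend
            cand = np.maximum(cur + step * delta, floor)
            if np.allclose(cand, cur, rtol=1e-12, atol=0.0):
                # stalled at the boundary: current point is the optimum
                converged = True
                break
            parts_c = _reml_parts(yt, xt, lam, cand[0], cand[1])
            if parts_c is not None and parts_c[0] >= ll - 1e-10:
                accepted = True
                break
            step *= 0.5
        if converged:
            break
        if not accepted:
            # fall back to an EM step (ascent, slow but safe near boundaries)
            cand = np.maximum(
                np.array(
                    [
                        sg + sg**2 * (float(py @ u_g) - tr_p_lam) / n,
                        se_ + se_**2 * (float(py @ u_e) - tr_p) / n,
                    ]
                ),
                floor,
            )
            if np.allclose(cand, cur, rtol=1e-10, atol=0.0):
                converged = True
                break
        sg, se_ = float(cand[0]), float(cand[1])
    if not converged:
        raise RemlError("AI-REML did not converge", trace=trace)

    # null model: sigma_g = 0
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta0) ** 2).sum())
    se0 = rss / (n - p)
    ll0 = _reml_parts(yt, xt, lam, 0.0, se0)[0]
    lrt = max(2.0 * (ll - ll0), 0.0)
    pval = 0.5 * stats.chi2.sf(lrt, 1) + (0.5 if lrt <= 0 else 0.0)

    h2 = sg / (sg + se_)
    grad = np.array([se_, -sg]) / (sg + se_) ** 2
    se_h2 = float(np.sqrt(max(grad @ ai_inv @ grad, 0.0)))
    return HeritabilityEstimate(
        method="SNP",
        var_genetic=sg,
        var_env=se_,
        h2=float(h2),
        se=se_h2,
        p=float(pval),
        loglik=float(ll),
        null_loglik=float(ll0),
        converged=converged,
        n=n,
        n_iter=len(trace),
    )


# --------------------------------------------------------------------------
# bivariate GREML
# --------------------------------------------------------------------------


def _chol2(params3, log_diag=True):
    """2×2 PSD matrix from (log l11, l21, log l22)."""
    l11 = np.exp(params3[0]) if log_diag else params3[0]
    l22 = np.exp(params3[2]) if log_diag else params3[2]
    L = np.array([[l11, 0.0], [params3[1], l22]])
    return L @ L.T


def _bivariate_reml_loglik(params, yt2, xt, lam, fix_cg=False):
    """REML log-likelihood of the two-trait model in the eigenbasis.

    params = (log lg11, [lg21], log lg22, log le11, le21, log le22); the
    genetic cross term lg21 is omitted when ``fix_cg`` (null model).
    """
    if fix_cg:
        g = _chol2(np.array([params[0], 0.0, params[1]]))
        e = _chol2(params[2:5])
    else:
        g = _chol2(params[0:3])
        e = _chol2(params[3:6])
    n, p = xt.shape
    v = lam[:, None, None] * g[None] + e[None]  # (n, 2, 2)
    det = v[:, 0, 0] * v[:, 1, 1] - v[:, 0, 1] ** 2
    if np.any(det <= 0) or np.any(v[:, 0, 0] <= 0):
        return -np.inf
    w = np.empty_like(v)  # per-component 2x2 inverses
    w[:, 0, 0] = v[:, 1, 1] / det
    w[:, 1, 1] = v[:, 0, 0] / det
    w[:, 0, 1] = w[:, 1, 0] = -v[:, 0, 1] / det

    # X' V^-1 X (2p x 2p), X' V^-1 y (2p), y' V^-1 y
    xtx = np.empty((2 * p, 2 * p))
    xty = np.empty(2 * p)
    quad_y = 0.0
    for t in range(2):
        for s in range(2):
            xtx[t * p:(t + 1) * p, s * p:(s + 1) * p] = (
                xt.T * w[:, t, s]
            ) @ xt
        xty[t * p:(t + 1) * p] = xt.T @ (
            w[:, t, 0] * yt2[:, 0] + w[:, t, 1] * yt2[:, 1]
        )
    quad_y = float(
        np.einsum("it,its,is->", yt2, w, yt2)
    )
    sign, logdet_b = np.linalg.slogdet(xtx)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(xtx, xty)
    return -0.5 * (np.log(det).sum() + logdet_b + quad_y - float(xty @ beta))


def greml_bivariate(
    y1: np.ndarray,
    y2: np.ndarray,
    grm: GRM,
    covariates: np.ndarray | None = None,
    n_pcs: int = 10,
) -> GeneticCorrelationEstimate:
    """Bivariate GREML genetic correlation.

    Maximizes the two-trait REML likelihood over Cholesky-parametrized
    genetic and environmental covariance blocks (rG is therefore bounded
    in [−1, 1] by construction); p tests zero genetic covariance by a
    χ²₁ likelihood-ratio test against the constrained fit.
    """
    y1, y2 = np.asarray(y1, float), np.asarray(y2, float)
    n = len(y1)
    lam, q = grm.eig()
    X = [np.ones((n, 1))]
    if n_pcs:
        X.append(grm_pcs(grm, n_pcs))
    if covariates is not None:
        X.append(np.atleast_2d(np.asarray(covariates, float).T).T)
    X = np.hstack(X)
    xt = q.T @ X
    yt2 = np.column_stack([q.T @ y1, q.T @ y2])

    v1, v2 = y1.var(), y2.var()
    lo = np.log(np.sqrt(np.array([v1, v2]) * 1e-4))
    x0 = np.array(
        [np.log(np.sqrt(v1 / 2)), 0.0, np.log(np.sqrt(v2 / 2)),
         np.log(np.sqrt(v1 / 2)), 0.0, np.log(np.sqrt(v2 / 2))]
    )
    bounds = [(lo[0], None), (None, None), (lo[1], None),
              (lo[0], None), (None, None), (lo[1], None)]

    def neg(params):
        return -_bivariate_reml_loglik(params, yt2, xt, lam)

    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"maxfev": 4000, "fatol": 1e-9,
                                     "xatol": 1e-6})
    res = optimize.minimize(neg, res.x, method="L-BFGS-B", bounds=bounds)
    ll = -res.fun

    def neg0(params):
        return -_bivariate_reml_loglik(params, yt2, xt, lam, fix_cg=True)

    x0_null = np.delete(res.x, 1)
    res0 = optimize.minimize(neg0, x0_null, method="Nelder-Mead",
                             options={"maxfev": 3000, "fatol": 1e-9,
                                      "xatol": 1e-6})
    ll0 = -res0.fun

    g = _chol2(res.x[0:3])
    e = _chol2(res.x[3:6])
    rg = g[0, 1] / np.sqrt(max(g[0, 0] * g[1, 1], 1e-300))
    lrt = max(2.0 * (ll - ll0), 0.0)
    pval = float(stats.chi2.sf(lrt, 1))

    # delta-method SE from the numerical Hessian at the optimum
    se_rg = _numerical_rg_se(
        lambda prm: _bivariate_reml_loglik(prm, yt2, xt, lam),
        res.x,
        lambda prm: _chol2(prm[0:3]),
    )
    return GeneticCorrelationEstimate(
        method="SNP",
        rG=float(np.clip(rg, -1.0, 1.0)),
        se=se_rg,
        p=pval,
        var_genetic=(float(g[0, 0]), float(g[1, 1])),
        var_env=(float(e[0, 0]), float(e[1, 1])),
        loglik=float(ll),
        null_loglik=float(ll0),
        n=n,
    )


def _numerical_rg_se(loglik_fn, params, g_fn, h=1e-4) -> float:
    """SE of rG by inverse numerical Hessian + numerical delta method."""
    k = len(params)

    def rg_of(prm):
        g = g_fn(prm)
        return g[0, 1] / np.sqrt(max(g[0, 0] * g[1, 1], 1e-300))

    hess = np.zeros((k, k))
    f0 = loglik_fn(params)
    for i in range(k):
        for j in range(i, k):
            ei, ej = np.zeros(k), np.zeros(k)
            ei[i], ej[j] = h, h
            fpp = loglik_fn(params + ei + ej)
            fpm = loglik_fn(params + ei - ej)
            fmp = loglik_fn(params - ei + ej)
            fmm = loglik_fn(params - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    grad = np.zeros(k)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        grad[i] = (rg_of(params + ei) - rg_of(params - ei)) / (2 * h)
    try:
        cov = np.linalg.inv(-hess)
        var = float(grad @ cov @ grad)
        return float(np.sqrt(var)) if var > 0 else np.nan
    except np.linalg.LinAlgError:
        return np.nan


# --------------------------------------------------------------------------
# twin AE models
# --------------------------------------------------------------------------


def _family_groups(families: FamilyData, traits):
    """Rotate family blocks into independent components.

    Returns a list of (kinship eigenvalue, count, sufficient statistic):
    for one trait the statistic is the sum of squared rotated values; for
    two traits the summed 2×2 outer products.
    """
    groups: dict[float, list] = {}
    nt = len(traits)
    eig_cache: dict[str, tuple] = {}
    for _, grp in families.table.groupby("family_id", sort=True):
        rel = grp["relation_class"].iloc[0]
        if rel not in eig_cache:
            K = FamilyData.kinship_matrix(rel)
            eig_cache[rel] = np.linalg.eigh(K)
        mu, Q = eig_cache[rel]
        z = Q.T @ grp[list(traits)].to_numpy(dtype=float)
        for row, m in zip(z, mu):
            key = round(float(m), 12)
            if key not in groups:
                groups[key] = [0, np.zeros((nt, nt))]
            groups[key][0] += 1
            groups[key][1] += np.outer(row, row)
    return [(m, cnt, ss) for m, (cnt, ss) in sorted(groups.items())]


def _check_identifiable(families: FamilyData) -> None:
    coeffs = {
        1.0 if rel.startswith("MZ") else 0.5
        for rel in families.table["relation_class"].unique()
    }
    has_trio = families.table["relation_class"].str.contains(r"\+").any()
    if len(coeffs) < 2 and not has_trio:
        raise HeritabilityError(
            "single relationship class: A and E are not separable"
        )


def twin_ae(
    families: FamilyData, adjust: bool = True, trait: str = "y1"
) -> HeritabilityEstimate:
    """Univariate AE twin model by maximum likelihood on family blocks.

    Family covariance is a²·K + e²·I.  Phenotypes are age/sex-adjusted and
    z-scored first (``adjust=True``).  p tests a² = 0 by LRT against the
    boundary mixture 0.5·χ²₀ + 0.5·χ²₁.
    """
    _check_identifiable(families)
    fam = families.table.copy()
    if adjust:
        fam[trait] = adjust_phenotype(fam[trait], fam["age"], fam["sex"])
    data = FamilyData(table=fam, n_traits=families.n_traits)
    groups = _family_groups(data, [trait])
    n_tot = sum(cnt for _, cnt, _ in groups)
    var_tot = sum(float(ss[0, 0]) for _, _, ss in groups) / n_tot

    def negll(params):
        a2, e2 = params
        ll = 0.0
        for m, cnt, ss in groups:
            v = a2 * m + e2
            if v <= 0:
                return np.inf
            ll += -0.5 * (cnt * np.log(v) + float(ss[0, 0]) / v)
        return -ll

    floor = 1e-8 * var_tot
    res = optimize.minimize(
        negll,
        x0=np.array([var_tot / 2, var_tot / 2]),
        method="L-BFGS-B",
        bounds=[(0.0, None), (floor, None)],
    )
    a2, e2 = res.x
    ll = -res.fun
    ll0 = -negll(np.array([0.0, var_tot]))  # MLE under a2=0 is e2=var
    lrt = max(2.0 * (ll - ll0), 0.0)
    pval = 0.5 * stats.chi2.sf(lrt, 1) + (0.5 if lrt <= 0 else 0.0)

    # delta-method SE from the numerical Hessian of the log-likelihood
    h = 1e-5 * max(var_tot, 1e-8)
    hess = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei, ej = np.zeros(2), np.zeros(2)
            ei[i], ej[j] = h, h
            hess[i, j] = hess[j, i] = (
                -negll(res.x + ei + ej)
                + negll(res.x + ei - ej)
                + negll(res.x - ei + ej)
                - negll(res.x - ei - ej)
            ) / (4 * h * h)
    grad = np.array([e2, -a2]) / (a2 + e2) ** 2
    try:
        var_h2 = float(grad @ np.linalg.inv(-hess) @ grad)
        se_h2 = float(np.sqrt(var_h2)) if var_h2 > 0 else np.nan
    except np.linalg.LinAlgError:
        se_h2 = np.nan
    return HeritabilityEstimate(
        method="twin",
        var_genetic=float(a2),
        var_env=float(e2),
        h2=float(a2 / (a2 + e2)),
        se=se_h2,
        p=float(pval),
        loglik=float(ll),
        null_loglik=float(ll0),
        converged=bool(res.success),
        n=n_tot,
    )


def twin_ae_bivariate(
    families: FamilyData, adjust: bool = True,
    traits: tuple[str, str] = ("y1", "y2"),
) -> GeneticCorrelationEstimate:
    """Bivariate Cholesky AE twin model; rG from the genetic block.

    Family covariance is K ⊗ Σ_A + I ⊗ Σ_E with Σ_A, Σ_E Cholesky-
    parametrized 2×2 blocks; p tests zero genetic covariance (χ²₁).
    """
    _check_identifiable(families)
    if families.n_traits < 2:
        raise HeritabilityError("bivariate model needs two phenotypes")
    fam = families.table.copy()
    if adjust:
        for t in traits:
            fam[t] = adjust_phenotype(fam[t], fam["age"], fam["sex"])
    data = FamilyData(table=fam, n_traits=2)
    groups = _family_groups(data, list(traits))
    n_tot = sum(cnt for _, cnt, _ in groups)
    v1 = sum(float(ss[0, 0]) for _, _, ss in groups) / n_tot
    v2 = sum(float(ss[1, 1]) for _, _, ss in groups) / n_tot

    def loglik(params, fix_cg=False):
        if fix_cg:
            g = _chol2(np.array([params[0], 0.0, params[1]]))
            e = _chol2(params[2:5])
        else:
            g = _chol2(params[0:3])
            e = _chol2(params[3:6])
        ll = 0.0
        for m, cnt, ss in groups:
            v = m * g + e
            det = v[0, 0] * v[1, 1] - v[0, 1] ** 2
            if det <= 0 or v[0, 0] <= 0:
                return -np.inf
            vinv = np.array([[v[1, 1], -v[0, 1]], [-v[0, 1], v[0, 0]]]) / det
            ll += -0.5 * (cnt * np.log(det) + float(np.sum(vinv * ss)))
        return ll

    lo = np.log(np.sqrt(np.array([v1, v2]) * 1e-4))
    x0 = np.array([np.log(np.sqrt(v1 / 2)), 0.0, np.log(np.sqrt(v2 / 2)),
                   np.log(np.sqrt(v1 / 2)), 0.0, np.log(np.sqrt(v2 / 2))])
    res = optimize.minimize(lambda p: -loglik(p), x0, method="Nelder-Mead",
                            options={"maxfev": 4000, "fatol": 1e-10,
                                     "xatol": 1e-7})
    res = optimize.minimize(
        lambda p: -loglik(p), res.x, method="L-BFGS-B",
        bounds=[(lo[0], None), (None, None), (lo[1], None),
                (lo[0], None), (None, None), (lo[1], None)],
    )
    ll = -res.fun
    res0 = optimize.minimize(
        lambda p: -loglik(p, fix_cg=True), np.delete(res.x, 1),
        method="Nelder-Mead",
        options={"maxfev": 3000, "fatol": 1e-10, "xatol": 1e-7},
    )
    ll0 = -res0.fun
    g = _chol2(res.x[0:3])
    e = _chol2(res.x[3:6])
    rg = g[0, 1] / np.sqrt(max(g[0, 0] * g[1, 1], 1e-300))
    lrt = max(2.0 * (ll - ll0), 0.0)
    se_rg = _numerical_rg_se(loglik, res.x, lambda p: _chol2(p[0:3]))
    return GeneticCorrelationEstimate(
        method="twin",
        rG=float(np.clip(rg, -1.0, 1.0)),
        se=se_rg,
        p=float(stats.chi2.sf(lrt, 1)),
        var_genetic=(float(g[0, 0]), float(g[1, 1])),
        var_env=(float(e[0, 0]), float(e[1, 1])),
        loglik=float(ll),
        null_loglik=float(ll0),
        n=n_tot,
    )


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (rejection flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise HeritabilityError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def bonferroni_alpha(n_tests: int, alpha_base: float = 0.05) -> float:
    """Bonferroni-corrected per-test significance threshold."""
    if n_tests < 1:
        raise HeritabilityError("need at least one test")
    return alpha_base / n_tests
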