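"""Per-SNP covariate-adjusted logistic association.

Two genetic codings are supported: additive (0/1/2 copies of the minor
allele) and dominant (carrier 0/1); the recessive coding is deliberately
unavailable because low minor-allele frequencies leave it underpowered.

Three fitting routes:

``fit_snp_logistic``
    single-SNP maximum-likelihood fit through statsmodels (reference
    route, used for reported tables and as a cross-check).
``batch_logistic_wald``
    vectorized IRLS over many SNPs at once, exact casewise deletion of
    samples with a missing genotype; used for observed-column association
    and available to the permutation engine.
``batch_logistic_score``
    score test against the covariate-only null (one null fit per
    phenotype column, a handful of matrix products for all SNPs); missing
    genotypes are mean-imputed.  The fast path for permutation runs.

The statistic handed to GSEA is |t| (Wald/score z); ARTP consumes the
matching two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .containers import COVARIATES, Cohort
from .errors import ValidationError

GENETIC_MODELS = ("additive", "dominant")

#: |coefficient| beyond which a logistic fit is treated as separated
SEPARATION_BOUND = 15.0
MAX_ITER = 100
LL_TOL = 1e-8


def code_genotypes(genotypes: np.ndarray, model: str) -> np.ndarray:
    """Apply the genetic-model coding; NaN (missing) propagates."""
    if model == "additive":
        return genotypes
    if model == "dominant":
        return np.minimum(genotypes, 1.0)
    raise ValidationError(f"unknown genetic model {model!r} (recessive not available)")


@dataclass
class SnpFit:
    snp_id: str
    model: str
    coef: float
    se: float
    tstat: float
    p: float
    n_used: int
    flag: str  # "" | "monomorphic" | "separation" | "nonconvergence"


def fit_snp_logistic(cohort: Cohort, snp, model: str = "additive",
                     adjust=COVARIATES, phenotype=None) -> SnpFit:
    """ML logistic fit of status ~ genotype + covariates for one SNP.

    Samples with a missing genotype are dropped casewise.  Separation or
    non-convergence flags the SNP and reports p = 1 (flagged SNPs are
    ineligible for best-SNP selection).
    """
    import statsmodels.api as sm

    j = int(np.flatnonzero(cohort.snp_ids == snp)[0]) if isinstance(snp, str) else int(snp)
    g = code_genotypes(cohort.genotypes[:, j], model)
    y = np.asarray(cohort.phenotype if phenotype is None else phenotype, dtype=float)
    keep = ~np.isnan(g)
    C = cohort.covariate_matrix(adjust)[keep]
    g, y = g[keep], y[keep]
    snp_id = str(cohort.snp_ids[j])
    n_used = int(keep.sum())

    if np.ptp(g) == 0:
        return SnpFit(snp_id, model, np.nan, np.nan, np.nan, 1.0, n_used, "monomorphic")

    X = np.column_stack([C, g])
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=MAX_ITER)
    except Exception:
        return SnpFit(snp_id, model, np.nan, np.nan, np.nan, 1.0, n_used, "nonconvergence")
    coef, se = res.params[-1], res.bse[-1]
    if not res.mle_retvals.get("converged", True) or not np.isfinite(se):
        return SnpFit(snp_id, model, float(coef), np.nan, np.nan, 1.0, n_used, "nonconvergence")
    if abs(coef) > SEPARATION_BOUND:
        return SnpFit(snp_id, model, float(coef), float(se), np.nan, 1.0, n_used, "separation")
    t = coef / se
    p = 2.0 * norm.sf(abs(t))
    return SnpFit(snp_id, model, float(coef), float(se), float(t), float(p), n_used, "")


# ---------------------------------------------------------------------------
# batched Wald (exact casewise deletion)
# ---------------------------------------------------------------------------

def _loglik(eta, y, mask):
    # stable Bernoulli log-likelihood, masked per SNP
    return np.sum(mask * (y[:, None] * eta - np.logaddexp(0.0, eta)), axis=0)


def batch_logistic_wald(G: np.ndarray, C: np.ndarray, y: np.ndarray,
                        max_iter: int = MAX_ITER, tol: float = LL_TOL):
    """Vectorized per-SNP Newton/IRLS logistic fits.

    Parameters
    ----------
    G : (n, m) coded genotypes, NaN = missing (casewise deleted per SNP)
    C : (n, k) covariate design including intercept
    y : (n,) binary phenotype

    Returns
    -------
    coef, se, tstat, p : (m,) arrays
    flags : (m,) object array of "" / "monomorphic" / "separation" /
        "nonconvergence"; flagged SNPs report p = 1.
    """
    n, m = G.shape
    k = C.shape[1]
    y = np.asarray(y, dtype=np.float64)
    mask = (~np.isnan(G)).astype(np.float64)
    Gz = np.nan_to_num(G, nan=0.0)

    # monomorphic after casewise deletion: zero variance among observed
    nobs = mask.sum(axis=0)
    mean_g = np.where(nobs > 0, (Gz * mask).sum(axis=0) / np.maximum(nobs, 1), 0.0)
    var_g = (mask * (Gz - mean_g) ** 2).sum(axis=0)
    mono = (var_g <= 0) | (nobs == 0)

    beta = np.zeros((m, k + 1))
    p_case = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    beta[:, 0] = np.log(p_case / (1 - p_case))  # intercept warm start

    active = ~mono
    ll_prev = np.full(m, -np.inf)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = C @ beta[:, :k].T + Gz * beta[:, k]
        mu = expit(eta)
        w = mu * (1.0 - mu) * mask + 1e-12
        r = (y[:, None] - mu) * mask

        gC = np.einsum("nm,nk->mk", r, C)
        gg = (Gz * r).sum(axis=0)
        A = np.einsum("nm,nj,nk->mjk", w, C, C)
        b = np.einsum("nm,nm,nk->mk", w, Gz, C)
        c = (w * Gz * Gz).sum(axis=0)

        H = np.empty((m, k + 1, k + 1))
        H[:, :k, :k] = A
        H[:, k, :k] = b
        H[:, :k, k] = b
        H[:, k, k] = c
        grad = np.concatenate([gC, gg[:, None]], axis=1)

        idx = np.flatnonzero(active)
        try:
            step = np.linalg.solve(H[idx], grad[idx][..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(H[i], grad[i], rcond=None)[0] for i in idx])
        beta[idx] += step

        eta = C @ beta[:, :k].T + Gz * beta[:, k]
        ll = _loglik(eta, y, mask)
        done = np.abs(ll - ll_prev) <= tol * (np.abs(ll) + 1.0)
        newly = active & done
        converged |= newly
        active &= ~done
        ll_prev = ll
        # runaway coefficients: stop iterating, flag as separated below
        active &= np.abs(beta[:, k]) <= SEPARATION_BOUND * 2

    # final observed-information standard errors
    eta = C @ beta[:, :k].T + Gz * beta[:, k]
    mu = expit(eta)
    w = mu * (1.0 - mu) * mask + 1e-12
    A = np.einsum("nm,nj,nk->mjk", w, C, C)
    b = np.einsum("nm,nm,nk->mk", w, Gz, C)
    c = (w * Gz * Gz).sum(axis=0)
    H = np.empty((m, k + 1, k + 1))
    H[:, :k, :k] = A
    H[:, k, :k] = b
    H[:, :k, k] = b
    H[:, k, k] = c
    with np.errstate(all="ignore"):
        Hinv = np.full((m, k + 1, k + 1), np.nan)
        ok = np.flatnonzero(~mono)
        if ok.size:
            try:
                Hinv[ok] = np.linalg.inv(H[ok])
            except np.linalg.LinAlgError:
                for i in ok:
                    try:
                        Hinv[i] = np.linalg.inv(H[i])
                    except np.linalg.LinAlgError:
                        pass
        se = np.sqrt(Hinv[:, k, k])

    coef = beta[:, k].copy()
    flags = np.full(m, "", dtype=object)
    flags[mono] = "monomorphic"
    sep = (~mono) & (np.abs(coef) > SEPARATION_BOUND)
    flags[sep] = "separation"
    nonconv = (~mono) & (~sep) & (~converged)
    flags[nonconv] = "nonconvergence"
    bad = mono | sep | nonconv | ~np.isfinite(se)
    flags[(~mono) & (~sep) & (~nonconv) & ~np.isfinite(se)] = "nonconvergence"

    with np.errstate(all="ignore"):
        t = np.where(bad, np.nan, coef / se)
        p = np.where(bad, 1.0, 2.0 * norm.sf(np.abs(t)))
    coef[mono] = np.nan
    return coef, se, t, p, flags


# ---------------------------------------------------------------------------
# score-test fast path
# ---------------------------------------------------------------------------

def fit_null_logistic(C: np.ndarray, y: np.ndarray,
                      max_iter: int = MAX_ITER, tol: float = LL_TOL) -> np.ndarray:
    """IRLS fit of the covariate-only logistic model; returns coefficients."""
    y = np.asarray(y, dtype=np.float64)
    beta = np.zeros(C.shape[1])
    p_case = np.clip(y.mean(), 1e-12, 1 - 1e-12)
    beta[0] = np.log(p_case / (1 - p_case))
    ll_prev = -np.inf
    for _ in range(max_iter):
        eta = C @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        grad = C.T @ (y - mu)
        H = (C * w[:, None]).T @ C
        beta = beta + np.linalg.solve(H, grad)
        ll = float(np.sum(y * (C @ beta) - np.logaddexp(0.0, C @ beta)))
        if abs(ll - ll_prev) <= tol * (abs(ll) + 1.0):
            break
        ll_prev = ll
    return beta


def mean_impute(G: np.ndarray) -> np.ndarray:
    """Replace missing genotypes by the per-SNP observed mean."""
    out = G.copy()
    means = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
    means = np.nan_to_num(means, nan=0.0)
    nan_r, nan_c = np.nonzero(np.isnan(out))
    out[nan_r, nan_c] = means[nan_c]
    return out


def batch_logistic_score(G_imputed: np.ndarray, C: np.ndarray, y: np.ndarray,
                         null_beta: np.ndarray | None = None):
    """Rao score test of each genotype column against the covariate null.

    ``G_imputed`` must already be mean-imputed (see :func:`mean_impute`).
    Returns ``(z, p, flags)``; degenerate columns (no genotype variance in
    the weighted metric) are flagged "monomorphic" with p = 1.
    """
    y = np.asarray(y, dtype=np.float64)
    if null_beta is None:
        null_beta = fit_null_logistic(C, y)
    mu = expit(C @ null_beta)
    w = mu * (1.0 - mu)
    U = G_imputed.T @ (y - mu)
    CW = C * w[:, None]
    A = C.T @ CW
    B = G_imputed.T @ CW                    # (m, k)
    gWg = ((G_imputed * G_imputed) * w[:, None]).sum(axis=0)
    V = gWg - np.einsum("mk,kl,ml->m", B, np.linalg.inv(A), B)

    flags = np.full(G_imputed.shape[1], "", dtype=object)
    bad = V <= 1e-10
    flags[bad] = "monomorphic"
    with np.errstate(all="ignore"):
        z = np.where(bad, np.nan, U / np.sqrt(V))
        p = np.where(bad, 1.0, 2.0 * norm.sf(np.abs(z)))
    return z, p, flags


def association_table(cohort: Cohort, models=GENETIC_MODELS,
                      adjust=COVARIATES, phenotype=None) -> pd.DataFrame:
    """Observed-label AssocTable: one row per SNP × genetic model (Wald)."""
    C = cohort.covariate_matrix(adjust)
    y = cohort.phenotype if phenotype is None else phenotype
    nobs = (~np.isnan(cohort.genotypes)).sum(axis=0)
    frames = []
    for model in models:
        G = code_genotypes(cohort.genotypes, model)
        coef, se, t, p, flags = batch_logistic_wald(G, C, y)
        frames.append(pd.DataFrame({
            "snp_id": cohort.snp_ids,
            "model": model,
            "coef": coef,
            "se": se,
            "tstat": t,
            "p": p,
            "n_used": nobs,
            "flag": flags,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# demographic odds ratios
# ---------------------------------------------------------------------------

def demographic_or(a: float, b: float, c: float, d: float,
                   continuity: bool = False) -> dict:
    """Univariate odds ratio from a 2×2 table.

    Layout: a = exposed cases, b = exposed controls, c = unexposed cases,
    d = unexposed controls.  OR = ad/bc with a Wald 95% CI and p-value.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells <= 0).any():
        if not continuity:
            raise ValidationError(
                "zero cell in 2x2 table; rerun with continuity=True to add "
                "0.5 to every cell"
            )
        cells = cells + 0.5
    a, b, c, d = cells
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    return {
        "or": float(np.exp(log_or)),
        "ci_low": float(np.exp(log_or - 1.96 * se)),
        "ci_high": float(np.exp(log_or + 1.96 * se)),
        "p": float(2.0 * norm.sf(abs(z))),
    }


def multivariate_demographics(cohort: Cohort, adjust=COVARIATES) -> pd.DataFrame:
    """Joint logistic fit of status on the demographic covariates.

    Mirrors the multivariate column of a standard case-control Table 1:
    per-covariate OR (per unit; per year for age), Wald 95% CI and p.
    """
    import statsmodels.api as sm

    X = cohort.covariate_matrix(adjust)
    y = np.asarray(cohort.phenotype, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("singular covariate design")
    res = sm.Logit(y, X).fit(disp=0, maxiter=MAX_ITER)
    rows = []
    for i, name in enumerate(adjust, start=1):
        coef, se = res.params[i], res.bse[i]
        rows.append({
            "covariate": name,
            "or": float(np.exp(coef)),
            "ci_low": float(np.exp(coef - 1.96 * se)),
            "ci_high": float(np.exp(coef + 1.96 * se)),
            "p": float(2.0 * norm.sf(abs(coef / se))),
        })
    return pd.DataFrame(rows)
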