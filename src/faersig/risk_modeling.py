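"""Univariate -> LASSO -> multivariate logistic cascade.

The report-level design matrix carries one 0/1 primary-suspect exposure
indicator per candidate drug plus age (years), weight (kg) and a female-sex
indicator.  Candidate drugs are screened by cross-validated L1-penalized
logistic regression (coordinate descent on the working weighted
least-squares problem, glmnet-style, with warm starts along a geometric
lambda path); demographics and the intercept are never penalized.  The
surviving drugs enter an unpenalized maximum-likelihood logistic fit by
iteratively reweighted least squares, reported as Wald odds ratios with
log-symmetric 95% intervals and Bonferroni-adjusted p-values over the drug
terms.  Model discrimination is summarized by the ROC curve and its
rank-based (Mann–Whitney) AUC.

Coefficients are always reported on the original covariate scale (odds
ratios per year of age, per kg of weight); standardization happens only
inside the penalized solver.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata

from . import config
from .report_store import ReportSet

logger = logging.getLogger(__name__)

DEMOGRAPHIC_COLUMNS = ("age_years", "weight_kg", "sex_female")


@dataclass
class DesignMatrix:
    """Report-level design: X (n x p) with named columns, binary outcome y.

    ``drug_columns`` lists the penalizable exposure indicators; the final
    three columns are the unpenalized demographics.
    """

    X: pd.DataFrame
    y: np.ndarray
    drug_columns: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.X.columns)


@dataclass
class LassoPath:
    lambda_grid: np.ndarray
    coefficients: pd.DataFrame        # rows = lambdas, columns = intercept + features
    cv_mean_deviance: np.ndarray
    cv_se: np.ndarray
    selected_lambda: float
    selected_columns: tuple[str, ...]
    converged: np.ndarray = field(default=None)


@dataclass
class ModelFit:
    """Wald summary of an unpenalized logistic maximum-likelihood fit."""

    params: pd.DataFrame              # coef, se, or_point, or_low, or_high, p_raw, p_adj, separation
    converged: bool
    n_iterations: int
    log_likelihood: float
    dropped_columns: tuple[str, ...] = ()

    def predict_proba(self, dm: DesignMatrix) -> np.ndarray:
        eta = np.full(dm.n, self.params.loc["intercept", "coef"])
        for col in self.params.index:
            if col != "intercept" and col in dm.X.columns:
                eta = eta + self.params.loc[col, "coef"] * dm.X[col].to_numpy(float)
        return expit(eta)


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def build_design_matrix(
    clean_set: ReportSet,
    candidate_drugs: Sequence[str],
    event_terms: Iterable[str] = config.DEFAULT_EVENT_TERMS,
) -> DesignMatrix:
    """One row per report: candidate primary-suspect indicators + age,
    weight, female sex; outcome = event reported.

    Candidates with zero exposed rows are dropped with a warning.  The set
    must already have passed the demographic filters, so the matrix is
    complete-case by construction.
    """
    terms = {str(t).strip().upper() for t in event_terms if str(t).strip()}
    if not terms:
        raise ValueError("event_terms must be non-empty")
    demo = clean_set.demo
    if demo[["age_years", "weight_kg"]].isna().any().any() or (~demo["sex"].isin(["female", "male"])).any():
        raise ValueError("design matrix requires complete demographics; run apply_demographic_filters first")

    event_ids = set(clean_set.reactions.loc[clean_set.reactions["pt"].isin(terms), "report_id"])
    y = demo.index.isin(event_ids).astype(float)
    if y.min() == y.max():
        raise ValueError("outcome is constant; cannot model")

    X = pd.DataFrame(index=demo.index)
    kept = []
    pairs = clean_set.drugs[["report_id", "ingredient"]].drop_duplicates()
    for drug in candidate_drugs:
        exposed = pairs.loc[pairs["ingredient"] == drug, "report_id"]
        col = demo.index.isin(set(exposed)).astype(float)
        if col.sum() == 0:
            warnings.warn(f"candidate drug {drug!r} has no exposed reports; dropped")
            continue
        X[drug] = col
        kept.append(drug)
    X["age_years"] = demo["age_years"].to_numpy(float)
    X["weight_kg"] = demo["weight_kg"].to_numpy(float)
    X["sex_female"] = demo["sex"].eq("female").to_numpy(float)
    return DesignMatrix(X=X, y=np.asarray(y, float), drug_columns=tuple(kept))


# ---------------------------------------------------------------------------
# Penalized logistic regression (coordinate descent)
# ---------------------------------------------------------------------------

def _irls_fit(X: np.ndarray, y: np.ndarray, tol: float = 1e-10, max_iter: int = 100):
    """Plain Newton/IRLS on a dense design (first column = intercept)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = math.log((y.mean() + 1e-12) / (1 - y.mean() + 1e-12))
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _cd_solve(
    Xs: np.ndarray,
    y: np.ndarray,
    lam: float,
    penalized: np.ndarray,
    beta0: float,
    beta: np.ndarray,
    tol: float = 1e-9,
    max_outer: int = 60,
    max_inner: int = 200,
):
    """One penalized logistic fit at penalty *lam* by IRLS-outer /
    coordinate-descent-inner iterations on standardized columns.

    Objective: (1/n) sum log(1 + exp(-(2y-1) eta)) + lam * sum_pen |beta_j|.
    Returns (beta0, beta, converged).
    """
    n, p = Xs.shape
    converged = False
    for _ in range(max_outer):
        eta = beta0 + Xs @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        sw = w.sum()
        b0_old, b_old = beta0, beta.copy()
        r = z - eta  # working residual
        for _inner in range(max_inner):
            delta = 0.0
            # intercept (unpenalized)
            upd = float(w @ r) / sw
            beta0 += upd
            r -= upd
            delta = max(delta, abs(upd))
            for j in range(p):
                xj = Xs[:, j]
                bj = beta[j]
                rho = float(w @ (xj * r)) / n + bj * float(w @ (xj * xj)) / n
                denom = float(w @ (xj * xj)) / n
                if penalized[j]:
                    bj_new = math.copysign(max(abs(rho) - lam, 0.0), rho) / denom
                else:
                    bj_new = rho / denom
                if bj_new != bj:
                    r -= xj * (bj_new - bj)
                    beta[j] = bj_new
                    delta = max(delta, abs(bj_new - bj))
            if delta < tol:
                break
        if max(abs(beta0 - b0_old), float(np.max(np.abs(beta - b_old))) if p else 0.0) < 1e-6:
            converged = True
            break
    return beta0, beta, converged


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels 0..k-1, stratified by outcome, shuffled by *rng*."""
    fold = np.empty(len(y), dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def fit_lasso_logistic(
    dm: DesignMatrix,
    grid_size: int = 50,
    k_folds: int = 10,
    seed: int = 0,
    n_decades: float = 4.0,
) -> LassoPath:
    """Cross-validated L1 logistic path over the candidate drugs.

    The lambda grid runs geometrically from lambda_max (the smallest
    penalty at which every drug coefficient is zero, computed from the
    working residual of the demographics-only fit) down ``n_decades``
    decades.  Folds are stratified on the outcome and seeded on the
    canonical (sorted report_id) row ordering, so permuting the input rows
    changes nothing.  The selected lambda minimizes the mean held-out
    deviance; ``selected_columns`` are the drugs with nonzero coefficients
    there.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    order = np.argsort(dm.X.index.to_numpy())
    X = dm.X.to_numpy(float)[order]
    y = np.asarray(dm.y, float)[order]
    cols = list(dm.X.columns)
    penalized = np.array([c in dm.drug_columns for c in cols])

    xm = X.mean(axis=0)
    xs = X.std(axis=0)
    if np.any(xs == 0):
        bad = [c for c, s in zip(cols, xs) if s == 0]
        raise ValueError(f"constant columns in design matrix: {bad}")
    Xs = (X - xm) / xs
    n = len(y)

    # lambda_max from the unpenalized (demographics-only) working residual
    null_cols = np.concatenate([np.ones((n, 1)), Xs[:, ~penalized]], axis=1)
    null_beta = _irls_fit(null_cols, y)
    mu0 = expit(null_cols @ null_beta)
    lam_max = float(np.max(np.abs(Xs[:, penalized].T @ (y - mu0))) / n)
    lam_grid = np.geomspace(lam_max, lam_max * 10 ** (-n_decades), grid_size)

    def _path(X_fit, y_fit):
        beta0 = math.log((y_fit.mean() + 1e-12) / (1 - y_fit.mean() + 1e-12))
        beta = np.zeros(X_fit.shape[1])
        out = np.empty((grid_size, X_fit.shape[1] + 1))
        conv = np.empty(grid_size, dtype=bool)
        for i, lam in enumerate(lam_grid):
            beta0, beta, ok = _cd_solve(X_fit, y_fit, lam, penalized, beta0, beta)
            out[i, 0] = beta0
            out[i, 1:] = beta
            conv[i] = ok
            if not ok:
                logger.warning("coordinate descent did not converge at lambda=%g", lam)
        return out, conv

    full_path, conv = _path(Xs, y)

    rng = np.random.default_rng(seed)
    fold = _stratified_folds(y, k_folds, rng)
    dev = np.empty((k_folds, grid_size))
    for k in range(k_folds):
        tr, va = fold != k, fold == k
        if y[va].min() == y[va].max() or y[tr].min() == y[tr].max():
            raise ValueError("a CV fold has a one-class outcome; reduce k_folds")
        path_k, _ = _path(Xs[tr], y[tr])
        eta = path_k[:, 0:1] + path_k[:, 1:] @ Xs[va].T   # grid x n_val
        ll = y[va] * eta - np.logaddexp(0.0, eta)
        dev[k] = -2.0 * ll.mean(axis=1)
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / math.sqrt(k_folds)

    i_best = int(np.argmin(cv_mean))
    sel_mask = full_path[i_best, 1:][penalized] != 0.0
    selected = tuple(str(c) for c in np.array(cols)[penalized][sel_mask])

    # back to the original scale
    coefs = full_path[:, 1:] / xs
    intercepts = full_path[:, 0] - coefs @ xm
    coef_df = pd.DataFrame(
        np.concatenate([intercepts[:, None], coefs], axis=1),
        columns=["intercept"] + cols,
        index=pd.Index(lam_grid, name="lambda"),
    )
    return LassoPath(
        lambda_grid=lam_grid,
        coefficients=coef_df,
        cv_mean_deviance=cv_mean,
        cv_se=cv_se,
        selected_lambda=float(lam_grid[i_best]),
        selected_columns=selected,
        converged=conv,
    )


# ---------------------------------------------------------------------------
# Unpenalized multivariate fit (IRLS)
# ---------------------------------------------------------------------------

def fit_logistic_irls(
    dm: DesignMatrix,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_coef: float = 15.0,
) -> ModelFit:
    """Maximum-likelihood logistic fit by damped IRLS with Wald inference.

    Collinear columns are dropped (pivoted-QR rank check) with a warning.
    Convergence means the score max-norm on internally standardized
    covariates falls below *tol*.  Columns whose coefficient exceeds
    ``separation_coef`` in absolute value (on the standardized scale within
    the fit, reported on the raw scale) are flagged as possibly separated;
    the fit is still returned.  Bonferroni adjustment is applied over the
    drug terms only.
    """
    cols = list(dm.X.columns)
    X_raw = dm.X.to_numpy(float)
    y = np.asarray(dm.y, float)

    # rank check on the raw design (with intercept)
    full = np.concatenate([np.ones((len(y), 1)), X_raw], axis=1)
    from scipy.linalg import qr

    _, R, piv = qr(full, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    keep_piv = piv[diag > max(full.shape) * np.finfo(float).eps * diag[0]]
    dropped = tuple(cols[j - 1] for j in sorted(set(range(full.shape[1])) - set(keep_piv)) if j > 0)
    if dropped:
        warnings.warn(f"dropping collinear columns: {dropped}")
        cols = [c for c in cols if c not in dropped]
        X_raw = dm.X[cols].to_numpy(float)

    # standardize internally for numerics; exact affine back-transform below
    xm = X_raw.mean(axis=0)
    xs = X_raw.std(axis=0)
    xs[xs == 0] = 1.0
    Xs = np.concatenate([np.ones((len(y), 1)), (X_raw - xm) / xs], axis=1)

    beta = np.zeros(Xs.shape[1])
    beta[0] = math.log((y.mean() + 1e-12) / (1 - y.mean() + 1e-12))

    def _loglik(b):
        eta = Xs @ b
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    ll = _loglik(beta)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = Xs @ beta
        mu = expit(eta)
        score = Xs.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        w = np.clip(mu * (1 - mu), 1e-10, None)
        info = (Xs * w[:, None]).T @ Xs
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # damping: halve the step until the log-likelihood does not decrease
        t_step = 1.0
        for _ in range(30):
            cand = beta + t_step * step
            ll_new = _loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            t_step /= 2.0
        beta = beta + t_step * step
        ll = _loglik(beta)
        if np.max(np.abs(t_step * step)) < 1e-14:
            break

    eta = Xs @ beta
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = (Xs * w[:, None]).T @ Xs
    cov_s = np.linalg.pinv(info)

    # affine back-transform: beta_raw_j = beta_s_j / s_j ; intercept shifts
    scale = np.concatenate([[1.0], 1.0 / xs])
    A = np.diag(scale)
    A[0, 1:] = -xm / xs
    beta_raw = A @ beta
    cov_raw = A @ cov_s @ A.T
    se = np.sqrt(np.clip(np.diag(cov_raw), 0.0, None))

    names = ["intercept"] + cols
    z = np.divide(beta_raw, se, out=np.zeros_like(beta_raw), where=se > 0)
    p_raw = 2.0 * norm.sf(np.abs(z))
    drug_terms = [c for c in cols if c in dm.drug_columns]
    m = max(len(drug_terms), 1)
    p_adj = [min(1.0, m * p) if name in drug_terms else np.nan for name, p in zip(names, p_raw)]
    separated = np.abs(beta_raw * np.concatenate([[1.0], xs])) > separation_coef
    if separated.any():
        warnings.warn(
            "possible separation for terms: "
            + ", ".join(np.array(names)[separated])
        )
    params = pd.DataFrame(
        {
            "coef": beta_raw,
            "se": se,
            "or_point": np.exp(beta_raw),
            "or_low": np.exp(beta_raw - 1.96 * se),
            "or_high": np.exp(beta_raw + 1.96 * se),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "separation": separated,
        },
        index=pd.Index(names, name="term"),
    )
    params["flagged_independent"] = params.index.isin(drug_terms) & (params["p_adj"] < 0.01)
    return ModelFit(
        params=params,
        converged=converged,
        n_iterations=n_iter,
        log_likelihood=ll,
        dropped_columns=dropped,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie), via average
    ranks."""
    y = np.asarray(y, float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def compute_roc_auc(fit: ModelFit, dm: DesignMatrix) -> RocCurve:
    """ROC curve of the fitted probabilities against the outcome, with the
    rank-based AUC (ties counted one half)."""
    scores = fit.predict_proba(dm)
    y = dm.y.astype(float)
    auc = rank_auc(scores, y)
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    tpr = np.r_[0.0, tp / tp[-1]]
    fpr = np.r_[0.0, fp / fp[-1]]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)
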