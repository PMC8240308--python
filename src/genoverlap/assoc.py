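"""Per-SD association of polygenic scores with binary or continuous outcomes.

The logistic fit is a from-scratch iteratively reweighted least squares
(IRLS) maximum-likelihood routine with step-halving, standard errors from
the inverse observed information; continuous outcomes use ordinary least
squares with homoskedastic standard errors.  Effects are reported per one
standard deviation of the score, as an odds ratio with a Wald 95% CI for
binary outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .prs import PrsResult

logger = logging.getLogger(__name__)

_SEPARATION_NORM = 50.0  # |coef| beyond this on standardized inputs ≈ separation


@dataclass
class AssocResult:
    """Per-SD effect of a score on one outcome (log-odds or linear units)."""

    beta: float
    se: float
    pval: float
    n: int
    outcome: str
    family: str  # "logistic" | "linear"
    or_point: float = np.nan
    ci_lower: float = np.nan
    ci_upper: float = np.nan
    n_cases: int = 0
    n_controls: int = 0
    threshold: float = np.nan
    n_snps: int = 0
    subtype: str = "all"


class SeparationError(RuntimeError):
    """Raised when the logistic MLE diverges (perfect separation)."""


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # Stable Bernoulli log-likelihood: sum y*eta - log(1 + exp(eta))
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    column_names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximum-likelihood logistic regression via IRLS with step-halving.

    Parameters
    ----------
    y : binary response in {0, 1}, both classes present.
    X : design matrix including the intercept column; must be full rank.

    Returns ``(coef, se, cov)`` where ``cov`` is the inverse observed
    information at the optimum.  Convergence is declared when the largest
    absolute coefficient change falls below ``tol``.  Diverging
    coefficients (infinity-norm beyond 50 on standardized inputs) raise
    :class:`SeparationError` naming the offending column.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("response has a single class; logistic fit undefined")
    n, p = X.shape
    names = column_names or [f"x{j}" for j in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")

    beta = np.zeros(p)
    ll = _loglik(y, X @ beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        # Newton step solved via the weighted normal equations
        XtW = X.T * w
        info = XtW @ X
        score = X.T @ (y - mu)
        step = np.linalg.solve(info, score)

        new_beta = beta + step
        new_ll = _loglik(y, X @ new_beta)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = _loglik(y, X @ new_beta)
            halvings += 1

        delta = np.max(np.abs(new_beta - beta))
        beta, ll = new_beta, new_ll
        if np.max(np.abs(beta)) > _SEPARATION_NORM:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"logistic fit diverging (|coef| > {_SEPARATION_NORM}); "
                f"column {worst!r} likely separates the response"
            )
        if delta < tol:
            break
    else:
        logger.warning("fit_logistic: not converged after %d iterations (delta=%.2e)", max_iter, delta)

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, cov


def _fit_ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS with homoskedastic standard errors."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = resid @ resid / (n - p)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return coef, np.sqrt(np.diag(cov))


def prs_association(
    pheno: pd.DataFrame,
    prs: PrsResult,
    covariate_names: list[str],
    outcome: str = "status",
    family: str | None = None,
) -> AssocResult:
    """Fit ``outcome ~ z_score + covariates`` and report the per-SD effect.

    Individuals are matched on the ``iid`` column.  ``family`` is inferred
    from the outcome values when not given: a {0,1}-valued column is fit by
    logistic regression, anything else by OLS.  The returned record carries
    the Wald 95% CI (odds-ratio scale for logistic) and two-sided normal p.
    """
    scores = prs.to_frame()
    merged = pheno.merge(scores, on="iid", how="inner")
    if len(merged) == 0:
        raise ValueError("phenotype table and PRS share no individuals")
    merged = merged.dropna(subset=[outcome, "z"] + list(covariate_names))

    y = merged[outcome].to_numpy(float)
    if family is None:
        family = "logistic" if set(np.unique(y)) <= {0.0, 1.0} else "linear"
    if family == "linear" and np.var(y) == 0:
        raise ValueError(f"continuous outcome {outcome!r} has zero variance")

    X = np.column_stack(
        [np.ones(len(merged)), merged["z"].to_numpy(float)]
        + [merged[c].to_numpy(float) for c in covariate_names]
    )
    names = ["intercept", "z_score"] + list(covariate_names)

    if family == "logistic":
        coef, se, _ = fit_logistic(y, X, column_names=names)
    else:
        coef, se = _fit_ols(y, X)

    b, s = float(coef[1]), float(se[1])
    z975 = stats.norm.ppf(0.975)
    pval = float(2 * stats.norm.sf(abs(b / s)))
    res = AssocResult(
        beta=b,
        se=s,
        pval=pval,
        n=len(merged),
        outcome=outcome,
        family=family,
        threshold=prs.threshold,
        n_snps=prs.n_snps,
    )
    if family == "logistic":
        res.or_point = float(np.exp(b))
        res.ci_lower = float(np.exp(b - z975 * s))
        res.ci_upper = float(np.exp(b + z975 * s))
        res.n_cases = int(y.sum())
        res.n_controls = int(len(y) - y.sum())
    else:
        res.ci_lower = b - z975 * s
        res.ci_upper = b + z975 * s
    return res


def subtype_association(
    pheno: pd.DataFrame,
    prs: PrsResult,
    covariate_names: list[str],
    subtype_column: str,
    outcome: str = "status",
) -> list[AssocResult]:
    """All-cases association plus one per case subtype against shared controls.

    ``subtype_column`` labels cases (rows with ``outcome == 1``); controls
    are reused for every subtype analysis.  Subtypes with zero cases are
    skipped with a logged note.
    """
    results = [prs_association(pheno, prs, covariate_names, outcome=outcome)]
    results[0].subtype = "all"
    controls = pheno[pheno[outcome] == 0]
    cases = pheno[pheno[outcome] == 1]
    for label, sub_cases in cases.groupby(subtype_column):
        if len(sub_cases) == 0:
            logger.info("subtype %r has zero cases; skipped", label)
            continue
        sub = pd.concat([sub_cases, controls], ignore_index=True)
        res = prs_association(sub, prs, covariate_names, outcome=outcome)
        res.subtype = str(label)
        results.append(res)
    return results
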