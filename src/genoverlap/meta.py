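"""Fixed-effects inverse-variance meta-analysis of log odds ratios.

Supports both direct (beta, se) study inputs and reconstruction from a
printed odds ratio with its confidence interval, which is how a published
estimate without standard errors enters a pooled analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sumstats import ci_to_se


@dataclass
class StudyEstimate:
    """One cohort's log-odds estimate with its standard error."""

    label: str
    beta: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"study {self.label!r}: standard error must be positive")


@dataclass
class EstimateRecord:
    """A pooled (or single-method) estimate with CI on the fitted scale."""

    method: str
    beta: float
    se: float
    ci_lower: float
    ci_upper: float
    pval: float
    n_studies: int
    or_point: float = np.nan
    or_ci_lower: float = np.nan
    or_ci_upper: float = np.nan


def fixed_effect_meta(estimates: list[StudyEstimate], level: float = 0.95) -> EstimateRecord:
    """Inverse-variance-weighted fixed-effects pooling of study estimates.

    Weights are ``1/se_k^2``; the pooled beta is the weighted mean, pooled
    se ``1/sqrt(sum of weights)``, with a Wald CI and two-sided normal p.
    """
    if len(estimates) == 0:
        raise ValueError("meta-analysis requires at least one study estimate")
    beta = np.array([e.beta for e in estimates])
    se = np.array([e.se for e in estimates])
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = stats.norm.ppf((1 + level) / 2)
    pval = float(2 * stats.norm.sf(abs(pooled / pooled_se)))
    lo, hi = pooled - z * pooled_se, pooled + z * pooled_se
    return EstimateRecord(
        method="fixed_effect_meta",
        beta=pooled,
        se=pooled_se,
        ci_lower=lo,
        ci_upper=hi,
        pval=pval,
        n_studies=len(estimates),
        or_point=float(np.exp(pooled)),
        or_ci_lower=float(np.exp(lo)),
        or_ci_upper=float(np.exp(hi)),
    )


def meta_odds_ratios(
    or_ci_list: list[tuple[float, float, float]],
    level: float = 0.95,
    labels: list[str] | None = None,
) -> EstimateRecord:
    """Pool printed odds-ratio estimates ``(OR, ci_lower, ci_upper)``.

    Each study is converted to the log scale — ``beta = ln(OR)``, standard
    error reconstructed from the symmetric log-scale CI — then pooled with
    :func:`fixed_effect_meta`; the result is reported back on the OR scale.
    """
    if len(or_ci_list) == 0:
        raise ValueError("meta-analysis requires at least one estimate")
    labels = labels or [f"study{i + 1}" for i in range(len(or_ci_list))]
    estimates = []
    for label, (or_point, lo, hi) in zip(labels, or_ci_list):
        if min(or_point, lo, hi) <= 0:
            raise ValueError(f"study {label!r}: odds ratio and CI bounds must be positive")
        if not lo <= or_point <= hi:
            raise ValueError(f"study {label!r}: OR must lie within its CI")
        estimates.append(
            StudyEstimate(label, beta=float(np.log(or_point)), se=ci_to_se(lo, hi, level, "odds_ratio"))
        )
    return fixed_effect_meta(estimates, level=level)
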