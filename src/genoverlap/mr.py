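"""Two-sample Mendelian randomization estimators and diagnostics.

Given J instruments with harmonized exposure/outcome effects
(beta_X, sigma_X, beta_Y, sigma_Y), the per-instrument causal estimate is the
Wald ratio beta_Y / beta_X with first-order standard error sigma_Y / |beta_X|
(NOME: exposure-side uncertainty is ignored, reasonable for genome-wide
significant instruments).  The suite combines instruments five ways:

* IVW — inverse-variance-weighted mean of Wald ratios; algebraically the
  weighted least-squares slope of beta_Y on beta_X through the origin with
  weights sigma_Y^-2.  Fixed-effect version is the primary estimate.
* MR-Egger — the same regression with a free intercept; the intercept
  estimates average directional pleiotropy, the slope the causal effect
  under the InSIDE assumption.  Standard errors carry a multiplicative
  overdispersion factor max(1, sqrt(RSS_w / (J - 2))) and p-values use the
  t distribution with J - 2 df.
* Weighted median — consistent when >= 50% of weight comes from valid
  instruments; SE by parametric bootstrap.
* Weighted mode — the peak of a weighted Gaussian-kernel density over the
  Wald ratios (largest homogeneous cluster); SE by parametric bootstrap.
* Cochran's Q — weighted heterogeneity of the Wald ratios around the IVW
  estimate, chi-square with J - 1 df; excess heterogeneity flags pleiotropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumStatTable, harmonize


@dataclass
class MrInput:
    """Harmonized instrument effects for the two samples."""

    snp_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray

    def __post_init__(self) -> None:
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        if not (
            len(self.snp_ids)
            == len(self.beta_exposure)
            == len(self.se_exposure)
            == len(self.beta_outcome)
            == len(self.se_outcome)
        ):
            raise ValueError("instrument arrays must have equal length")
        if len(self.snp_ids) < 1:
            raise ValueError("at least one instrument required")
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_instruments(self) -> int:
        return len(self.snp_ids)

    @classmethod
    def from_harmonized(cls, harmonized: pd.DataFrame) -> "MrInput":
        return cls(
            snp_ids=list(harmonized["snp_id"]),
            beta_exposure=harmonized["beta_exposure"].to_numpy(),
            se_exposure=harmonized["se_exposure"].to_numpy(),
            beta_outcome=harmonized["beta_outcome"].to_numpy(),
            se_outcome=harmonized["se_outcome"].to_numpy(),
        )


@dataclass
class MrResult:
    """One estimator's output, with OR-scale display fields where meaningful."""

    method: str
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    pval: float
    n_snps: int
    or_point: float = np.nan
    or_ci_lower: float = np.nan
    or_ci_upper: float = np.nan


def _with_or(res: MrResult) -> MrResult:
    res.or_point = float(np.exp(res.estimate))
    res.or_ci_lower = float(np.exp(res.ci_lower))
    res.or_ci_upper = float(np.exp(res.ci_upper))
    return res


def wald_ratios(input: MrInput) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument causal ratio and first-order standard error."""
    bx = input.beta_exposure
    if np.any(bx == 0):
        bad = input.snp_ids[int(np.flatnonzero(bx == 0)[0])]
        raise ValueError(f"instrument {bad!r} has zero exposure effect; Wald ratio undefined")
    return input.beta_outcome / bx, input.se_outcome / np.abs(bx)


def mr_ivw(input: MrInput) -> MrResult:
    """Fixed-effects inverse-variance-weighted estimate.

    ``estimate = sum(bx * by / sy^2) / sum(bx^2 / sy^2)``,
    ``se = 1 / sqrt(sum(bx^2 / sy^2))`` — the weighted least-squares slope
    through the origin of outcome on exposure betas with weights sy^-2.
    """
    bx, by, sy = input.beta_exposure, input.beta_outcome, input.se_outcome
    wx2 = np.sum(bx**2 / sy**2)
    est = float(np.sum(bx * by / sy**2) / wx2)
    se = float(1.0 / np.sqrt(wx2))
    z = stats.norm.ppf(0.975)
    pval = float(2 * stats.norm.sf(abs(est / se)))
    return _with_or(
        MrResult("ivw", est, se, est - z * se, est + z * se, pval, input.n_instruments)
    )


def mr_egger(input: MrInput) -> tuple[MrResult, MrResult]:
    """MR-Egger regression: (slope, intercept) results.

    Exposure effects are oriented non-negative (both members of a pair are
    sign-flipped where beta_X < 0) before the weighted regression of
    beta_Y on beta_X with intercept, weights sigma_Y^-2.
    """
    j = input.n_instruments
    if j < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    flip = np.sign(input.beta_exposure)
    flip[flip == 0] = 1.0
    bx = input.beta_exposure * flip
    by = input.beta_outcome * flip
    w = 1.0 / input.se_outcome**2

    X = np.column_stack([np.ones(j), bx])
    if np.var(bx) == 0:
        raise ValueError("oriented exposure effects have zero variance; Egger slope unidentified")
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ by)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    # Multiplicative overdispersion, never shrinking below the fixed-effect SE
    phi = max(1.0, np.sqrt(rss_w / (j - 2)))
    cov = np.linalg.inv(A) * phi**2
    se = np.sqrt(np.diag(cov))

    tq = stats.t.ppf(0.975, df=j - 2)
    out = []
    for name, est, s in (("egger_slope", coef[1], se[1]), ("egger_intercept", coef[0], se[0])):
        pval = float(2 * stats.t.sf(abs(est / s), df=j - 2))
        res = MrResult(name, float(est), float(s), float(est - tq * s), float(est + tq * s), pval, j)
        if name == "egger_slope":
            res = _with_or(res)
        out.append(res)
    return out[0], out[1]


def _weighted_median_value(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Ratio at which normalized cumulative weight crosses 0.5, with linear
    interpolation between the straddling order statistics."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint convention: centers mass on each ratio
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def _bootstrap_se(input: MrInput, estimator, n_boot: int, seed: int) -> float:
    """Parametric bootstrap: resample betas from normals at their SEs."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    j = input.n_instruments
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bx = input.beta_exposure + input.se_exposure * rng.standard_normal(j)
        by = input.beta_outcome + input.se_outcome * rng.standard_normal(j)
        bx = np.where(bx == 0, np.finfo(float).tiny, bx)
        ratios = by / bx
        ses = input.se_outcome / np.abs(bx)
        ests[b] = estimator(ratios, 1.0 / ses**2)
    return float(np.std(ests, ddof=1))


def weighted_median(input: MrInput, n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Weighted-median estimator with parametric-bootstrap standard error."""
    if input.n_instruments < 2:
        raise ValueError("weighted median requires at least 2 instruments")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    ratios, ses = wald_ratios(input)
    est = _weighted_median_value(ratios, 1.0 / ses**2)
    se = _bootstrap_se(input, _weighted_median_value, n_boot, seed)
    z = stats.norm.ppf(0.975)
    pval = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else float(est == 0)
    return _with_or(
        MrResult("weighted_median", est, se, est - z * se, est + z * se, pval, input.n_instruments)
    )


def _mode_value(ratios: np.ndarray, weights: np.ndarray, phi: float = 1.0) -> float:
    """Argmax of the weighted Gaussian-kernel density over the ratios.

    Bandwidth is phi * 0.9 * min(SD, IQR/1.349) * J^(-1/5) (Silverman); a
    zero bandwidth (all ratios equal) returns the common ratio.  The argmax
    is located on a dense grid and refined by golden-section search.
    """
    j = len(ratios)
    if j == 1:
        return float(ratios[0])
    sd = np.std(ratios, ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = phi * 0.9 * scale * j ** (-0.2)
    if h == 0 or not np.isfinite(h):
        return float(ratios[0])

    w = weights / weights.sum()

    def density(x):
        x = np.atleast_1d(x)
        return (w * np.exp(-0.5 * ((x[:, None] - ratios) / h) ** 2)).sum(axis=1)

    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = density(grid)
    k = int(np.argmax(dens))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]

    invphi = (np.sqrt(5.0) - 1) / 2
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    for _ in range(60):
        if density(np.array([c]))[0] > density(np.array([d]))[0]:
            b, d = d, c
            c = b - invphi * (b - a)
        else:
            a, c = c, d
            d = a + invphi * (b - a)
        if b - a < 1e-12:
            break
    return float((a + b) / 2)


def weighted_mode(input: MrInput, phi: float = 1.0, n_boot: int = 1000, seed: int = 0) -> MrResult:
    """Mode-based estimator with parametric-bootstrap standard error."""
    if input.n_instruments < 2:
        raise ValueError("weighted mode requires at least 2 instruments")
    ratios, ses = wald_ratios(input)
    est = _mode_value(ratios, 1.0 / ses**2, phi=phi)
    se = _bootstrap_se(input, lambda r, w: _mode_value(r, w, phi=phi), n_boot, seed)
    z = stats.norm.ppf(0.975)
    pval = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else float(est == 0)
    return _with_or(
        MrResult("weighted_mode", est, se, est - z * se, est + z * se, pval, input.n_instruments)
    )


def cochran_q(input: MrInput) -> MrResult:
    """Cochran's Q heterogeneity of the Wald ratios around the IVW estimate.

    ``Q = sum w_j (ratio_j - beta_IVW)^2`` with first-order weights
    ``w_j = se_j^-2``; p-value from chi-square with J - 1 df.  The
    ``estimate`` field holds Q; CI fields are the chi-square critical range.
    """
    j = input.n_instruments
    if j < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    ratios, ses = wald_ratios(input)
    w = 1.0 / ses**2
    ivw = mr_ivw(input).estimate
    q = float(np.sum(w * (ratios - ivw) ** 2))
    pval = float(stats.chi2.sf(q, df=j - 1))
    return MrResult(
        "cochran_q",
        q,
        float(np.sqrt(2 * (j - 1))),  # SD of the null chi-square
        float(stats.chi2.ppf(0.025, j - 1)),
        float(stats.chi2.ppf(0.975, j - 1)),
        pval,
        j,
    )


SUITE_ORDER = ("ivw", "cochran_q", "egger_intercept", "egger_slope", "weighted_median", "weighted_mode")


def run_mr_suite(
    exposure: SumStatTable,
    outcome: SumStatTable,
    instrument_ids: list[str],
    n_boot: int = 1000,
    seed: int = 0,
    phi: float = 1.0,
    palindrome_policy: str = "infer_by_eaf",
) -> pd.DataFrame:
    """Harmonize, restrict to the instrument list, and run all estimators.

    Returns one row per method in the fixed order IVW, Cochran's Q, Egger
    intercept, Egger slope, weighted median, weighted mode, on both the
    log-odds and odds-ratio scales.  With fewer than 3 surviving
    instruments the Egger rows are skipped with a warning; with fewer than
    2, so are Q, median, and mode.
    """
    import logging  # noqa: PLC0415

    logger = logging.getLogger(__name__)
    harm = harmonize(exposure.subset(instrument_ids), outcome.subset(instrument_ids), palindrome_policy)
    if len(harm) == 0:
        raise ValueError("no instruments survive harmonization")
    mr_in = MrInput.from_harmonized(harm)
    j = mr_in.n_instruments

    results: list[MrResult] = [mr_ivw(mr_in)]
    if j >= 2:
        results.append(cochran_q(mr_in))
    if j >= 3:
        slope, intercept = mr_egger(mr_in)
        results.extend([intercept, slope])
    else:
        logger.warning("run_mr_suite: %d instruments — MR-Egger skipped", j)
    if j >= 2:
        results.append(weighted_median(mr_in, n_boot=n_boot, seed=seed))
        results.append(weighted_mode(mr_in, phi=phi, n_boot=n_boot, seed=seed + 1))

    by_method = {r.method: r for r in results}
    rows = []
    for method in SUITE_ORDER:
        r = by_method.get(method)
        if r is None:
            continue
        rows.append(
            {
                "method": method,
                "n_snps": r.n_snps,
                "estimate": r.estimate,
                "se": r.se,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "pval": r.pval,
                "or": r.or_point,
                "or_ci_lower": r.or_ci_lower,
                "or_ci_upper": r.or_ci_upper,
            }
        )
    return pd.DataFrame(rows)
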