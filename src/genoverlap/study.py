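"""One-call simulation-study replicates of the full score pipeline.

A replicate draws a fresh architecture realisation — discovery summary
statistics for trait 1, a target case-control sample ascertained on trait 2,
and an LD reference panel — then runs clumping, threshold-ladder scoring,
and covariate-adjusted per-SD association, returning the per-threshold
results.  Used by the calibration/power test suites and the acceptance
script; real-data analyses go through the CLI instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import prs_association
from .prs import build_prs_series
from .simulate import (
    ArchitectureSpec,
    random_snp_map,
    simulate_case_control,
    simulate_effects,
    simulate_reference_panel,
    simulate_sumstats,
)


def prs_pipeline_replicate(
    arch: ArchitectureSpec,
    seed: int,
    n_reference: int = 300,
    n_cases: int = 500,
    n_controls: int = 500,
    n_eff_discovery: float = 20_000,
    n_covariates: int = 3,
    thresholds: list[float] | None = None,
    r2_threshold: float = 0.1,
    window_kb: int = 250,
) -> pd.DataFrame:
    """Simulate one study and run clump -> score ladder -> association.

    Returns one row per scored threshold with columns ``threshold, n_snps,
    beta, se, or, ci_lower, ci_upper, pval``.  All randomness derives from
    ``seed``.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    derive = lambda s: int(s.generate_state(1)[0] % (2**31))  # noqa: E731

    snp_map = random_snp_map(arch.m, block_size=arch.block_size, seed=derive(ss[0]))
    b1, b2 = simulate_effects(snp_map, arch, seed=derive(ss[1]))
    reference = simulate_reference_panel(n_reference, snp_map, arch.ld_rho, seed=derive(ss[2]))
    target, pheno = simulate_case_control(
        snp_map,
        b2,
        arch.prevalence2,
        n_cases,
        n_controls,
        ld_rho=arch.ld_rho,
        n_covariates=n_covariates,
        seed=derive(ss[3]),
    )
    sumstats = simulate_sumstats(snp_map, b1, n_eff_discovery, seed=derive(ss[0]) + 1)

    covariates = ["age", "sex"] + [f"pc{i + 1}" for i in range(n_covariates)]
    rows = []
    for prs_result in build_prs_series(
        target,
        sumstats,
        reference,
        r2_threshold=r2_threshold,
        window_kb=window_kb,
        thresholds=thresholds,
    ):
        res = prs_association(pheno, prs_result, covariates)
        rows.append(
            {
                "threshold": res.threshold,
                "n_snps": res.n_snps,
                "beta": res.beta,
                "se": res.se,
                "or": res.or_point,
                "ci_lower": res.ci_lower,
                "ci_upper": res.ci_upper,
                "pval": res.pval,
            }
        )
    return pd.DataFrame(rows)
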