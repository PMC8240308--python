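"""Synthetic genotypes, correlated binary traits, and noisy discovery GWAS.

The generator emulates the statistical structure the pipeline consumes:

* LD-structured biallelic genotypes.  Haplotype alleles within a block are
  drawn from a Gaussian copula with exchangeable latent correlation
  ``ld_rho`` thresholded at the allele-frequency quantile, so marginal
  frequencies are controlled exactly and block LD is tunable; blocks are
  independent of each other.
* Two binary traits under a liability-threshold model.  A shared set of
  causal SNPs receives effect pairs from a bivariate normal with
  cross-trait correlation ``rho_g`` (the genetic correlation) and per-trait
  variances chosen so each trait's liability-scale heritability equals
  ``h2``.  An individual is a case when their liability (genetic value plus
  standard-normal residual, total variance 1) exceeds the prevalence
  threshold; case/control quotas are filled by rejection sampling.
* Discovery summary statistics with sampling noise: the estimated beta for
  SNP j is the true effect plus Gaussian noise with the standard
  ``1/sqrt(2 n p_j (1 - p_j))`` GWAS standard error.

All randomness flows from one integer seed through ``numpy`` SeedSequence
spawning, so every artefact is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


def random_snp_map(
    m: int,
    block_size: int = 10,
    seed: int = 0,
    chrom: str = "1",
    start: int = 1_000_000,
    spacing: int = 5_000,
    freq_range: tuple[float, float] = (0.05, 0.95),
) -> pd.DataFrame:
    """Build a SNP map: positions strictly increasing, frequencies uniform
    on ``freq_range`` (clipped to [0.01, 0.99]), non-palindromic allele
    pairs, and consecutive blocks of ``block_size`` SNPs.
    """
    rng = np.random.default_rng(seed)
    pos = start + spacing * np.arange(m) + rng.integers(0, spacing // 2, size=m)
    pos = np.maximum.accumulate(pos + np.arange(m))  # strictly increasing
    lo, hi = freq_range
    freqs = np.clip(rng.uniform(lo, hi, size=m), 0.01, 0.99)
    pairs = [ALLELE_PAIRS[i] for i in rng.integers(0, len(ALLELE_PAIRS), size=m)]
    return pd.DataFrame(
        {
            "snp_id": [f"rs{chrom}_{i:06d}" for i in range(m)],
            "chrom": chrom,
            "pos": pos.astype(int),
            "effect_allele": [p[0] for p in pairs],
            "other_allele": [p[1] for p in pairs],
            "freq": freqs,
            "block": np.arange(m) // block_size,
        }
    )


@dataclass
class ArchitectureSpec:
    """Genetic architecture shared by two binary traits.

    ``h2_trait1``/``h2_trait2`` are liability-scale heritabilities; ``rho_g``
    the genetic correlation between the traits' causal effects;
    ``causal_fraction`` the proportion of SNPs (a shared subset) with
    nonzero effects on both traits.
    """

    m: int
    causal_fraction: float = 0.5
    h2_trait1: float = 0.5
    h2_trait2: float = 0.5
    rho_g: float = 0.5
    prevalence1: float = 0.1
    prevalence2: float = 0.1
    ld_rho: float = 0.2
    block_size: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.m:
            raise ValueError("m must be positive")
        if not 0 <= self.causal_fraction <= 1:
            raise ValueError("causal_fraction must be in [0, 1]")
        for h2 in (self.h2_trait1, self.h2_trait2):
            if not 0 <= h2 < 1:
                raise ValueError("heritabilities must be in [0, 1)")
        if not -1 <= self.rho_g <= 1:
            raise ValueError("rho_g must be in [-1, 1]")
        for k in (self.prevalence1, self.prevalence2):
            if not 0 < k < 1:
                raise ValueError("prevalences must be in (0, 1)")
        if not 0 <= self.ld_rho <= 1:
            raise ValueError("ld_rho must be in [0, 1]")


def _draw_dosages(rng: np.random.Generator, n: int, snp_map: pd.DataFrame, ld_rho: float) -> np.ndarray:
    """Draw n individuals' dosages under the block-exchangeable Gaussian
    copula: allele present on a haplotype iff its latent normal falls below
    the Phi^-1(p_j) threshold; dosage is the sum of two haplotypes."""
    m = len(snp_map)
    thresholds = stats.norm.ppf(snp_map["freq"].to_numpy())
    blocks = snp_map["block"].to_numpy()
    block_of = pd.factorize(blocks)[0]
    n_blocks = block_of.max() + 1

    shared = rng.standard_normal((n, 2, n_blocks))
    eps = rng.standard_normal((n, 2, m))
    z = np.sqrt(ld_rho) * shared[:, :, block_of] + np.sqrt(1.0 - ld_rho) * eps
    alleles = z < thresholds  # marginal P(allele) = p_j
    return alleles.sum(axis=1).astype(float)


def simulate_reference_panel(
    n: int, snp_map: pd.DataFrame, ld_rho: float = 0.2, seed: int = 0
) -> GenotypeMatrix:
    """Simulate an LD reference panel of ``n`` individuals."""
    if n < 2:
        raise ValueError("reference panel needs at least 2 individuals")
    if not 0 <= ld_rho <= 1:
        raise ValueError("ld_rho must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    dosages = _draw_dosages(rng, n, snp_map, ld_rho)
    snps = snp_map[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    samples = [f"ref{i:05d}" for i in range(n)]
    return GenotypeMatrix(dosages, snps, samples)


def simulate_effects(
    snp_map: pd.DataFrame, spec: ArchitectureSpec, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-SNP allele-count effects ``(b1, b2)`` for the two traits.

    A shared subset of ``round(causal_fraction * m)`` SNPs receives effects
    from a bivariate normal with correlation ``rho_g``; the per-SNP variance
    on the allele-count scale is ``h2 / (n_causal * 2 p_j (1 - p_j))`` so
    each causal SNP contributes equally to liability variance.  Effects are
    then rescaled so the independent-SNP genetic liability variance
    ``sum_j b_j^2 * 2 p_j (1 - p_j)`` equals ``h2`` exactly.
    """
    m = len(snp_map)
    if m != spec.m:
        raise ValueError("snp_map length does not match spec.m")
    n_causal = int(round(spec.causal_fraction * m))
    b1 = np.zeros(m)
    b2 = np.zeros(m)
    if n_causal == 0:
        if spec.h2_trait1 > 0 or spec.h2_trait2 > 0:
            raise ValueError("causal_fraction = 0 requires zero heritability")
        return b1, b2
    if n_causal < 2 and spec.rho_g not in (-1.0, 0.0, 1.0):
        raise ValueError("cross-trait correlation undefined with fewer than 2 causal SNPs")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    causal = np.sort(rng.choice(m, size=n_causal, replace=False))
    if abs(spec.rho_g) == 1.0:
        u1 = rng.standard_normal(n_causal)
        u = np.column_stack([u1, np.sign(spec.rho_g) * u1])
    else:
        cov = np.array([[1.0, spec.rho_g], [spec.rho_g, 1.0]])
        u = rng.multivariate_normal([0.0, 0.0], cov, size=n_causal, method="cholesky")

    p = snp_map["freq"].to_numpy()[causal]
    het = 2.0 * p * (1.0 - p)
    for k, (h2, b) in enumerate(((spec.h2_trait1, b1), (spec.h2_trait2, b2))):
        if h2 == 0:
            continue
        raw = u[:, k] * np.sqrt(h2 / (n_causal * het))
        var_g = np.sum(raw**2 * het)
        b[causal] = raw * np.sqrt(h2 / var_g)  # standardize realized variance
    return b1, b2


def genetic_values(dosages: np.ndarray, snp_map: pd.DataFrame, effects: np.ndarray) -> np.ndarray:
    """Centered genetic liability ``sum_j b_j (g_j - 2 p_j)``."""
    centered = dosages - 2.0 * snp_map["freq"].to_numpy()
    return centered @ effects


def simulate_case_control(
    snp_map: pd.DataFrame,
    effects: np.ndarray,
    prevalence: float,
    n_cases: int,
    n_controls: int,
    ld_rho: float = 0.2,
    n_covariates: int = 10,
    covariate_confounding: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Sample a case-control study under the liability-threshold model.

    Individuals are drawn from the population genotype model; liability is
    the centered genetic value plus (optionally) a confounding multiple of
    the first covariate plus a Gaussian residual scaled so total liability
    variance is 1.  A draw is a case iff liability exceeds
    ``Phi^-1(1 - prevalence)``; rejection sampling runs until both quotas
    are met.  The genetic liability variance is estimated by Monte Carlo on
    an initial population batch so realized heritability is respected even
    under LD.

    Returns the genotypes and a phenotype table with columns ``iid, status,
    age, sex, pc1..pcK``.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    if min(prevalence, 1 - prevalence) < 1e-6:
        raise ValueError("expected acceptance rate below 1e-6; increase prevalence")

    ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(ss[0])
    rng_cov = np.random.default_rng(ss[1])
    threshold = stats.norm.ppf(1.0 - prevalence)

    # Population-batch Monte Carlo estimate of genetic-liability variance
    # (analytic scaling ignores LD between causal SNPs).
    var_probe = _draw_dosages(rng, 4000, snp_map, ld_rho)
    var_g = float(np.var(genetic_values(var_probe, snp_map, effects)))
    var_resid = 1.0 - var_g - covariate_confounding**2
    if var_resid <= 0.01:
        raise ValueError("genetic plus confounder variance leaves no room for residual liability")
    sd_resid = np.sqrt(var_resid)

    need = {1: n_cases, 0: n_controls}
    kept_geno: list[np.ndarray] = []
    kept_cov: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    batch = max(2048, int(2 * (n_cases / prevalence + n_controls / (1 - prevalence)) / 4))
    while need[1] > 0 or need[0] > 0:
        g = _draw_dosages(rng, batch, snp_map, ld_rho)
        k = max(n_covariates, 1)
        pcs = rng_cov.standard_normal((batch, k))[:, :n_covariates]
        conf = covariate_confounding * (pcs[:, 0] if n_covariates else rng_cov.standard_normal(batch) * 0)
        liab = genetic_values(g, snp_map, effects) + conf + sd_resid * rng.standard_normal(batch)
        status = (liab > threshold).astype(int)
        for s in (1, 0):
            if need[s] <= 0:
                continue
            idx = np.flatnonzero(status == s)[: need[s]]
            if len(idx):
                kept_geno.append(g[idx])
                kept_cov.append(pcs[idx])
                kept_status.append(np.full(len(idx), s))
                need[s] -= len(idx)

    dosages = np.vstack(kept_geno)
    pcs = np.vstack(kept_cov)
    status = np.concatenate(kept_status)
    order = rng.permutation(len(status))
    dosages, pcs, status = dosages[order], pcs[order], status[order]

    n = len(status)
    samples = [f"id{i:06d}" for i in range(n)]
    pheno = pd.DataFrame({"iid": samples, "status": status})
    pheno["age"] = rng_cov.uniform(40.0, 70.0, size=n).round(1)
    pheno["sex"] = rng_cov.integers(0, 2, size=n)
    for j in range(n_covariates):
        pheno[f"pc{j + 1}"] = pcs[:, j]

    snps = snp_map[["snp_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    return GenotypeMatrix(dosages, snps, samples), pheno


def simulate_sumstats(
    snp_map: pd.DataFrame,
    effects: np.ndarray,
    n_eff: float,
    seed: int = 0,
    noiseless: bool = False,
    study: str = "synthetic-discovery",
    trait: str = "trait1",
):
    """Generate discovery summary statistics around the true effects.

    Per SNP, ``se_j = 1 / sqrt(2 n_eff p_j (1 - p_j))`` (the GWAS standard
    error for a standardized continuous or effective-sample-size binary
    analysis) and ``beta_hat_j ~ N(b_j, se_j^2)``; the p-value is the
    two-sided normal test of ``beta_hat_j / se_j``.  ``noiseless=True``
    returns the true effects with the same standard errors.
    """
    from .sumstats import SumStatTable  # noqa: PLC0415 — avoid import cycle

    if n_eff <= 0:
        raise ValueError("effective sample size must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    p = snp_map["freq"].to_numpy()
    se = 1.0 / np.sqrt(2.0 * n_eff * p * (1.0 - p))
    beta_hat = effects.copy() if noiseless else effects + se * rng.standard_normal(len(se))
    pval = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    df = pd.DataFrame(
        {
            "snp_id": snp_map["snp_id"],
            "chrom": snp_map["chrom"].astype(str),
            "pos": snp_map["pos"],
            "effect_allele": snp_map["effect_allele"],
            "other_allele": snp_map["other_allele"],
            "eaf": snp_map["freq"],
            "beta": beta_hat,
            "se": se,
            "pval": pval,
        }
    )
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SumStatTable(df, study=study, trait=trait)
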