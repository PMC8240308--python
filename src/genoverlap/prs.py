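"""Weighted-allele polygenic scores at a ladder of p-value thresholds.

A polygenic risk score is the per-individual sum of discovery-GWAS effect
sizes multiplied by effect-allele dosages over the (clumped, thresholded)
SNP set.  Scores are reported both raw and standardized to mean 0 / SD 1
over the analysis sample, so association effects read as "per 1 SD of
score".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .sumstats import COMPLEMENT, SumStatTable

logger = logging.getLogger(__name__)

#: The 11-point p-value inclusion ladder used throughout the pipeline.
_THRESHOLDS = (1e-6, 5e-6, 1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2, 1e-1)


def threshold_series() -> list[float]:
    """The 11 p-value inclusion thresholds, ascending (1e-6 ... 0.1)."""
    return list(_THRESHOLDS)


@dataclass
class PrsResult:
    """Scores at one threshold: raw and z-standardized, with provenance."""

    threshold: float
    n_snps: int
    sample_ids: list[str]
    raw_scores: np.ndarray
    z_scores: np.ndarray
    snp_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iid": self.sample_ids, "raw": self.raw_scores, "z": self.z_scores}
        )


def _align_weights(weights: SumStatTable, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Orient weight betas to the genotype panel's counted (effect) allele.

    Matching mirrors summary-statistic harmonization: same orientation keeps
    the beta; swapped alleles (weight effect allele = genotype other allele)
    negate it; strand complements are resolved first; palindromic or
    irreconcilable SNPs are dropped with a logged count (dosage data carry
    no frequency to disambiguate strand for A/T and C/G SNPs).
    """
    gsnp = genotypes.snps.set_index("snp_id")
    rows = []
    n_dropped = 0
    for _, w in weights.df.iterrows():
        sid = w["snp_id"]
        if sid not in gsnp.index:
            continue
        g = gsnp.loc[sid]
        w_ea, w_oa = w["effect_allele"], w["other_allele"]
        g_ea, g_oa = g["effect_allele"], g["other_allele"]
        if COMPLEMENT[w_ea] == w_oa:  # palindromic: strand unresolvable
            n_dropped += 1
            continue
        if (w_ea, w_oa) == (g_ea, g_oa) or (COMPLEMENT[w_ea], COMPLEMENT[w_oa]) == (g_ea, g_oa):
            sign = 1.0
        elif (w_ea, w_oa) == (g_oa, g_ea) or (COMPLEMENT[w_ea], COMPLEMENT[w_oa]) == (g_oa, g_ea):
            sign = -1.0
        else:
            n_dropped += 1
            continue
        eaf = w.get("eaf", np.nan)
        if sign < 0 and pd.notna(eaf):
            eaf = 1.0 - eaf
        rows.append({"snp_id": sid, "beta": sign * w["beta"], "eaf": eaf})
    if n_dropped:
        logger.info("build_prs: dropped %d weights with unmatchable alleles", n_dropped)
    return pd.DataFrame(rows, columns=["snp_id", "beta", "eaf"])


def build_prs(
    genotypes: GenotypeMatrix,
    weights: SumStatTable,
    threshold: float = np.nan,
) -> PrsResult:
    """Score individuals: ``S_i = sum_j beta_j * g_ij`` over overlap SNPs.

    Weights are first oriented to the genotype panel's counted allele.
    Missing dosages are mean-imputed as ``2 * eaf`` when the weight table
    carries a frequency, otherwise the SNP is dropped for all individuals.
    z-scores standardize S with the sample mean and sample SD (n-1
    denominator) over the full analysis sample; a degenerate score (zero
    SD) or empty overlap is a hard error.
    """
    aligned = _align_weights(weights, genotypes)
    if len(aligned) == 0:
        raise ValueError("no overlap between weight SNPs and genotype panel")

    snp_idx = genotypes.snp_index()
    cols = aligned["snp_id"].map(snp_idx).to_numpy(int)
    G = genotypes.dosages[:, cols]
    betas = aligned["beta"].to_numpy(float)
    eafs = aligned["eaf"].to_numpy(float)

    missing_any = np.isnan(G).any(axis=0)
    drop = missing_any & np.isnan(eafs)
    if drop.any():
        logger.info("build_prs: dropped %d SNPs with missing dosages and no eaf", int(drop.sum()))
        keep = ~drop
        G, betas, eafs, cols = G[:, keep], betas[keep], eafs[keep], cols[keep]
        aligned = aligned[keep]
        if G.shape[1] == 0:
            raise ValueError("no scorable SNPs after missing-data handling")
    G = np.where(np.isnan(G), 2.0 * eafs, G)

    raw = G @ betas
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate polygenic score: zero variance across individuals")
    z = (raw - raw.mean()) / sd
    return PrsResult(
        threshold=threshold,
        n_snps=G.shape[1],
        sample_ids=list(genotypes.samples),
        raw_scores=raw,
        z_scores=z,
        snp_ids=list(aligned["snp_id"]),
    )


def build_prs_series(
    genotypes: GenotypeMatrix,
    stats: SumStatTable,
    reference: GenotypeMatrix,
    r2_threshold: float = 0.1,
    window_kb: int = 250,
    thresholds: list[float] | None = None,
    order: str = "threshold-first",
) -> list[PrsResult]:
    """Clump-then-score at every threshold of the ladder.

    Each threshold's score is built from the summary statistics filtered at
    that threshold and clumped against the reference panel, matching the
    threshold-then-clump construction of the score ladder.  Thresholds whose
    SNP set is empty or degenerate are skipped with a logged note.
    """
    from .clump import ClumpParams, clump  # noqa: PLC0415 — avoid import cycle

    results = []
    for t in thresholds if thresholds is not None else threshold_series():
        retained = clump(
            stats,
            reference,
            ClumpParams(r2_threshold=r2_threshold, window_kb=window_kb, p_include=t),
            order=order,
        )
        if len(retained) == 0:
            logger.info("threshold %g: no SNPs retained, skipping", t)
            continue
        try:
            results.append(build_prs(genotypes, retained, threshold=t))
        except ValueError as exc:
            logger.info("threshold %g: %s — skipping", t, exc)
    return results
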