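"""Pairwise LD (r^2) from a reference panel and greedy p-value clumping.

Clumping selects an approximately LD-independent subset of SNPs: iterating
in ascending p-value order, each not-yet-absorbed SNP becomes an index SNP
and absorbs every other candidate on the same chromosome within the window
whose squared dosage correlation with it reaches the r^2 threshold.  This is
the standard greedy procedure used to build thresholded polygenic scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix
from .sumstats import SumStatTable

logger = logging.getLogger(__name__)


@dataclass
class ClumpParams:
    """r^2 cutoff, physical window, and p-value inclusion threshold."""

    r2_threshold: float = 0.1
    window_kb: int = 250
    p_include: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not 0 < self.p_include <= 1:
            raise ValueError("p_include must be in (0, 1]")


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing entries are pairwise-deleted; a vector with zero variance over
    the complete pairs gives r^2 = 0 by convention.
    """
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("dosage vectors must be 1-D and of equal length")
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if len(a) < 2:
        raise ValueError("need at least 2 paired-complete observations")
    va = a - a.mean()
    vb = b - b.mean()
    den = np.sqrt((va @ va) * (vb @ vb))
    if den == 0:
        return 0.0
    r = float((va @ vb) / den)
    return min(r * r, 1.0)


def clump(
    stats: SumStatTable,
    reference: GenotypeMatrix,
    params: ClumpParams | None = None,
    order: str = "threshold-first",
) -> SumStatTable:
    """Greedy p-value-ordered LD clumping of a summary-statistic table.

    ``order='threshold-first'`` (default) restricts to ``pval <= p_include``
    before clumping — each thresholded score is clumped on exactly the SNPs
    it may contain.  ``order='clump-first'`` clumps the full table and then
    applies the p-value filter to the retained index SNPs.

    SNPs absent from the reference panel are dropped (logged): without LD
    information they cannot be cleared of redundancy.  Ties in p-value are
    broken by (chrom, pos, snp_id) ascending so output is deterministic.
    Any two retained SNPs within the window have pairwise r^2 below the
    threshold.
    """
    params = params or ClumpParams()
    if order not in ("threshold-first", "clump-first"):
        raise ValueError(f"unknown clumping order {order!r}")

    df = stats.df
    if order == "threshold-first":
        df = df[df["pval"] <= params.p_include]

    snp_idx = reference.snp_index()
    in_ref = df["snp_id"].map(snp_idx).notna()
    n_missing = int((~in_ref).sum())
    if n_missing:
        logger.info("clump: dropped %d SNPs absent from the reference panel", n_missing)
    df = df[in_ref]
    if len(df) == 0:
        logger.info("clump: no SNPs pass the inclusion threshold")
        return SumStatTable(df.copy(), study=stats.study, trait=stats.trait)

    cand = df.sort_values(["pval", "chrom", "pos", "snp_id"], kind="mergesort").reset_index(drop=True)
    cols = cand["snp_id"].map(snp_idx).to_numpy(int)
    chrom = cand["chrom"].to_numpy(str)
    pos = cand["pos"].to_numpy(int)
    window = params.window_kb * 1000

    D = reference.dosages[:, cols]
    complete = not np.isnan(D).any()
    if complete:
        Dc = D - D.mean(axis=0)
        norms = np.sqrt((Dc**2).sum(axis=0))

    absorbed = np.zeros(len(cand), dtype=bool)
    index_rows: list[int] = []
    for i in range(len(cand)):
        if absorbed[i]:
            continue
        index_rows.append(i)
        near = np.flatnonzero(
            (~absorbed) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        )
        near = near[near != i]
        if len(near) == 0:
            continue
        if complete:
            den = norms[near] * norms[i]
            with np.errstate(divide="ignore", invalid="ignore"):
                r2 = np.where(den > 0, (Dc[:, near].T @ Dc[:, i]) ** 2 / den**2, 0.0)
            absorbed[near[r2 >= params.r2_threshold]] = True
        else:
            x = D[:, i]
            for j in near:
                if ld_r2(x, D[:, j]) >= params.r2_threshold:
                    absorbed[j] = True
        n_absorbed = int(absorbed[near].sum())
        if n_absorbed:
            logger.debug("clump: index %s absorbed %d SNPs", cand.at[i, "snp_id"], n_absorbed)

    out = cand.iloc[index_rows]
    if order == "clump-first":
        out = out[out["pval"] <= params.p_include]
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SumStatTable(out.copy(), study=stats.study, trait=stats.trait)
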