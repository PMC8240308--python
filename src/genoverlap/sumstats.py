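"""GWAS summary-statistic tables, allele harmonization, and CI/SE conversions.

Summary statistics are the per-SNP association records (alleles, effect-allele
frequency, log-odds beta, standard error, p-value) produced by a discovery
GWAS.  They serve two roles downstream: as weights for polygenic scoring and
as exposure/outcome inputs to two-sample Mendelian randomization, where the
two tables must first be aligned to a common effect allele per SNP
(harmonization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Logical column names a summary-statistic table must provide.
REQUIRED_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
)
OPTIONAL_COLUMNS = ("eaf",)

#: Default header-name mapping: logical name -> file column name.
DEFAULT_DIALECT = {c: c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}


@dataclass
class SumStatTable:
    """An ordered collection of per-SNP GWAS association records.

    The backing frame has the logical columns of :data:`REQUIRED_COLUMNS`
    (plus ``eaf`` when available), one row per SNP, unique ``snp_id``,
    sorted by ``(chrom, pos)``.
    """

    df: pd.DataFrame
    study: str = ""
    trait: str = ""

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> pd.Series:
        return self.df["snp_id"]

    def subset(self, snp_ids) -> "SumStatTable":
        keep = self.df[self.df["snp_id"].isin(set(snp_ids))]
        return SumStatTable(keep.copy(), study=self.study, trait=self.trait)

    def filter_pval(self, p_max: float) -> "SumStatTable":
        keep = self.df[self.df["pval"] <= p_max]
        return SumStatTable(keep.copy(), study=self.study, trait=self.trait)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _validate_rows(df: pd.DataFrame, pval_rtol: float = 0.10) -> tuple[pd.DataFrame, int]:
    """Drop rows violating record invariants; return (clean frame, n dropped).

    Invariants: alleles are single A/C/G/T letters and differ; se > 0;
    pval in (0, 1]; eaf (when present) in [0, 1]; and the p-value agrees
    with the two-sided normal test of beta/se to 10% relative tolerance.
    """
    n0 = len(df)
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    df = df.assign(effect_allele=ea, other_allele=oa)

    ok = (
        ea.isin(VALID_ALLELES)
        & oa.isin(VALID_ALLELES)
        & (ea != oa)
        & (df["se"] > 0)
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & np.isfinite(df["beta"])
    )
    if "eaf" in df.columns:
        eaf_ok = df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1))
        ok &= eaf_ok

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(df["beta"].to_numpy(float) / df["se"].to_numpy(float))
    implied = 2.0 * stats.norm.sf(z)
    pv = df["pval"].to_numpy(float)
    # Relative agreement; where the implied p underflows to 0 accept tiny pv.
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(pv - implied) / np.maximum(implied, np.finfo(float).tiny)
    consistent = (rel <= pval_rtol) | ((implied == 0) & (pv < 1e-300))
    ok &= pd.Series(consistent, index=df.index).fillna(False)

    clean = df[ok.to_numpy(bool)]
    return clean, n0 - len(clean)


def read_sumstats(
    path,
    dialect: dict | None = None,
    study: str = "",
    trait: str = "",
    check_pval: bool = True,
) -> SumStatTable:
    """Read a delimited summary-statistic file into a validated table.

    Parameters
    ----------
    path
        Tab- or whitespace-delimited file with a header row.
    dialect
        Mapping from logical column names (:data:`REQUIRED_COLUMNS`) to the
        header names used in the file.  Defaults to the identity mapping.
    check_pval
        Enforce consistency of the stored p-value with the two-sided normal
        test of ``beta/se`` (10% relative tolerance).  Disable for files with
        heavily rounded p-values.

    Rows failing type or invariant checks are dropped with a logged count.
    A missing required column, or zero valid rows, is a hard error.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    raw = pd.read_csv(path, sep=None, engine="python")

    rename = {}
    for logical in REQUIRED_COLUMNS:
        src = dialect[logical]
        if src not in raw.columns:
            raise ValueError(f"summary-statistic file {path} lacks required column {src!r} ({logical})")
        rename[src] = logical
    for logical in OPTIONAL_COLUMNS:
        src = dialect.get(logical)
        if src in raw.columns:
            rename[src] = logical
    df = raw.rename(columns=rename)
    df = df[[c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]]

    df = df.astype({"snp_id": str, "chrom": str})
    for col in ("pos", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "eaf" in df.columns:
        df["eaf"] = pd.to_numeric(df["eaf"], errors="coerce")
    df = df.dropna(subset=["pos", "beta", "se", "pval"])
    df["pos"] = df["pos"].astype(int)

    df, n_dropped = _validate_rows(df, pval_rtol=0.10 if check_pval else np.inf)
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d invalid rows", path, n_dropped)

    df = df.drop_duplicates(subset="snp_id", keep="first")
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if len(df) == 0:
        raise ValueError(f"summary-statistic file {path} contains no valid rows")
    return SumStatTable(df, study=study, trait=trait)


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G SNPs are strand-ambiguous (allele pair maps to itself)."""
    return COMPLEMENT[a1] == a2


def _classify(exp_ea, exp_oa, out_ea, out_oa) -> str:
    """Orientation of an outcome record relative to the exposure alleles."""
    if (out_ea, out_oa) == (exp_ea, exp_oa):
        return "same"
    if (out_ea, out_oa) == (exp_oa, exp_ea):
        return "swap"
    c_ea, c_oa = COMPLEMENT[out_ea], COMPLEMENT[out_oa]
    if (c_ea, c_oa) == (exp_ea, exp_oa):
        return "same"
    if (c_ea, c_oa) == (exp_oa, exp_ea):
        return "swap"
    return "mismatch"


def harmonize(
    exposure: SumStatTable,
    outcome: SumStatTable,
    palindrome_policy: str = "infer_by_eaf",
    eaf_threshold: float = 0.42,
) -> pd.DataFrame:
    """Align outcome records to the exposure's effect allele per shared SNP.

    For each SNP in both tables the outcome record is copied unchanged when
    its alleles match the exposure orientation, or sign-flipped
    (``beta -> -beta``, ``eaf -> 1 - eaf``) when its effect allele is the
    exposure's other allele; strand complements (A<->T, C<->G) are resolved
    before these rules.  Palindromic SNPs, where letters cannot distinguish a
    swap from a strand flip, are handled by policy:

    ``drop_all``
        remove every palindromic SNP;
    ``infer_by_eaf``
        orient by allele frequency when both frequencies are informative
        (minor-allele frequency below ``eaf_threshold``): same side of 0.5
        means already aligned, opposite sides means flip; otherwise drop.

    Returns a frame of harmonized records with columns ``snp_id,
    beta_exposure, se_exposure, beta_outcome, se_outcome, effect_allele,
    other_allele, eaf_exposure, eaf_outcome, flip_applied, palindromic``.
    Irreconcilable allele pairs (e.g. A/G vs A/C) are dropped with a logged
    count; an empty SNP intersection is a hard error.
    """
    if palindrome_policy not in ("drop_all", "infer_by_eaf"):
        raise ValueError(f"unknown palindrome policy {palindrome_policy!r}")
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValueError("harmonize requires non-empty exposure and outcome tables")

    exp = exposure.df.set_index("snp_id")
    out = outcome.df.set_index("snp_id")
    shared = exp.index.intersection(out.index)
    if len(shared) == 0:
        raise ValueError("no shared SNPs between exposure and outcome tables")

    rows = []
    n_mismatch = n_palin_dropped = 0
    for snp in shared:
        e, o = exp.loc[snp], out.loc[snp]
        ea, oa = e["effect_allele"], e["other_allele"]
        palin = is_palindromic(ea, oa)
        beta_o = float(o["beta"])
        eaf_o = float(o["eaf"]) if "eaf" in o.index and pd.notna(o.get("eaf")) else np.nan
        eaf_e = float(e["eaf"]) if "eaf" in e.index and pd.notna(e.get("eaf")) else np.nan
        flip = False

        if palin:
            if not is_palindromic(o["effect_allele"], o["other_allele"]) or {
                o["effect_allele"],
                o["other_allele"],
            } != {ea, oa}:
                n_mismatch += 1
                continue
            if palindrome_policy == "drop_all":
                n_palin_dropped += 1
                continue
            # infer_by_eaf: both frequencies must be informative (clear MAF).
            if np.isnan(eaf_e) or np.isnan(eaf_o):
                n_palin_dropped += 1
                continue
            maf_e, maf_o = min(eaf_e, 1 - eaf_e), min(eaf_o, 1 - eaf_o)
            if maf_e >= eaf_threshold or maf_o >= eaf_threshold:
                n_palin_dropped += 1
                continue
            same_side = (eaf_e - 0.5) * (eaf_o - 0.5) > 0
            if not same_side:
                beta_o, eaf_o, flip = -beta_o, 1 - eaf_o, True
        else:
            kind = _classify(ea, oa, o["effect_allele"], o["other_allele"])
            if kind == "mismatch":
                n_mismatch += 1
                continue
            if kind == "swap":
                beta_o, flip = -beta_o, True
                if not np.isnan(eaf_o):
                    eaf_o = 1 - eaf_o

        rows.append(
            {
                "snp_id": snp,
                "beta_exposure": float(e["beta"]),
                "se_exposure": float(e["se"]),
                "beta_outcome": beta_o,
                "se_outcome": float(o["se"]),
                "effect_allele": ea,
                "other_allele": oa,
                "eaf_exposure": eaf_e,
                "eaf_outcome": eaf_o,
                "flip_applied": flip,
                "palindromic": palin,
            }
        )

    if n_mismatch:
        logger.info("harmonize: dropped %d SNPs with irreconcilable alleles", n_mismatch)
    if n_palin_dropped:
        logger.info("harmonize: dropped %d palindromic SNPs per policy", n_palin_dropped)
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "beta_exposure",
            "se_exposure",
            "beta_outcome",
            "se_outcome",
            "effect_allele",
            "other_allele",
            "eaf_exposure",
            "eaf_outcome",
            "flip_applied",
            "palindromic",
        ],
    )


def ci_to_se(lower: float, upper: float, level: float = 0.95, scale: str = "odds_ratio") -> float:
    """Recover a standard error from a symmetric Wald confidence interval.

    On the ``odds_ratio`` scale the bounds are log-transformed first, so
    ``se = (ln(upper) - ln(lower)) / (2 z)`` with ``z`` the standard-normal
    quantile at ``(1 + level) / 2``; on the ``linear`` scale the bounds are
    used as-is.  This is how a printed "OR (95% CI)" is converted back to a
    log-odds estimate with uncertainty for meta-analysis.
    """
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    if lower > upper:
        raise ValueError(f"lower bound {lower} exceeds upper bound {upper}")
    if scale == "odds_ratio":
        if lower <= 0:
            raise ValueError("odds-ratio scale requires positive bounds")
        t_lower, t_upper = np.log(lower), np.log(upper)
    elif scale == "linear":
        t_lower, t_upper = lower, upper
    else:
        raise ValueError(f"unknown scale {scale!r}")
    z = stats.norm.ppf((1 + level) / 2)
    return float((t_upper - t_lower) / (2 * z))
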