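"""Additive-dosage genotype matrices with SNP metadata, plus VCF/TSV I/O.

Dosages count copies of the *effect allele* (the ALT allele when written as
VCF) in {0, 1, 2}; missing calls are NaN.  The same container serves as the
target sample for polygenic scoring and as the reference panel for LD
computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SNP_COLUMNS = ("snp_id", "chrom", "pos", "effect_allele", "other_allele")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive effect-allele dosages.

    ``dosages`` is an (n_samples, n_snps) float array with NaN for missing
    calls; ``snps`` carries one metadata row per column (snp_id, chrom,
    pos, effect_allele, other_allele); ``samples`` the row identifiers.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x SNPs array")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError("SNP metadata rows must match dosage columns")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample ids must match dosage rows")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        idx = self.snp_index().get(snp_id)
        if idx is None:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix")
        return self.dosages[:, idx]

    def snp_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.snps["snp_id"])}

    def empirical_eaf(self) -> np.ndarray:
        """Per-SNP effect-allele frequency, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    # ------------------------------------------------------------------ I/O

    def to_dosage_tsv(self, path) -> None:
        """Write a plain dosage matrix: SNP metadata columns then one column
        per sample."""
        sample_cols = pd.DataFrame(self.dosages.T, columns=list(self.samples))
        out = pd.concat([self.snps.loc[:, list(SNP_COLUMNS)].reset_index(drop=True), sample_cols], axis=1)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in SNP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dosage file {path} lacks columns {missing}")
        samples = [c for c in df.columns if c not in SNP_COLUMNS]
        dosages = df[samples].to_numpy(float).T
        snps = df[list(SNP_COLUMNS)].astype({"chrom": str, "snp_id": str, "pos": int})
        return cls(dosages, snps, samples)

    def to_vcf(self, path) -> None:
        """Write hard-call genotypes as a minimal VCFv4.2 file.

        REF is the other allele, ALT the effect allele; dosage d maps to
        GT 0/0, 0/1, 1/1 and NaN to ./. .
        """
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(self.samples) + "\n")
            for j, row in self.snps.iterrows():
                calls = []
                for d in self.dosages[:, j]:
                    if np.isnan(d):
                        calls.append("./.")
                    else:
                        calls.append(gt_map[int(round(d))])
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t{row['snp_id']}\t"
                    f"{row['other_allele']}\t{row['effect_allele']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read GT calls from a VCF, counting ALT alleles as the dosage.

        Uses cyvcf2 when importable, otherwise a plain-text reader adequate
        for the uncompressed single-ALT VCFs this package writes.
        """
        try:
            from cyvcf2 import VCF  # noqa: PLC0415
        except ImportError:
            return cls._from_vcf_text(path)
        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, dosage_cols = [], []
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        remap = np.array([0.0, 1.0, np.nan, 2.0])
        for var in vcf:
            if len(var.ALT) != 1:
                continue
            rows.append(
                {
                    "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                    "chrom": str(var.CHROM),
                    "pos": int(var.POS),
                    "effect_allele": var.ALT[0],
                    "other_allele": var.REF,
                }
            )
            dosage_cols.append(remap[var.gt_types])
        vcf.close()
        dosages = np.array(dosage_cols, dtype=float).T if dosage_cols else np.empty((len(samples), 0))
        return cls(dosages, pd.DataFrame(rows, columns=list(SNP_COLUMNS)), samples)

    @classmethod
    def _from_vcf_text(cls, path) -> "GenotypeMatrix":
        rows, dosage_cols, samples = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("##") or not line:
                    continue
                fields = line.split("\t")
                if line.startswith("#CHROM"):
                    samples = fields[9:]
                    continue
                chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
                if "," in alt:
                    continue
                fmt = fields[8].split(":")
                gt_i = fmt.index("GT")
                col = []
                for cell in fields[9:]:
                    gt = cell.split(":")[gt_i].replace("|", "/")
                    if "." in gt:
                        col.append(np.nan)
                    else:
                        col.append(float(sum(int(a) for a in gt.split("/"))))
                rows.append(
                    {
                        "snp_id": vid if vid != "." else f"{chrom}:{pos}",
                        "chrom": str(chrom),
                        "pos": int(pos),
                        "effect_allele": alt,
                        "other_allele": ref,
                    }
                )
                dosage_cols.append(col)
        dosages = np.array(dosage_cols, dtype=float).T if dosage_cols else np.empty((len(samples), 0))
        return cls(dosages, pd.DataFrame(rows, columns=list(SNP_COLUMNS)), samples)
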