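import numpy as np
import pandas as pd
import pytest

from genoverlap.genotypes import GenotypeMatrix
from genoverlap.sumstats import SumStatTable


def make_sumstats(rows, study="test", trait="t"):
    """Build a SumStatTable from dicts; fills se-consistent p-values and
    positions unless given."""
    from scipy import stats

    records = []
    for i, r in enumerate(rows):
        rec = {
            "snp_id": r.get("snp_id", f"rs{i}"),
            "chrom": str(r.get("chrom", "1")),
            "pos": int(r.get("pos", 1_000_000 + 10_000 * i)),
            "effect_allele": r.get("effect_allele", "A"),
            "other_allele": r.get("other_allele", "G"),
            "eaf": r.get("eaf", 0.3),
            "beta": float(r.get("beta", 0.1)),
            "se": float(r.get("se", 0.05)),
        }
        rec["pval"] = float(
            r.get("pval", 2 * stats.norm.sf(abs(rec["beta"] / rec["se"])))
        )
        records.append(rec)
    df = pd.DataFrame(records).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return SumStatTable(df, study=study, trait=trait)


def make_genotypes(dosages, snp_rows=None, sample_prefix="s"):
    """Build a GenotypeMatrix from an (n, m) array and optional SNP dicts."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    rows = []
    for j in range(m):
        base = (snp_rows[j] if snp_rows else {})
        rows.append(
            {
                "snp_id": base.get("snp_id", f"rs{j}"),
                "chrom": str(base.get("chrom", "1")),
                "pos": int(base.get("pos", 1_000_000 + 10_000 * j)),
                "effect_allele": base.get("effect_allele", "A"),
                "other_allele": base.get("other_allele", "G"),
            }
        )
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    return GenotypeMatrix(dosages, pd.DataFrame(rows), samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
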