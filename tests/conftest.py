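import numpy as np
import pandas as pd
import pytest

from rohmap import ROHSet, SimConfig, simulate_dataset
from rohmap.detect import ROH_COLUMNS


@pytest.fixture(scope="session")
def small_panel():
    """20 samples x 2 chromosomes x 100 SNPs with a little missingness."""
    cfg = SimConfig(
        n_cases=10, n_controls=10, n_chromosomes=2, snps_per_chrom=100,
        missing_rate=0.02, seed=42,
    )
    return simulate_dataset(cfg)


def make_variant_map(n_snps, spacing_bp=10_000, chrom=1, start=1):
    bp = start + spacing_bp * np.arange(n_snps)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "snp_id": [f"c{chrom}s{i}" for i in range(n_snps)],
            "cm": 0.0,
            "bp": bp,
        }
    )


def make_rohset(segments, sample_ids, phenotype, variant_map=None):
    """segments: list of (sample_id, chrom, start_bp, end_bp)."""
    rows = []
    pheno = dict(zip(sample_ids, phenotype))
    for sid, chrom, s, e in segments:
        rows.append(
            {
                "sample_id": sid, "phenotype": pheno.get(sid, -9), "chrom": chrom,
                "snp1": "", "snp2": "", "start_bp": s, "end_bp": e,
                "n_snps": max(2, (e - s) // 10_000 + 1),
                "length_kb": (e - s + 1) / 1000.0, "n_het": 0, "n_miss": 0,
            }
        )
    df = pd.DataFrame(rows, columns=ROH_COLUMNS)
    return ROHSet(df, list(sample_ids), np.asarray(phenotype), variant_map)
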