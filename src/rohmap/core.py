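"""Core in-memory containers shared by every pipeline stage.

Genotypes are stored as an ``int8`` matrix of shape (n_samples, n_snps)
with one code per genotype:

========  =====  ==========================================
code      name   meaning
========  =====  ==========================================
``0``     HOM_A  homozygous for the A (reference) allele
``1``     HET    heterozygous
``2``     HOM_B  homozygous for the B (minor) allele
``-1``    MISSING  no call
========  =====  ==========================================

Every downstream computation uses only het/hom/missing status; the A/B
orientation is kept so that on-disk round trips preserve allele content.

Coordinates are 1-based and inclusive at both ends throughout the package
(PLINK convention); BED input is shifted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_A = np.int8(0)
HET = np.int8(1)
HOM_B = np.int8(2)
MISSING = np.int8(-1)

#: phenotype codes
CASE = 1
CONTROL = 0
PHENO_MISSING = -9

AUTOSOMES = frozenset(range(1, 23))


def validate_variant_map(vmap: pd.DataFrame) -> pd.DataFrame:
    """Validate a variant map DataFrame (columns: chrom, snp_id, cm, bp).

    Enforces autosomal chromosomes, unique SNP ids and strictly increasing
    base-pair positions within each chromosome.
    """
    required = {"chrom", "snp_id", "bp"}
    if not required.issubset(vmap.columns):
        raise ValueError(f"variant map needs columns {sorted(required)}")
    if "cm" not in vmap.columns:
        vmap = vmap.assign(cm=0.0)
    bad = set(vmap["chrom"].unique()) - AUTOSOMES
    if bad:
        raise ValueError(f"non-autosomal chromosome labels: {sorted(bad)}")
    if vmap["snp_id"].duplicated().any():
        dup = vmap.loc[vmap["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id {dup!r}")
    for chrom, sub in vmap.groupby("chrom", sort=False):
        d = np.diff(sub["bp"].to_numpy())
        if (d <= 0).any():
            raise ValueError(f"bp not strictly increasing on chromosome {chrom}")
    return vmap.reset_index(drop=True)


@dataclass
class GenotypeDataset:
    """Samples x SNPs genotype matrix plus variant map and sample metadata.

    Attributes
    ----------
    variant_map : DataFrame with columns (chrom, snp_id, cm, bp), autosomes
        only, bp strictly increasing per chromosome.
    sample_ids : list of unique sample identifiers.
    phenotype : int array, 1=case, 0=control, -9=missing.
    genotypes : int8 array (n_samples, n_snps) of genotype codes.
    allele_a, allele_b : per-SNP allele symbols backing codes 0/2.
    family_ids : PED family column (defaults to sample id).
    """

    variant_map: pd.DataFrame
    sample_ids: list[str]
    phenotype: np.ndarray
    genotypes: np.ndarray
    allele_a: np.ndarray | None = None
    allele_b: np.ndarray | None = None
    family_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.variant_map = validate_variant_map(self.variant_map)
        n, m = len(self.sample_ids), len(self.variant_map)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (n, m):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{n} samples x {m} SNPs"
            )
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length does not match sample count")
        if self.allele_a is None:
            self.allele_a = np.full(m, "A", dtype=object)
        if self.allele_b is None:
            self.allele_b = np.full(m, "B", dtype=object)
        if self.family_ids is None:
            self.family_ids = list(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.variant_map)

    def chrom_slices(self) -> dict[int, slice]:
        """Column slice of the genotype matrix for each chromosome."""
        out: dict[int, slice] = {}
        chroms = self.variant_map["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[int(chroms[start])] = slice(start, i)
                start = i
        return out

    def allele_pair_codes(self) -> np.ndarray:
        """Orientation-free genotype summary used for semantic equality.

        Encodes each genotype as the unordered allele pair it represents:
        missing -> '', hom -> 'xx', het -> sorted 'xy'.
        """
        out = np.empty(self.genotypes.shape, dtype=object)
        for j in range(self.n_snps):
            a, b = str(self.allele_a[j]), str(self.allele_b[j])
            het = "".join(sorted((a, b)))
            col = self.genotypes[:, j]
            out[:, j] = np.choose(
                col + 1, ["", a + a, het, b + b]
            )
        return out

    def equals(self, other: "GenotypeDataset") -> bool:
        """Semantic equality: same map, samples, phenotypes and genotypes
        up to allele orientation (A/B swap at a SNP does not change the data).
        """
        if self.sample_ids != other.sample_ids:
            return False
        if not np.array_equal(self.phenotype, other.phenotype):
            return False
        cols = ["chrom", "snp_id", "bp"]
        if not self.variant_map[cols].equals(other.variant_map[cols]):
            return False
        return bool(
            np.array_equal(self.allele_pair_codes(), other.allele_pair_codes())
        )


def read_covariates(path) -> pd.DataFrame:
    """Read a per-sample covariate table (TSV with header).

    Expected columns include ``sample_id``; optional columns ``phenotype``,
    ``age``, ``aao``, ``cohort``, ``f``, ``C1``, ``C2``. Ages must be
    non-negative where present.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError("covariate table must have a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    for col in ("age", "aao"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValueError(f"negative values in covariate column {col!r}")
    return df


def write_covariates(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class IntervalList:
    """Genomic intervals, 1-based inclusive at both ends."""

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "start_bp", "end_bp", "name"]
        )
    )

    def __post_init__(self) -> None:
        d = self.df
        if len(d) and (d["start_bp"] > d["end_bp"]).any():
            bad = d.index[d["start_bp"] > d["end_bp"]][0]
            raise ValueError(f"interval with start > end at row {bad}")

    def __len__(self) -> int:
        return len(self.df)
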