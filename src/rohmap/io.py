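"""Readers and writers for the on-disk formats the pipeline touches.

* PLINK text genotypes (PED/MAP, whitespace-delimited)
* ROH tables (tab-delimited, PLINK ``.hom``-style columns)
* interval lists (BED 0-based half-open, or 1-based inclusive TSV)
* per-sample covariate tables (TSV; see :func:`rohmap.core.read_covariates`)

Genotype codes are assigned by per-SNP allele-frequency orientation: the
minor allele becomes B, so code 2 is the minor-allele homozygote.  ``0 0``
allele pairs map to MISSING.  Non-autosomal variants are dropped at read
time with a logged count (ROH on sex chromosomes is sex-confounded).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AUTOSOMES,
    CASE,
    CONTROL,
    PHENO_MISSING,
    GenotypeDataset,
    IntervalList,
    read_covariates,
    write_covariates,
)
from .detect import ROH_COLUMNS, ROHSet

log = logging.getLogger(__name__)

ROH_TABLE_HEADER = [
    "SAMPLE", "PHENOTYPE", "CHR", "SNP1", "SNP2",
    "POS1", "POS2", "KB", "NSNP", "DENSITY", "NHET", "NMISS",
]

_PHENO_STR = {CASE: "case", CONTROL: "control", PHENO_MISSING: "missing"}
_PHENO_INT = {v: k for k, v in _PHENO_STR.items()}


def read_map(map_path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a 4-column MAP file; returns (autosomal map, keep-mask)."""
    vmap = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp"],
        dtype={"chrom": str, "snp_id": str, "cm": float, "bp": np.int64},
    )
    numeric = pd.to_numeric(vmap["chrom"], errors="coerce")
    keep = numeric.isin(list(AUTOSOMES)).to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d non-autosomal variants from %s", dropped, map_path)
    vmap = vmap.loc[keep].reset_index(drop=True)
    vmap["chrom"] = numeric[keep].astype(int).to_numpy()
    return vmap, keep


def read_plink_text(ped_path, map_path) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    PED rows: FID IID PAT MAT SEX PHENO then two allele columns per SNP.
    Phenotype 2 -> case, 1 -> control, anything else -> missing.
    """
    vmap, keep = read_map(map_path)
    n_all = len(keep)
    fam, iid, pheno, rows_a, rows_b = [], [], [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_all:
                raise ValueError(
                    f"{ped_path}: row {lineno} has {len(parts)} fields, "
                    f"expected {6 + 2 * n_all} for {n_all} SNPs"
                )
            fam.append(parts[0])
            iid.append(parts[1])
            p = parts[5]
            pheno.append(CASE if p == "2" else CONTROL if p == "1" else PHENO_MISSING)
            alleles = parts[6:]
            rows_a.append(alleles[0::2])
            rows_b.append(alleles[1::2])
    a1 = np.asarray(rows_a, dtype=object)[:, keep] if iid else np.empty((0, keep.sum()), object)
    a2 = np.asarray(rows_b, dtype=object)[:, keep] if iid else np.empty((0, keep.sum()), object)
    n, m = len(iid), len(vmap)
    genotypes = np.full((n, m), -1, dtype=np.int8)
    allele_a = np.full(m, "A", dtype=object)
    allele_b = np.full(m, "B", dtype=object)
    for j in range(m):
        c1, c2 = a1[:, j], a2[:, j]
        called = (c1 != "0") & (c2 != "0")
        sym, counts = np.unique(
            np.concatenate([c1[called], c2[called]]), return_counts=True
        )
        if len(sym) > 2:
            raise ValueError(f"SNP {vmap['snp_id'][j]!r} has >2 alleles: {list(sym)}")
        if len(sym) == 0:
            continue
        if len(sym) == 1:
            maj = minor = sym[0]
        else:
            # minor allele = B; tie broken by symbol order for determinism
            order = np.argsort(counts, kind="stable")
            minor, maj = sym[order[0]], sym[order[1]]
            if counts[0] == counts[1]:
                maj, minor = sorted(sym)
        allele_a[j], allele_b[j] = maj, minor
        het = called & (c1 != c2)
        hom_b = called & (c1 == minor) & (c2 == minor)
        hom_a = called & (c1 == maj) & (c2 == maj) & (maj != minor)
        if maj == minor:
            hom_a = called
            hom_b = np.zeros_like(called)
        col = genotypes[:, j]
        col[hom_a] = 0
        col[het] = 1
        col[hom_b] = 2
    return GenotypeDataset(
        variant_map=vmap[["chrom", "snp_id", "cm", "bp"]],
        sample_ids=list(iid),
        phenotype=np.asarray(pheno),
        genotypes=genotypes,
        allele_a=allele_a,
        allele_b=allele_b,
        family_ids=list(fam),
    )


def write_plink_text(dataset: GenotypeDataset, prefix) -> tuple[Path, Path]:
    """Write a PED/MAP pair that round-trips through :func:`read_plink_text`."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    vm = dataset.variant_map
    with open(map_path, "w") as fh:
        for row in vm.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp_id}\t{row.cm:g}\t{row.bp}\n")
    pheno_out = {CASE: "2", CONTROL: "1", PHENO_MISSING: "0"}
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(dataset.sample_ids):
            fields = [
                dataset.family_ids[i], sid, "0", "0", "0",
                pheno_out.get(int(dataset.phenotype[i]), "0"),
            ]
            g = dataset.genotypes[i]
            for j in range(dataset.n_snps):
                a, b = str(dataset.allele_a[j]), str(dataset.allele_b[j])
                code = g[j]
                pair = ("0", "0") if code == -1 else (
                    (a, a) if code == 0 else (a, b) if code == 1 else (b, b)
                )
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


def write_roh_table(rohs: ROHSet, path) -> Path:
    """Write a ROH table (PLINK ``.hom``-style layout, tab-delimited).

    KB = (POS2 - POS1 + 1)/1000; DENSITY = NSNP/KB.  NHET/NMISS make the
    table lossless for the in-memory segment records.
    """
    path = Path(path)
    df = rohs.df
    out = pd.DataFrame(
        {
            "SAMPLE": df["sample_id"],
            "PHENOTYPE": df["phenotype"].map(_PHENO_STR),
            "CHR": df["chrom"],
            "SNP1": df["snp1"],
            "SNP2": df["snp2"],
            "POS1": df["start_bp"],
            "POS2": df["end_bp"],
            "KB": df["length_kb"],
            "NSNP": df["n_snps"],
            "DENSITY": df["n_snps"] / df["length_kb"],
            "NHET": df["n_het"],
            "NMISS": df["n_miss"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_roh_table(
    path, sample_ids=None, phenotype=None, variant_map=None
) -> ROHSet:
    """Read a ROH table written by :func:`write_roh_table`.

    If the full sample roster is not supplied, the roster defaults to the
    samples present in the table (ROH-free samples are then unknown).
    """
    t = pd.read_csv(path, sep="\t", dtype={"SAMPLE": str, "SNP1": str, "SNP2": str})
    df = pd.DataFrame(
        {
            "sample_id": t["SAMPLE"],
            "phenotype": t["PHENOTYPE"].map(_PHENO_INT).fillna(PHENO_MISSING).astype(int),
            "chrom": t["CHR"].astype(int),
            "snp1": t["SNP1"].fillna(""),
            "snp2": t["SNP2"].fillna(""),
            "start_bp": t["POS1"].astype(int),
            "end_bp": t["POS2"].astype(int),
            "n_snps": t["NSNP"].astype(int),
            "length_kb": t["KB"].astype(float),
            "n_het": t.get("NHET", pd.Series(0, index=t.index)).astype(int),
            "n_miss": t.get("NMISS", pd.Series(0, index=t.index)).astype(int),
        },
        columns=ROH_COLUMNS,
    )
    if sample_ids is None:
        sample_ids = list(dict.fromkeys(df["sample_id"]))
        ph = df.drop_duplicates("sample_id").set_index("sample_id")["phenotype"]
        phenotype = ph.reindex(sample_ids).to_numpy()
    return ROHSet(df, list(sample_ids), np.asarray(phenotype), variant_map)


def read_intervals(path, convention: str = "one_inclusive") -> IntervalList:
    """Read a 3/4-column interval list, normalised to 1-based inclusive.

    ``convention='bed0half'`` interprets columns as BED (0-based,
    half-open); ``'one_inclusive'`` takes them as already 1-based
    inclusive.  When several intervals share a name only the longest is
    kept (longest-transcript rule).
    """
    if convention not in ("bed0half", "one_inclusive"):
        raise ValueError(f"unknown convention {convention!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#") or parts[0].lower() in ("track", "browser"):
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: need >=3 columns")
            chrom = parts[0].removeprefix("chr")
            start, end = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"iv{lineno}"
            if convention == "bed0half":
                start += 1
            if start > end:
                raise ValueError(f"{path}: line {lineno}: start > end after normalisation")
            rows.append((int(chrom), start, end, name))
    df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name"])
    if len(df):
        df["_len"] = df["end_bp"] - df["start_bp"] + 1
        df = (
            df.sort_values(["name", "_len"], kind="mergesort")
            .drop_duplicates("name", keep="last")
            .drop(columns="_len")
            .sort_values(["chrom", "start_bp"], kind="mergesort")
            .reset_index(drop=True)
        )
    return IntervalList(df)


def write_intervals(intervals: IntervalList, path) -> Path:
    path = Path(path)
    intervals.df.to_csv(path, sep="\t", index=False, header=False)
    return path
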