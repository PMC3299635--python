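"""Synthetic genotype panels with known planted truth.

The generator emulates a post-QC case-control SNP panel:

* SNP positions are cumulative sums of positive inter-SNP gaps with a
  configurable mean (default 6,500 bp, i.e. ~50 SNPs per 325 kb — dense
  enough that any planted run of >=2 Mb is detectable by construction).
* Background genotypes are drawn independently per SNP from
  Hardy-Weinberg proportions inflated by a per-sample inbreeding
  coefficient F: (p^2 + pqF, 2pq(1-F), q^2 + pqF).
* Autozygous (IBD-like) segments are planted by overwriting genotypes
  with homozygous calls whose allele is drawn by population frequency;
  heterozygote miscall and missingness noise are applied afterwards.
* Regional IBS clusters (common low-heterozygosity hotspots) are planted
  with :func:`make_common_region`.
* Case/control labels are either fixed by the configured group sizes or
  drawn from a logistic model on the planted long-run count
  (:func:`assign_phenotypes`).

There is no background linkage disequilibrium between SNPs (ROH calling
depends on homozygosity runs, not phased haplotypes); an optional
block-correlation mode plants LD blocks so that LD pruning has something
to prune.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CASE, CONTROL, GenotypeDataset

COHORTS = ("FR", "NL", "GER", "USA", "UK")


@dataclass(frozen=True)
class PlantedSegmentSpec:
    """One family of planted autozygous segments.

    ``group`` targets cases, controls or anybody; ``length_mb`` is a fixed
    length or an inclusive (low, high) range sampled uniformly;
    ``carrier_fraction`` is the per-individual probability of being a
    carrier; carriers receive ``count_per_carrier`` independent segments.
    ``chromosome`` pins all segments of the family to one chromosome
    (default: drawn uniformly per segment).
    """

    group: str = "either"          # case | control | either
    length_mb: float | tuple[float, float] = 3.0
    count_per_carrier: int = 1
    carrier_fraction: float = 1.0
    chromosome: int | None = None

    def draw_length_mb(self, rng: np.random.Generator) -> float:
        if isinstance(self.length_mb, tuple):
            lo, hi = self.length_mb
            return float(rng.uniform(lo, hi))
        return float(self.length_mb)


@dataclass(frozen=True)
class CommonRegionSpec:
    """A planted IBS cluster: ``carrier_fraction`` of all samples receive an
    independent homozygous run, length Normal(mean, sd) Mb truncated at
    2 Mb, centred inside [start_bp, end_bp] of ``chromosome``."""

    chromosome: int
    start_bp: int
    end_bp: int
    carrier_fraction: float
    length_mb_mean: float = 3.0
    length_mb_sd: float = 0.3


@dataclass(frozen=True)
class EffectModel:
    """Logistic disease model: logit P(case) = intercept + beta * count of
    planted segments at least ``min_length_mb`` long."""

    beta: float
    intercept: float = 0.0
    min_length_mb: float = 0.0


@dataclass
class SimConfig:
    n_cases: int = 100
    n_controls: int = 100
    n_chromosomes: int = 2
    snps_per_chrom: int = 5000
    mean_spacing_bp: float = 6500.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    het_error_rate: float = 0.0
    missing_rate: float = 0.0
    planted_segments: list[PlantedSegmentSpec] = field(default_factory=list)
    common_regions: list[CommonRegionSpec] = field(default_factory=list)
    f_distribution: float | tuple[float, float] | np.ndarray = 0.0
    effect_model: EffectModel | None = None
    age_range: tuple[float, float] = (40.0, 75.0)
    ld_block_size: int | None = None
    ld_block_r: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.het_error_rate, self.missing_rate):
            if not 0 <= frac <= 1:
                raise ValueError("rates must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated panel.

    ``segments`` has one row per planted run (sample_id, chrom, start_bp,
    end_bp, length_kb, kind in {ibd, cluster}); ``f_true`` is the
    per-sample inbreeding coefficient used by the generator;
    ``linear_predictor`` is set when labels came from an effect model.
    """

    segments: pd.DataFrame
    f_true: np.ndarray
    linear_predictor: np.ndarray | None = None


_TRUTH_COLS = ["sample_id", "chrom", "start_bp", "end_bp", "length_kb", "kind"]


def _sample_f(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.f_distribution
    n = config.n_samples
    if isinstance(spec, (int, float)):
        return np.full(n, float(spec))
    if isinstance(spec, tuple):
        mean, sd = spec
        return np.clip(rng.normal(mean, sd, n), 0.0, 0.99)
    f = np.asarray(spec, dtype=float)
    if f.shape != (n,):
        raise ValueError("per-sample f array must have one entry per sample")
    return f


def _make_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in range(1, config.n_chromosomes + 1):
        gaps = np.maximum(1, rng.exponential(config.mean_spacing_bp, config.snps_per_chrom).astype(np.int64))
        bp = np.cumsum(gaps)
        rows.append(pd.DataFrame({
            "chrom": c,
            "snp_id": [f"rs{c}_{i}" for i in range(config.snps_per_chrom)],
            "cm": 0.0,
            "bp": bp,
        }))
    return pd.concat(rows, ignore_index=True)


def _background_genotypes(
    maf: np.ndarray, f: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """HWE-with-F genotypes: code 0 = major hom, 1 = het, 2 = minor hom."""
    q = maf[None, :]
    p = 1.0 - q
    fcol = f[:, None]
    p_hom_major = p * p + p * q * fcol
    p_het = 2 * p * q * (1 - fcol)
    u = rng.random((len(f), len(maf)))
    g = np.full(u.shape, 2, dtype=np.int8)
    g[u < p_hom_major + p_het] = 1
    g[u < p_hom_major] = 0
    return g


def _block_genotypes(config: SimConfig, maf, rng) -> np.ndarray:
    """Blocked-LD background: SNPs inside a block share a latent biallelic
    haplotype pair; each SNP copies the latent allele with error eps chosen
    so that the between-SNP genotype correlation is ~ld_block_r."""
    n, m = config.n_samples, len(maf)
    k = config.ld_block_size
    eps = (1.0 - np.sqrt(config.ld_block_r)) / 2.0
    g = np.empty((n, m), dtype=np.int8)
    for start in range(0, m, k):
        stop = min(start + k, m)
        q = float(np.mean(maf[start:stop]))
        h1 = rng.random(n) < q          # latent haplotype alleles per sample
        h2 = rng.random(n) < q
        for j in range(start, stop):
            a1 = h1 ^ (rng.random(n) < eps)
            a2 = h2 ^ (rng.random(n) < eps)
            g[:, j] = a1.astype(np.int8) + a2.astype(np.int8)
    return g


def plant_run(
    genotypes: np.ndarray,
    vmap: pd.DataFrame,
    sample_index: int,
    chrom: int,
    start_bp: int,
    length_mb: float,
    maf: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Overwrite one sample's genotypes with a homozygous run.

    SNPs in [start_bp, start_bp + length_mb*1e6) on ``chrom`` become
    homozygous; the allele at each SNP is drawn by population frequency
    (major with probability 1-MAF).  Returns the (start_bp, end_bp) span of
    the SNPs actually covered.
    """
    chroms = vmap["chrom"].to_numpy()
    bp = vmap["bp"].to_numpy()
    mask = (chroms == chrom) & (bp >= start_bp) & (bp < start_bp + length_mb * 1e6)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("planted run covers no SNPs")
    hom_minor = rng.random(len(idx)) < maf[idx]
    genotypes[sample_index, idx] = np.where(hom_minor, 2, 0).astype(np.int8)
    return int(bp[idx[0]]), int(bp[idx[-1]])


def _chrom_extent(vmap: pd.DataFrame, chrom: int) -> tuple[int, int]:
    sub = vmap.loc[vmap["chrom"] == chrom, "bp"]
    return int(sub.iloc[0]), int(sub.iloc[-1])


def simulate_dataset(
    config: SimConfig,
) -> tuple[GenotypeDataset, pd.DataFrame, SimTruth]:
    """Generate a panel, covariate table and planted truth.

    Deterministic given ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    vmap = _make_map(config, rng)
    m = len(vmap)
    maf = rng.uniform(*config.maf_range, m)
    f = _sample_f(config, rng)
    if config.ld_block_size:
        genotypes = _block_genotypes(config, maf, rng)
    else:
        genotypes = _background_genotypes(maf, f, rng)

    n = config.n_samples
    labels = np.concatenate(
        [np.full(config.n_cases, CASE), np.full(config.n_controls, CONTROL)]
    )
    if config.effect_model is not None:
        bad = [s for s in config.planted_segments if s.group != "either"]
        if bad:
            raise ValueError(
                "group-targeted planted segments cannot be combined with an "
                "effect model (labels are drawn after planting)"
            )

    truth_rows: list[tuple] = []
    sample_ids = [f"S{i:05d}" for i in range(n)]
    bp = vmap["bp"].to_numpy()
    chroms = vmap["chrom"].to_numpy()
    for spec in config.planted_segments:
        if spec.group == "case":
            pool = np.flatnonzero(labels == CASE)
        elif spec.group == "control":
            pool = np.flatnonzero(labels == CONTROL)
        else:
            pool = np.arange(n)
        carriers = pool[rng.random(len(pool)) < spec.carrier_fraction]
        for si in carriers:
            for _ in range(spec.count_per_carrier):
                length_mb = spec.draw_length_mb(rng)
                if spec.chromosome is not None:
                    chrom = int(spec.chromosome)
                else:
                    chrom = int(rng.integers(1, config.n_chromosomes + 1))
                lo, hi = _chrom_extent(vmap, chrom)
                span = hi - lo - length_mb * 1e6
                if span <= 0:
                    raise ValueError(
                        f"planted segment of {length_mb} Mb longer than chromosome {chrom}"
                    )
                start = int(lo + rng.uniform(0, span))
                s, e = plant_run(genotypes, vmap, si, chrom, start, length_mb, maf, rng)
                truth_rows.append(
                    (sample_ids[si], chrom, s, e, (e - s + 1) / 1000.0, "ibd")
                )

    for region in config.common_regions:
        _plant_cluster(genotypes, vmap, maf, region, rng, sample_ids, truth_rows)

    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLS)

    # noise: het miscalls inside planted runs, then global missingness
    if config.het_error_rate > 0 and len(truth):
        for row in truth.itertuples(index=False):
            si = sample_ids.index(row.sample_id)
            idx = np.flatnonzero(
                (chroms == row.chrom) & (bp >= row.start_bp) & (bp <= row.end_bp)
            )
            flip = idx[rng.random(len(idx)) < config.het_error_rate]
            genotypes[si, flip] = 1
    if config.missing_rate > 0:
        miss = rng.random(genotypes.shape) < config.missing_rate
        genotypes[miss] = -1

    linear_predictor = None
    if config.effect_model is not None:
        counts = _planted_counts(truth, sample_ids, config.effect_model.min_length_mb)
        linear_predictor = config.effect_model.intercept + config.effect_model.beta * counts
        labels = (rng.random(n) < 1.0 / (1.0 + np.exp(-linear_predictor))).astype(int)

    allele_a = np.full(m, "A", dtype=object)
    allele_b = np.full(m, "G", dtype=object)
    dataset = GenotypeDataset(
        variant_map=vmap,
        sample_ids=sample_ids,
        phenotype=labels,
        genotypes=genotypes,
        allele_a=allele_a,
        allele_b=allele_b,
    )
    ages = rng.uniform(*config.age_range, n)
    aao = np.where(labels == CASE, np.round(rng.uniform(20, 50, n), 1), np.nan)
    covariates = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "phenotype": labels,
            "age": np.round(ages, 1),
            "aao": aao,
            "cohort": [COHORTS[i % len(COHORTS)] for i in range(n)],
        }
    )
    return dataset, covariates, SimTruth(truth, f, linear_predictor)


def _plant_cluster(genotypes, vmap, maf, region: CommonRegionSpec, rng,
                   sample_ids, truth_rows) -> None:
    import warnings

    n = genotypes.shape[0]
    n_carriers = int(round(region.carrier_fraction * n))
    if n_carriers < 1:
        warnings.warn("carrier_fraction too small: no cluster carriers planted")
        return
    carriers = rng.choice(n, size=n_carriers, replace=False)
    centre_lo = region.start_bp + 0.4 * (region.end_bp - region.start_bp)
    centre_hi = region.start_bp + 0.6 * (region.end_bp - region.start_bp)
    for si in carriers:
        length_mb = max(2.0, rng.normal(region.length_mb_mean, region.length_mb_sd))
        centre = rng.uniform(centre_lo, centre_hi)
        start = int(centre - length_mb * 5e5)
        s, e = plant_run(
            genotypes, vmap, si, region.chromosome, start, length_mb, maf, rng
        )
        truth_rows.append(
            (sample_ids[si], region.chromosome, s, e, (e - s + 1) / 1000.0, "cluster")
        )


def make_common_region(
    dataset: GenotypeDataset,
    spec: CommonRegionSpec,
    maf: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant an IBS cluster into an existing panel (in place).

    Returns the truth rows for the planted runs.  ``maf`` defaults to the
    empirical minor-allele frequency of the panel.
    """
    rng = np.random.default_rng(seed)
    if maf is None:
        g = dataset.genotypes
        called = g >= 0
        with np.errstate(invalid="ignore"):
            maf = np.where(
                called.sum(0) > 0,
                (g * called).sum(0) / (2.0 * np.maximum(called.sum(0), 1)),
                0.25,
            )
    rows: list[tuple] = []
    _plant_cluster(dataset.genotypes, dataset.variant_map, maf, spec, rng,
                   dataset.sample_ids, rows)
    return pd.DataFrame(rows, columns=_TRUTH_COLS)


def _planted_counts(truth: pd.DataFrame, sample_ids, min_length_mb: float) -> np.ndarray:
    counts = np.zeros(len(sample_ids), dtype=float)
    if len(truth) == 0:
        return counts
    qual = truth[(truth["length_kb"] >= 1000.0 * min_length_mb) & (truth["kind"] == "ibd")]
    idx = pd.Index(sample_ids)
    grouped = qual.groupby("sample_id").size()
    counts[idx.get_indexer(grouped.index)] = grouped.to_numpy()
    return counts


def assign_phenotypes(
    truth: SimTruth,
    sample_ids: list[str],
    effect_model: EffectModel | None,
    seed: int = 0,
    n_cases: int | None = None,
) -> np.ndarray:
    """Draw case/control labels.

    With an effect model: P(case) = logistic(intercept + beta * planted-run
    count at the model's length floor).  Without one (null model): a random
    permutation of ``n_cases`` case labels, independent of the truth.
    """
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    if effect_model is None:
        if n_cases is None:
            n_cases = n // 2
        labels = np.concatenate([np.full(n_cases, CASE), np.full(n - n_cases, CONTROL)])
        return rng.permutation(labels)
    counts = _planted_counts(truth.segments, sample_ids, effect_model.min_length_mb)
    lp = effect_model.intercept + effect_model.beta * counts
    return (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
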