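"""Locus-level homozygosity mapping.

Rare ROHs are pooled into connected components of the pairwise-overlap
graph per chromosome (a pool needs at least two members; allelic matching
is not required).  Each pool yields one or more *consensus regions*: the
interval common to every member of a maximal clique of mutually
overlapping segments (for a pool whose global intersection is non-empty
this is simply the intersection of all members).  A consensus region is
kept only if it covers at least two consecutive SNPs of the map, and
duplicated intervals across pools are emitted once.

Individuals *carry* a region when at least one of their ROHs contains the
whole region (complete overlap); carrier counts per phenotype group are
compared by case/control label permutation.  Pointwise p-values use the
add-one estimator on the case-carrier count statistic (group sizes are
fixed under permutation, so this is equivalent to case excess);
family-wise corrected p-values use the max-T permutation distribution of
per-region standardised statistics, with Bonferroni also reported.

Gene-based mapping applies the same machinery with a caller-supplied gene
interval list as the family; genes with identical carrier sets are merged
into groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CASE, CONTROL, IntervalList
from .detect import ROHSet


@dataclass
class ROHPool:
    """A connected component (>=2 members) of the overlap graph."""

    chrom: int
    member_index: np.ndarray      # row indices into the ROHSet frame

    def __len__(self) -> int:
        return len(self.member_index)


@dataclass
class ConsensusRegion:
    chrom: int
    start_bp: int
    end_bp: int
    n_snps_inside: int
    carriers_cases: int = 0
    carriers_controls: int = 0
    p_pointwise: float = np.nan
    p_corrected: float = np.nan
    p_bonferroni: float = np.nan
    carrier_rows: np.ndarray | None = None


def pool_roh(rare_rohs: ROHSet) -> list[ROHPool]:
    """Pools of overlapping ROHs per chromosome (components with >=2
    segments), ordered by leftmost coordinate."""
    df = rare_rohs.df
    pools: list[ROHPool] = []
    for chrom in sorted(df["chrom"].unique()):
        sub = df[df["chrom"] == chrom].sort_values("start_bp", kind="mergesort")
        idx = sub.index.to_numpy()
        starts = sub["start_bp"].to_numpy()
        ends = sub["end_bp"].to_numpy()
        comp_start = 0
        reach = ends[0] if len(ends) else 0
        for i in range(1, len(idx) + 1):
            if i == len(idx) or starts[i] > reach:
                if i - comp_start >= 2:
                    pools.append(ROHPool(int(chrom), idx[comp_start:i]))
                if i < len(idx):
                    comp_start = i
                    reach = ends[i]
            else:
                reach = max(reach, ends[i])
    return pools


def _maximal_cliques(starts: np.ndarray, ends: np.ndarray) -> list[np.ndarray]:
    """Maximal cliques of an interval overlap graph.

    In an interval graph every maximal clique is the set of intervals
    covering some point; it suffices to inspect each interval's right
    endpoint.  Returns member-index arrays, deduplicated, non-maximal
    sets dropped.
    """
    cliques: list[frozenset] = []
    for e in np.unique(ends):
        members = frozenset(np.flatnonzero((starts <= e) & (ends >= e)).tolist())
        if len(members) >= 2 and members not in cliques:
            cliques.append(members)
    maximal = [
        c for c in cliques if not any(c < other for other in cliques)
    ]
    return [np.fromiter(sorted(c), dtype=int) for c in maximal]


def consensus_region(
    pool: ROHPool, rohs: ROHSet, variant_map: pd.DataFrame
) -> list[ConsensusRegion]:
    """Consensus interval(s) of a pool.

    The intersection of all members is used when non-empty; otherwise the
    pool splits into its maximal mutually-overlapping sub-groups, each
    contributing its own intersection.  Candidates covering fewer than two
    consecutive SNPs are dropped.
    """
    sub = rohs.df.loc[pool.member_index]
    starts = sub["start_bp"].to_numpy()
    ends = sub["end_bp"].to_numpy()
    lo, hi = starts.max(), ends.min()
    if lo <= hi:
        groups = [np.arange(len(sub))]
    else:
        groups = _maximal_cliques(starts, ends)
    cbp = variant_map.loc[variant_map["chrom"] == pool.chrom, "bp"].to_numpy()
    out: list[ConsensusRegion] = []
    for g in groups:
        s, e = int(starts[g].max()), int(ends[g].min())
        n_inside = int(
            np.searchsorted(cbp, e, side="right") - np.searchsorted(cbp, s, side="left")
        )
        if n_inside >= 2:
            out.append(ConsensusRegion(pool.chrom, s, e, n_inside))
    return out


def build_consensus_regions(
    rare_rohs: ROHSet, variant_map: pd.DataFrame
) -> list[ConsensusRegion]:
    """All unique consensus regions of a rare ROH set."""
    seen: set[tuple[int, int, int]] = set()
    regions: list[ConsensusRegion] = []
    for pool in pool_roh(rare_rohs):
        for reg in consensus_region(pool, rare_rohs, variant_map):
            key = (reg.chrom, reg.start_bp, reg.end_bp)
            if key not in seen:
                seen.add(key)
                regions.append(reg)
    regions.sort(key=lambda r: (r.chrom, r.start_bp, r.end_bp))
    return regions


def _carrier_matrix(
    intervals: list[tuple[int, int, int]], rohs: ROHSet
) -> np.ndarray:
    """(n_intervals, n_samples) boolean: sample has a ROH containing the
    whole interval."""
    df = rohs.df
    roster = pd.Index(rohs.sample_ids)
    seg_sample = roster.get_indexer(df["sample_id"])
    seg_chrom = df["chrom"].to_numpy()
    seg_start = df["start_bp"].to_numpy()
    seg_end = df["end_bp"].to_numpy()
    out = np.zeros((len(intervals), len(roster)), dtype=bool)
    for i, (chrom, s, e) in enumerate(intervals):
        hit = (seg_chrom == chrom) & (seg_start <= s) & (seg_end >= e)
        out[i, seg_sample[hit]] = True
    return out


def count_complete_overlap(
    region: tuple[int, int, int], rohs: ROHSet
) -> tuple[int, int]:
    """Distinct case and control carriers whose ROH contains the region."""
    carriers = _carrier_matrix([region], rohs)[0]
    pheno = rohs.phenotype
    return int(carriers[pheno == CASE].sum()), int(carriers[pheno == CONTROL].sum())


def _permutation_pvalues(
    carriers: np.ndarray,
    pheno: np.ndarray,
    n_perm: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise, max-T corrected and Bonferroni p for each interval.

    ``carriers`` is (R, n) over the case/control samples only.  The max-T
    standardisation uses each interval's permutation mean/sd; intervals
    with a degenerate (constant) permutation distribution standardise
    to 0.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100: corrected p-values are unstable")
    rng = np.random.default_rng(seed)
    used = (pheno == CASE) | (pheno == CONTROL)
    car = carriers[:, used]
    is_case = (pheno[used] == CASE)
    n, n_case = int(used.sum()), int(is_case.sum())
    observed = car[:, is_case].sum(axis=1)

    order = np.argpartition(rng.random((n_perm, n)), n_case - 1, axis=1)[:, :n_case]
    masks = np.zeros((n_perm, n), dtype=np.float32)
    masks[np.repeat(np.arange(n_perm), n_case), order.ravel()] = 1.0
    perm = np.rint(car.astype(np.float32) @ masks.T).astype(np.int64)
    p_point = (1 + (perm >= observed[:, None]).sum(axis=1)) / (1 + n_perm)

    mu = perm.mean(axis=1)
    sd = perm.std(axis=1)
    safe = np.where(sd > 0, sd, 1.0)
    z_obs = np.where(sd > 0, (observed - mu) / safe, 0.0)
    z_perm = (perm - mu[:, None]) / safe[:, None]
    z_perm[sd == 0] = 0.0
    max_per_perm = z_perm.max(axis=0)
    p_corr = (1 + (max_per_perm[None, :] >= z_obs[:, None] - 1e-12).sum(axis=1)) / (
        1 + n_perm
    )
    r = carriers.shape[0]
    p_bonf = np.minimum(1.0, p_point * r)
    case_counts = observed
    ctrl_counts = car.sum(axis=1) - observed
    return p_point, p_corr, p_bonf, case_counts, ctrl_counts


def permutation_map(
    regions: list[ConsensusRegion],
    rohs: ROHSet,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[ConsensusRegion]:
    """Attach carrier counts and pointwise/corrected p-values to regions."""
    if not regions:
        raise ValueError("no regions to test")
    intervals = [(r.chrom, r.start_bp, r.end_bp) for r in regions]
    carriers = _carrier_matrix(intervals, rohs)
    p_point, p_corr, p_bonf, cc, ctrl = _permutation_pvalues(
        carriers, rohs.phenotype, n_perm, seed
    )
    for i, r in enumerate(regions):
        r.carriers_cases = int(cc[i])
        r.carriers_controls = int(ctrl[i])
        r.p_pointwise = float(p_point[i])
        r.p_corrected = float(p_corr[i])
        r.p_bonferroni = float(p_bonf[i])
        r.carrier_rows = carriers[i]
    return regions


def map_consensus(
    rare_rohs: ROHSet,
    variant_map: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full consensus-region mapping: pool, intersect, count, permute."""
    regions = build_consensus_regions(rare_rohs, variant_map)
    if not regions:
        return pd.DataFrame(
            columns=["chrom", "start_bp", "end_bp", "n_snps_inside",
                     "carriers_cases", "carriers_controls",
                     "p_pointwise", "p_corrected", "p_bonferroni"]
        )
    permutation_map(regions, rare_rohs, n_perm=n_perm, seed=seed)
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "n_snps_inside": r.n_snps_inside,
                "carriers_cases": r.carriers_cases,
                "carriers_controls": r.carriers_controls,
                "p_pointwise": r.p_pointwise,
                "p_corrected": r.p_corrected,
                "p_bonferroni": r.p_bonferroni,
            }
            for r in regions
        ]
    ).sort_values("p_pointwise", kind="mergesort").reset_index(drop=True)


def gene_mapping(
    genes: IntervalList,
    rare_rohs: ROHSet,
    n_perm: int = 10_000,
    seed: int = 0,
    containment: bool = True,
) -> pd.DataFrame:
    """Gene-based mapping: carrier counting by full containment of the gene
    in a ROH (``containment=False`` counts any overlap), permutation p with
    the gene list as the family, and grouping of genes with identical
    carrier sets."""
    gd = genes.df
    if len(gd) == 0:
        raise ValueError("empty gene list")
    intervals = list(zip(gd["chrom"], gd["start_bp"], gd["end_bp"]))
    if containment:
        carriers = _carrier_matrix(intervals, rare_rohs)
    else:
        carriers = _overlap_matrix(intervals, rare_rohs)
    p_point, p_corr, p_bonf, cc, ctrl = _permutation_pvalues(
        carriers, rare_rohs.phenotype, n_perm, seed
    )
    # genes spanned by identical carrier sets share a group
    group_of: dict[bytes, int] = {}
    group_ids = np.empty(len(gd), dtype=int)
    for i in range(len(gd)):
        key = carriers[i].tobytes()
        group_ids[i] = group_of.setdefault(key, len(group_of))
    return pd.DataFrame(
        {
            "gene": gd["name"].to_numpy(),
            "chrom": gd["chrom"].to_numpy(),
            "start_bp": gd["start_bp"].to_numpy(),
            "end_bp": gd["end_bp"].to_numpy(),
            "carriers_cases": cc,
            "carriers_controls": ctrl,
            "p_pointwise": p_point,
            "p_corrected": p_corr,
            "p_bonferroni": p_bonf,
            "group_id": group_ids,
        }
    ).sort_values(["p_pointwise", "chrom", "start_bp"], kind="mergesort").reset_index(
        drop=True
    )


def _overlap_matrix(intervals, rohs: ROHSet) -> np.ndarray:
    df = rohs.df
    roster = pd.Index(rohs.sample_ids)
    seg_sample = roster.get_indexer(df["sample_id"])
    seg_chrom = df["chrom"].to_numpy()
    seg_start = df["start_bp"].to_numpy()
    seg_end = df["end_bp"].to_numpy()
    out = np.zeros((len(intervals), len(roster)), dtype=bool)
    for i, (chrom, s, e) in enumerate(intervals):
        hit = (seg_chrom == chrom) & (seg_start <= e) & (seg_end >= s)
        out[i, seg_sample[hit]] = True
    return out
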