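"""Separating common (IBS) from rare (IBD-like) runs of homozygosity.

Short-to-medium ROHs cluster at population hotspots where a common
haplotype happens to be frequent; these are homozygous by state and would
swamp a case-control comparison.  The filter finds all regions where at
least ``freq_threshold`` (default 1%) of all individuals — cases and
controls pooled — carry a qualifying ROH, and removes ROHs overlapping
such regions unless they are length outliers (> mean + ``sd_multiplier``
x SD of the lengths of all qualifying ROHs overlapping the region), which
are retained as likely autozygous segments spanning the hotspot.

The procedure is repeated for minimum-length strata (default 2, 3, 4 and
5 Mb); a ROH flagged common in any stratum is common overall.  ROHs below
the smallest stratum are outside the rare/common split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import ROHSet


@dataclass(frozen=True)
class CommonRegion:
    """A hotspot interval where >= ``carrier_fraction`` of individuals carry
    a qualifying ROH, with the length statistics that set its retention
    cutoff (``mean + sd_multiplier * sd``, population-SD convention)."""

    chrom: int
    start_bp: int
    end_bp: int
    carrier_count: int
    carrier_fraction: float
    overlap_length_mean_kb: float
    overlap_length_sd_kb: float
    sd_multiplier: float = 3.0
    source_threshold_mb: float = 2.0

    @property
    def retention_cutoff_kb(self) -> float:
        return self.overlap_length_mean_kb + self.sd_multiplier * self.overlap_length_sd_kb

    def retains(self, length_kb: float) -> bool:
        """A ROH through this region is retained (kept rare) iff its length
        strictly exceeds the cutoff."""
        return length_kb > self.retention_cutoff_kb


def carrier_frequency_track(
    rohs: ROHSet, variant_map: pd.DataFrame, min_length_mb: float
) -> np.ndarray:
    """Per-SNP count of distinct individuals with >= 1 ROH of at least
    ``min_length_mb`` Mb covering that SNP.

    One individual's qualifying segments on a chromosome are non-overlapping
    (caller invariant), so each covered SNP counts each individual once.
    """
    bp = variant_map["bp"].to_numpy()
    chroms = variant_map["chrom"].to_numpy()
    track = np.zeros(len(variant_map), dtype=np.int64)
    sub = rohs.df[rohs.df["length_kb"] >= 1000.0 * min_length_mb]
    for chrom, seg in sub.groupby("chrom"):
        cmask = np.flatnonzero(chroms == chrom)
        if len(cmask) == 0:
            continue
        cbp = bp[cmask]
        lo = np.searchsorted(cbp, seg["start_bp"].to_numpy(), side="left")
        hi = np.searchsorted(cbp, seg["end_bp"].to_numpy(), side="right")
        diff = np.zeros(len(cbp) + 1, dtype=np.int64)
        np.add.at(diff, lo, 1)
        np.add.at(diff, hi, -1)
        track[cmask] += np.cumsum(diff[:-1])
    return track


def find_common_regions(
    track: np.ndarray,
    variant_map: pd.DataFrame,
    n_samples: int,
    rohs: ROHSet,
    min_length_mb: float,
    freq_threshold: float = 0.01,
    sd_multiplier: float = 3.0,
) -> list[CommonRegion]:
    """Maximal runs of consecutive SNPs at carrier frequency >=
    ``freq_threshold`` become regions; each carries the mean/SD (population
    formula) of the lengths of all qualifying ROHs overlapping it by >=1 bp.

    A region overlapped by fewer than 2 qualifying ROHs has undefined SD;
    SD is then taken as 0 so the cutoff collapses to the mean (logged in
    spirit: such regions cannot arise at a 1% threshold on realistic n).
    """
    bp = variant_map["bp"].to_numpy()
    chroms = variant_map["chrom"].to_numpy()
    hot = track >= freq_threshold * n_samples
    qual = rohs.df[rohs.df["length_kb"] >= 1000.0 * min_length_mb]
    regions: list[CommonRegion] = []
    f = np.concatenate([[False], hot, [False]])
    d = np.diff(f.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    for s, e in zip(starts, ends):
        if chroms[s] != chroms[e]:
            # a hot run never spans chromosomes: split at the boundary
            cut = s + np.flatnonzero(np.diff(chroms[s : e + 1]) != 0)
            pieces = list(zip(np.r_[s, cut + 1], np.r_[cut, e]))
        else:
            pieces = [(s, e)]
        for a, b in pieces:
            chrom = int(chroms[a])
            start_bp, end_bp = int(bp[a]), int(bp[b])
            ov = qual[
                (qual["chrom"] == chrom)
                & (qual["start_bp"] <= end_bp)
                & (qual["end_bp"] >= start_bp)
            ]
            lengths = ov["length_kb"].to_numpy()
            carrier_count = ov["sample_id"].nunique()
            mean = float(lengths.mean()) if len(lengths) else 0.0
            sd = float(lengths.std(ddof=0)) if len(lengths) >= 2 else 0.0
            regions.append(
                CommonRegion(
                    chrom=chrom,
                    start_bp=start_bp,
                    end_bp=end_bp,
                    carrier_count=int(carrier_count),
                    carrier_fraction=carrier_count / n_samples,
                    overlap_length_mean_kb=mean,
                    overlap_length_sd_kb=sd,
                    sd_multiplier=sd_multiplier,
                    source_threshold_mb=min_length_mb,
                )
            )
    return regions


def classify_rare(
    rohs: ROHSet,
    variant_map: pd.DataFrame | None = None,
    strata: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0),
    freq_threshold: float = 0.01,
    sd_multiplier: float = 3.0,
    containment: bool = False,
) -> tuple[ROHSet, ROHSet, list[CommonRegion]]:
    """Partition ROHs >= min(strata) Mb into (rare, common) sets.

    For each stratum t: build the carrier track from ROHs >= t Mb, find
    hotspot regions, and mark any such ROH overlapping a region as common
    UNLESS its length exceeds the region's retention cutoff.  A ROH is
    rare iff no stratum marks it common.  ``containment=True`` requires a
    ROH to lie fully inside a region to be marked (default: any overlap).
    """
    if variant_map is None:
        variant_map = rohs.variant_map
    if variant_map is None:
        raise ValueError("classify_rare needs the variant map the ROHs were called on")
    floor_mb = min(strata)
    base = rohs.threshold(floor_mb)
    df = base.df
    common_mask = np.zeros(len(df), dtype=bool)
    all_regions: list[CommonRegion] = []
    n_samples = len(rohs.sample_ids)
    for t in sorted(strata):
        stratum = rohs.threshold(t)
        track = carrier_frequency_track(stratum, variant_map, t)
        regions = find_common_regions(
            track, variant_map, n_samples, stratum, t, freq_threshold, sd_multiplier
        )
        all_regions.extend(regions)
        if not regions:
            continue
        in_stratum = df["length_kb"].to_numpy() >= 1000.0 * t
        for reg in regions:
            on_chrom = df["chrom"].to_numpy() == reg.chrom
            if containment:
                hits = (
                    (df["start_bp"].to_numpy() >= reg.start_bp)
                    & (df["end_bp"].to_numpy() <= reg.end_bp)
                )
            else:
                hits = (
                    (df["start_bp"].to_numpy() <= reg.end_bp)
                    & (df["end_bp"].to_numpy() >= reg.start_bp)
                )
            flag = in_stratum & on_chrom & hits
            retained = df["length_kb"].to_numpy() > reg.retention_cutoff_kb
            common_mask |= flag & ~retained
    rare = ROHSet(
        df.loc[~common_mask].reset_index(drop=True),
        base.sample_ids,
        base.phenotype,
        variant_map,
    )
    common = ROHSet(
        df.loc[common_mask].reset_index(drop=True),
        base.sample_ids,
        base.phenotype,
        variant_map,
    )
    return rare, common, all_regions


def regions_to_frame(regions: list[CommonRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "carrier_count": r.carrier_count,
                "carrier_fraction": r.carrier_fraction,
                "overlap_length_mean_kb": r.overlap_length_mean_kb,
                "overlap_length_sd_kb": r.overlap_length_sd_kb,
                "retention_cutoff_kb": r.retention_cutoff_kb,
                "source_threshold_mb": r.source_threshold_mb,
            }
            for r in regions
        ]
    )
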