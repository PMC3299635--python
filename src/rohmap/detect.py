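"""Sliding-window detection of runs of homozygosity (ROH).

The caller follows the PLINK ``--homozyg`` window semantics: a window of
``window_snps`` consecutive SNPs is *homozygous* if it contains at most
``max_het_per_window`` heterozygous and ``max_missing_per_window`` missing
calls.  Windows are slid along each chromosome; a SNP is flagged as ROH
material when the fraction of windows spanning it that are homozygous
exceeds ``window_hit_threshold`` (strictly greater than, default 5%).
Maximal runs of flagged SNPs are split at inter-SNP gaps larger than
``max_gap_kb`` and kept if they satisfy the SNP-count, physical-length and
SNP-density floors.

Two implementations of the same contract are provided:

* :func:`call_roh_sample` / :func:`detect_roh` — incremental, vectorised.
* :func:`brute_force_roh` — explicit enumeration of every window, used as
  an independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HET, MISSING, GenotypeDataset

ROH_COLUMNS = [
    "sample_id",
    "phenotype",
    "chrom",
    "snp1",
    "snp2",
    "start_bp",
    "end_bp",
    "n_snps",
    "length_kb",
    "n_het",
    "n_miss",
]


@dataclass(frozen=True)
class ROHCallParams:
    """Tuning knobs of the window caller (defaults: 50-SNP windows, at most
    1 het and 1 missing call per window, >5% spanning-window hit fraction,
    1 Mb / 50 SNP / 1-per-50 kb segment floors, 1 Mb maximum gap)."""

    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 1
    window_hit_threshold: float = 0.05
    min_length_kb: float = 1000.0
    min_snps: int = 50
    min_density_snp_per_kb: float = 1.0 / 50.0
    max_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.window_hit_threshold):
            raise ValueError("window_hit_threshold must be positive")
        for name in ("window_snps", "min_length_kb", "min_snps",
                     "min_density_snp_per_kb", "max_gap_kb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run of one sample.

    ``start_bp``/``end_bp`` are the 1-based positions of the first and last
    SNP in the run; ``length_kb = (end_bp - start_bp + 1) / 1000``.
    """

    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int = 0
    n_miss: int = 0
    snp1: str = ""
    snp2: str = ""

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


@dataclass
class ROHSet:
    """All segments called against one panel, as a tidy DataFrame.

    ``df`` columns follow :data:`ROH_COLUMNS`.  ``sample_ids`` is the roster
    of samples the calls were made against (including ROH-free samples, which
    matters for per-person rates), ``phenotype`` the matching label array.
    """

    df: pd.DataFrame
    sample_ids: list[str]
    phenotype: np.ndarray
    variant_map: pd.DataFrame | None = None

    _DTYPES = {
        "sample_id": object, "phenotype": np.int64, "chrom": np.int64,
        "snp1": object, "snp2": object, "start_bp": np.int64,
        "end_bp": np.int64, "n_snps": np.int64, "length_kb": float,
        "n_het": np.int64, "n_miss": np.int64,
    }

    def __post_init__(self) -> None:
        if list(self.df.columns) != ROH_COLUMNS:
            self.df = self.df.reindex(columns=ROH_COLUMNS)
        self.df = self.df.astype(self._DTYPES)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.df)

    def threshold(self, min_length_mb: float) -> "ROHSet":
        """Pure length filter: keep segments >= ``min_length_mb`` Mb."""
        keep = self.df["length_kb"] >= 1000.0 * min_length_mb
        return ROHSet(
            self.df.loc[keep].reset_index(drop=True),
            self.sample_ids,
            self.phenotype,
            self.variant_map,
        )

    def counts_per_sample(self, min_length_mb: float = 0.0) -> np.ndarray:
        """Number of qualifying segments per roster sample."""
        sub = self.df[self.df["length_kb"] >= 1000.0 * min_length_mb]
        idx = pd.Index(self.sample_ids)
        counts = sub.groupby("sample_id").size()
        out = np.zeros(len(idx), dtype=np.int64)
        pos = idx.get_indexer(counts.index)
        out[pos] = counts.to_numpy()
        return out


def threshold_roh(rohs: ROHSet, min_length_mb: float) -> ROHSet:
    """Subset a ROHSet to segments at least ``min_length_mb`` Mb long."""
    if min_length_mb < 1:
        raise ValueError("min_length_mb must be >= 1")
    return rohs.threshold(min_length_mb)


def window_hit_fraction(genotypes: np.ndarray, params: ROHCallParams) -> np.ndarray:
    """Fraction of spanning windows that are homozygous, per SNP.

    Windows never cross chromosome ends; near the edges the number of
    spanning windows shrinks and the denominator shrinks with it.  A
    chromosome shorter than one window supports no windows at all and
    every fraction is 0.
    """
    g = np.asarray(genotypes)
    n = g.shape[-1]
    w = params.window_snps
    if n == 0:
        return np.zeros(0)
    if n < w:
        return np.zeros(g.shape, dtype=float)
    ok = _window_ok(g, params)          # (..., n - w + 1) booleans per start
    c = np.cumsum(ok, axis=-1, dtype=np.int64)
    c = np.concatenate([np.zeros(c.shape[:-1] + (1,), dtype=np.int64), c], axis=-1)
    i = np.arange(n)
    lo = np.maximum(0, i - w + 1)
    hi = np.minimum(i, n - w)
    num = c[..., hi + 1] - c[..., lo]
    den = hi - lo + 1
    return num / den


def _window_ok(g: np.ndarray, params: ROHCallParams) -> np.ndarray:
    """Boolean per window start: window satisfies the het/missing caps."""
    w = params.window_snps
    het = (g == HET).astype(np.int32)
    mis = (g == MISSING).astype(np.int32)
    ch = _sliding_sum(het, w)
    cm = _sliding_sum(mis, w)
    return (ch <= params.max_het_per_window) & (cm <= params.max_missing_per_window)


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    c = np.cumsum(x, axis=-1, dtype=np.int64)
    c = np.concatenate([np.zeros(c.shape[:-1] + (1,), dtype=np.int64), c], axis=-1)
    return c[..., w:] - c[..., :-w]


def _segments_from_flags(
    flags: np.ndarray,
    genotypes: np.ndarray,
    bp: np.ndarray,
    snp_ids: np.ndarray | None,
    chrom: int,
    sample_id: str,
    params: ROHCallParams,
) -> list[ROHSegment]:
    """Turn one sample's flagged-SNP mask into qualifying segments."""
    if not flags.any():
        return []
    f = np.concatenate([[False], flags, [False]])
    d = np.diff(f.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    out: list[ROHSegment] = []
    max_gap_bp = params.max_gap_kb * 1000.0
    for s, e in zip(starts, ends):
        # split the run where adjacent SNPs are further apart than max_gap
        gaps = np.flatnonzero(np.diff(bp[s : e + 1]) > max_gap_bp)
        bounds = np.concatenate([[s], s + gaps + 1, [e + 1]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            b -= 1
            seg = _qualify(a, b, genotypes, bp, snp_ids, chrom, sample_id, params)
            if seg is not None:
                out.append(seg)
    return out


def _qualify(a, b, genotypes, bp, snp_ids, chrom, sample_id, params):
    n_snps = b - a + 1
    length_kb = (bp[b] - bp[a] + 1) / 1000.0
    if n_snps < params.min_snps:
        return None
    if length_kb < params.min_length_kb:
        return None
    if n_snps / length_kb < params.min_density_snp_per_kb:
        return None
    inside = genotypes[a : b + 1]
    return ROHSegment(
        sample_id=sample_id,
        chrom=int(chrom),
        start_bp=int(bp[a]),
        end_bp=int(bp[b]),
        n_snps=int(n_snps),
        n_het=int(np.count_nonzero(inside == HET)),
        n_miss=int(np.count_nonzero(inside == MISSING)),
        snp1="" if snp_ids is None else str(snp_ids[a]),
        snp2="" if snp_ids is None else str(snp_ids[b]),
    )


def call_roh_sample(
    genotypes: np.ndarray,
    variant_map: pd.DataFrame,
    params: ROHCallParams = ROHCallParams(),
    sample_id: str = "S",
) -> list[ROHSegment]:
    """Call ROH for one sample.  ``variant_map`` may span several
    chromosomes; windows and runs never cross a chromosome boundary."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    out: list[ROHSegment] = []
    chroms = variant_map["chrom"].to_numpy()
    bp_all = variant_map["bp"].to_numpy()
    ids_all = variant_map["snp_id"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            sl = slice(start, i)
            g = genotypes[sl]
            frac = window_hit_fraction(g, params)
            flags = frac > params.window_hit_threshold
            out.extend(
                _segments_from_flags(
                    flags, g, bp_all[sl], ids_all[sl], chroms[start], sample_id, params
                )
            )
            start = i
    return out


def detect_roh(
    dataset: GenotypeDataset, params: ROHCallParams = ROHCallParams()
) -> ROHSet:
    """Call ROH for every sample on every chromosome.

    The window pass is vectorised across samples; output ordering is by
    sample roster then chromosome then position and is independent of any
    input permutation of samples.
    """
    rows: list[ROHSegment] = []
    vm = dataset.variant_map
    bp_all = vm["bp"].to_numpy()
    ids_all = vm["snp_id"].to_numpy()
    for chrom, sl in dataset.chrom_slices().items():
        g = dataset.genotypes[:, sl]
        frac = window_hit_fraction(g, params)
        flags = frac > params.window_hit_threshold
        bp = bp_all[sl]
        ids = ids_all[sl]
        carriers = np.flatnonzero(flags.any(axis=1))
        for si in carriers:
            rows.extend(
                _segments_from_flags(
                    flags[si], g[si], bp, ids, chrom, dataset.sample_ids[si], params
                )
            )
    return rohset_from_segments(rows, dataset)


def rohset_from_segments(
    segments: list[ROHSegment], dataset: GenotypeDataset
) -> ROHSet:
    """Assemble a sorted :class:`ROHSet` from per-sample segment lists."""
    pheno = {s: int(p) for s, p in zip(dataset.sample_ids, dataset.phenotype)}
    df = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "phenotype": pheno.get(s.sample_id, -9),
                "chrom": s.chrom,
                "snp1": s.snp1,
                "snp2": s.snp2,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_snps": s.n_snps,
                "length_kb": s.length_kb,
                "n_het": s.n_het,
                "n_miss": s.n_miss,
            }
            for s in segments
        ],
        columns=ROH_COLUMNS,
    )
    order = pd.Index(dataset.sample_ids)
    if len(df):
        df = (
            df.assign(_s=order.get_indexer(df["sample_id"]))
            .sort_values(["_s", "chrom", "start_bp"], kind="mergesort")
            .drop(columns="_s")
            .reset_index(drop=True)
        )
    return ROHSet(df, list(dataset.sample_ids), dataset.phenotype, dataset.variant_map)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_roh(
    genotypes,
    variant_map: pd.DataFrame,
    params: ROHCallParams = ROHCallParams(),
    sample_id: str = "S",
) -> list[ROHSegment]:
    """Reference implementation by explicit enumeration (small inputs only).

    Every window is enumerated and tested with plain Python counting; the
    per-SNP hit fraction, run splitting and segment floors are applied with
    no incremental shortcuts.  Output contract is identical to
    :func:`call_roh_sample`.
    """
    genotypes = list(np.asarray(genotypes, dtype=int))
    if len(genotypes) > 5000:
        raise ValueError("brute_force_roh is for small inputs (<=5000 SNPs)")
    chroms = list(variant_map["chrom"])
    bp = list(variant_map["bp"])
    ids = list(variant_map["snp_id"])
    out: list[ROHSegment] = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out.extend(
                _brute_one_chrom(
                    genotypes[start:i],
                    bp[start:i],
                    ids[start:i],
                    chroms[start],
                    sample_id,
                    params,
                )
            )
            start = i
    return out


def _brute_one_chrom(g, bp, ids, chrom, sample_id, params):
    n = len(g)
    w = params.window_snps
    ok = []
    for j in range(0, n - w + 1):
        window = g[j : j + w]
        n_het = sum(1 for x in window if x == int(HET))
        n_mis = sum(1 for x in window if x == int(MISSING))
        ok.append(
            n_het <= params.max_het_per_window
            and n_mis <= params.max_missing_per_window
        )
    flagged = []
    for i in range(n):
        spanning = [ok[j] for j in range(max(0, i - w + 1), min(i, n - w) + 1)]
        if not spanning:
            flagged.append(False)
        else:
            frac = sum(spanning) / len(spanning)
            flagged.append(frac > params.window_hit_threshold)
    # maximal runs of flagged SNPs, split at large gaps
    runs = []
    i = 0
    while i < n:
        if flagged[i]:
            j = i
            while j + 1 < n and flagged[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    pieces = []
    for a, b in runs:
        cur = a
        for k in range(a, b):
            if bp[k + 1] - bp[k] > params.max_gap_kb * 1000.0:
                pieces.append((cur, k))
                cur = k + 1
        pieces.append((cur, b))
    out = []
    for a, b in pieces:
        n_snps = b - a + 1
        length_kb = (bp[b] - bp[a] + 1) / 1000.0
        if n_snps < params.min_snps:
            continue
        if length_kb < params.min_length_kb:
            continue
        if n_snps / length_kb < params.min_density_snp_per_kb:
            continue
        out.append(
            ROHSegment(
                sample_id=sample_id,
                chrom=int(chrom),
                start_bp=int(bp[a]),
                end_bp=int(bp[b]),
                n_snps=n_snps,
                n_het=sum(1 for x in g[a : b + 1] if x == int(HET)),
                n_miss=sum(1 for x in g[a : b + 1] if x == int(MISSING)),
                snp1=str(ids[a]),
                snp2=str(ids[b]),
            )
        )
    return out
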