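"""Consensus-region pooling, complete-overlap counting and permutation p."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_rohset, make_variant_map
from rohmap import (
    IntervalList,
    build_consensus_regions,
    consensus_region,
    count_complete_overlap,
    gene_mapping,
    map_consensus,
    permutation_map,
    pool_roh,
)
from rohmap.mapping import ConsensusRegion, _maximal_cliques


MB = 1_000_000


class TestPooling:
    def test_two_identical_segments_one_pool(self):
        rohs = make_rohset(
            [("S1", 1, 2 * MB, 5 * MB), ("S2", 1, 2 * MB, 5 * MB)],
            ["S1", "S2"], [1, 0],
        )
        pools = pool_roh(rohs)
        assert len(pools) == 1 and len(pools[0]) == 2

    def test_isolated_segment_no_pool(self):
        rohs = make_rohset([("S1", 1, 2 * MB, 5 * MB)], ["S1", "S2"], [1, 0])
        assert pool_roh(rohs) == []

    def test_transitive_chaining_matches_pairwise_closure(self):
        segs = [("A", 1, 1 * MB, 5 * MB), ("B", 1, 4 * MB, 8 * MB),
                ("C", 1, 7 * MB, 12 * MB)]
        rohs = make_rohset(segs, ["A", "B", "C"], [1, 1, 0])
        pools = pool_roh(rohs)
        assert len(pools) == 1 and len(pools[0]) == 3
        # naive closure oracle: repeated pairwise merging
        intervals = [(s, e) for _, _, s, e in segs]
        groups = [{i} for i in range(3)]
        changed = True
        while changed:
            changed = False
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    if any(
                        intervals[a][0] <= intervals[b][1]
                        and intervals[b][0] <= intervals[a][1]
                        for a in groups[i] for b in groups[j]
                    ):
                        groups[i] |= groups.pop(j)
                        changed = True
                        break
                if changed:
                    break
        assert sorted(map(len, groups)) == [3]


class TestConsensus:
    def test_intersection_of_two(self):
        vm = make_variant_map(1500, spacing_bp=10_000)
        rohs = make_rohset(
            [("S1", 1, 1 * MB, 5 * MB), ("S2", 1, 3 * MB, 8 * MB)],
            ["S1", "S2"], [1, 0], vm,
        )
        pools = pool_roh(rohs)
        regions = consensus_region(pools[0], rohs, vm)
        assert len(regions) == 1
        assert (regions[0].start_bp, regions[0].end_bp) == (3 * MB, 5 * MB)

    def test_chain_with_empty_intersection_splits(self):
        vm = make_variant_map(1500, spacing_bp=10_000)
        rohs = make_rohset(
            [("A", 1, 1 * MB, 5 * MB), ("B", 1, 4 * MB, 8 * MB),
             ("C", 1, 7 * MB, 12 * MB)],
            ["A", "B", "C"], [1, 1, 0], vm,
        )
        regions = consensus_region(pool_roh(rohs)[0], rohs, vm)
        spans = sorted((r.start_bp, r.end_bp) for r in regions)
        assert spans == [(4 * MB, 5 * MB), (7 * MB, 8 * MB)]

    def test_maximal_cliques_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(17)
        from itertools import combinations
        for _ in range(20):
            k = int(rng.integers(3, 7))
            starts = rng.integers(0, 50, k)
            ends = starts + rng.integers(5, 40, k)
            got = {frozenset(c.tolist()) for c in _maximal_cliques(starts, ends)}
            # exhaustive: all subsets with common point, maximal ones only
            all_cliques = set()
            for r in range(2, k + 1):
                for sub in combinations(range(k), r):
                    if max(starts[list(sub)]) <= min(ends[list(sub)]):
                        all_cliques.add(frozenset(sub))
            maximal = {
                c for c in all_cliques
                if not any(c < d for d in all_cliques)
            }
            assert got == maximal

    def test_single_snp_consensus_dropped(self):
        vm = make_variant_map(100, spacing_bp=1_000_000)
        rohs = make_rohset(
            [("S1", 1, 1, 10 * MB), ("S2", 1, 9_500_001, 30 * MB)],
            ["S1", "S2"], [1, 0], vm,
        )
        # intersection 9.5-10 Mb holds one map SNP (at 10 Mb) only
        assert consensus_region(pool_roh(rohs)[0], rohs, vm) == []

    def test_regions_contained_in_every_member_and_unique(self):
        rng = np.random.default_rng(18)
        vm = make_variant_map(3000, spacing_bp=10_000)
        ids = [f"S{i}" for i in range(60)]
        segs = []
        for s in ids:
            a = int(rng.integers(1, 24 * MB))
            segs.append((s, 1, a, a + int(rng.integers(2 * MB, 5 * MB))))
        rohs = make_rohset(segs, ids, [1] * 30 + [0] * 30, vm)
        regions = build_consensus_regions(rohs, vm)
        keys = [(r.chrom, r.start_bp, r.end_bp) for r in regions]
        assert len(keys) == len(set(keys))
        df = rohs.df
        for r in regions:
            members = df[
                (df["chrom"] == r.chrom)
                & (df["start_bp"] <= r.start_bp)
                & (df["end_bp"] >= r.end_bp)
            ]
            assert len(members) >= 2


class TestCounting:
    def _rohs(self):
        return make_rohset(
            [("S1", 1, 2 * MB, 5 * MB),          # equals region
             ("S2", 1, 2 * MB + 30_000, 5 * MB), # misses the first 30 kb
             ("S3", 1, 1 * MB, 6 * MB)],
            ["S1", "S2", "S3", "S4"], [1, 1, 0, 0],
        )

    def test_containment_boundary(self):
        cc, ck = count_complete_overlap((1, 2 * MB, 5 * MB), self._rohs())
        assert (cc, ck) == (1, 1)  # S1 (exact) and S3 (superset); S2 excluded

    def test_partial_overlap_not_counted(self):
        cc, ck = count_complete_overlap((1, 2 * MB, 5 * MB), self._rohs())
        assert cc == 1  # S2's 99% overlap does not qualify


class TestPermutation:
    def _regions_rohs(self, n=400, k=30, seed=19):
        rng = np.random.default_rng(seed)
        vm = make_variant_map(2000, spacing_bp=10_000)
        ids = [f"S{i}" for i in range(n)]
        carriers = rng.choice(n, k, replace=False)
        segs = [(ids[i], 1, 4 * MB, 9 * MB) for i in carriers]
        pheno = np.array([1] * (n // 2) + [0] * (n // 2))
        rohs = make_rohset(segs, ids, pheno, vm)
        return rohs, vm

    def test_single_region_corrected_equals_pointwise(self):
        rohs, vm = self._regions_rohs()
        regions = [ConsensusRegion(1, 5 * MB, 8 * MB, 100)]
        permutation_map(regions, rohs, n_perm=2000, seed=0)
        assert regions[0].p_corrected == pytest.approx(regions[0].p_pointwise, abs=5e-3)

    def test_corrected_dominates_pointwise(self):
        rohs, vm = self._regions_rohs()
        regions = [
            ConsensusRegion(1, 5 * MB, 8 * MB, 100),
            ConsensusRegion(1, 4 * MB, 6 * MB, 100),
        ]
        permutation_map(regions, rohs, n_perm=1000, seed=1)
        for r in regions:
            assert r.p_corrected >= r.p_pointwise - 1e-12

    def test_two_independent_regions_closed_form(self):
        """For two independent null tests the family-wise p of a region with
        pointwise p approximates 1 - (1 - p)^2."""
        rng = np.random.default_rng(20)
        n = 1000
        ids = [f"S{i}" for i in range(n)]
        pheno = np.array([1] * 500 + [0] * 500)
        segs = []
        for i in rng.choice(n, 120, replace=False):
            segs.append((ids[i], 1, 2 * MB, 6 * MB))
        for i in rng.choice(n, 120, replace=False):
            segs.append((ids[i], 2, 2 * MB, 6 * MB))
        vm = pd.concat(
            [make_variant_map(800, 10_000, chrom=1),
             make_variant_map(800, 10_000, chrom=2)],
            ignore_index=True,
        )
        rohs = make_rohset(segs, ids, pheno, vm)
        regions = [ConsensusRegion(1, 3 * MB, 5 * MB, 100),
                   ConsensusRegion(2, 3 * MB, 5 * MB, 100)]
        permutation_map(regions, rohs, n_perm=20_000, seed=2)
        r = regions[0]
        expect = 1 - (1 - r.p_pointwise) ** 2
        assert r.p_corrected == pytest.approx(expect, abs=0.05)


class TestGeneMapping:
    def test_zero_carrier_gene_p_one(self):
        rohs = make_rohset(
            [("S1", 1, 2 * MB, 5 * MB)],
            [f"S{i}" for i in range(20)], [1] * 10 + [0] * 10,
        )
        genes = IntervalList(pd.DataFrame(
            {"chrom": [2], "start_bp": [MB], "end_bp": [2 * MB], "name": ["G1"]}
        ))
        out = gene_mapping(genes, rohs, n_perm=200, seed=0)
        assert out.iloc[0]["p_pointwise"] == 1.0

    def test_identical_carrier_sets_share_group_and_p(self):
        segs = [(f"S{i}", 1, 2 * MB, 8 * MB) for i in range(5)]
        rohs = make_rohset(
            segs, [f"S{i}" for i in range(40)], [1] * 20 + [0] * 20,
        )
        genes = IntervalList(pd.DataFrame({
            "chrom": [1, 1, 1],
            "start_bp": [3 * MB, 5 * MB, 9 * MB],
            "end_bp": [4 * MB, 6 * MB, 10 * MB],
            "name": ["G1", "G2", "G3"],
        }))
        out = gene_mapping(genes, rohs, n_perm=500, seed=1).set_index("gene")
        assert out.loc["G1", "group_id"] == out.loc["G2", "group_id"]
        assert out.loc["G1", "p_pointwise"] == out.loc["G2", "p_pointwise"]
        assert out.loc["G3", "group_id"] != out.loc["G1", "group_id"]

    def test_planted_case_locus_is_top_gene(self):
        rng = np.random.default_rng(21)
        n = 300
        ids = [f"S{i}" for i in range(n)]
        pheno = np.array([1] * 150 + [0] * 150)
        segs = [(ids[i], 1, 4 * MB, 7 * MB) for i in range(6)]  # 6 cases
        for i in rng.choice(np.arange(50, n), 30, replace=False):
            a = int(rng.integers(10 * MB, 20 * MB))
            segs.append((ids[i], 1, a, a + 2 * MB))
        rohs = make_rohset(segs, ids, pheno)
        genes = IntervalList(pd.DataFrame({
            "chrom": [1, 1, 1],
            "start_bp": [5 * MB, 12 * MB, 15 * MB],
            "end_bp": [6 * MB, 13 * MB, 16 * MB],
            "name": ["TARGET", "BG1", "BG2"],
        }))
        out = gene_mapping(genes, rohs, n_perm=2000, seed=2)
        assert out.iloc[0]["gene"] == "TARGET"
        assert out.iloc[0]["carriers_cases"] == 6
        assert out.iloc[0]["carriers_controls"] == 0
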