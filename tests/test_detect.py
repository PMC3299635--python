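"""Window-based ROH calling vs the brute-force enumeration oracle."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_variant_map
from rohmap import (
    PlantedSegmentSpec,
    ROHCallParams,
    SimConfig,
    brute_force_roh,
    call_roh_sample,
    detect_roh,
    simulate_dataset,
    threshold_roh,
    window_hit_fraction,
)

SMALL = ROHCallParams(window_snps=10, min_snps=10, min_length_kb=50,
                      min_density_snp_per_kb=1 / 50, max_gap_kb=100)


class TestWindowFraction:
    def test_all_homozygous_fraction_one(self):
        g = np.zeros(200, dtype=np.int8)
        assert np.all(window_hit_fraction(g, ROHCallParams()) == 1.0)

    def test_all_het_fraction_zero(self):
        g = np.ones(200, dtype=np.int8)
        assert np.all(window_hit_fraction(g, ROHCallParams()) == 0.0)

    def test_short_chromosome_no_windows(self):
        g = np.zeros(30, dtype=np.int8)
        assert np.all(window_hit_fraction(g, ROHCallParams()) == 0.0)

    def test_matches_explicit_window_enumeration(self):
        """Hets at indices 30 and 60 of 120 homozygous SNPs: the fraction at
        each SNP equals passing/spanning windows counted by hand."""
        params = ROHCallParams()
        g = np.zeros(120, dtype=np.int8)
        g[30] = g[60] = 1
        frac = window_hit_fraction(g, params)
        w = params.window_snps
        n = len(g)
        for i in (0, 29, 30, 45, 60, 100, 119):
            spanning = range(max(0, i - w + 1), min(i, n - w) + 1)
            passing = sum(
                1 for j in spanning
                if np.count_nonzero(g[j:j + w] == 1) <= 1
            )
            assert frac[i] == pytest.approx(passing / len(range(max(0, i - w + 1), min(i, n - w) + 1)))

    def test_more_het_tolerance_flags_more_snps(self):
        rng = np.random.default_rng(0)
        g = rng.choice([0, 1, 2], 400, p=[0.45, 0.2, 0.35]).astype(np.int8)
        strict = ROHCallParams(max_het_per_window=0)
        loose = ROHCallParams(max_het_per_window=3)
        f_strict = window_hit_fraction(g, strict)
        f_loose = window_hit_fraction(g, loose)
        assert np.all(f_loose >= f_strict)


class TestCallRoh:
    def test_planted_run_called_with_window_slack(self):
        vm = make_variant_map(600, spacing_bp=7000)
        g = np.ones(600, dtype=np.int8)
        g[150:450] = 0  # ~2.1 Mb homozygous
        segs = call_roh_sample(g, vm, ROHCallParams())
        assert len(segs) == 1
        bp = vm["bp"].to_numpy()
        w = 50
        assert abs(segs[0].start_bp - bp[150]) <= (w - 1) * 7000
        assert abs(segs[0].end_bp - bp[449]) <= (w - 1) * 7000

    def test_short_run_below_length_floor(self):
        vm = make_variant_map(600, spacing_bp=1000)  # 0.6 Mb chromosome
        g = np.zeros(600, dtype=np.int8)
        assert call_roh_sample(g, vm, ROHCallParams()) == []

    def test_sparse_run_fails_density(self):
        vm = make_variant_map(80, spacing_bp=80_000)  # 1 SNP per 80 kb
        g = np.zeros(80, dtype=np.int8)
        params = ROHCallParams(max_gap_kb=200)
        assert call_roh_sample(g, vm, params) == []

    def test_gap_splitting(self):
        vm = make_variant_map(400, spacing_bp=4000)
        vm.loc[200:, "bp"] += 2_000_000  # 2 Mb hole in the middle
        g = np.zeros(400, dtype=np.int8)
        segs = call_roh_sample(g, vm, ROHCallParams(min_length_kb=500))
        assert len(segs) == 2

    def test_unsatisfiable_threshold_empty(self):
        vm = make_variant_map(600, spacing_bp=7000)
        g = np.zeros(600, dtype=np.int8)
        assert call_roh_sample(g, vm, ROHCallParams(window_hit_threshold=1.5)) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        vm = make_variant_map(n, spacing_bp=int(rng.integers(2000, 12000)))
        g = rng.choice(
            [0, 1, 2, -1], n, p=[0.5, 0.25, 0.2, 0.05]
        ).astype(np.int8)
        for _ in range(rng.integers(1, 4)):
            s = int(rng.integers(0, n - 60))
            g[s:s + int(rng.integers(20, 60))] = 0
        assert call_roh_sample(g, vm, SMALL) == brute_force_roh(g, vm, SMALL)

    def test_all_homozygous_single_segment(self):
        vm = make_variant_map(300, spacing_bp=10_000)
        g = np.zeros(300, dtype=np.int8)
        segs = brute_force_roh(g, vm, SMALL)
        assert len(segs) == 1
        assert segs[0].n_snps == 300

    def test_empty_input(self):
        vm = make_variant_map(0)
        assert brute_force_roh(np.empty(0, dtype=np.int8), vm, SMALL) == []


class TestDetect:
    def test_all_het_dataset_empty(self, small_panel):
        ds, _, _ = small_panel
        import copy
        ds2 = copy.deepcopy(ds)
        ds2.genotypes[:] = 1
        assert len(detect_roh(ds2)) == 0

    def test_planted_truth_recovery(self):
        cfg = SimConfig(
            n_cases=50, n_controls=50, n_chromosomes=1, snps_per_chrom=2000,
            het_error_rate=0.002,
            planted_segments=[PlantedSegmentSpec("either", 3.0, 1, 1.0)],
            seed=13,
        )
        ds, _, truth = simulate_dataset(cfg)
        rohs = detect_roh(ds)
        recovered = 0
        for row in truth.segments.itertuples(index=False):
            hits = rohs.df[
                (rohs.df["sample_id"] == row.sample_id)
                & (rohs.df["chrom"] == row.chrom)
                & (rohs.df["start_bp"] <= row.end_bp)
                & (rohs.df["end_bp"] >= row.start_bp)
            ]
            recovered += len(hits) > 0
        assert recovered >= 0.95 * len(truth.segments)

    def test_sample_order_invariance(self, small_panel):
        from rohmap.core import GenotypeDataset

        ds, _, _ = small_panel
        rohs = detect_roh(ds)
        perm = np.arange(ds.n_samples)[::-1]
        shuffled = GenotypeDataset(
            variant_map=ds.variant_map,
            sample_ids=[ds.sample_ids[i] for i in perm],
            phenotype=ds.phenotype[perm],
            genotypes=ds.genotypes[perm],
            allele_a=ds.allele_a,
            allele_b=ds.allele_b,
        )
        a = detect_roh(ds).df.sort_values(["sample_id", "chrom", "start_bp"]).reset_index(drop=True)
        b = detect_roh(shuffled).df.sort_values(["sample_id", "chrom", "start_bp"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        assert len(rohs.df) == len(a)


class TestThreshold:
    def _rohs(self):
        from conftest import make_rohset
        return make_rohset(
            [("S1", 1, 1_000_000, 3_499_999),   # 2.5 Mb
             ("S2", 1, 1_000_000, 7_999_999),   # 7.0 Mb
             ("S3", 2, 1_000_000, 10_499_999)], # 9.5 Mb
            ["S1", "S2", "S3"], [1, 0, 1],
        )

    def test_floor_is_identity(self):
        rohs = self._rohs()
        assert len(threshold_roh(rohs, 1)) == 3

    def test_filtering_at_8mb(self):
        kept = threshold_roh(self._rohs(), 8)
        assert list(kept.df["sample_id"]) == ["S3"]

    def test_counts_non_increasing(self):
        rohs = self._rohs()
        counts = [len(threshold_roh(rohs, t)) for t in range(1, 11)]
        assert counts == sorted(counts, reverse=True)
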