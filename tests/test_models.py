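"""LD pruning, inbreeding f, MDS ancestry axes and the logistic series."""

import numpy as np
import pandas as pd
import pytest

from rohmap import (
    GenotypeDataset,
    SimConfig,
    fit_logistic,
    inbreeding_f,
    ld_prune,
    mds_components,
    run_model_series,
    simulate_dataset,
)
from conftest import make_rohset, make_variant_map


def _panel(n=60, m=1500, seed=0, **kw):
    cfg = SimConfig(n_cases=n // 2, n_controls=n - n // 2, n_chromosomes=1,
                    snps_per_chrom=m, seed=seed, **kw)
    return simulate_dataset(cfg)[0]


class TestLdPrune:
    def test_independent_snps_mostly_retained(self):
        ds = _panel(200, 2000, seed=1)
        kept = ld_prune(ds)
        assert len(kept) >= 0.95 * ds.n_snps

    def test_duplicated_column_dropped_once(self):
        ds = _panel(100, 500, seed=2)
        ds.genotypes[:, 101] = ds.genotypes[:, 100]
        kept = set(ld_prune(ds))
        assert (100 in kept) != (101 in kept)

    def test_block_ld_collapses_to_one_per_block(self):
        cfg = SimConfig(n_cases=150, n_controls=150, n_chromosomes=1,
                        snps_per_chrom=500, ld_block_size=10, ld_block_r=0.9,
                        seed=3)
        ds, _, _ = simulate_dataset(cfg)
        kept = ld_prune(ds)
        # ~1 SNP per 10-SNP block survives aggressive within-block correlation
        assert len(kept) <= 0.35 * ds.n_snps


class TestInbreedingF:
    def test_all_het_sample_is_minus_one(self):
        vm = make_variant_map(400)
        rng = np.random.default_rng(4)
        g = rng.integers(0, 3, (80, 400)).astype(np.int8)
        g[0] = 1
        ds = GenotypeDataset(vm, [f"S{i}" for i in range(80)],
                             np.ones(80, dtype=int), g)
        est = inbreeding_f(ds)
        assert est.f[0] == pytest.approx(-1.0, abs=0.15)

    def test_fully_homozygous_sample_is_one(self):
        vm = make_variant_map(400)
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, (80, 400)).astype(np.int8)
        g[0] = np.where(rng.random(400) < 0.5, 0, 2).astype(np.int8)
        ds = GenotypeDataset(vm, [f"S{i}" for i in range(80)],
                             np.ones(80, dtype=int), g)
        assert inbreeding_f(ds).f[0] == pytest.approx(1.0, abs=1e-9)

    def test_outbred_panel_centred_at_zero(self):
        ds = _panel(300, 4000, seed=6)
        est = inbreeding_f(ds)
        assert abs(est.f.mean()) < 0.01

    def test_first_cousin_level_recovery(self):
        f_true = np.full(100, 0.0625)
        ds = _panel(100, 6000, seed=7, f_distribution=f_true)
        est = inbreeding_f(ds)
        assert est.f.mean() == pytest.approx(0.0625, abs=0.012)


class TestMDS:
    def test_duplicated_sample_identical_coordinates(self):
        ds = _panel(40, 800, seed=8)
        ds.genotypes[1] = ds.genotypes[0]
        mds = mds_components(ds, 2)
        assert np.allclose(mds.coords[0], mds.coords[1], atol=1e-8)

    def test_two_subpopulations_separate_on_c1(self):
        rng = np.random.default_rng(9)
        m, n = 2000, 200
        vm = make_variant_map(m)
        base = rng.uniform(0.15, 0.35, m)
        shift = np.clip(base + 0.2, 0.01, 0.99)
        g = np.empty((n, m), dtype=np.int8)
        for i in range(n):
            q = base if i < n // 2 else shift
            g[i] = rng.binomial(2, q)
        ds = GenotypeDataset(vm, [f"S{i}" for i in range(n)],
                             np.ones(n, dtype=int), g)
        mds = mds_components(ds, 2)
        group = np.array([0] * (n // 2) + [1] * (n // 2))
        r = np.corrcoef(mds.coords[:, 0], group)[0, 1]
        assert abs(r) > 0.9

    def test_homogeneous_population_no_structure(self):
        ds = _panel(200, 2000, seed=10)
        mds = mds_components(ds, 2)
        rng = np.random.default_rng(11)
        labels = rng.permutation([0] * 100 + [1] * 100)
        r = np.corrcoef(mds.coords[:, 0], labels)[0, 1]
        assert abs(r) < 0.2

    def test_distance_matrix_symmetric_zero_diagonal(self):
        from rohmap.models import ibs_distance_matrix
        ds = _panel(30, 400, seed=12)
        d = ibs_distance_matrix(ds)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)


class TestFitLogistic:
    def test_two_by_two_matches_log_odds_ratio(self):
        rng = np.random.default_rng(13)
        x = rng.binomial(1, 0.4, 3000)
        y = rng.binomial(1, np.where(x == 1, 0.6, 0.4))
        res = fit_logistic(y, x)
        n11 = ((x == 1) & (y == 1)).sum()
        n10 = ((x == 1) & (y == 0)).sum()
        n01 = ((x == 0) & (y == 1)).sum()
        n00 = ((x == 0) & (y == 0)).sum()
        assert res.coefficient == pytest.approx(
            np.log(n11 * n00 / (n10 * n01)), abs=1e-6
        )
        assert res.ci95_low < res.odds_ratio < res.ci95_high

    def test_perfect_separation_flagged(self):
        y = np.array([0, 0, 1, 1])
        x = np.array([0.0, 0.1, 5.0, 5.1])
        res = fit_logistic(y, x)
        assert res.separation

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.array([0, 1, 0, 1]), np.ones(4))


class TestModelSeries:
    def _inputs(self, seed=14):
        rng = np.random.default_rng(seed)
        n = 400
        ids = [f"S{i}" for i in range(n)]
        pheno = np.array([1] * (n // 2) + [0] * (n // 2))
        segs = [
            (s, 1, 1_000_000, 1_000_000 + int(rng.uniform(2e6, 8e6)))
            for s in ids if rng.random() < 0.4
        ]
        rohs = make_rohset(segs, ids, pheno)
        cov = pd.DataFrame({
            "sample_id": ids,
            "f": rng.normal(0, 0.01, n),
            "age": rng.uniform(40, 70, n),
            "C1": rng.normal(0, 1, n),
            "C2": rng.normal(0, 1, n),
        })
        return rohs, cov

    def test_model1_equals_unadjusted_fit(self):
        rohs, cov = self._inputs()
        out = run_model_series(rohs, cov, [2.0], models=(1,))
        counts = rohs.counts_per_sample(2.0).astype(float)
        direct = fit_logistic(rohs.phenotype, counts)
        row = out[(out["predictor"] == "rate")].iloc[0]
        assert row["coefficient"] == pytest.approx(direct.coefficient, abs=1e-9)

    def test_null_models_agree_and_not_anticonservative(self):
        rejections = {m: 0 for m in (1, 2, 3, 4)}
        reps = 30
        for rep in range(reps):
            rohs, cov = self._inputs(seed=100 + rep)
            out = run_model_series(rohs, cov, [2.0])
            for m in rejections:
                sub = out[(out["model_id"] == m) & (out["predictor"] == "rate")]
                rejections[m] += int((sub["p_wald"] < 0.05).any())
        for m, r in rejections.items():
            assert r / reps <= 0.2  # ~alpha with wide MC slack at 30 reps

    def test_age_confounding_attenuated_by_model3(self):
        rng = np.random.default_rng(15)
        n = 2000
        ids = [f"S{i}" for i in range(n)]
        age = rng.uniform(40, 80, n)
        # age drives both case status and ROH count: unadjusted OR inflated
        p_case = 1 / (1 + np.exp(-(age - 60) / 8))
        pheno = rng.binomial(1, p_case)
        lam = np.exp((age - 60) / 20)
        counts = rng.poisson(lam)
        segs = []
        for i, s in enumerate(ids):
            for k in range(counts[i]):
                start = 1_000_000 + 4_000_000 * k
                segs.append((s, 1, start, start + 2_999_999))
        rohs = make_rohset(segs, ids, pheno)
        cov = pd.DataFrame({"sample_id": ids, "f": rng.normal(0, 0.01, n), "age": age})
        out = run_model_series(rohs, cov, [2.0], models=(1, 3))
        rate = out[out["predictor"] == "rate"].set_index("model_id")
        b1 = rate.loc[1, "coefficient"]
        b3 = rate.loc[3, "coefficient"]
        assert b1 > 0.1            # confounded signal
        assert abs(b3) < abs(b1)   # adjustment pulls toward the true 0
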