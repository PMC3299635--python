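"""End-to-end orchestration: detect -> filter -> burden -> models ->
mapping, plus the locus-exclusion and long-ROH subgroup re-analyses and a
plain-text run report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as rio
from .burden import burden_table
from .core import CASE, CONTROL, GenotypeDataset, IntervalList
from .detect import ROHCallParams, ROHSet, detect_roh
from .filtering import classify_rare, regions_to_frame
from .mapping import gene_mapping, map_consensus
from .models import inbreeding_f, ld_prune, mds_components, run_model_series

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    ped_path: str
    map_path: str
    covariates_path: str | None = None
    exclusion_genes_path: str | None = None
    genes_path: str | None = None
    out_dir: str = "rohmap_run"
    call_params: ROHCallParams = field(default_factory=ROHCallParams)
    strata: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)
    freq_threshold: float = 0.01
    sd_multiplier: float = 3.0
    burden_thresholds: tuple[float, ...] = (2, 3, 4, 5, 6, 7, 8, 9, 10)
    n_perm_burden: int = 10_000
    n_perm_mapping: int = 10_000
    subgroup_cutoff_mb: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        for p in (self.ped_path, self.map_path, self.covariates_path,
                  self.exclusion_genes_path, self.genes_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def exclude_locus_carriers(
    rohs: ROHSet,
    genes: IntervalList,
    min_length_mb: float = 2.0,
    containment: bool = False,
) -> tuple[ROHSet, pd.DataFrame]:
    """Remove every sample with a ROH >= ``min_length_mb`` Mb overlapping a
    listed gene (any base-pair overlap by default).

    Returns the reduced ROHSet (roster shrinks too) and a per-gene audit of
    removed samples.
    """
    import warnings

    if len(genes) == 0:
        warnings.warn("empty gene list: exclusion is a no-op")
        return rohs, pd.DataFrame(columns=["gene", "n_samples_removed", "samples"])
    df = rohs.df[rohs.df["length_kb"] >= 1000.0 * min_length_mb]
    removed: dict[str, set] = {}
    hit_samples: set[str] = set()
    for g in genes.df.itertuples(index=False):
        on = df[df["chrom"] == g.chrom]
        if containment:
            hits = on[(on["start_bp"] >= g.start_bp) & (on["end_bp"] <= g.end_bp)]
        else:
            hits = on[(on["start_bp"] <= g.end_bp) & (on["end_bp"] >= g.start_bp)]
        samples = set(hits["sample_id"])
        removed[g.name] = samples
        hit_samples |= samples
    keep_mask = [s not in hit_samples for s in rohs.sample_ids]
    new_roster = [s for s in rohs.sample_ids if s not in hit_samples]
    reduced = ROHSet(
        rohs.df[~rohs.df["sample_id"].isin(hit_samples)].reset_index(drop=True),
        new_roster,
        rohs.phenotype[np.asarray(keep_mask)],
        rohs.variant_map,
    )
    audit = pd.DataFrame(
        [
            {"gene": g, "n_samples_removed": len(s), "samples": ",".join(sorted(s))}
            for g, s in removed.items()
        ]
    )
    return reduced, audit


def subgroup_long_roh(
    rohs: ROHSet,
    cutoff_mb: float = 8.0,
    covariates: pd.DataFrame | None = None,
    numeric_covariate: str = "aao",
    categorical_covariate: str = "cohort",
    f_column: str = "f",
    burden_thresholds: tuple[float, ...] = (2, 3, 4, 5, 6, 7),
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Re-analyses around carriers of ROHs longer than ``cutoff_mb`` Mb.

    (a) burden excluding carrier samples; (b) burden keeping all samples
    but dropping the long ROHs; (c) carriers vs non-carriers descriptives:
    equal-variance t-test on a numeric covariate, per-level one-vs-rest
    Fisher exact tests on a categorical covariate, and a mean-f comparison.
    """
    lengths = rohs.df["length_kb"].to_numpy()
    long_carriers = set(rohs.df.loc[lengths > cutoff_mb * 1000.0, "sample_id"])
    out: dict = {"n_carriers": len(long_carriers)}
    if not long_carriers:
        out["skipped"] = True
        return out

    keep = [s not in long_carriers for s in rohs.sample_ids]
    without_samples = ROHSet(
        rohs.df[~rohs.df["sample_id"].isin(long_carriers)].reset_index(drop=True),
        [s for s in rohs.sample_ids if s not in long_carriers],
        rohs.phenotype[np.asarray(keep)],
        rohs.variant_map,
    )
    without_long = ROHSet(
        rohs.df[lengths <= cutoff_mb * 1000.0].reset_index(drop=True),
        rohs.sample_ids,
        rohs.phenotype,
        rohs.variant_map,
    )
    out["burden_excl_samples"] = burden_table(
        without_samples, list(burden_thresholds), n_perm=n_perm, seed=seed
    )
    out["burden_excl_long_rohs"] = burden_table(
        without_long, list(burden_thresholds), n_perm=n_perm, seed=seed + 1
    )

    carrier_mask = np.array([s in long_carriers for s in rohs.sample_ids])
    counts_short = _count_between(rohs, 2.0, cutoff_mb - 1.0)
    out["rate_2_to_short_carriers"] = float(counts_short[carrier_mask].mean())
    out["rate_2_to_short_noncarriers"] = float(counts_short[~carrier_mask].mean())
    if covariates is not None:
        cov = covariates.set_index("sample_id").reindex(rohs.sample_ids)
        if numeric_covariate in cov.columns:
            x = cov[numeric_covariate].to_numpy(dtype=float)
            a = x[carrier_mask & np.isfinite(x)]
            b = x[~carrier_mask & np.isfinite(x)]
            if len(a) >= 2 and len(b) >= 2:
                res = stats.ttest_ind(a, b, equal_var=True)
                out["numeric_ttest"] = {
                    "mean_carriers": float(a.mean()),
                    "mean_noncarriers": float(b.mean()),
                    "t": float(res.statistic),
                    "p": float(res.pvalue),
                }
        if categorical_covariate in cov.columns:
            levels = cov[categorical_covariate].dropna().unique()
            fisher = {}
            for lvl in levels:
                in_lvl = (cov[categorical_covariate] == lvl).to_numpy()
                table = [
                    [int((carrier_mask & in_lvl).sum()), int((carrier_mask & ~in_lvl).sum())],
                    [int((~carrier_mask & in_lvl).sum()), int((~carrier_mask & ~in_lvl).sum())],
                ]
                fisher[str(lvl)] = {
                    "table": table,
                    "p": float(stats.fisher_exact(table)[1]),
                }
            out["fisher_by_level"] = fisher
        if f_column in cov.columns:
            fv = cov[f_column].to_numpy(dtype=float)
            a = fv[carrier_mask & np.isfinite(fv)]
            b = fv[~carrier_mask & np.isfinite(fv)]
            if len(a) >= 2 and len(b) >= 2:
                res = stats.ttest_ind(a, b, equal_var=True)
                out["f_comparison"] = {
                    "mean_f_carriers": float(a.mean()),
                    "mean_f_noncarriers": float(b.mean()),
                    "p": float(res.pvalue),
                }
    return out


def _count_between(rohs: ROHSet, lo_mb: float, hi_mb: float) -> np.ndarray:
    df = rohs.df
    sub = df[(df["length_kb"] >= lo_mb * 1000.0) & (df["length_kb"] <= hi_mb * 1000.0)]
    idx = pd.Index(rohs.sample_ids)
    out = np.zeros(len(idx), dtype=float)
    grouped = sub.groupby("sample_id").size()
    out[idx.get_indexer(grouped.index)] = grouped.to_numpy()
    return out


def _file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order, writing one TSV per stage plus a
    human-readable summary into ``config.out_dir``.  Deterministic under a
    fixed seed; any stage failure aborts with the stage named, partial
    outputs preserved."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "seed": config.seed,
        "inputs": {
            "ped": _file_hash(config.ped_path),
            "map": _file_hash(config.map_path),
        },
        "call_params": vars(config.call_params).copy()
        if not hasattr(config.call_params, "__dataclass_fields__")
        else {k: getattr(config.call_params, k) for k in config.call_params.__dataclass_fields__},
    }
    report: dict = {"out_dir": str(out_dir)}
    stage = "read"
    try:
        dataset = rio.read_plink_text(config.ped_path, config.map_path)
        covariates = (
            rio.read_covariates(config.covariates_path)
            if config.covariates_path
            else pd.DataFrame({"sample_id": dataset.sample_ids})
        )

        stage = "detect"
        rohs = detect_roh(dataset, config.call_params)
        rio.write_roh_table(rohs, out_dir / "roh_all.tsv")
        log.info("detected %d segments in %d samples", len(rohs), dataset.n_samples)

        stage = "filter"
        rare, common, regions = classify_rare(
            rohs,
            dataset.variant_map,
            strata=config.strata,
            freq_threshold=config.freq_threshold,
            sd_multiplier=config.sd_multiplier,
        )
        rio.write_roh_table(rare, out_dir / "roh_rare.tsv")
        rio.write_roh_table(common, out_dir / "roh_common.tsv")
        regions_to_frame(regions).to_csv(out_dir / "common_regions.tsv", sep="\t", index=False)

        stage = "burden"
        burden_all = burden_table(
            rohs, list(config.burden_thresholds),
            n_perm=config.n_perm_burden, seed=config.seed,
        )
        burden_rare = burden_table(
            rare, list(config.burden_thresholds),
            n_perm=config.n_perm_burden, seed=config.seed + 1,
        )
        burden_all.to_csv(out_dir / "burden_all.tsv", sep="\t", index=False)
        burden_rare.to_csv(out_dir / "burden_rare.tsv", sep="\t", index=False)
        report["burden_rare"] = burden_rare

        stage = "models"
        pruned = ld_prune(dataset)
        fhat = inbreeding_f(dataset, pruned)
        mds = mds_components(dataset, k=2, snp_subset=pruned)
        cov = covariates.set_index("sample_id").reindex(dataset.sample_ids).reset_index()
        cov["f"] = fhat.f
        cov["C1"] = mds.coords[:, 0]
        cov["C2"] = mds.coords[:, 1]
        rio.write_covariates(cov, out_dir / "covariates_computed.tsv")
        model_results = run_model_series(rare, cov, list(config.burden_thresholds))
        model_results.to_csv(out_dir / "models.tsv", sep="\t", index=False)
        report["models"] = model_results

        stage = "mapping"
        consensus = map_consensus(
            rare, dataset.variant_map,
            n_perm=config.n_perm_mapping, seed=config.seed + 2,
        )
        consensus.to_csv(out_dir / "consensus_regions.tsv", sep="\t", index=False)
        report["consensus"] = consensus
        if config.genes_path:
            genes = rio.read_intervals(config.genes_path)
            gene_res = gene_mapping(
                genes, rare, n_perm=config.n_perm_mapping, seed=config.seed + 3
            )
            gene_res.to_csv(out_dir / "gene_mapping.tsv", sep="\t", index=False)
            report["genes"] = gene_res

        stage = "exclusion"
        if config.exclusion_genes_path:
            excl = rio.read_intervals(config.exclusion_genes_path)
            reduced, audit = exclude_locus_carriers(rare, excl)
            audit.to_csv(out_dir / "exclusion_audit.tsv", sep="\t", index=False)
            if (reduced.phenotype == CASE).any() and (reduced.phenotype == CONTROL).any():
                burden_excl = burden_table(
                    reduced, list(config.burden_thresholds),
                    n_perm=config.n_perm_burden, seed=config.seed + 4,
                )
                burden_excl.to_csv(out_dir / "burden_after_exclusion.tsv", sep="\t", index=False)

        stage = "subgroup"
        sub = subgroup_long_roh(
            rare, cutoff_mb=config.subgroup_cutoff_mb, covariates=cov,
            n_perm=min(config.n_perm_burden, 1000), seed=config.seed + 5,
        )
        for key in ("burden_excl_samples", "burden_excl_long_rohs"):
            if key in sub:
                sub[key].to_csv(out_dir / f"subgroup_{key}.tsv", sep="\t", index=False)
                sub[key] = str(out_dir / f"subgroup_{key}.tsv")
        (out_dir / "subgroup.json").write_text(json.dumps(sub, indent=2, default=str))

        stage = "report"
        _write_summary(out_dir, burden_rare, model_results, consensus)
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    except Exception as exc:  # noqa: BLE001 - stage context matters to callers
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report


def _fmt_p(p: float) -> str:
    return "n.s." if p >= 0.05 else f"{p:.2g}"


def _write_summary(out_dir: Path, burden_rare, model_results, consensus) -> None:
    lines = ["# rohmap run summary", "", "## Rare-ROH burden (cases vs controls)", ""]
    for row in burden_rare.itertuples(index=False):
        lines.append(
            f">{row.threshold_mb:g} Mb  proportion {100*row.proportion_cases:.2f}% vs "
            f"{100*row.proportion_controls:.2f}% (ratio {row.ratio_proportion:.2f}, "
            f"p {_fmt_p(row.p_proportion)})  rate {row.rate_cases:.2f} vs "
            f"{row.rate_controls:.2f} (ratio {row.ratio_rate:.2f}, p {_fmt_p(row.p_rate)})"
        )
    lines += ["", "## Logistic models (fully adjusted)", ""]
    if len(model_results):
        best = model_results[model_results["model_id"] == model_results["model_id"].max()]
        for row in best.itertuples(index=False):
            lines.append(
                f">{row.threshold_mb:g} Mb {row.predictor:10s} OR "
                f"{row.odds_ratio:.2f} ({row.ci95_low:.2f}-{row.ci95_high:.2f}), "
                f"p {_fmt_p(row.p_wald)}"
            )
    lines += ["", "## Top mapped consensus regions", ""]
    for row in consensus.head(10).itertuples(index=False):
        lines.append(
            f"chr{row.chrom}:{row.start_bp:,}-{row.end_bp:,}  "
            f"{row.carriers_cases} cases / {row.carriers_controls} controls, "
            f"p {row.p_pointwise:.2g} (corrected {row.p_corrected:.2g})"
        )
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
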