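"""Covariate machinery and logistic model series for ROH burden.

Pieces:

* :func:`ld_prune` — greedy windowed r^2 pruning of the SNP panel
  (PLINK ``--indep-pairwise``-style; defaults 50 SNP window, step 5,
  r^2 <= 0.2).
* :func:`inbreeding_f` — method-of-moments excess-homozygosity
  coefficient per sample, f = (O_hom - E_hom) / (N - E_hom), with the
  small-sample allele-count correction in E_hom (PLINK ``--het``
  convention).  Computed on the LD-pruned subset so that local haplotype
  structure does not masquerade as autozygosity.
* :func:`mds_components` — classical metric scaling of the genome-wide
  1 - IBS-similarity distance matrix; the first two coordinates serve as
  ancestry covariates.
* :func:`fit_logistic` / :func:`run_model_series` — the four cumulative
  logistic models: 1 unadjusted; 2 + f; 3 + f, age; 4 + f, age, C1, C2,
  fit separately for the carrier-indicator (proportion) and count (rate)
  predictors at each minimum-length threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .core import CASE, CONTROL, GenotypeDataset
from .detect import ROHSet

MODEL_COVARIATES = {1: [], 2: ["f"], 3: ["f", "age"], 4: ["f", "age", "C1", "C2"]}


def _dosage(dataset: GenotypeDataset) -> np.ndarray:
    """Minor-allele dosage with missing as NaN."""
    g = dataset.genotypes.astype(float)
    g[g < 0] = np.nan
    return g


def ld_prune(
    dataset: GenotypeDataset,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns indices of retained SNPs.

    Within each sliding window, while any retained pair's genotype
    correlation r^2 exceeds ``r2_max``, the member of the worst pair with
    the lower MAF is dropped (ties: the later map position).  Windows
    advance ``step_snps`` at a time and never cross chromosomes.
    """
    x = _dosage(dataset)
    m = dataset.n_snps
    maf = np.nanmean(x, axis=0) / 2.0
    maf = np.minimum(maf, 1 - maf)
    keep = np.ones(m, dtype=bool)
    chrom = dataset.variant_map["chrom"].to_numpy()
    xc = x - np.nanmean(x, axis=0)
    xc = np.nan_to_num(xc)  # mean-imputed, centred dosages for correlations
    norms = np.sqrt((xc**2).sum(axis=0))
    norms[norms == 0] = np.inf
    for chrom_val in np.unique(chrom):
        cols = np.flatnonzero(chrom == chrom_val)
        for start in range(0, len(cols), step_snps):
            win = cols[start : start + window_snps]
            win = win[keep[win]]
            if len(win) < 2:
                continue
            sub = xc[:, win] / norms[win]
            r2 = (sub.T @ sub) ** 2
            np.fill_diagonal(r2, 0.0)
            while True:
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= r2_max:
                    break
                # drop the lower-MAF member; tie -> later position
                gi, gj = win[i], win[j]
                drop = i if (maf[gi], -gi) < (maf[gj], -gj) else j
                keep[win[drop]] = False
                r2[drop, :] = 0.0
                r2[:, drop] = 0.0
    return np.flatnonzero(keep)


@dataclass
class InbreedingEstimate:
    f: np.ndarray            # per-sample coefficient
    n_snps_used: int


def inbreeding_f(
    dataset: GenotypeDataset,
    snp_subset: np.ndarray | None = None,
    small_sample_correction: bool = True,
) -> InbreedingEstimate:
    """Method-of-moments inbreeding coefficient per sample.

    f_i = (O_i - E_i) / (N_i - E_i) where O_i is the observed homozygous
    count over sample i's non-missing genotypes, N_i that non-missing
    count, and E_i = sum_j (1 - 2 p_j q_j * T_j/(T_j - 1)) over the same
    SNPs, with p_j the panel allele frequency and T_j the non-missing
    allele count at SNP j (the T/(T-1) factor makes 2pq unbiased; disable
    with ``small_sample_correction=False`` for the naive formula).
    """
    g = dataset.genotypes
    if snp_subset is not None:
        g = g[:, snp_subset]
    called = g >= 0
    n_called = called.sum(axis=0)
    ok = n_called > 0
    dose = np.where(called, g, 0)
    q = dose.sum(axis=0) / np.maximum(2.0 * n_called, 1.0)
    p = 1.0 - q
    T = 2.0 * n_called
    if small_sample_correction:
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(T > 1, T / np.maximum(T - 1.0, 1e-12), 1.0)
    else:
        corr = 1.0
    e_j = np.where(ok, 1.0 - 2.0 * p * q * corr, 0.0)
    O = (called & (g != 1)).sum(axis=1).astype(float)
    N = called.sum(axis=1).astype(float)
    E = called @ e_j
    denom = N - E
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("degenerate panel: expected homozygosity equals N")
    return InbreedingEstimate(f=(O - E) / denom, n_snps_used=int(ok.sum()))


@dataclass
class MDSComponents:
    coords: np.ndarray       # (n_samples, k), centred, eigenvalue order
    eigenvalues: np.ndarray


def ibs_distance_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """Pairwise 1 - IBS-similarity.

    IBS similarity of two samples = mean over SNPs non-missing in both of
    (shared alleles)/2, i.e. 1 - |dosage_i - dosage_j| / 2; the distance is
    the complementary mean absolute dosage difference / 2.
    """
    g = dataset.genotypes
    called = (g >= 0)
    x = np.where(called, g, 0).astype(np.float64)
    b = called.astype(np.float64)
    counts = b @ b.T
    if np.any(counts == 0):
        raise ValueError(
            "a sample pair shares no called SNPs; filter missingness first"
        )
    # |a-b| = (a-b)^2 - 2*[unordered pair == (0,2)] for codes in {0,1,2}
    x2 = x**2
    s2 = x2 @ b.T + b @ x2.T - 2.0 * (x @ x.T)
    g0 = (called & (g == 0)).astype(np.float64)
    g2 = (called & (g == 2)).astype(np.float64)
    opp = g0 @ g2.T
    absdiff = s2 - 2.0 * (opp + opp.T)
    return absdiff / (2.0 * counts)


def mds_components(
    dataset: GenotypeDataset, k: int = 2, snp_subset: np.ndarray | None = None
) -> MDSComponents:
    """Classical metric scaling of the IBS distance matrix, top-k axes.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue), centred at 0,
    ordered by decreasing eigenvalue; each axis's sign is fixed by making
    its largest-magnitude loading positive.
    """
    if dataset.n_samples < k + 1:
        raise ValueError("need at least k+1 samples")
    ds = dataset
    if snp_subset is not None:
        ds = GenotypeDataset(
            variant_map=dataset.variant_map.iloc[snp_subset].reset_index(drop=True),
            sample_ids=dataset.sample_ids,
            phenotype=dataset.phenotype,
            genotypes=dataset.genotypes[:, snp_subset],
            allele_a=dataset.allele_a[snp_subset],
            allele_b=dataset.allele_b[snp_subset],
        )
    d = ibs_distance_matrix(ds)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    for c in range(k):
        imax = np.argmax(np.abs(coords[:, c]))
        if coords[imax, c] < 0:
            coords[:, c] = -coords[:, c]
    return MDSComponents(coords=coords, eigenvalues=lam)


@dataclass
class ModelResult:
    model_id: int
    predictor: str           # "proportion" or "rate"
    threshold_mb: float
    coefficient: float
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_wald: float
    n_used: int
    converged: bool = True
    separation: bool = False


def fit_logistic(
    phenotype: np.ndarray,
    predictor: np.ndarray,
    covariates: pd.DataFrame | None = None,
    model_id: int = 1,
    predictor_name: str = "rate",
    threshold_mb: float = 0.0,
) -> ModelResult:
    """Maximum-likelihood logistic fit of phenotype on one predictor plus
    optional covariates; complete cases only.  Quasi-separation or
    non-convergence is flagged rather than silently reported."""
    y = np.asarray(phenotype, dtype=float)
    x = np.asarray(predictor, dtype=float)
    cols = {"predictor": x}
    if covariates is not None:
        for name in covariates.columns:
            cols[name] = covariates[name].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    mask = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[mask], X.loc[mask]
    if X["predictor"].nunique() < 2:
        raise ValueError("constant predictor")
    Xd = sm.add_constant(X, has_constant="add")
    separation = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=100, tol=1e-8)
        converged = bool(res.mle_retvals.get("converged", True))
    except (PerfectSeparationError, PerfectSeparationWarning):
        separation = True
        converged = False
        model = sm.Logit(y, Xd)
        if hasattr(model, "raise_on_perfect_prediction"):
            model.raise_on_perfect_prediction = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(disp=0, maxiter=100, tol=1e-8, warn_convergence=False)
        except np.linalg.LinAlgError:
            res = None
    if res is None:
        # diverged under separation: report the flag, not numbers
        return ModelResult(
            model_id=model_id, predictor=predictor_name, threshold_mb=threshold_mb,
            coefficient=np.nan, odds_ratio=np.nan, ci95_low=np.nan,
            ci95_high=np.nan, p_wald=np.nan, n_used=int(mask.sum()),
            converged=False, separation=True,
        )
    coef = float(res.params["predictor"])
    se = float(res.bse["predictor"])
    return ModelResult(
        model_id=model_id,
        predictor=predictor_name,
        threshold_mb=threshold_mb,
        coefficient=coef,
        odds_ratio=float(np.exp(coef)),
        ci95_low=float(np.exp(coef - 1.96 * se)),
        ci95_high=float(np.exp(coef + 1.96 * se)),
        p_wald=float(res.pvalues["predictor"]),
        n_used=int(mask.sum()),
        converged=converged,
        separation=separation,
    )


def run_model_series(
    rohs: ROHSet,
    covariate_table: pd.DataFrame,
    thresholds: list[float],
    models: tuple[int, ...] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """Fit Models 1-4 for both predictors at each threshold.

    ``covariate_table`` must be indexed like the ROH roster (column
    ``sample_id``) and carry ``f``, ``age``, ``C1``, ``C2`` as needed by the
    requested models.  Returns a tidy frame of :class:`ModelResult` rows
    plus the mean -log10(p) delta between consecutive models in
    ``attrs['mean_log10p_delta']``.
    """
    cov = covariate_table.set_index("sample_id").reindex(rohs.sample_ids)
    pheno = rohs.phenotype
    used = (pheno == CASE) | (pheno == CONTROL)
    results: list[ModelResult] = []
    for t in thresholds:
        counts = rohs.counts_per_sample(t).astype(float)
        predictors = {
            "proportion": (counts > 0).astype(float),
            "rate": counts,
        }
        for pname, pred in predictors.items():
            for mid in models:
                names = MODEL_COVARIATES[mid]
                missing = [nm for nm in names if nm not in cov.columns]
                if missing:
                    raise ValueError(f"model {mid} needs covariates {missing}")
                covs = cov.loc[used, names] if names else None
                try:
                    results.append(
                        fit_logistic(
                            pheno[used], pred[used], covs,
                            model_id=mid, predictor_name=pname, threshold_mb=t,
                        )
                    )
                except ValueError as exc:
                    if "constant predictor" in str(exc):
                        continue  # nothing to model at extreme thresholds
                    raise
    out = pd.DataFrame([vars(r) for r in results])
    deltas = {}
    if len(out):
        bymodel = out.groupby("model_id")["p_wald"].apply(
            lambda p: np.mean(-np.log10(np.clip(p, 1e-300, None)))
        )
        ids = sorted(bymodel.index)
        deltas = {
            (a, b): float(bymodel[b] - bymodel[a]) for a, b in zip(ids[:-1], ids[1:])
        }
    out.attrs["mean_log10p_delta"] = deltas
    return out
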