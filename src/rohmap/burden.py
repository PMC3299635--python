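"""Case-control homozygosity burden statistics.

Two summary measures per minimum-length threshold t:

* proportion — fraction of group members with at least one ROH >= t Mb;
* rate — mean number of ROHs >= t Mb per group member.

Group means are compared with one-tailed two-sample t-tests (alternative:
cases > controls) and with empirical p-values from case/control label
permutation.  The permutation statistic is the difference in group means
(of the carrier indicator for proportion, of the count for rate) and the
empirical p uses the add-one estimator p = (1 + r) / (1 + B) so it is
never zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import CASE, CONTROL
from .detect import ROHSet


def permutation_pvalue(
    statistic_fn,
    labels: np.ndarray,
    n_perm: int,
    seed: int = 0,
    alternative: str = "greater",
) -> float:
    """Generic label-permutation p-value, add-one estimator.

    ``statistic_fn(labels) -> float`` must be exchangeable under the null;
    permutations preserve group sizes (labels are permuted as a vector).
    """
    if alternative != "greater":
        raise ValueError("only the upper-tailed alternative is implemented")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    observed = statistic_fn(labels)
    hits = 0
    for _ in range(n_perm):
        hits += statistic_fn(rng.permutation(labels)) >= observed
    return (1 + hits) / (1 + n_perm)


def _perm_case_masks(n: int, n_case: int, n_perm: int, rng) -> np.ndarray:
    """(n_perm, n) boolean matrix of random case assignments of fixed size."""
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, n_case - 1, axis=1)[:, :n_case]
    masks = np.zeros((n_perm, n), dtype=bool)
    rows = np.repeat(np.arange(n_perm), n_case)
    masks[rows, idx.ravel()] = True
    return masks


def _mean_diff_pvalues(
    values: np.ndarray, is_case: np.ndarray, n_perm: int, rng
) -> float:
    """Vectorised permutation p for the difference in group means."""
    n = len(values)
    n_case = int(is_case.sum())
    observed = values[is_case].mean() - values[~is_case].mean()
    masks = _perm_case_masks(n, n_case, n_perm, rng)
    total = values.sum()
    case_sums = masks @ values
    perm = case_sums / n_case - (total - case_sums) / (n - n_case)
    return (1 + int((perm >= observed - 1e-12).sum())) / (1 + n_perm)


def _ratio(case: float, ctrl: float) -> float:
    if ctrl > 0:
        return case / ctrl
    return np.nan if case == 0 else np.inf


def one_tailed_t(values_cases, values_controls) -> tuple[float, float]:
    """Equal-variance two-sample t, upper-tail p for cases > controls."""
    a = np.asarray(values_cases, dtype=float)
    b = np.asarray(values_controls, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return (np.inf, 0.0) if a.mean() > b.mean() else (-np.inf, 1.0)
    res = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def burden_table(
    rohs: ROHSet,
    thresholds: list[float],
    n_perm: int = 10_000,
    seed: int = 0,
    welch: bool = False,
) -> pd.DataFrame:
    """Burden summary per minimum-length threshold.

    Columns: threshold_mb, proportion/rate per group, case/control ratios,
    one-tailed t p-values and permutation empirical p-values (shared
    permutations across thresholds for determinism and speed).
    """
    pheno = rohs.phenotype
    is_case = pheno == CASE
    is_ctrl = pheno == CONTROL
    if is_case.sum() == 0 or is_ctrl.sum() == 0:
        raise ValueError("both phenotype groups must be non-empty")
    used = is_case | is_ctrl
    rng = np.random.default_rng(seed)
    rows = []
    for t in thresholds:
        counts = rohs.counts_per_sample(t).astype(float)
        carrier = (counts > 0).astype(float)
        c, k = counts[used], carrier[used]
        case_mask = is_case[used]
        prop_case, prop_ctrl = k[case_mask].mean(), k[~case_mask].mean()
        rate_case, rate_ctrl = c[case_mask].mean(), c[~case_mask].mean()
        t_prop, p_t_prop = one_tailed_t(k[case_mask], k[~case_mask])
        t_rate, p_t_rate = one_tailed_t(c[case_mask], c[~case_mask])
        if welch:
            p_t_prop = float(stats.ttest_ind(k[case_mask], k[~case_mask],
                                             equal_var=False, alternative="greater").pvalue)
            p_t_rate = float(stats.ttest_ind(c[case_mask], c[~case_mask],
                                             equal_var=False, alternative="greater").pvalue)
        p_prop = _mean_diff_pvalues(k, case_mask, n_perm, np.random.default_rng(rng.integers(2**31)))
        p_rate = _mean_diff_pvalues(c, case_mask, n_perm, np.random.default_rng(rng.integers(2**31)))
        rows.append(
            {
                "threshold_mb": t,
                "proportion_cases": prop_case,
                "proportion_controls": prop_ctrl,
                "ratio_proportion": _ratio(prop_case, prop_ctrl),
                "rate_cases": rate_case,
                "rate_controls": rate_ctrl,
                "ratio_rate": _ratio(rate_case, rate_ctrl),
                "t_proportion": t_prop,
                "p_t_proportion": p_t_prop,
                "t_rate": t_rate,
                "p_t_rate": p_t_rate,
                "p_proportion": p_prop,
                "p_rate": p_rate,
                "n_perm": n_perm,
            }
        )
    return pd.DataFrame(rows)
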