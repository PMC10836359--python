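"""Univariate and resampling inference used across the analysis.

All Monte-Carlo procedures are seeded and use the +1/+1 p-value
convention (the observed statistic counts as one member of its null
set), which keeps p-values valid under exchangeability.  The
Benjamini-Hochberg adjustment here is the single code path used by every
module that corrects for multiple testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "PermutationTestResult",
    "bh_adjust",
    "subgroup_permutation_test",
    "pairwise_vs_control",
    "kruskal_wallis",
    "contingency_test",
]


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    method: str
    p_bh: float | None = None
    label: str | None = None
    n_permutations: int | None = None
    seed: int | None = None


@dataclass
class PermutationTestResult:
    observed_median_difference: float
    p_one_sided: float
    n_permutations: int
    group_size: int
    seed: int | None
    alternative: str
    null_mode: str


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def subgroup_permutation_test(
    values,
    idx_a,
    idx_b,
    pool=None,
    n_permutations: int = 10000,
    seed: int | None = None,
    alternative: str = "greater",
    null_mode: str = "pool_resample",
) -> PermutationTestResult:
    """Permutation test on the difference in medians between two
    size-k subgroups.

    The observed statistic is ``median(values[idx_b]) -
    median(values[idx_a])``.  Under the default null model
    (``pool_resample``), each permutation sample draws two fresh
    disjoint size-k groups uniformly from the whole cohort pool; with
    ``label_perm`` the permutation shuffles labels within the 2k selected
    individuals only.  With ``alternative="greater"`` the one-sided
    p-value counts null differences at least as large as observed.
    """
    values = pd.Series(values) if not isinstance(values, pd.Series) else values
    idx_a, idx_b = list(idx_a), list(idx_b)
    k = len(idx_a)
    if len(idx_b) != k:
        raise ValueError("idx_a and idx_b must have the same size")
    if set(idx_a) & set(idx_b):
        raise ValueError("idx_a and idx_b must be disjoint")
    if pool is None:
        pool = list(values.index)
    pool = list(pool)
    if len(pool) < 2 * k:
        raise ValueError(
            f"pool of {len(pool)} too small for two disjoint groups of {k}"
        )
    if not (set(idx_a) | set(idx_b)) <= set(pool):
        raise ValueError("pool must contain both subgroups")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if null_mode not in ("pool_resample", "label_perm"):
        raise ValueError(f"unknown null_mode {null_mode!r}")

    observed = float(
        np.median(values.loc[idx_b].values) - np.median(values.loc[idx_a].values)
    )
    rng = np.random.default_rng(seed)
    if null_mode == "pool_resample":
        source = values.loc[pool].values.astype(float)
    else:
        source = values.loc[idx_a + idx_b].values.astype(float)
    m = source.shape[0]

    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(m)
        null[i] = np.median(source[perm[k:2 * k]]) - np.median(source[perm[:k]])

    if alternative == "greater":
        exceed = int(np.sum(null >= observed))
    elif alternative == "less":
        exceed = int(np.sum(null <= observed))
    else:
        exceed = int(np.sum(np.abs(null) >= abs(observed)))
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermutationTestResult(
        observed_median_difference=observed,
        p_one_sided=float(p),
        n_permutations=n_permutations,
        group_size=k,
        seed=seed,
        alternative=alternative,
        null_mode=null_mode,
    )


def pairwise_vs_control(
    values, groups, control_label: str = "control"
) -> list[TestResult]:
    """Two-sided rank-sum test of each non-control group against the
    control group, Benjamini-Hochberg-adjusted across comparisons.

    Groups with fewer than two members are skipped with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} not present")
    control = values[groups == control_label]
    if control.size == 0:
        raise ValueError("control group is empty")
    results: list[TestResult] = []
    for g in [g for g in pd.unique(groups) if g != control_label]:
        sample = values[groups == g]
        if sample.size < 2 or control.size < 2:
            warnings.warn(f"group {g!r} has <2 members; comparison skipped")
            continue
        stat, p = sps.mannwhitneyu(sample, control, alternative="two-sided")
        results.append(
            TestResult(float(stat), float(p), "wilcoxon_rank_sum", label=str(g))
        )
    adj = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_bh = float(a)
    return results


def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square reference)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in uniq]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two samples")
    if np.all(values == values[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis")
    stat, p = sps.kruskal(*samples)
    return TestResult(float(stat), float(p), "kruskal_wallis")


def _log_table_prob(table: np.ndarray) -> float:
    """Log probability of a contingency table under fixed margins
    (multivariate hypergeometric)."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(r + 1).sum()
        + gammaln(c + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def contingency_test(
    table,
    method: str = "fisher_mc",
    n_mc: int = 100000,
    seed: int | None = None,
) -> TestResult:
    """Association test for an r x c contingency table.

    ``fisher_mc`` is a Monte-Carlo exact test: tables are sampled with
    the observed margins fixed (Patefield's algorithm) and the p-value
    is the +1/+1 fraction of sampled tables whose probability does not
    exceed the observed table's.  ``chi2`` is the Pearson statistic with
    its chi-square reference (no continuity correction).  All-zero rows
    and columns are dropped first, so empty categories do not change the
    result.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(table < 0):
        raise ValueError("table entries must be non-negative")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            "table has fewer than two non-empty rows or columns"
        )

    if method == "chi2":
        res = sps.chi2_contingency(table, correction=False)
        return TestResult(float(res.statistic), float(res.pvalue), "chi2")
    if method != "fisher_mc":
        raise ValueError(f"unknown method {method!r}")

    obs_logp = _log_table_prob(table)
    rng = np.random.default_rng(seed)
    dist = sps.random_table(table.sum(axis=1), table.sum(axis=0))
    samples = dist.rvs(n_mc, method="patefield", random_state=rng)
    # Vectorised log-probabilities: only the cell term varies.
    r, c = table.sum(axis=1), table.sum(axis=0)
    const = gammaln(r + 1).sum() + gammaln(c + 1).sum() - gammaln(table.sum() + 1)
    logp = const - gammaln(samples + 1).sum(axis=(1, 2))
    exceed = int(np.sum(logp <= obs_logp + 1e-9))
    p = (1.0 + exceed) / (1.0 + n_mc)
    return TestResult(
        float(obs_logp), float(p), "fisher_mc", n_permutations=n_mc, seed=seed
    )
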