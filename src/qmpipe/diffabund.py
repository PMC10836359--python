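"""Compositional differential abundance between participant groups.

Counts are compositional, so differences are assessed on the centred
log-ratio (CLR) scale, with the technical (sampling) uncertainty of each
sample propagated by Monte-Carlo Dirichlet resampling: for every sample,
``n_mc`` plausible underlying compositions are drawn from
``Dirichlet(counts + prior)``, CLR-transformed, and a nonparametric test
is run per taxon on every instance.  The reported raw p-value is the
expectation over instances, and Benjamini-Hochberg correction is applied
across taxa.  Low-abundance taxa are removed beforehand by a prevalence
filter (present at least ``min_count`` times in at least a
``min_fraction`` share of samples).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "DiffAbundanceResult",
    "prevalence_filter",
    "clr_instances",
    "test_per_taxon",
    "differential_abundance",
]

logger = logging.getLogger(__name__)


@dataclass
class DiffAbundanceResult:
    taxon: str
    effect_size: float
    p_raw: float
    p_bh: float
    n_mc: int
    seed: int | None
    method: str


def prevalence_filter(
    counts: pd.DataFrame, min_count: int = 10, min_fraction: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """Retain taxa observed at least ``min_count`` times in at least
    ``ceil(min_fraction * n)`` samples.

    Returns the filtered matrix and the removed taxa.
    """
    n = counts.shape[1]
    required = max(ceil(min_fraction * n), 1)
    qualifying = (counts >= min_count).sum(axis=1)
    keep = qualifying >= required
    if not keep.any():
        raise ValueError("prevalence filter removed every taxon")
    removed = counts.index[~keep].tolist()
    return counts.loc[keep], removed


def clr_instances(
    counts: pd.DataFrame,
    n_mc: int = 128,
    prior: float = 0.5,
    seed: int | None = None,
) -> np.ndarray:
    """Monte-Carlo CLR instances, shape ``(n_mc, n_taxa, n_samples)``.

    Per sample, ``n_mc`` compositions are drawn from
    ``Dirichlet(counts + prior)`` (the prior removes zeros) and each is
    centred-log-ratio transformed: ``log x - mean(log x)`` over taxa.
    """
    x = counts.values.astype(float) + prior  # (S, n)
    if np.any(x <= 0):
        raise ValueError("counts + prior must be strictly positive")
    rng = np.random.default_rng(seed)
    # Dirichlet via normalised gammas, vectorised over instances/samples.
    g = rng.standard_gamma(x[None, :, :], size=(n_mc, *x.shape))
    g = np.maximum(g, np.finfo(float).tiny)
    comp = g / g.sum(axis=1, keepdims=True)
    logc = np.log(comp)
    return logc - logc.mean(axis=1, keepdims=True)


def _instance_pvalues(clr: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    """Per-taxon, per-instance p-values: rank-sum for two groups,
    Kruskal-Wallis otherwise.  Shape (n_mc, n_taxa)."""
    parts = [clr[:, :, idx] for idx in group_idx]
    if len(parts) == 2:
        res = sps.mannwhitneyu(
            parts[0], parts[1], alternative="two-sided", axis=-1
        )
        p = np.asarray(res.pvalue, dtype=float)
    else:
        res = sps.kruskal(*parts, axis=-1)
        p = np.asarray(res.pvalue, dtype=float)
    # Constant-across-groups taxa yield NaN; by convention p = 1.
    if np.isnan(p).any():
        logger.info("constant CLR vectors encountered; p set to 1")
        p = np.nan_to_num(p, nan=1.0)
    return p


def test_per_taxon(
    clr: np.ndarray,
    taxon_ids,
    groups,
    n_mc: int | None = None,
    seed: int | None = None,
) -> list[DiffAbundanceResult]:
    """Nonparametric group comparison per taxon over CLR instances.

    ``clr`` has shape ``(n_mc, n_taxa, n_samples)``.  ``p_raw`` is the
    mean over instances; BH adjustment is applied across taxa.  For
    two-group designs the effect size is the median over instances of
    the difference in group median CLR (second group minus first, in
    label sort order).
    """
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if clr.shape[2] != groups.shape[0]:
        raise ValueError("group labels do not match sample axis")
    group_idx = [np.flatnonzero(groups == g) for g in labels]

    p = _instance_pvalues(clr, group_idx)  # (n_mc, S)
    p_raw = p.mean(axis=0)
    p_adj = bh_adjust(p_raw)

    if len(labels) == 2:
        med_a = np.median(clr[:, :, group_idx[0]], axis=-1)
        med_b = np.median(clr[:, :, group_idx[1]], axis=-1)
        effect = np.median(med_b - med_a, axis=0)
    else:
        # Spread of group medians as an omnibus effect summary.
        meds = np.stack(
            [np.median(clr[:, :, idx], axis=-1) for idx in group_idx]
        )
        effect = np.median(meds.max(axis=0) - meds.min(axis=0), axis=0)

    n_instances = n_mc if n_mc is not None else clr.shape[0]
    method = "wilcoxon_rank_sum" if len(labels) == 2 else "kruskal_wallis"
    return [
        DiffAbundanceResult(
            taxon=str(t),
            effect_size=float(effect[i]),
            p_raw=float(p_raw[i]),
            p_bh=float(p_adj[i]),
            n_mc=n_instances,
            seed=seed,
            method=method,
        )
        for i, t in enumerate(taxon_ids)
    ]


def differential_abundance(
    counts: pd.DataFrame,
    groups,
    min_count: int = 10,
    min_fraction: float = 0.05,
    n_mc: int = 128,
    prior: float = 0.5,
    seed: int | None = None,
) -> tuple[list[DiffAbundanceResult], list[str]]:
    """Full engine: prevalence filter, Monte-Carlo CLR, per-taxon tests.

    Returns the per-taxon results and the list of filtered-out taxa.
    """
    filtered, removed = prevalence_filter(counts, min_count, min_fraction)
    clr = clr_instances(filtered, n_mc=n_mc, prior=prior, seed=seed)
    results = test_per_taxon(
        clr, filtered.index, groups, n_mc=n_mc, seed=seed
    )
    return results, removed
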