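"""Quantitative microbiome profiling (QMP) matrix construction.

Sequencing counts are compositional: the library size carries no
information about the microbial density of the original sample.  QMP
restores an absolute scale by combining 16S amplicon counts with a
flow-cytometric measurement of the total microbial load (cells per gram
of stool).  The procedure:

1. divide each taxon's counts by its predicted 16S gene copy number,
   giving the copy-number-corrected sequencing depth per sample;
2. define each sample's *sampling depth* ``s_i`` as corrected depth over
   microbial load, and downsize (rarefy) every sample to the common
   minimum ``s*`` so that each sample represents the same fraction of
   its community;
3. exclude samples whose rarefied read count falls below a floor
   (default 150 reads), iterating the minimum until stable;
4. rescale the rarefied counts to cells per gram, so each sample's
   column sum equals its measured load.

Rarefaction is a single seeded multivariate-hypergeometric draw
(sampling reads without replacement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QMPMatrix",
    "copy_number_correct",
    "sampling_depth",
    "rarefy_counts",
    "qmp_transform",
    "to_relative",
    "aggregate",
]


@dataclass
class QMPMatrix:
    """Estimated cells per gram for retained samples.

    ``cells_per_gram`` is taxa x samples; column sums equal the measured
    microbial loads up to the rounding of the rarefaction target.
    """

    cells_per_gram: pd.DataFrame
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    even_sampling_depth: float = float("nan")
    seed: int | None = None


def copy_number_correct(
    counts: pd.DataFrame, copy_numbers: pd.Series
) -> pd.DataFrame:
    """Divide each taxon's counts by its 16S copy number.

    The corrected column sum is the copy-number-corrected sequencing
    depth.  Every taxon must have a copy number >= 1.
    """
    missing = counts.index.difference(copy_numbers.index)
    if len(missing):
        raise ValueError(
            "missing copy numbers for taxa: " + ", ".join(map(str, missing[:10]))
        )
    cn = copy_numbers.loc[counts.index].astype(float)
    if (cn < 1).any():
        bad = cn.index[cn < 1].tolist()
        raise ValueError(f"copy numbers below 1 for taxa: {bad[:10]}")
    return counts.astype(float).div(cn, axis=0)


def sampling_depth(corrected_depth, load):
    """Sampling depth ``s_i``: corrected sequencing depth over microbial load.

    Accepts scalars or aligned array-likes; loads must be strictly
    positive.
    """
    load_arr = np.asarray(load, dtype=float)
    if np.any(load_arr <= 0):
        raise ValueError("microbial loads must be strictly positive")
    return np.asarray(corrected_depth, dtype=float) / load_arr


def rarefy_counts(
    counts: np.ndarray, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Downsample an integer count vector to ``target`` reads without
    replacement (multivariate hypergeometric draw)."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if target > total:
        raise ValueError(f"target {target} exceeds available reads {total}")
    if target == total:
        return counts.copy()
    return rng.multivariate_hypergeometric(counts, target)


_ROUNDERS = {
    "half_even": np.rint,
    "floor": np.floor,
    "ceil": np.ceil,
}


def qmp_transform(
    counts: pd.DataFrame,
    copy_numbers: pd.Series,
    loads: pd.Series,
    min_rarefied_reads: int = 150,
    seed: int | None = None,
    rounding: str = "half_even",
) -> QMPMatrix:
    """Build the QMP matrix (cells per gram) from counts, copy numbers
    and microbial loads.

    The even sampling depth ``s*`` is the minimum ``s_i`` over the
    samples that survive the minimum-rarefied-read filter; exclusion and
    recomputation iterate to a fixed point so that one ultra-shallow
    sample cannot drag ``s*`` below usability.  Each retained sample is
    rarefied to ``T_i = round(s* x L_i)`` reads and rescaled by
    ``L_i / T_i``, so its column sum equals its load.
    """
    if rounding not in _ROUNDERS:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    samples = list(counts.columns)
    if list(loads.index.intersection(counts.columns)) != samples and not set(
        samples
    ).issubset(set(loads.index)):
        missing = set(samples) - set(loads.index)
        raise ValueError(f"loads missing for samples: {sorted(missing)[:10]}")

    corrected = copy_number_correct(counts, copy_numbers)
    corrected_depth = corrected.sum(axis=0)
    load_vec = loads.loc[samples].astype(float)
    s_all = pd.Series(
        sampling_depth(corrected_depth.values, load_vec.values), index=samples
    )

    # Iterate exclusion of samples whose rarefaction target would fall
    # below the floor; s* only grows, so the loop reaches a fixed point.
    # When every retained target violates the floor, the sample with the
    # smallest sampling depth is dragging s* down: exclude it alone and
    # recompute, so one ultra-shallow sample cannot void the whole run.
    retained = list(samples)
    excluded: list[tuple[str, str]] = []
    while True:
        if not retained:
            raise ValueError("all samples excluded by the rarefied-read floor")
        s_star = float(s_all.loc[retained].min())
        targets = np.rint(s_star * load_vec.loc[retained].values).astype(np.int64)
        low = [
            (smp, t) for smp, t in zip(retained, targets)
            if t < min_rarefied_reads
        ]
        if not low:
            break
        if len(low) == len(retained):
            shallowest = s_all.loc[retained].idxmin()
            low = [(smp, t) for smp, t in low if smp == shallowest]
        for smp, t in low:
            excluded.append(
                (smp, f"rarefied depth {t} < {min_rarefied_reads}")
            )
        dropped = {smp for smp, _ in low}
        retained = [smp for smp in retained if smp not in dropped]

    rng = np.random.default_rng(seed)
    rounder = _ROUNDERS[rounding]
    qmp = np.zeros((counts.shape[0], len(retained)))
    for j, smp in enumerate(retained):
        urn = rounder(corrected[smp].values).astype(np.int64)
        urn = np.maximum(urn, 0)
        t_i = int(np.rint(s_star * load_vec[smp]))
        # Per-cell rounding can shave a few reads off the urn total
        # relative to round(corrected depth); clip within that slack.
        if t_i > urn.sum():
            assert t_i - urn.sum() <= len(urn), (
                f"rarefaction target {t_i} exceeds urn {urn.sum()} beyond "
                "rounding slack"
            )
            t_i = int(urn.sum())
        rare = rarefy_counts(urn, t_i, rng)
        qmp[:, j] = rare * (load_vec[smp] / t_i)

    matrix = pd.DataFrame(qmp, index=counts.index, columns=retained)
    return QMPMatrix(
        cells_per_gram=matrix,
        excluded_samples=excluded,
        even_sampling_depth=s_star,
        seed=seed,
    )


def to_relative(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert a count matrix to per-sample proportions (RMP).

    Every column must have a positive sum; each output column sums to 1.
    """
    totals = counts.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(
            "zero or negative column sum for samples: "
            + ", ".join(map(str, zero[:10]))
        )
    return counts.astype(float).div(totals, axis=1)


def aggregate(
    matrix: pd.DataFrame, taxonomy: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Sum rows of a taxon x sample matrix at a higher taxonomic rank.

    ``taxonomy`` is indexed by taxon id with one column per rank; taxa
    with a missing or empty label at the requested rank are pooled into
    ``unclassified_<rank>``.  Row totals per sample are preserved.
    """
    if rank not in taxonomy.columns:
        raise ValueError(f"taxonomy table has no rank column {rank!r}")
    unknown = matrix.index.difference(taxonomy.index)
    if len(unknown):
        raise ValueError(
            "taxa absent from taxonomy: " + ", ".join(map(str, unknown[:10]))
        )
    labels = taxonomy.loc[matrix.index, rank]
    labels = labels.where(
        labels.notna() & (labels.astype(str).str.len() > 0),
        f"unclassified_{rank}",
    ).astype(str)
    out = matrix.groupby(labels, sort=True).sum()
    out.index.name = rank
    return out
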