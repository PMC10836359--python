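"""Community ecology: alpha diversity, Bray-Curtis, PCoA and PERMANOVA.

Distances are computed on taxon x sample matrices (QMP cell counts or
RMP proportions).  PERMANOVA follows the classical pseudo-F
decomposition of the squared dissimilarities with a seeded label
permutation null; the p-value uses the +1/+1 convention (the observed
statistic is a member of its own null set), which keeps the test valid
under exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "PcoaResult",
    "PermanovaResult",
    "shannon",
    "shannon_per_sample",
    "bray_curtis",
    "pcoa",
    "permanova",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match matrix")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix.

    Axes are ordered by decreasing eigenvalue; coordinates are reported
    only for positive-eigenvalue axes.  Negative eigenvalues (possible
    for non-Euclidean dissimilarities such as Bray-Curtis) are reported
    uncorrected.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    sample_ids: list[str]


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    seed: int | None
    ss_between: float
    ss_within: float
    ss_total: float


def shannon(abundances, base: float | None = None) -> float:
    """Shannon diversity index of one abundance vector (nats by default)."""
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def shannon_per_sample(matrix: pd.DataFrame, base: float | None = None) -> pd.Series:
    """Shannon index for every column of a taxon x sample matrix."""
    return pd.Series(
        {smp: shannon(matrix[smp].values, base=base) for smp in matrix.columns},
        name="shannon",
    )


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples (columns).

    ``d_ij = 1 - 2 sum_k min(x_ki, x_kj) / (sum_k x_ki + sum_k x_kj)``.
    Two all-zero samples have an undefined dissimilarity and raise.
    """
    x = matrix.values.T.astype(float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    d = squareform(pdist(x, metric="braycurtis"))
    if np.any(~np.isfinite(d)):
        raise ValueError(
            "Bray-Curtis undefined: at least two all-zero samples present"
        )
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(matrix.columns), d)


def pcoa(dist: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Classical multidimensional scaling (Gower's principal coordinates).

    Double-centres the squared distances, eigendecomposes, and scales
    eigenvectors by the square roots of the positive eigenvalues.
    """
    d2 = dist.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = max(abs(eigvals[0]), 1.0) * 1e-12 if n else 0.0
    n_pos = int(np.sum(eigvals > tol))
    if n_axes is None or n_axes > n_pos:
        n_axes = n_pos
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    pos_sum = eigvals[:n_pos].sum()
    prop = np.where(eigvals > tol, eigvals / pos_sum, 0.0) if pos_sum > 0 else (
        np.zeros_like(eigvals)
    )
    return PcoaResult(
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=prop,
        sample_ids=list(dist.sample_ids),
    )


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Within- and total sums of squares for one labelling.

    ``sum_{i<j in g} d2_ij = z_g' D2 z_g / 2`` with one-hot columns z_g.
    """
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss_within, ss_total


def permanova(
    dist: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor permutational multivariate analysis of variance.

    ``pseudo_F = (SS_between/(g-1)) / (SS_within/(n-g))`` on the squared
    dissimilarities; the p-value counts permuted statistics at least as
    large as the observed one under the +1/+1 convention.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != dist.values.shape[0]:
        raise ValueError("labels length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("PERMANOVA requires at least two groups")
    counts = np.bincount(codes)
    if np.any(counts < 2):
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    d2 = dist.values ** 2
    n = d2.shape[0]
    ss_within, ss_total = _permanova_ss(d2, codes, g)
    ss_between = ss_total - ss_within
    df_between, df_within = g - 1, n - g
    f_obs = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        ssw, _ = _permanova_ss(d2, perm, g)
        ssb = ss_total - ssw
        f_perm = (ssb / df_between) / (ssw / df_within)
        if f_perm >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        p=float(p),
        n_permutations=n_permutations,
        seed=seed,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
    )
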