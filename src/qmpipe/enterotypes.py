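"""Dirichlet-multinomial mixture (DMM) enterotyping.

Gut communities are summarised into a small number of community types
("enterotypes") by fitting a finite mixture of Dirichlet-multinomial
distributions to a genus-level count matrix.  Each component k has a
mixture weight pi_k and a concentration vector alpha_k over genera; a
sample's component membership is its posterior responsibility.  Fitting
is expectation-maximisation with damped fixed-point updates for alpha,
multiple seeded restarts, and Bayesian-information-criterion model
selection over the number of components K.  In this cohort analysis the
selected four components are labelled Bact1, Bact2, Prev and Rum after
their dominant genera.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, psi
from sklearn.cluster import KMeans

__all__ = [
    "DMMModel",
    "EnterotypeAssignment",
    "dm_logpmf",
    "dmm_fit",
    "dmm_select",
    "assign_enterotypes",
    "derive_enterotype_labels",
    "rarefied_genus_richness",
]

logger = logging.getLogger(__name__)

_ALPHA_FLOOR = 1e-8


@dataclass
class DMMModel:
    """Fitted Dirichlet-multinomial mixture."""

    K: int
    weights: np.ndarray  # (K,)
    concentrations: np.ndarray  # (K, S)
    log_likelihood: float
    taxon_ids: list[str]
    sample_ids: list[str]
    responsibilities: np.ndarray  # (n, K)
    n_iter: int
    converged: bool
    seed: int | None = None
    fit_criteria: dict = field(default_factory=dict)

    def bic(self) -> float:
        """BIC with nu = (K-1) + K*S free parameters."""
        n = len(self.sample_ids)
        s = len(self.taxon_ids)
        nu = (self.K - 1) + self.K * s
        return -2.0 * self.log_likelihood + nu * np.log(n)

    def mean_compositions(self) -> np.ndarray:
        """Per-component expected composition (alpha_k normalised)."""
        a = self.concentrations
        return a / a.sum(axis=1, keepdims=True)


@dataclass
class EnterotypeAssignment:
    sample_id: str
    component: int | None
    label: str
    posterior: float


def dm_logpmf(x: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Log density of the Dirichlet-multinomial for count rows ``x``.

    ``x`` is (n, S), ``alpha`` is (S,).  Includes the multinomial
    coefficient, so values are comparable across models.
    """
    x = np.asarray(x, dtype=float)
    n_tot = x.sum(axis=1)
    a_tot = alpha.sum()
    coef = gammaln(n_tot + 1.0) - gammaln(x + 1.0).sum(axis=1)
    return (
        coef
        + gammaln(a_tot)
        - gammaln(n_tot + a_tot)
        + (gammaln(x + alpha) - gammaln(alpha)).sum(axis=1)
    )


def _mixture_loglik(x, log_weights, alphas) -> tuple[float, np.ndarray]:
    """Total log-likelihood and per-sample component log-joint matrix."""
    log_joint = np.column_stack(
        [lw + dm_logpmf(x, a) for lw, a in zip(log_weights, alphas)]
    )
    per_sample = logsumexp(log_joint, axis=1)
    return float(per_sample.sum()), log_joint


def _moment_alpha(x: np.ndarray, weights: np.ndarray, scale: float = 50.0) -> np.ndarray:
    """Moment-matching initial alpha from responsibility-weighted mean
    proportions."""
    props = x / np.maximum(x.sum(axis=1, keepdims=True), 1.0)
    w = weights / max(weights.sum(), 1e-12)
    mean = w @ props
    return np.maximum(scale * mean, 1e-3)


def _alpha_fixed_point(
    x: np.ndarray, resp_k: np.ndarray, alpha: np.ndarray, n_inner: int = 5
) -> np.ndarray:
    """Responsibility-weighted Minka fixed-point update of one
    concentration vector."""
    n_tot = x.sum(axis=1)
    for _ in range(n_inner):
        a_tot = alpha.sum()
        num = resp_k @ (psi(x + alpha) - psi(alpha))
        den = resp_k @ (psi(n_tot + a_tot) - psi(a_tot))
        if den <= 0:
            break
        alpha = np.maximum(alpha * num / den, _ALPHA_FLOOR)
    return alpha


def _fit_once(
    x: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    kmeans_init: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    n, s = x.shape

    if kmeans_init and K > 1:
        logp = np.log(x + 0.5) - np.log(x.sum(axis=1, keepdims=True) + 0.5 * s)
        km = KMeans(
            n_clusters=K, n_init=10,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(logp)
        resp = np.full((n, K), 1e-3)
        resp[np.arange(n), km.labels_] = 1.0
        resp /= resp.sum(axis=1, keepdims=True)
    else:
        resp = rng.dirichlet(np.ones(K), size=n)

    alphas = np.stack([_moment_alpha(x, resp[:, k]) for k in range(K)])
    weights = resp.mean(axis=0)
    loglik, log_joint = _mixture_loglik(x, np.log(weights), alphas)

    history = [loglik]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        resp = np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))

        # Degenerate component: effectively no responsibility mass.
        mass = resp.sum(axis=0)
        for k in np.flatnonzero(mass < 1.0):
            logger.info("re-initialising degenerate component %d", k)
            i = int(rng.integers(0, n))
            alphas[k] = np.maximum(
                50.0 * (x[i] + 0.5) / (x[i] + 0.5).sum(), 1e-3
            )
            resp[:, k] = 1.0 / n
            resp /= resp.sum(axis=1, keepdims=True)
            mass = resp.sum(axis=0)

        # M-step: exact for weights, damped fixed point for alphas.
        weights = np.maximum(mass / n, 1e-12)
        weights /= weights.sum()
        prev_alphas = alphas.copy()
        alphas = np.stack(
            [_alpha_fixed_point(x, resp[:, k], alphas[k]) for k in range(K)]
        )
        new_loglik, log_joint = _mixture_loglik(x, np.log(weights), alphas)
        halvings = 0
        while new_loglik < loglik - 1e-10 and halvings < 10:
            alphas = 0.5 * (alphas + prev_alphas)
            new_loglik, log_joint = _mixture_loglik(x, np.log(weights), alphas)
            halvings += 1
        if new_loglik < loglik - 1e-10:
            alphas = prev_alphas
            new_loglik, log_joint = _mixture_loglik(x, np.log(weights), alphas)

        gain = new_loglik - loglik
        loglik = new_loglik
        history.append(loglik)
        if abs(gain) < tol:
            converged = True
            break

    resp = np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))
    return weights, alphas, resp, loglik, it, converged, history


def dmm_fit(
    genus_counts: pd.DataFrame,
    K: int,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 5,
) -> DMMModel:
    """Fit a K-component Dirichlet-multinomial mixture by EM.

    ``genus_counts`` is genera x samples with integer entries.  The first
    restart is initialised from k-means clusters of the log-proportion
    profiles, the remainder from random responsibilities; the restart
    with the best final log-likelihood is kept.
    """
    x = genus_counts.values.T
    if not np.allclose(x, np.rint(x)) or np.any(x < 0):
        raise ValueError("genus counts must be non-negative integers")
    x = np.rint(x).astype(np.int64).astype(float)
    n = x.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if n <= K:
        raise ValueError(f"need more samples ({n}) than components ({K})")
    if np.any(x.sum(axis=1) <= 0):
        raise ValueError("every sample must have a positive total count")

    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(n_restarts, 1)):
        result = _fit_once(
            x, K, rng, max_iter=max_iter, tol=tol, kmeans_init=(r == 0)
        )
        if best is None or result[3] > best[3]:
            best = result
    weights, alphas, resp, loglik, n_iter, converged, history = best
    model = DMMModel(
        K=K,
        weights=weights,
        concentrations=alphas,
        log_likelihood=loglik,
        taxon_ids=list(genus_counts.index),
        sample_ids=list(genus_counts.columns),
        responsibilities=resp,
        n_iter=n_iter,
        converged=converged,
        seed=seed,
        fit_criteria={"criterion": "bic"},
    )
    model.fit_criteria["bic"] = model.bic()
    model.fit_criteria["loglik_history"] = history
    return model


def dmm_select(
    genus_counts: pd.DataFrame,
    K_range,
    seed: int | None = None,
    **fit_kwargs,
) -> tuple[int, dict[int, DMMModel]]:
    """Fit a DMM for each K and return the BIC-optimal one.

    Failures for individual K are recorded and skipped; at least one K
    must succeed.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    models: dict[int, DMMModel] = {}
    failures: dict[int, str] = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(len(K_range))]
    for K, ks in zip(K_range, child_seeds):
        try:
            models[K] = dmm_fit(genus_counts, K, seed=ks, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal per K
            logger.warning("DMM fit failed for K=%d: %s", K, exc)
            failures[K] = str(exc)
    if not models:
        raise RuntimeError(f"all DMM fits failed: {failures}")
    best_K = min(models, key=lambda k: models[k].bic())
    return best_K, models


def assign_enterotypes(
    model: DMMModel,
    genus_counts: pd.DataFrame,
    label_map: dict[int, str] | None = None,
) -> list[EnterotypeAssignment]:
    """Assign each sample to its maximum-posterior mixture component.

    Samples with a zero total count cannot be assigned and are reported
    with component ``None`` and label ``"unassigned"``.
    """
    missing = genus_counts.index.difference(pd.Index(model.taxon_ids))
    if len(missing):
        raise ValueError(
            "samples contain genera unknown to the model: "
            + ", ".join(map(str, missing[:10]))
        )
    x = (
        genus_counts.reindex(model.taxon_ids)
        .fillna(0.0)
        .values.T.astype(float)
    )
    if label_map is None:
        label_map = {k: f"component_{k}" for k in range(model.K)}
    out: list[EnterotypeAssignment] = []
    totals = x.sum(axis=1)
    valid = totals > 0
    log_joint = np.full((x.shape[0], model.K), -np.inf)
    if valid.any():
        log_joint[valid] = np.column_stack(
            [
                np.log(w) + dm_logpmf(x[valid], a)
                for w, a in zip(model.weights, model.concentrations)
            ]
        )
    for i, smp in enumerate(genus_counts.columns):
        if not valid[i]:
            out.append(EnterotypeAssignment(smp, None, "unassigned", float("nan")))
            continue
        post = np.exp(log_joint[i] - logsumexp(log_joint[i]))
        k = int(np.argmax(post))
        out.append(EnterotypeAssignment(smp, k, label_map[k], float(post[k])))
    return out


def derive_enterotype_labels(
    model: DMMModel, taxonomy: pd.DataFrame | None = None
) -> dict[int, str]:
    """Name components after their dominant genera.

    A *Prevotella*-dominated component becomes ``Prev``; a component
    dominated by Ruminococcaceae genera (requires ``taxonomy`` with a
    ``family`` column) becomes ``Rum``; *Bacteroides*-dominated
    components become ``Bact1``/``Bact2``, the less even (lower total
    concentration) one being Bact2.  Anything else keeps a generic
    ``component_<k>`` name.
    """
    comps = model.mean_compositions()
    taxa = list(model.taxon_ids)
    family = None
    if taxonomy is not None and "family" in taxonomy.columns:
        family = taxonomy["family"].reindex(taxa)

    provisional: dict[int, str] = {}
    bacteroides: list[int] = []
    for k in range(model.K):
        top = taxa[int(np.argmax(comps[k]))]
        if "Prevotella" in top:
            provisional[k] = "Prev"
        elif "Bacteroides" in top:
            bacteroides.append(k)
        elif family is not None and str(family.get(top)) == "Ruminococcaceae":
            provisional[k] = "Rum"
        else:
            provisional[k] = f"component_{k}"
    if len(bacteroides) >= 1:
        # Less concentrated (lower alpha total) = less even = Bact2.
        ordered = sorted(
            bacteroides, key=lambda k: -model.concentrations[k].sum()
        )
        provisional[ordered[0]] = "Bact1"
        for extra, k in enumerate(ordered[1:], start=2):
            provisional[k] = "Bact2" if extra == 2 else f"Bact{extra}"

    # De-duplicate while keeping the first occurrence of each name.
    seen: set[str] = set()
    labels: dict[int, str] = {}
    for k in range(model.K):
        name = provisional[k]
        if name in seen:
            name = f"{name}_component_{k}"
        seen.add(name)
        labels[k] = name
    return labels


def rarefied_genus_richness(
    genus_counts: pd.DataFrame, depth: int = 10000, seed: int | None = None
) -> tuple[pd.Series, list[str]]:
    """Observed genus richness after downsizing each sample to ``depth``
    reads without replacement.

    Samples with fewer than ``depth`` total reads are excluded and
    returned in the second element.
    """
    x = genus_counts.values
    if not np.allclose(x, np.rint(x)) or np.any(x < 0):
        raise ValueError("genus counts must be non-negative integers")
    x = np.rint(x).astype(np.int64)
    rng = np.random.default_rng(seed)
    richness: dict[str, int] = {}
    excluded: list[str] = []
    for j, smp in enumerate(genus_counts.columns):
        total = int(x[:, j].sum())
        if total < depth:
            excluded.append(smp)
            continue
        if total == depth:
            rare = x[:, j]
        else:
            rare = rng.multivariate_hypergeometric(x[:, j], depth)
        richness[smp] = int(np.count_nonzero(rare))
    return pd.Series(richness, dtype=int, name="genus_richness"), excluded
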