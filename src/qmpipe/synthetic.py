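"""Synthetic cohort generator.

The analysis operates on data that combine 16S amplicon counts,
flow-cytometric microbial loads, faecal calprotectin and rich clinical
metadata, none of which are publicly deposited.  This module generates
complete synthetic cohorts with the statistical structure the pipeline
assumes, so every downstream stage is exercisable and testable offline:

* a four-group cohort (control / high genetic risk / autoimmunity /
  symptomatic) whose serology, genotype and symptom fields are drawn so
  that the staging classifier reproduces the intended group for every
  participant (the generator verifies this round trip and fails loudly
  otherwise);
* enterotype-structured compositions: each sample draws a latent
  community type (Bact1 / Bact2 / Prev / Rum) and its genus composition
  from that enterotype's Dirichlet concentration vector, optionally
  perturbed by configured fold-change effects on target taxa;
* ASV-level structure: each genus is split into 1-5 ASVs with fixed
  Dirichlet-split proportions, so ASV-level code paths (QMP, prevalence
  filtering) are exercised;
* per-sample read depths (negative binomial), microbial loads and
  calprotectin (log-normal), and per-ASV 16S copy numbers (uniform).

Everything is driven by a single integer seed; identical configurations
produce bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as qio
from .cohort import GROUPS, ParticipantRecord, classify_participant

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "default_genus_taxonomy",
    "default_enterotype_profiles",
    "simulate_cohort",
    "simulate_reference_panel",
    "write_cohort",
    "read_cohort",
]

ENTEROTYPES = ("Bact1", "Bact2", "Prev", "Rum")

#: Assay upper limits of normal used for the synthetic serology.
ULN = {"acpa": 20.0, "rf": 15.0, "ra33": 20.0}

# Named genera with their families; the remainder of the taxon universe
# is filled with synthetic genera grouped into synthetic families.
_CORE_GENERA = [
    ("Bacteroides", "Bacteroidaceae"),
    ("Prevotella", "Prevotellaceae"),
    ("Paraprevotella", "Prevotellaceae"),
    ("Alloprevotella", "Prevotellaceae"),
    ("Faecalibacterium", "Ruminococcaceae"),
    ("Ruminococcus", "Ruminococcaceae"),
    ("Subdoligranulum", "Ruminococcaceae"),
    ("Gemmiger", "Ruminococcaceae"),
    ("Blautia", "Lachnospiraceae"),
    ("Roseburia", "Lachnospiraceae"),
    ("Dorea", "Lachnospiraceae"),
    ("Coprococcus", "Lachnospiraceae"),
    ("Anaerostipes", "Lachnospiraceae"),
    ("Alistipes", "Rikenellaceae"),
    ("Parabacteroides", "Tannerellaceae"),
    ("Akkermansia", "Akkermansiaceae"),
    ("Bifidobacterium", "Bifidobacteriaceae"),
    ("Collinsella", "Coriobacteriaceae"),
    ("Eggerthella", "Eggerthellaceae"),
    ("Streptococcus", "Streptococcaceae"),
    ("Lactobacillus", "Lactobacillaceae"),
    ("Escherichia", "Enterobacteriaceae"),
    ("Fusobacterium", "Fusobacteriaceae"),
    ("Dialister", "Veillonellaceae"),
    ("Veillonella", "Veillonellaceae"),
    ("Phascolarctobacterium", "Acidaminococcaceae"),
    ("Oscillibacter", "Oscillospiraceae"),
    ("Clostridium", "Clostridiaceae"),
    ("Eubacterium", "Eubacteriaceae"),
    ("Butyricicoccus", "Butyricicoccaceae"),
]

_FAMILY_LINEAGE = {
    "Bacteroidaceae": ("Bacteroidota", "Bacteroidia", "Bacteroidales"),
    "Prevotellaceae": ("Bacteroidota", "Bacteroidia", "Bacteroidales"),
    "Rikenellaceae": ("Bacteroidota", "Bacteroidia", "Bacteroidales"),
    "Tannerellaceae": ("Bacteroidota", "Bacteroidia", "Bacteroidales"),
    "Ruminococcaceae": ("Bacillota", "Clostridia", "Oscillospirales"),
    "Oscillospiraceae": ("Bacillota", "Clostridia", "Oscillospirales"),
    "Butyricicoccaceae": ("Bacillota", "Clostridia", "Oscillospirales"),
    "Lachnospiraceae": ("Bacillota", "Clostridia", "Lachnospirales"),
    "Clostridiaceae": ("Bacillota", "Clostridia", "Clostridiales"),
    "Eubacteriaceae": ("Bacillota", "Clostridia", "Eubacteriales"),
    "Veillonellaceae": ("Bacillota", "Negativicutes", "Veillonellales"),
    "Acidaminococcaceae": ("Bacillota", "Negativicutes", "Acidaminococcales"),
    "Streptococcaceae": ("Bacillota", "Bacilli", "Lactobacillales"),
    "Lactobacillaceae": ("Bacillota", "Bacilli", "Lactobacillales"),
    "Akkermansiaceae": ("Verrucomicrobiota", "Verrucomicrobiae", "Verrucomicrobiales"),
    "Bifidobacteriaceae": ("Actinomycetota", "Actinomycetes", "Bifidobacteriales"),
    "Coriobacteriaceae": ("Actinomycetota", "Coriobacteriia", "Coriobacteriales"),
    "Eggerthellaceae": ("Actinomycetota", "Coriobacteriia", "Eggerthellales"),
    "Enterobacteriaceae": ("Pseudomonadota", "Gammaproteobacteria", "Enterobacterales"),
    "Fusobacteriaceae": ("Fusobacteriota", "Fusobacteriia", "Fusobacteriales"),
}


def default_genus_taxonomy(n_taxa: int = 120) -> pd.DataFrame:
    """Genus-level taxonomy table (index: genus; columns: six ranks)."""
    if n_taxa < len(_CORE_GENERA):
        raise ValueError(f"n_taxa must be >= {len(_CORE_GENERA)}")
    rows = []
    for genus, family in _CORE_GENERA:
        phylum, cls, order = _FAMILY_LINEAGE[family]
        rows.append(("Bacteria", phylum, cls, order, family, genus))
    for i in range(len(_CORE_GENERA), n_taxa):
        family = f"Family_{(i - len(_CORE_GENERA)) // 5 + 1:02d}"
        rows.append(
            ("Bacteria", "Bacillota", "Clostridia", "Lachnospirales",
             family, f"Genus_{i + 1:03d}")
        )
    df = pd.DataFrame(
        rows, columns=["kingdom", "phylum", "class", "order", "family", "genus"]
    )
    return df.set_index(df["genus"].rename("taxon_id"), drop=False)


def default_enterotype_profiles(n_taxa: int = 120) -> dict[str, np.ndarray]:
    """Dirichlet concentration vectors for the four enterotypes.

    Built from a shared power-law baseline with a dominance multiplier
    on each enterotype's hallmark genera and a per-enterotype total
    concentration: Bact2 has the lowest (least even communities), Rum
    the highest.
    """
    taxonomy = default_genus_taxonomy(n_taxa)
    genera = list(taxonomy.index)
    base = (np.arange(n_taxa) + 2.0) ** -1.1
    base /= base.sum()

    def boosted(boosts: dict[str, float], theta: float) -> np.ndarray:
        w = base.copy()
        for j, genus in enumerate(genera):
            fam = taxonomy.iloc[j]["family"]
            for key, mult in boosts.items():
                if genus == key or fam == key:
                    w[j] *= mult
        w /= w.sum()
        return theta * w

    return {
        # Bact1: Bacteroides-led but diverse, Faecalibacterium-rich.
        "Bact1": boosted(
            {"Bacteroides": 30.0, "Faecalibacterium": 10.0,
             "Lachnospiraceae": 3.0}, 220.0,
        ),
        # Bact2: Bacteroides-dominated, low richness/evenness,
        # Faecalibacterium-depleted.
        "Bact2": boosted(
            {"Bacteroides": 120.0, "Faecalibacterium": 0.3}, 60.0,
        ),
        "Prev": boosted({"Prevotella": 70.0, "Prevotellaceae": 8.0}, 170.0),
        "Rum": boosted({"Ruminococcaceae": 15.0, "Akkermansia": 5.0}, 300.0),
    }


@dataclass(frozen=True)
class EffectSpec:
    """A multiplicative fold change on the relative abundance of a
    target taxon set (genus or family names) within one group."""

    taxa: tuple[str, ...]
    group: str
    fold_change: float

    def __post_init__(self):
        if isinstance(self.taxa, str):
            object.__setattr__(self, "taxa", (self.taxa,))
        else:
            object.__setattr__(self, "taxa", tuple(self.taxa))
        if self.fold_change <= 0:
            raise ValueError("fold_change must be strictly positive")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def _default_group_sizes() -> dict[str, int]:
    return {
        "control": 226,
        "high_genetic_risk": 50,
        "autoimmunity": 49,
        "symptomatic": 46,
    }


def _default_mixing() -> dict[str, tuple[float, ...]]:
    # Bact1 / Bact2 / Prev / Rum shares, identical across groups by
    # default: enterotype structure is not a group effect.
    mix = (0.33, 0.24, 0.11, 0.32)
    return {g: mix for g in GROUPS}


def _default_effects() -> tuple[EffectSpec, ...]:
    # Modest Prevotellaceae enrichment in the later preclinical stages;
    # diluted at whole-group scale, mirroring the study design this
    # generator emulates.
    return (
        EffectSpec(("Prevotellaceae",), "autoimmunity", 1.5),
        EffectSpec(("Prevotellaceae",), "symptomatic", 1.5),
    )


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator.

    ``depth_distribution`` is (mean, dispersion) of a negative binomial
    on per-sample read totals; ``load_distribution`` and
    ``calprotectin_distribution`` are (mean, sd) on the natural-log
    scale (defaults: median load 1e11 cells/g, median calprotectin
    30 ug/g).  ``enterotype_mixing`` maps each group to its probability
    vector over (Bact1, Bact2, Prev, Rum).
    """

    group_sizes: dict[str, int] = field(default_factory=_default_group_sizes)
    n_taxa: int = 120
    enterotype_profiles: Optional[dict[str, np.ndarray]] = None
    enterotype_mixing: dict[str, tuple[float, ...]] = field(
        default_factory=_default_mixing
    )
    depth_distribution: tuple[float, float] = (20000.0, 10.0)
    min_depth: int = 2000
    load_distribution: tuple[float, float] = (np.log(1e11), 0.8)
    copy_number_range: tuple[float, float] = (1.0, 12.0)
    effect_spec: Sequence[EffectSpec] = field(default_factory=_default_effects)
    calprotectin_distribution: tuple[float, float] = (np.log(30.0), 1.0)
    calprotectin_group_shift: dict[str, float] = field(default_factory=dict)
    missing_ra33_prob: float = 0.2
    max_asv_per_genus: int = 5
    seed: int = 0

    def resolved_profiles(self) -> dict[str, np.ndarray]:
        if self.enterotype_profiles is not None:
            return {k: np.asarray(v, float) for k, v in self.enterotype_profiles.items()}
        return default_enterotype_profiles(self.n_taxa)

    def validate(self) -> None:
        if set(self.group_sizes) != set(GROUPS):
            raise ValueError(f"group_sizes must cover exactly {GROUPS}")
        if self.group_sizes["control"] <= 0:
            raise ValueError("control group size must be positive (matching needs controls)")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be non-negative")
        profiles = self.resolved_profiles()
        if set(profiles) != set(ENTEROTYPES):
            raise ValueError(f"enterotype profiles must cover {ENTEROTYPES}")
        for name, alpha in profiles.items():
            alpha = np.asarray(alpha, float)
            if alpha.shape != (self.n_taxa,) or np.any(alpha <= 0):
                raise ValueError(f"profile {name!r}: need {self.n_taxa} positive concentrations")
        for g, mix in self.enterotype_mixing.items():
            mix = np.asarray(mix, float)
            if mix.shape != (len(ENTEROTYPES),) or np.any(mix < 0):
                raise ValueError(f"mixing for {g!r} must be 4 non-negative probabilities")
            if abs(mix.sum() - 1.0) > 1e-9:
                raise ValueError(f"mixing for {g!r} must sum to 1")
        if self.depth_distribution[0] <= 0 or self.depth_distribution[1] <= 0:
            raise ValueError("depth distribution parameters must be positive")
        if self.load_distribution[1] <= 0:
            raise ValueError("load log-sd must be positive")
        lo, hi = self.copy_number_range
        if not (1.0 <= lo <= hi):
            raise ValueError("copy_number_range must satisfy 1 <= lo <= hi")
        taxonomy = default_genus_taxonomy(self.n_taxa)
        known = set(taxonomy["genus"]) | set(taxonomy["family"])
        for eff in self.effect_spec:
            unknown = set(eff.taxa) - known
            if unknown:
                raise ValueError(f"effect targets unknown taxa: {sorted(unknown)}")
        if not 0.0 <= self.missing_ra33_prob <= 1.0:
            raise ValueError("missing_ra33_prob must be in [0, 1]")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        profiles = self.resolved_profiles()
        out["enterotype_profiles"] = {
            k: [float(v) for v in vec] for k, vec in profiles.items()
        }
        out["enterotype_mixing"] = {
            g: [float(v) for v in mix] for g, mix in self.enterotype_mixing.items()
        }
        out["effect_spec"] = [
            {"taxa": list(e.taxa), "group": e.group, "fold_change": e.fold_change}
            for e in self.effect_spec
        ]
        out["depth_distribution"] = list(self.depth_distribution)
        out["load_distribution"] = list(self.load_distribution)
        out["copy_number_range"] = list(self.copy_number_range)
        out["calprotectin_distribution"] = list(self.calprotectin_distribution)
        return out


@dataclass
class SyntheticCohort:
    """A fully simulated cohort: metadata, ASV counts, taxonomy, copy
    numbers, loads, calprotectin and the generating truth."""

    participants: list[ParticipantRecord]
    counts: pd.DataFrame  # ASV x sample integer counts
    taxonomy: pd.DataFrame  # per ASV: kingdom..genus
    copy_numbers: pd.Series
    loads: pd.Series
    calprotectin: pd.Series
    truth: dict

    @property
    def sample_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    def genus_counts(self) -> pd.DataFrame:
        from .qmp import aggregate

        return aggregate(self.counts, self.taxonomy, "genus").round().astype(np.int64)


# --------------------------------------------------------------------------
# Clinical metadata generation
# --------------------------------------------------------------------------

_FEMALE_FRACTION = {
    "control": 0.78, "high_genetic_risk": 0.82,
    "autoimmunity": 0.73, "symptomatic": 0.87,
}
_SE_PROBS = {
    "control": (0.53, 0.47, 0.0),
    "high_genetic_risk": (0.0, 0.0, 1.0),
    "autoimmunity": (0.47, 0.39, 0.14),
    "symptomatic": (0.50, 0.41, 0.09),
}


def _negative_titre(rng, uln: float, cap_factor: float) -> float:
    """Log-normal titre around 0.3 x ULN, capped below the category
    boundary (only threshold relationships matter downstream)."""
    t = rng.lognormal(np.log(0.3 * uln), 0.5)
    return min(t, 0.95 * cap_factor * uln)


def _draw_serology(rng, significant: bool, ra33_missing: bool):
    """Titres for one participant.  When ``significant``, at least one
    analyte crosses its clinical-significance threshold."""
    acpa = _negative_titre(rng, ULN["acpa"], 1.0)
    rf = (
        rng.uniform(1.0, 2.9) * ULN["rf"]
        if rng.random() < 0.10
        else _negative_titre(rng, ULN["rf"], 1.0)
    )
    ra33 = None
    if not ra33_missing:
        ra33 = (
            rng.uniform(1.0, 2.9) * ULN["ra33"]
            if rng.random() < 0.15
            else _negative_titre(rng, ULN["ra33"], 1.0)
        )
    if significant:
        acpa_pos = rng.random() < 0.33
        rf_pos = rng.random() < 0.70
        ra33_pos = (not ra33_missing) and rng.random() < 0.08
        if not (acpa_pos or rf_pos or ra33_pos):
            rf_pos = True
        if acpa_pos:
            acpa = rng.uniform(1.0, 10.0) * ULN["acpa"]
        if rf_pos:
            rf = rng.uniform(3.0, 10.0) * ULN["rf"]
        if ra33_pos:
            ra33 = rng.uniform(3.0, 10.0) * ULN["ra33"]
    return acpa, rf, ra33


def _make_csa_items(rng, score: int, n_missing: int):
    """Arrange a CSA score and missing count into seven indicators."""
    idx = rng.permutation(7)
    items: list[Optional[bool]] = [False] * 7
    for i in idx[:n_missing]:
        items[i] = None
    positives = [i for i in idx[n_missing:]][:score]
    for i in positives:
        items[i] = True
    return tuple(items)


def _choice(rng, options, probs):
    return options[rng.choice(len(options), p=np.asarray(probs) / np.sum(probs))]


def _draw_participant(rng, pid: str, group: str, cfg: SimulationConfig) -> ParticipantRecord:
    sex = "female" if rng.random() < _FEMALE_FRACTION[group] else "male"
    age = float(np.clip(rng.normal(53.0, 13.0), 20.0, 85.0))
    bmi = float(np.clip(rng.normal(24.5, 4.0), 16.0, 45.0))
    se = _choice(rng, (0, 1, 2), _SE_PROBS[group])
    ra33_missing = rng.random() < cfg.missing_ra33_prob
    ra_diagnosis = False

    if group == "control":
        significant = False
        n_missing = 1 if rng.random() < 0.04 else 0
        score = _choice(rng, (0, 1, 2, 3), (0.45, 0.32, 0.17, 0.06))
        if n_missing:
            score = min(score, 2)
    elif group == "high_genetic_risk":
        significant = False
        se = 2
        n_missing = 1 if rng.random() < 0.04 else 0
        score = _choice(rng, (0, 1, 2, 3), (0.55, 0.30, 0.12, 0.03))
        if n_missing:
            score = min(score, 2)
    elif group == "autoimmunity":
        significant = True
        n_missing = 1 if rng.random() < 0.05 else 0
        score = _choice(rng, (0, 1, 2), (0.60, 0.25, 0.15))
    else:  # symptomatic
        ra_diagnosis = rng.random() < 8.0 / 46.0
        significant = rng.random() < 0.26
        if ra_diagnosis:
            n_missing = _choice(rng, (0, 1, 2), (0.8, 0.1, 0.1))
            score = _choice(rng, (0, 2, 4, 5), (0.2, 0.2, 0.4, 0.2))
            score = min(score, 7 - n_missing)
        else:
            n_missing = _choice(rng, (0, 1, 2), (0.90, 0.08, 0.02))
            if significant or n_missing > 0:
                score = _choice(rng, (3, 4, 5, 6), (0.45, 0.35, 0.12, 0.08))
            else:
                score = _choice(rng, (4, 5, 6), (0.70, 0.20, 0.10))
            score = min(score, 7 - n_missing)

    acpa, rf, ra33 = _draw_serology(rng, significant, ra33_missing)
    return ParticipantRecord(
        participant_id=pid,
        age=age,
        sex=sex,
        bmi=bmi,
        se_copies=se,
        acpa_titre=acpa,
        acpa_uln=ULN["acpa"],
        rf_titre=rf,
        rf_uln=ULN["rf"],
        ra33_titre=ra33,
        ra33_uln=ULN["ra33"] if ra33 is not None else ULN["ra33"],
        csa_items=_make_csa_items(rng, score, n_missing),
        ra_diagnosis=ra_diagnosis,
    )


# --------------------------------------------------------------------------
# Microbiome generation
# --------------------------------------------------------------------------


def _resolve_effect_targets(
    effects: Sequence[EffectSpec], taxonomy: pd.DataFrame
) -> dict[str, list[tuple[np.ndarray, float]]]:
    """Per group: list of (genus index mask, fold change)."""
    out: dict[str, list[tuple[np.ndarray, float]]] = {g: [] for g in GROUPS}
    genera = taxonomy["genus"].values
    families = taxonomy["family"].values
    for eff in effects:
        mask = np.zeros(len(genera), dtype=bool)
        for name in eff.taxa:
            hit = (genera == name) | (families == name)
            if not hit.any():
                raise ValueError(f"effect target {name!r} not in taxon universe")
            mask |= hit
        out[eff.group].append((mask, eff.fold_change))
    return out


def _apply_effects(rel: np.ndarray, effects: list[tuple[np.ndarray, float]]) -> np.ndarray:
    for mask, fold in effects:
        rel = rel.copy()
        rel[mask] *= fold
        rel /= rel.sum()
    return rel


def _draw_depth(rng, mean: float, dispersion: float, min_depth: int) -> int:
    p = dispersion / (dispersion + mean)
    return int(max(rng.negative_binomial(dispersion, p), min_depth))


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate one complete synthetic cohort.

    The clinical metadata round trip is verified: applying the staging
    classifier to the generated records must recover the intended group
    for every participant, otherwise a ``RuntimeError`` is raised.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genus_tax = default_genus_taxonomy(cfg.n_taxa)
    profiles = cfg.resolved_profiles()
    effect_masks = _resolve_effect_targets(cfg.effect_spec, genus_tax)

    # Participants, in group blocks (order: GROUPS).
    participants: list[ParticipantRecord] = []
    intended: list[str] = []
    counter = 1
    for group in GROUPS:
        for _ in range(cfg.group_sizes[group]):
            pid = f"S{counter:04d}"
            participants.append(_draw_participant(rng, pid, group, cfg))
            intended.append(group)
            counter += 1

    mismatches = [
        (p.participant_id, g, classify_participant(p).group)
        for p, g in zip(participants, intended)
        if classify_participant(p).group != g
    ]
    if mismatches:
        raise RuntimeError(
            f"generator/classifier round-trip failed for {len(mismatches)} "
            f"participants, e.g. {mismatches[:3]}"
        )

    # ASV universe: 1..max_asv ASVs per genus with fixed split weights.
    n_asv_per_genus = rng.integers(1, cfg.max_asv_per_genus + 1, size=cfg.n_taxa)
    asv_ids: list[str] = []
    asv_genus_idx: list[int] = []
    asv_weights: list[float] = []
    asv_counter = 1
    for gi in range(cfg.n_taxa):
        k = int(n_asv_per_genus[gi])
        w = rng.dirichlet(np.full(k, 1.5))
        for j in range(k):
            asv_ids.append(f"ASV_{asv_counter:04d}")
            asv_genus_idx.append(gi)
            asv_weights.append(float(w[j]))
            asv_counter += 1
    asv_genus_idx = np.asarray(asv_genus_idx)
    asv_weights = np.asarray(asv_weights)

    asv_tax = genus_tax.iloc[asv_genus_idx].copy()
    asv_tax.index = pd.Index(asv_ids, name="taxon_id")

    samples = [p.participant_id for p in participants]
    n = len(samples)
    depth_mean, depth_disp = cfg.depth_distribution
    alpha_stack = {e: np.asarray(profiles[e], float) for e in ENTEROTYPES}

    counts = np.zeros((len(asv_ids), n), dtype=np.int64)
    latent: list[str] = []
    for i, group in enumerate(intended):
        mix = np.asarray(cfg.enterotype_mixing[group], float)
        etype = ENTEROTYPES[rng.choice(len(ENTEROTYPES), p=mix / mix.sum())]
        latent.append(etype)
        rel = rng.dirichlet(alpha_stack[etype])
        rel = _apply_effects(rel, effect_masks[group])
        assert abs(rel.sum() - 1.0) < 1e-9
        p_asv = rel[asv_genus_idx] * asv_weights
        p_asv /= p_asv.sum()
        depth = _draw_depth(rng, depth_mean, depth_disp, cfg.min_depth)
        counts[:, i] = rng.multinomial(depth, p_asv)

    loads = pd.Series(
        rng.lognormal(cfg.load_distribution[0], cfg.load_distribution[1], size=n),
        index=samples, name="value",
    )
    cal_shift = np.array(
        [cfg.calprotectin_group_shift.get(g, 1.0) for g in intended]
    )
    calprotectin = pd.Series(
        rng.lognormal(
            cfg.calprotectin_distribution[0],
            cfg.calprotectin_distribution[1],
            size=n,
        ) * cal_shift,
        index=samples, name="value",
    )
    copy_numbers = pd.Series(
        rng.uniform(cfg.copy_number_range[0], cfg.copy_number_range[1],
                    size=len(asv_ids)),
        index=asv_ids, name="copy_number",
    )

    truth = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "intended_groups": dict(zip(samples, intended)),
        "enterotypes": dict(zip(samples, latent)),
        "effects": [
            {"taxa": list(e.taxa), "group": e.group, "fold_change": e.fold_change}
            for e in cfg.effect_spec
        ],
    }
    return SyntheticCohort(
        participants=participants,
        counts=pd.DataFrame(counts, index=asv_tax.index, columns=samples),
        taxonomy=asv_tax,
        copy_numbers=copy_numbers,
        loads=loads,
        calprotectin=calprotectin,
        truth=truth,
    )


def simulate_reference_panel(
    n_samples: int = 1045,
    seed: int = 0,
    n_taxa: int = 120,
    mixing: Sequence[float] = (0.30, 0.25, 0.10, 0.35),
    depth_distribution: tuple[float, float] = (20000.0, 10.0),
    min_depth: int = 10000,
) -> tuple[pd.DataFrame, list[str]]:
    """Genus-level counts for a synthetic enterotype reference panel.

    Emulates the role of a large external reference population in the
    combined enterotyping fit: four well-represented community types at
    fixed mixing proportions.  Returns (genus counts, latent labels).
    """
    rng = np.random.default_rng(seed)
    profiles = default_enterotype_profiles(n_taxa)
    genera = list(default_genus_taxonomy(n_taxa).index)
    mix = np.asarray(mixing, float)
    mix = mix / mix.sum()
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    latent: list[str] = []
    depth_mean, depth_disp = depth_distribution
    for i in range(n_samples):
        etype = ENTEROTYPES[rng.choice(len(ENTEROTYPES), p=mix)]
        latent.append(etype)
        rel = rng.dirichlet(profiles[etype])
        depth = _draw_depth(rng, depth_mean, depth_disp, min_depth)
        counts[:, i] = rng.multinomial(depth, rel)
    df = pd.DataFrame(
        counts, index=pd.Index(genera, name="taxon_id"),
        columns=[f"REF{i + 1:04d}" for i in range(n_samples)],
    )
    return df, latent


# --------------------------------------------------------------------------
# Serialisation
# --------------------------------------------------------------------------

_FILES = (
    "counts.tsv", "taxonomy.tsv", "copy_numbers.tsv",
    "loads.csv", "metadata.csv", "calprotectin.csv", "truth.json",
)


def write_cohort(cohort: SyntheticCohort, directory, overwrite: bool = False) -> list[Path]:
    """Write a cohort to its seven-file plain-text representation.

    Refuses to overwrite existing files unless ``overwrite`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    existing = [f for f in _FILES if (directory / f).exists()]
    if existing and not overwrite:
        raise FileExistsError(
            f"refusing to overwrite {existing} in {directory}; pass overwrite=True"
        )
    qio.write_count_matrix(cohort.counts, directory / "counts.tsv")
    qio.write_taxonomy(cohort.taxonomy, directory / "taxonomy.tsv")
    qio.write_copy_numbers(cohort.copy_numbers, directory / "copy_numbers.tsv")
    qio.write_sample_values(cohort.loads, directory / "loads.csv")
    qio.write_sample_values(cohort.calprotectin, directory / "calprotectin.csv")
    qio.write_metadata(cohort.participants, directory / "metadata.csv")
    with open(directory / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return [directory / f for f in _FILES]


def read_cohort(directory) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    counts = qio.read_count_matrix(directory / "counts.tsv")
    taxonomy = qio.read_taxonomy(directory / "taxonomy.tsv")
    copy_numbers = qio.read_copy_numbers(directory / "copy_numbers.tsv")
    loads = qio.read_sample_values(directory / "loads.csv")
    calprotectin = qio.read_sample_values(directory / "calprotectin.csv")
    participants = qio.read_metadata(directory / "metadata.csv")
    with open(directory / "truth.json", encoding="utf-8") as fh:
        truth = json.load(fh)
    return SyntheticCohort(
        participants=participants,
        counts=counts,
        taxonomy=taxonomy,
        copy_numbers=copy_numbers,
        loads=loads,
        calprotectin=calprotectin,
        truth=truth,
    )
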