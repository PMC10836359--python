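"""Preclinical rheumatoid-arthritis staging of cohort participants.

Participants (first-degree relatives of RA patients, plus untreated
new-onset RA cases) are assigned to one of four mutually exclusive
preclinical stages:

* ``control`` — asymptomatic, no clinically significant autoantibodies;
* ``high_genetic_risk`` — asymptomatic, two copies of the HLA-DRB1
  shared epitope;
* ``autoimmunity`` — asymptomatic but with clinically significant
  RA-associated autoimmunity (ACPA >= ULN, or RF / anti-Ra33 >= 3x ULN);
* ``symptomatic`` — clinically suspect arthralgia (CSA score above
  cutoff) or a diagnosis of untreated new-onset RA.

The rules are applied in strict precedence order (diagnosis, symptoms,
autoimmunity, genotype) so that each participant receives exactly one
stage.  The module also implements the "pronounced phenotype" subgroup
selection with sex- and age-matched controls used in sensitivity
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GROUPS",
    "ParticipantRecord",
    "SerologyCategory",
    "StageAssignment",
    "csa_score",
    "serology_category",
    "classify_participant",
    "classify_cohort",
    "select_pronounced_subgroups",
]

#: Canonical stage labels, ordered from lowest to highest risk.
GROUPS = ("control", "high_genetic_risk", "autoimmunity", "symptomatic")

#: Number of items on the clinically-suspect-arthralgia questionnaire.
N_CSA_ITEMS = 7

#: Multiplier on the ULN above which RF / anti-Ra33 become clinically
#: significant (ACPA is significant from 1x ULN).
HIGH_TITRE_FACTOR = 3.0


@dataclass(frozen=True)
class ParticipantRecord:
    """Serology, genotype, symptom and demographic data for one participant.

    ``csa_items`` holds exactly seven indicators, each ``True`` (positive),
    ``False`` (negative) or ``None`` (missing).  Titres may be ``None``
    when the assay was not run; the paired ULN must be positive whenever
    the titre is present.
    """

    participant_id: str
    age: float
    sex: str  # "female" | "male"
    acpa_titre: Optional[float]
    acpa_uln: Optional[float]
    rf_titre: Optional[float]
    rf_uln: Optional[float]
    ra33_titre: Optional[float]
    ra33_uln: Optional[float]
    csa_items: Sequence[Optional[bool]]
    ra_diagnosis: bool
    se_copies: Optional[int] = None
    bmi: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.csa_items) != N_CSA_ITEMS:
            raise ValueError(
                f"{self.participant_id}: expected {N_CSA_ITEMS} CSA items, "
                f"got {len(self.csa_items)}"
            )
        if self.sex not in ("female", "male"):
            raise ValueError(f"{self.participant_id}: invalid sex {self.sex!r}")
        if self.se_copies is not None and self.se_copies not in (0, 1, 2):
            raise ValueError(
                f"{self.participant_id}: se_copies must be 0, 1 or 2"
            )
        for name in ("acpa", "rf", "ra33"):
            titre = getattr(self, f"{name}_titre")
            uln = getattr(self, f"{name}_uln")
            if titre is not None:
                if titre < 0:
                    raise ValueError(f"{self.participant_id}: negative {name} titre")
                if uln is None or uln <= 0:
                    raise ValueError(
                        f"{self.participant_id}: {name} titre present but ULN "
                        "missing or non-positive"
                    )


@dataclass(frozen=True)
class SerologyCategory:
    """Categorised autoantibody result for one analyte."""

    analyte: str  # "acpa" | "rf" | "ra33"
    category: str  # "negative" | "low" | "high" | "missing"
    clinically_significant: bool


@dataclass
class StageAssignment:
    """Result of the four-group staging algorithm for one participant."""

    participant_id: str
    group: str
    csa_score: Optional[int]
    csa_cutoff_used: str  # "standard" | "lowered" | "not_applicable"
    autoimmunity_flag: bool
    rationale: list[str] = field(default_factory=list)


def csa_score(items: Sequence[Optional[bool]]) -> tuple[int, int]:
    """Count positive clinically-suspect-arthralgia items.

    Returns ``(score, n_missing)`` where the score counts positives among
    the non-missing items.  Requires exactly seven items.
    """
    if len(items) != N_CSA_ITEMS:
        raise ValueError(f"expected {N_CSA_ITEMS} CSA items, got {len(items)}")
    score = sum(1 for it in items if it is True)
    n_missing = sum(1 for it in items if it is None)
    return score, n_missing


def serology_category(
    titre: Optional[float], uln: Optional[float], analyte: str
) -> SerologyCategory:
    """Categorise a titre relative to its upper limit of normal.

    All three analytes share the category boundaries (negative below ULN,
    high at or above 3x ULN, low in between), but clinical significance
    differs: ACPA is significant from the ULN upward, RF and anti-Ra33
    only from 3x ULN.
    """
    if analyte not in ("acpa", "rf", "ra33"):
        raise ValueError(f"unknown analyte {analyte!r}")
    if titre is None:
        return SerologyCategory(analyte, "missing", False)
    if uln is None or uln <= 0:
        raise ValueError(f"{analyte}: ULN must be positive when titre is present")
    if titre < uln:
        category = "negative"
    elif titre >= HIGH_TITRE_FACTOR * uln:
        category = "high"
    else:
        category = "low"
    if analyte == "acpa":
        significant = titre >= uln
    else:
        significant = titre >= HIGH_TITRE_FACTOR * uln
    return SerologyCategory(analyte, category, significant)


def _autoimmunity_flag(record: ParticipantRecord) -> tuple[bool, list[str]]:
    flags = []
    for analyte in ("acpa", "rf", "ra33"):
        cat = serology_category(
            getattr(record, f"{analyte}_titre"),
            getattr(record, f"{analyte}_uln"),
            analyte,
        )
        if cat.clinically_significant:
            flags.append(f"significant_{analyte}")
    return bool(flags), flags


def classify_participant(
    record: ParticipantRecord,
    standard_cutoff: int = 4,
    lowered_cutoff: int = 3,
) -> StageAssignment:
    """Assign one participant to a preclinical RA stage.

    Precedence: (1) an RA diagnosis is symptomatic outright; (2) a CSA
    score at or above the cutoff is symptomatic — the lowered cutoff
    applies when one or two items are missing or when autoimmunity is
    also present; (3) clinically significant autoimmunity; (4) two
    shared-epitope copies; (5) control.  A missing anti-Ra33 titre is
    treated as non-significant, so it can neither trigger nor block any
    rule.  A missing genotype with no other rule fired yields control,
    flagged in the rationale.
    """
    score, n_missing = csa_score(record.csa_items)
    ai_flag, ai_rules = _autoimmunity_flag(record)
    rationale: list[str] = []

    if record.ra33_titre is None:
        rationale.append("ra33_missing_treated_nonsignificant")

    if record.ra_diagnosis:
        rationale.append("ra_diagnosis")
        return StageAssignment(
            record.participant_id, "symptomatic", score, "not_applicable",
            ai_flag, rationale,
        )

    lowered = n_missing in (1, 2) or ai_flag
    cutoff = lowered_cutoff if lowered else standard_cutoff
    if score >= cutoff:
        rationale.append(
            "csa_lowered_cutoff" if lowered else "csa_standard_cutoff"
        )
        return StageAssignment(
            record.participant_id, "symptomatic", score,
            "lowered" if lowered else "standard", ai_flag, rationale,
        )

    if ai_flag:
        rationale.extend(ai_rules)
        return StageAssignment(
            record.participant_id, "autoimmunity", score, "not_applicable",
            True, rationale,
        )

    if record.se_copies == 2:
        rationale.append("two_shared_epitope_copies")
        return StageAssignment(
            record.participant_id, "high_genetic_risk", score,
            "not_applicable", False, rationale,
        )

    if record.se_copies is None:
        rationale.append("se_copies_missing_assumed_control")
    rationale.append("no_rule_fired_control")
    return StageAssignment(
        record.participant_id, "control", score, "not_applicable", False,
        rationale,
    )


def classify_cohort(
    records: Iterable[ParticipantRecord], **kwargs
) -> list[StageAssignment]:
    """Classify every participant; order is preserved."""
    return [classify_participant(r, **kwargs) for r in records]


def _titre_ratio(record: ParticipantRecord) -> float:
    """Scale-free autoimmunity severity: max titre relative to its
    significance threshold (ULN for ACPA, 3x ULN for RF / anti-Ra33)."""
    ratios = [0.0]
    if record.acpa_titre is not None:
        ratios.append(record.acpa_titre / record.acpa_uln)
    if record.rf_titre is not None:
        ratios.append(record.rf_titre / (HIGH_TITRE_FACTOR * record.rf_uln))
    if record.ra33_titre is not None:
        ratios.append(record.ra33_titre / (HIGH_TITRE_FACTOR * record.ra33_uln))
    return max(ratios)


def select_pronounced_subgroups(
    assignments: Sequence[StageAssignment],
    records: Sequence[ParticipantRecord],
    k: int = 20,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Select the ``k`` most pronounced phenotypes per non-control group.

    Ranking within each group: RA diagnosis first, then higher CSA score,
    then higher maximal titre/threshold ratio; ties break on participant
    identifier.  The control subgroup consists of ``k`` controls matched
    greedily to the symptomatic subgroup on exact sex and nearest age
    (ties again on identifier).  ``seed`` is accepted for interface
    symmetry; the procedure is fully deterministic.
    """
    by_id: Mapping[str, ParticipantRecord] = {r.participant_id: r for r in records}
    members: dict[str, list[str]] = {g: [] for g in GROUPS}
    for a in assignments:
        members[a.group].append(a.participant_id)
    score_by_id = {a.participant_id: a.csa_score for a in assignments}

    def sort_key(pid: str):
        rec = by_id[pid]
        score = score_by_id.get(pid)
        return (
            0 if rec.ra_diagnosis else 1,
            -(score if score is not None else -1),
            -_titre_ratio(rec),
            pid,
        )

    out: dict[str, list[str]] = {}
    for group in ("high_genetic_risk", "autoimmunity", "symptomatic"):
        pool = members[group]
        if len(pool) < k:
            raise ValueError(
                f"group {group!r} has {len(pool)} members, need at least {k}"
            )
        out[group] = sorted(pool, key=sort_key)[:k]

    # Controls: greedy nearest-age match within exact sex against the
    # symptomatic subgroup.
    controls = list(members["control"])
    if len(controls) < k:
        raise ValueError(
            f"group 'control' has {len(controls)} members, need at least {k}"
        )
    available = set(controls)
    matched: list[str] = []
    for pid in out["symptomatic"]:
        target = by_id[pid]
        candidates = [
            c for c in available if by_id[c].sex == target.sex
        ]
        if not candidates:
            raise ValueError(
                f"no remaining control of sex {target.sex!r} to match "
                f"participant {pid}"
            )
        best = min(candidates, key=lambda c: (abs(by_id[c].age - target.age), c))
        matched.append(best)
        available.discard(best)
    out["control"] = matched
    return out
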