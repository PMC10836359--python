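"""End-to-end orchestration of the cohort microbiome analysis.

Stages (each independently toggleable, each with its own derived seed):

1. **data** — simulate a synthetic cohort or ingest one from disk;
2. **classification** — four-group preclinical staging;
3. **qmp** — QMP (cells/gram) and RMP (proportions) matrices;
4. **ecology** — Shannon diversity, Bray-Curtis, PCoA, PERMANOVA;
5. **enterotyping** — DMM community typing against a synthetic
   reference panel, enterotype x group contingency test;
6. **differential_abundance** — CLR Monte-Carlo engine at family rank;
7. **subgroups** — pronounced-phenotype selection and the
   median-difference permutation test on Prevotellaceae;
8. **calprotectin** — overall and pairwise-vs-control comparisons.

The report embeds the config hash and every seed, so a rerun with the
same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as qio
from .cohort import GROUPS, classify_cohort, select_pronounced_subgroups
from .diffabund import clr_instances, prevalence_filter, test_per_taxon
from .ecology import bray_curtis, pcoa, permanova, shannon_per_sample
from .enterotypes import (
    assign_enterotypes,
    derive_enterotype_labels,
    dmm_select,
    rarefied_genus_richness,
)
from .qmp import aggregate, qmp_transform, to_relative
from .stats import contingency_test, kruskal_wallis, pairwise_vs_control, subgroup_permutation_test
from .synthetic import SimulationConfig, SyntheticCohort, read_cohort, simulate_cohort, simulate_reference_panel

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = (
    "classification", "qmp", "ecology", "enterotyping",
    "differential_abundance", "subgroups", "calprotectin",
)

# Fixed per-stage seed offsets: stage randomness is reproducible and
# independent of which other stages are enabled.
_SEED_OFFSETS = {
    "simulation": 0, "qmp": 1, "ecology": 2, "enterotyping": 3,
    "differential_abundance": 4, "subgroups": 5, "reference": 6,
    "richness": 7, "contingency": 8,
}

_STAGE_DEPS = {
    "ecology": ("classification", "qmp"),
    "enterotyping": ("classification",),
    "differential_abundance": ("classification",),
    "subgroups": ("classification", "qmp"),
    "calprotectin": ("classification",),
}


class AnalysisReport(dict):
    """The machine-readable result of a pipeline run (a plain mapping)."""


@dataclass
class PipelineConfig:
    """Structured configuration of a full pipeline run."""

    output_dir: str | Path = "qmpipe_output"
    input_dir: str | Path | None = None  # if None, simulate
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    seed: int = 0
    n_permutations: int = 999
    min_rarefied_reads: int = 150
    enterotype_k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    enterotype_rarefy_depth: int = 10000
    dmm_restarts: int = 2
    reference_size: int = 1045
    diff_rank: str = "family"
    n_mc: int = 128
    clr_prior: float = 0.5
    subgroup_k: int = 20
    subgroup_permutations: int = 10000
    fisher_mc: int = 10000
    calprotectin_threshold: float = 100.0

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage, deps in _STAGE_DEPS.items():
            if self.stages.get(stage, False):
                missing = [d for d in deps if not self.stages.get(d, False)]
                if missing:
                    raise ValueError(
                        f"stage {stage!r} requires disabled stage(s) {missing}"
                    )
        if self.input_dir is None:
            self.simulation.validate()

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + _SEED_OFFSETS[stage]) % (2**31 - 1)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["output_dir"] = str(self.output_dir)
        out["input_dir"] = None if self.input_dir is None else str(self.input_dir)
        out["simulation"] = self.simulation.to_dict()
        out["enterotype_k_range"] = list(self.enterotype_k_range)
        return out

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {
            f.name for f in dataclasses.fields(cls)
        }})
        if sim_raw:
            from .synthetic import EffectSpec

            effects = sim_raw.pop("effect_spec", None)
            sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim = SimulationConfig(
                **{k: v for k, v in sim_raw.items() if k in sim_fields}
            )
            if effects is not None:
                sim.effect_spec = tuple(
                    EffectSpec(tuple(e["taxa"]), e["group"], float(e["fold_change"]))
                    for e in effects
                )
            cfg.simulation = sim
        if "enterotype_k_range" in raw:
            cfg.enterotype_k_range = tuple(raw["enterotype_k_range"])
        return cfg


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for deterministic JSON."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _group_summary(values: pd.Series, groups: pd.Series) -> dict:
    out = {}
    for g in GROUPS:
        v = values[groups[values.index] == g]
        if len(v) == 0:
            continue
        out[g] = {
            "n": int(len(v)),
            "median": float(np.median(v)),
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        }
    return out


def _family_row(matrix: pd.DataFrame, taxonomy: pd.DataFrame, family: str) -> pd.Series:
    fam = aggregate(matrix, taxonomy, "family")
    if family in fam.index:
        return fam.loc[family]
    return pd.Series(0.0, index=matrix.columns)


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute all enabled stages in dependency order.

    Writes ``report.json`` plus per-stage CSV/TSV artifacts into the
    output directory; a stage failure aborts with the failing stage
    named, leaving earlier outputs and a manifest behind.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    report = AnalysisReport()
    report["versions"] = {"qmpipe": __version__}
    report["seed"] = int(config.seed)
    # The output location is not part of the analytic configuration:
    # runs into different directories must hash identically.
    cfg_dict = config.to_dict()
    cfg_dict.pop("output_dir", None)
    cfg_json = json.dumps(_jsonable(cfg_dict), sort_keys=True)
    report["config_hash"] = hashlib.sha256(cfg_json.encode()).hexdigest()
    report["config"] = json.loads(cfg_json)

    def _finish_stage(name: str) -> None:
        manifest.append(name)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump({"completed_stages": manifest}, fh, indent=1)

    def _run(name: str, fn):
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        _finish_stage(name)

    # ---------------------------------------------------------------- data
    state: dict = {}

    def _data():
        if config.input_dir is not None:
            cohort = read_cohort(config.input_dir)
        else:
            sim = dataclasses.replace(
                config.simulation, seed=config.stage_seed("simulation")
            )
            cohort = simulate_cohort(sim)
        state["cohort"] = cohort
        logger.info("data: %d samples, %d taxa",
                    cohort.counts.shape[1], cohort.counts.shape[0])

    _run("data", _data)
    cohort: SyntheticCohort = state["cohort"]
    samples = cohort.sample_ids
    report["n_samples"] = len(samples)

    # ------------------------------------------------------ classification
    groups = None
    if config.stages.get("classification", False):
        def _classify():
            assignments = classify_cohort(cohort.participants)
            df = pd.DataFrame(
                {
                    "participant_id": [a.participant_id for a in assignments],
                    "group": [a.group for a in assignments],
                    "csa_score": [a.csa_score for a in assignments],
                    "csa_cutoff_used": [a.csa_cutoff_used for a in assignments],
                    "autoimmunity_flag": [a.autoimmunity_flag for a in assignments],
                    "rationale": [";".join(a.rationale) for a in assignments],
                }
            )
            df.to_csv(outdir / "assignments.csv", index=False)
            state["assignments"] = assignments
            state["groups"] = pd.Series(
                df["group"].values, index=df["participant_id"].values
            )
            report["group_sizes"] = {
                g: int((df["group"] == g).sum()) for g in GROUPS
            }

        _run("classification", _classify)
        groups = state["groups"]

    # ----------------------------------------------------------------- qmp
    if config.stages.get("qmp", False):
        def _qmp():
            qmp = qmp_transform(
                cohort.counts, cohort.copy_numbers, cohort.loads,
                min_rarefied_reads=config.min_rarefied_reads,
                seed=config.stage_seed("qmp"),
            )
            rmp = to_relative(cohort.counts)
            qmp.cells_per_gram.rename_axis("taxon_id").to_csv(
                outdir / "qmp.tsv", sep="\t"
            )
            rmp.rename_axis("taxon_id").to_csv(outdir / "rmp.tsv", sep="\t")
            pd.DataFrame(
                qmp.excluded_samples, columns=["sample_id", "reason"]
            ).to_csv(outdir / "excluded.csv", index=False)
            state["qmp"] = qmp
            state["rmp"] = rmp
            report["qmp"] = {
                "even_sampling_depth": float(qmp.even_sampling_depth),
                "n_retained": int(qmp.cells_per_gram.shape[1]),
                "excluded_samples": [list(e) for e in qmp.excluded_samples],
                "seed": config.stage_seed("qmp"),
            }
            logger.info("qmp: retained %d samples, excluded %d",
                        qmp.cells_per_gram.shape[1], len(qmp.excluded_samples))

        _run("qmp", _qmp)

    # ------------------------------------------------------------- ecology
    if config.stages.get("ecology", False):
        def _ecology():
            qmp = state["qmp"]
            rmp = state["rmp"]
            sh = shannon_per_sample(cohort.counts)
            sh.to_csv(outdir / "shannon.csv", header=True)
            eco = {
                "shannon_by_group": _group_summary(sh, groups),
                "shannon_kruskal": dataclasses.asdict(
                    kruskal_wallis(sh.values, groups[sh.index].values)
                ),
            }
            seed = config.stage_seed("ecology")
            results = {}
            for name, matrix in (("qmp", qmp.cells_per_gram), ("rmp", rmp)):
                labels = groups[matrix.columns].values
                dist = bray_curtis(matrix)
                res = permanova(
                    dist, labels, n_permutations=config.n_permutations,
                    seed=seed,
                )
                ord_res = pcoa(dist, n_axes=2)
                coords = pd.DataFrame(
                    ord_res.coordinates,
                    index=dist.sample_ids,
                    columns=[f"PCo{i+1}" for i in range(ord_res.coordinates.shape[1])],
                )
                coords.to_csv(outdir / f"pcoa_{name}.csv")
                results[name] = {
                    "permanova": dataclasses.asdict(res),
                    "pcoa_proportion_explained": [
                        float(p) for p in ord_res.proportion_explained[:5]
                    ],
                }
            eco["beta_diversity"] = results
            report["ecology"] = eco

        _run("ecology", _ecology)

    # -------------------------------------------------------- enterotyping
    if config.stages.get("enterotyping", False):
        def _enterotyping():
            genus = cohort.genus_counts()
            richness, rich_excluded = rarefied_genus_richness(
                genus, depth=config.enterotype_rarefy_depth,
                seed=config.stage_seed("richness"),
            )
            # Rarefy cohort genus matrix for the DMM fit; shallow samples
            # stay unassigned (they are excluded from the fit).
            rng = np.random.default_rng(config.stage_seed("enterotyping"))
            deep = [
                s for s in genus.columns
                if genus[s].sum() >= config.enterotype_rarefy_depth
            ]
            rarefied = pd.DataFrame(
                {
                    s: rng.multivariate_hypergeometric(
                        genus[s].values.astype(np.int64),
                        config.enterotype_rarefy_depth,
                    )
                    for s in deep
                },
                index=genus.index,
            )
            reference, _ = simulate_reference_panel(
                n_samples=config.reference_size,
                seed=config.stage_seed("reference"),
                n_taxa=len(genus.index),
            )
            ref_rarefied = pd.DataFrame(
                {
                    s: rng.multivariate_hypergeometric(
                        reference[s].values.astype(np.int64),
                        config.enterotype_rarefy_depth,
                    )
                    for s in reference.columns
                },
                index=reference.index,
            )
            combined = pd.concat([rarefied, ref_rarefied], axis=1).fillna(0)
            combined = combined.round().astype(np.int64)
            best_k, models = dmm_select(
                combined, config.enterotype_k_range,
                seed=config.stage_seed("enterotyping"),
                n_restarts=config.dmm_restarts,
                tol=1e-4,
            )
            model = models[best_k]
            genus_tax = (
                cohort.taxonomy.drop_duplicates("genus").set_index("genus")
            )
            label_map = derive_enterotype_labels(model, genus_tax)
            assignments = assign_enterotypes(
                model, genus.loc[:, genus.columns], label_map
            )
            # Shallow samples were not rarefied: mark unassigned.
            deep_set = set(deep)
            for a in assignments:
                if a.sample_id not in deep_set:
                    a.component, a.label = None, "unassigned"
                    a.posterior = float("nan")
            ent = pd.Series(
                {a.sample_id: a.label for a in assignments}, name="enterotype"
            )
            ent.rename_axis("sample_id").to_csv(outdir / "enterotypes.csv", header=True)
            assigned = ent[ent != "unassigned"]
            table = pd.crosstab(
                assigned.values, groups[assigned.index].values
            )
            ct = contingency_test(
                table.values, method="fisher_mc", n_mc=config.fisher_mc,
                seed=config.stage_seed("contingency"),
            )
            report["enterotyping"] = {
                "best_K": int(best_k),
                "bic_by_K": {str(k): float(m.bic()) for k, m in models.items()},
                "labels": {str(k): v for k, v in label_map.items()},
                "n_unassigned": int((ent == "unassigned").sum()),
                "contingency_table": {
                    "rows": list(map(str, table.index)),
                    "cols": list(map(str, table.columns)),
                    "counts": table.values.tolist(),
                },
                "fisher_mc": dataclasses.asdict(ct),
                "genus_richness_by_group": _group_summary(
                    richness.astype(float), groups
                ),
                "richness_excluded": rich_excluded,
                "seed": config.stage_seed("enterotyping"),
            }
            state["enterotypes"] = ent

        _run("enterotyping", _enterotyping)

    # -------------------------------------------- differential abundance
    if config.stages.get("differential_abundance", False):
        def _diffabund():
            filtered, removed = prevalence_filter(cohort.counts)
            fam = aggregate(filtered, cohort.taxonomy, config.diff_rank)
            fam = fam.round().astype(np.int64)
            seed = config.stage_seed("differential_abundance")
            clr = clr_instances(
                fam, n_mc=config.n_mc, prior=config.clr_prior, seed=seed
            )
            results = test_per_taxon(
                clr, fam.index, groups[fam.columns].values,
                n_mc=config.n_mc, seed=seed,
            )
            df = pd.DataFrame([dataclasses.asdict(r) for r in results])
            df.to_csv(outdir / "differential_abundance.csv", index=False)
            report["differential_abundance"] = {
                "rank": config.diff_rank,
                "n_taxa_tested": int(len(results)),
                "n_asvs_removed_by_prevalence": int(len(removed)),
                "n_significant_bh_0.05": int((df["p_bh"] < 0.05).sum()),
                "top": df.nsmallest(5, "p_bh")[
                    ["taxon", "effect_size", "p_raw", "p_bh"]
                ].to_dict("records"),
                "seed": seed,
            }

        _run("differential_abundance", _diffabund)

    # ----------------------------------------------------------- subgroups
    if config.stages.get("subgroups", False):
        def _subgroups():
            sub = select_pronounced_subgroups(
                state["assignments"], cohort.participants,
                k=config.subgroup_k, seed=config.stage_seed("subgroups"),
            )
            rows = [
                {"group": g, "participant_id": pid}
                for g in sub for pid in sub[g]
            ]
            pd.DataFrame(rows).to_csv(outdir / "subgroups.csv", index=False)
            qmp = state["qmp"]
            prev_qmp = _family_row(
                qmp.cells_per_gram, cohort.taxonomy, "Prevotellaceae"
            )
            prev_rmp = _family_row(state["rmp"], cohort.taxonomy, "Prevotellaceae")
            seed = config.stage_seed("subgroups")
            tests = {}
            for contrast in ("autoimmunity", "symptomatic"):
                for name, values in (("qmp", prev_qmp), ("rmp", prev_rmp)):
                    avail = set(values.index)
                    idx_a = [s for s in sub["control"] if s in avail]
                    idx_b = [s for s in sub[contrast] if s in avail]
                    k = min(len(idx_a), len(idx_b))
                    res = subgroup_permutation_test(
                        values, idx_a[:k], idx_b[:k],
                        pool=list(values.index),
                        n_permutations=config.subgroup_permutations,
                        seed=seed,
                    )
                    tests[f"{contrast}_{name}"] = dataclasses.asdict(res)
            report["subgroups"] = {
                "k": config.subgroup_k,
                "members": sub,
                "prevotellaceae_permutation": tests,
                "seed": seed,
            }
            # Whole-cohort Prevotellaceae group comparisons.
            report["prevotellaceae"] = {
                "rmp_by_group": _group_summary(prev_rmp, groups),
                "rmp_kruskal": dataclasses.asdict(
                    kruskal_wallis(prev_rmp.values, groups[prev_rmp.index].values)
                ),
                "qmp_kruskal": dataclasses.asdict(
                    kruskal_wallis(prev_qmp.values, groups[prev_qmp.index].values)
                ),
            }

        _run("subgroups", _subgroups)

    # -------------------------------------------------------- calprotectin
    if config.stages.get("calprotectin", False):
        def _calprotectin():
            cal = cohort.calprotectin
            labels = groups[cal.index].values
            pairwise = pairwise_vs_control(cal.values, labels)
            report["calprotectin"] = {
                "by_group": _group_summary(cal, groups),
                "kruskal": dataclasses.asdict(kruskal_wallis(cal.values, labels)),
                "pairwise_vs_control": [dataclasses.asdict(r) for r in pairwise],
                "elevated_fraction": float(
                    (cal > config.calprotectin_threshold).mean()
                ),
            }

        _run("calprotectin", _calprotectin)

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=1, sort_keys=True)
    return report
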