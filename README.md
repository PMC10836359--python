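# qmpipe

Quantitative microbiome profiling (QMP) analysis for preclinical
rheumatoid-arthritis (RA) cohort studies.

## The problem

First-degree relatives of RA patients pass through *preclinical* disease
stages — genetic risk, asymptomatic autoimmunity, clinically suspect
arthralgia — before (possibly) developing RA, and gut microbes such as
*Prevotellaceae* have been proposed as markers of that transition.
Standard 16S sequencing yields only relative abundances (RMP); QMP
combines sequencing counts with a flow-cytometric measurement of total
microbial load to express every taxon as estimated **cells per gram of
stool**, removing the compositional distortion of library size.

`qmpipe` implements the full analytic path for such a study, from an
ASV count table plus clinical metadata to group-level inference, and
ships a synthetic cohort generator so that everything runs end to end
with no external data.

## What is inside

| Stage | Method |
|---|---|
| Staging | Four-group classifier (control / high genetic risk / autoimmunity / symptomatic) from serology (ACPA ≥ ULN, RF and anti-Ra33 ≥ 3×ULN), shared-epitope genotype, the 7-item CSA score (cutoff ≥4, lowered to ≥3 with 1–2 missing items or concomitant autoimmunity) and RA diagnosis |
| QMP | 16S copy-number correction, rarefaction of every sample to the even sampling depth `s* = min_i(corrected depth_i / load_i)`, exclusion of samples whose rarefied count falls below 150 reads, rescaling so column sums equal loads |
| Ecology | Shannon index, Bray–Curtis dissimilarity, principal coordinates (Gower double-centering), one-factor PERMANOVA with pseudo-F `= (SS_B/(g−1))/(SS_W/(n−g))` and a seeded +1/+1 permutation p |
| Enterotyping | Dirichlet-multinomial mixture fitted by damped EM, BIC model selection over K, components named Bact1 / Bact2 / Prev / Rum, fitted jointly with a synthetic reference panel |
| Differential abundance | Prevalence filter (≥10 counts in ≥5% of samples), Monte-Carlo Dirichlet instances, centred log-ratio transform, per-instance Kruskal–Wallis / rank-sum tests, expected p with Benjamini–Hochberg correction |
| Subgroup inference | The 20 most pronounced phenotypes per group with sex/age-matched controls, and a 10 000-draw permutation test on the difference in median *Prevotellaceae* abundance |

## Worked example

```python
from qmpipe import SimulationConfig, simulate_cohort, classify_cohort
from qmpipe import qmp_transform, bray_curtis, permanova

cohort = simulate_cohort(SimulationConfig(seed=1))
groups = [cohort.truth["intended_groups"][s] for s in cohort.sample_ids]

qmp = qmp_transform(cohort.counts, cohort.copy_numbers, cohort.loads, seed=2)
labels = [cohort.truth["intended_groups"][s] for s in qmp.cells_per_gram.columns]
res = permanova(bray_curtis(qmp.cells_per_gram), labels,
                n_permutations=999, seed=3)
print(f"retained {qmp.cells_per_gram.shape[1]} of {len(groups)} samples")
print(f"PERMANOVA R2={res.R2:.5f}, p={res.p:.3f}")
```

prints

```
retained 279 of 371 samples
PERMANOVA R2=0.00922, p=0.565
```

i.e. on the default synthetic cohort (371 participants, a diluted 1.5×
*Prevotellaceae* enrichment in the two later stages) the preclinical
grouping explains under one percent of the between-sample Bray–Curtis
variance and is indistinguishable from label noise — the expected
behaviour for a whole-cohort analysis of a weak, subgroup-concentrated
effect.

The same analysis is available from the shell:

```bash
qmpipe simulate --seed 1 --out cohort/
qmpipe run --seed 1 --out results/
```

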