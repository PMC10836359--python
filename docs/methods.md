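# Methods

This note documents the models, algorithms, defaults and numerical
choices implemented in `qmpipe`, and what the synthetic data can and
cannot show about real cohorts.

## Preclinical staging

Participants are staged by rules applied in strict precedence:

1. an RA diagnosis → *symptomatic*;
2. clinically suspect arthralgia: CSA score (count of positive items
   among the seven, missing items not counted) at or above the cutoff →
   *symptomatic*.  The standard cutoff is 4; it is lowered to 3 when one
   or two items are missing or when clinically significant autoimmunity
   is also present.  Both cutoffs are configurable; ≥3 was adopted for
   the lowered rule as the operational reading of "more than 3 with
   missing data", and the alternative strict reading (>3) is available
   through the `lowered_cutoff` knob;
3. clinically significant autoimmunity — ACPA ≥ 1× its upper limit of
   normal (ULN), or RF or anti-Ra33 ≥ 3× ULN → *autoimmunity*;
4. two shared-epitope copies → *high_genetic_risk*;
5. otherwise *control*.

A missing anti-Ra33 titre is treated as non-significant: it can neither
trigger nor veto any rule (the package does not impute from earlier
sera).  A missing genotype with no earlier rule fired yields *control*
and is flagged in the rule trace, so missingness cannot abort a cohort
run.  Every assignment carries an ordered list of the rules that fired.

**Pronounced subgroups.**  For sensitivity analyses the k (default 20)
most pronounced phenotypes per non-control group are selected by
ranking on (RA diagnosis, CSA score, maximal titre/threshold ratio),
where the ratio divides ACPA by 1× ULN and RF/anti-Ra33 by 3× ULN so
that "clinical significance" is scale-free across analytes.  The
composite is a package choice (no canonical definition exists) and is
deterministic, with ties broken on participant identifier.  Controls
are matched to the symptomatic subgroup by exact sex and greedy
nearest age; optimal (global) matching is out of scope.

## QMP construction

With counts `x_ji`, copy numbers `c_j`, loads `L_i`:

* corrected counts `y_ji = x_ji / c_j`; corrected depth `d_i = Σ_j y_ji`;
* sampling depth `s_i = d_i / L_i` (fraction of the community the
  library represents);
* even depth `s* = min_i s_i` over retained samples; per-sample target
  `T_i = round(s* · L_i)`;
* rarefaction of the rounded corrected counts to `T_i` reads by a
  single seeded multivariate-hypergeometric draw (no averaging over
  repeated rarefactions);
* `cells_per_gram_ji = rarefied_ji · L_i / T_i`, so each column sums to
  `L_i` exactly up to the rounding of `T_i` (conservation within 0.5%).

**Exclusion rule.**  Samples whose target `T_i` falls below the minimum
rarefied read count (default 150) are excluded and `s*` recomputed,
iterating to a fixed point.  One amendment to the naive sweep: if *every*
retained target violates the floor, the sample with the smallest `s_i`
(the one dragging `s*` down) is dropped alone and the loop continues —
otherwise a single ultra-shallow sample would exclude the entire cohort.

Corrected counts are real-valued; they are rounded half-to-even
immediately before rarefaction (the urn needs integers; mode
configurable).  Because per-cell rounding can shave a few reads off the
urn relative to `round(d_i)`, the target is clipped to the urn total
when the discrepancy is within that rounding slack.

## Ecology

* Shannon index in nats (base configurable).
* Bray–Curtis `d_ij = 1 − 2Σ min(x_ki, x_kj) / (Σx_ki + Σx_kj)`,
  computed on QMP cells/gram (primary) and RMP proportions (secondary).
* PCoA by Gower double-centering `B = −½ J D² J` and
  eigendecomposition; coordinates are reported only on
  positive-eigenvalue axes, negative eigenvalues are reported
  uncorrected (no Lingoes/Cailliez), and proportions explained are
  relative to the positive-eigenvalue total.
* PERMANOVA: `SS_total = Σ_{i<j} d²_ij / n`,
  `SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g`, pseudo-F as usual; the
  permutation p uses the +1/+1 convention (the observed statistic is a
  member of its own null set), which guarantees validity under
  exchangeability.  Only the one-factor design is implemented.  The
  default permutation count (999) is recorded in the output.

## Dirichlet-multinomial mixture enterotyping

Counts for sample i given component k are Dirichlet-multinomial with
concentration vector `α_k`; the mixture has weights `π_k`.  Fitting is
EM:

* E-step: responsibilities from component DM log-densities (log-gamma
  form, multinomial coefficient included so likelihoods are comparable
  across K);
* M-step: exact weight update; `α_k` by responsibility-weighted
  fixed-point iteration (5 inner steps), with step-halving toward the
  previous iterate whenever the observed log-likelihood would decrease,
  keeping EM monotone (asserted in tests within 1e-8);
* components that lose essentially all responsibility mass (<1 sample)
  are re-seeded from a random sample's profile;
* initialisation: the first restart clusters log-proportion profiles by
  k-means (10 initialisations) and moment-matches `α_k` within
  clusters; additional restarts use random responsibilities.  The best
  final likelihood wins.

Model selection minimises `BIC = −2 logL + ν ln n` with
`ν = (K−1) + K·S` (S genera).  BIC was chosen for transparency over the
Laplace approximation used by some DMM software; the criterion is
pluggable.  Genus matrices are rarefied to 10 000 reads before fitting
(mirroring the richness preprocessing); the DM likelihood needs counts,
so rarefied counts stand in where a proportions matrix is described —
an intentional, documented substitution.  Samples below the rarefaction
depth stay unassigned and are reported.

Component naming is a top-genus heuristic: *Prevotella*-dominated →
Prev; Ruminococcaceae-dominated → Rum; *Bacteroides*-dominated
components → Bact1/Bact2, with the lower total concentration (less
even) one as Bact2.  The cohort is fitted jointly with a synthetic
four-enterotype reference panel (default 1 045 samples) that plays the
role of a large external reference population.

## Differential abundance

Taxa are prevalence-filtered (count ≥10 in ≥ `ceil(0.05·n)` samples) at
the ASV level, aggregated to family (or genus), and tested on the
centred log-ratio scale.  Technical sampling uncertainty is propagated
by Monte-Carlo Dirichlet instances: per sample, `n_mc = 128`
compositions from `Dirichlet(counts + 0.5)`, each CLR-transformed.  Per
taxon and instance a Kruskal–Wallis (or two-group rank-sum) p is
computed; the reported raw p is the mean over instances (median
available), and BH correction is applied across taxa.  `n_mc` and the
prior follow the conventions of the standard compositional tool for
this analysis; both are flags.  The calprotectin-associated analysis is
this same engine with a binary grouping at 100 µg/g.

The expected-p statistic is *conservative for rare taxa*: when a
taxon's counts are small, the Dirichlet instances decorrelate and the
averaged p is pulled toward its centre.  Calibration tests therefore
check size in the abundant-taxon regime (uniform base composition,
expected count ≈100 per taxon), where instance correlation is high and
the statistic is approximately uniform under the null; the power check
injects a 3-fold change under moderate biological overdispersion
(Dirichlet concentration 200).

## Resampling inference

* **Subgroup permutation test**: observed statistic
  `median(values[B]) − median(values[A])` for two disjoint size-k
  subgroups; each of the 10 000 permutation samples redraws two fresh
  disjoint size-k groups uniformly from the whole cohort (a restricted
  label-permutation mode is also provided).  One-sided by default, in
  the direction "later stage exceeds control"; direction is a flag.
* **Pairwise comparisons vs control** use the unpaired two-sided
  rank-sum test with BH correction.  A signed-rank (paired) test is
  sometimes named for this design, but the groups are independent and
  unpaired, so the rank-sum test is the correct instrument; the
  discrepancy is deliberate.
* **Contingency tests**: Monte-Carlo Fisher test sampling tables with
  fixed margins (Patefield's algorithm), p = +1/+1 fraction of tables
  no more probable than the observed; or Pearson χ² without continuity
  correction.  All-zero rows/columns are dropped first, so empty
  categories are inert.
* Benjamini–Hochberg adjustment is one shared code path.

## Synthetic cohorts

The generator emulates the study-shaped inputs end to end.

* **Design**: 226/50/49/46 participants in
  control/high-genetic-risk/autoimmunity/symptomatic; the symptomatic
  group includes ~8 RA diagnoses.
* **Metadata**: serology is drawn so the staging classifier provably
  recovers the intended group — negatives log-normal around 0.3× ULN
  (capped below the category boundary; only threshold relationships
  matter downstream), positives uniform in [1,10]× ULN (ACPA) or
  [3,10]× ULN (RF/anti-Ra33); anti-Ra33 missing with probability 0.2;
  CSA scores drawn from per-group distributions compatible with the
  target stage and arranged into seven indicator items with 0–2 missing.
  The generator verifies the classifier round trip and fails otherwise.
* **Microbiome**: each sample draws a latent enterotype from its
  group's mixing vector (default 0.33/0.24/0.11/0.32 over
  Bact1/Bact2/Prev/Rum, identical across groups), a genus composition
  from that enterotype's Dirichlet concentration vector, then applies
  any configured fold-change effects and renormalises.  The four
  default profiles share a power-law baseline over 120 genera with
  hallmark-genus boosts; Bact2 is Bacteroides-dominated with low total
  concentration (low evenness) and depleted *Faecalibacterium*, Rum is
  the most even.  Genera are split into 1–5 ASVs with fixed
  Dirichlet-split weights so ASV-level code paths are exercised.
* **Depths and loads**: read totals negative-binomial (mean 20 000,
  dispersion 10, floored at 2 000); loads log-normal with median 1e11
  cells/g (a typical faecal order of magnitude) and log-sd 0.8; 16S
  copy numbers uniform in [1,12] per ASV; calprotectin log-normal with
  median 30 µg/g, log-sd 1, optional per-group multiplicative shift
  (none by default).
* **Default effect**: a 1.5× fold change on *Prevotellaceae* relative
  abundance in the autoimmunity and symptomatic groups — a weak,
  whole-group effect that leaves cohort-level PERMANOVA and
  Kruskal–Wallis tests near-null while remaining detectable in
  favourable subgroup contrasts, the regime the pipeline is designed to
  probe.
* The per-group serology titre distributions are stand-ins chosen for
  threshold behaviour, not estimates of any real cohort.

**What the synthetic data do not model**: sequencing error, chimeras and
PCR bias; phylogenetic correlation between genera; co-occurrence
structure beyond the enterotype mixture; longitudinal dynamics;
covariance between load, diversity and enterotype; and any real
effect-size calibration.  Passing tests demonstrate the *procedures*
(conservation laws, calibration, recovery of injected structure), not
biological conclusions.

## Problem sizes and determinism

Every stochastic step takes an explicit integer seed; the pipeline
derives fixed per-stage seeds from one master seed, so identical
configurations write byte-identical reports regardless of which stages
are enabled.  Test and acceptance experiments use deliberately scaled
problem sizes chosen as a balance of statistical resolution and
turnaround: PERMANOVA calibration uses 500 null cohorts of 30 samples
with 199 permutations; DMM order selection uses 20 panels of 600
samples over K ∈ {3,4,5} with one k-means-seeded restart; the
differential-abundance size/power checks use 200/50 taxa at depth
20 000 with 128 Monte-Carlo instances; the end-to-end determinism check
runs a reduced cohort (76 participants, reference panel of 120).  The
full-size default configuration (371 participants, 1 045-sample
reference panel, K ∈ 1..6, 999 permutations, 10 000 permutation draws)
is exercised by `scripts/acceptance.py`.

## Known limitations

* The DMM fit is a local optimiser; pathological initialisations can
  select a neighbouring K.  More restarts (`dmm_restarts`) trade time
  for robustness.
* The expected-p differential-abundance statistic is conservative for
  rare taxa (see above); interpret rare-taxon nulls accordingly.
* PERMANOVA covariates/strata, UniFrac distances, copy-number
  *prediction* and raw-read processing are out of scope: the pipeline
  starts at the ASV table and consumes copy numbers as an input table.
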