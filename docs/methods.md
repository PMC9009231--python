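# Methods

This note records the model underlying `kinflux`, the parameters and
units of every stage, the scope of the synthetic generators used for
validation, and the numerical choices that affect results.

## 1. Model

### 1.1 Constraint-based backbone

A metabolic network with stoichiometric matrix **S** (metabolites ×
reactions) constrains the flux vector *v* (mmol/L/min) by steady state
**S**·*v* = 0 and box bounds *lb* ≤ *v* ≤ *ub*. Flux balance analysis
(FBA) maximises a designated objective flux over this polytope; flux
variability analysis (FVA) reports each reaction's attainable
(min, max), optionally while holding the objective at a fraction of
its optimum. Both are delegated to `cobra`/`optlang` (GLPK). Bounds
read as ±∞ from model files are replaced by the conventional ±1000.

### 1.2 Kinetic caps

For each reaction *r* with a turnover number, the flux cap is

  V<sub>max,r</sub> = k<sub>cat,r</sub> · 60 · [E]<sub>r</sub> · 10⁻⁶  (mmol/L/min)

with k<sub>cat</sub> in s⁻¹ and [E] in nmol/L (60 converts s⁻¹ to
min⁻¹, 10⁻⁶ converts nmol to mmol). The effective enzyme concentration
[E]<sub>r</sub> is obtained by evaluating the reaction's boolean
gene–protein–reaction (GPR) rule over per-gene abundances: OR
(isozymes) sums the operands, AND (enzyme complexes) takes their
minimum, an empty rule yields an unlimited cap. Per-gene abundance is
predicted from transcript level M (FPKM) as [E] = (α/γ)·M, where the
per-gene α/γ ratio is the median protein/mRNA ratio across reference
tissues; genes without a usable tissue observation receive the global
median ratio and are flagged. Caps apply as *ub* ← min(*ub*, V) and,
for reversible reactions, *lb* ← max(*lb*, −V); they never widen
existing bounds.

Turnover lookup prefers a reaction-id-specific record; otherwise all
records under the reaction's EC numbers are pooled and their median
taken. A fixed whitelist of oxidative-phosphorylation reactions
(`ATPS4mi`, `CYOOm2i`, `CYOOm3i`, `CYOR_u10mi`, `NADH2_u10mi`, `r0205`,
`FADH2ETC`, `GLYC3PFADm`) is never capped, because in vitro turnover
numbers for the respiratory chain are systematic underestimates.

Exchange bounds come from an uptake table with four categories:
`nutrient` (measured uptake rate), `essential_amino_acid` (default
0.01 mmol/L/min), `cofactor` (explicit rate), and `iron_oxygen`
(unlimited).

### 1.3 Context-specific reduction

Reduction follows the GIMME scheme with kinetic coverage as the
penalty: reactions lacking a turnover record get penalty 1, covered
reactions 0. For each stated objective, one LP minimises
Σ penalty·|v| subject to steady state, bounds, and objective flux
≥ *f*·optimum (default *f* = 0.9; absolute values are linearised with
auxiliary variables). The reduced model keeps every unpenalised
reaction plus any penalised reaction carrying |v| > 10⁻⁶ in some
objective's minimiser, so each objective remains attainable at
≥ *f*·optimum on the reduced model. A single minimiser per objective is
used; penalised reactions that appear only in alternative optima of
the penalty LP may be dropped.

### 1.4 Per-sample flux distributions

For each sample: apply kinetic and uptake bounds, run FVA, remove
reactions whose range is within 10⁻⁶ of zero (with orphaned
metabolites), then sample the remaining polytope with an
artificial-centering hit-and-run (ACHR) chain. Warmup points are LP
solutions maximising/minimising random Gaussian directions
(`scipy.optimize.linprog`, HiGHS), projected onto the stoichiometric
null space. Each step moves from the current point along the direction
from the running centre to a randomly chosen warmup point, with the
step length uniform over the feasible chord; the centre is updated as
the mean of visited points. Every `thinning`-th point is recorded;
points are re-projected onto the null space every 500 steps and
clipped to bounds, so recorded draws satisfy |**S**·*v*| ≤ 10⁻⁶ and
bounds ±10⁻⁹. Defaults: 1000 draws, 200 warmup points, thinning 100.
A sample's flux profile is the mean of its draws; reactions pruned
from the individual model contribute flux 0 to cohort matrices.

`cobra`'s bundled ACHR sampler was evaluated and rejected: on a 1-D
polytope its draws failed a Kolmogorov–Smirnov test against the exact
uniform distribution by a wide margin, while the implementation here
passes at α = 0.01 across seeds.

### 1.5 Cohort signatures

Two per-feature ordinary-least-squares models separate case effects
from aging:

- Model 1 (case + control samples): flux ~ intercept + case indicator + sex.
- Model 2 (control samples only): flux ~ intercept + age + sex.

A feature is called **up** when the model-1 case coefficient is
positive with p < α (default 0.05) and there is *no* significant
positive age effect in model 2; **down** symmetrically. Features
constant across samples are excluded and reported. The OLS backend is
a closed-form vectorised implementation validated against
`statsmodels` to 10⁻¹⁰.

Per-subsystem differential abundance is
DA = (#up − #down) / #features ∈ [−1, 1]. Significance comes from a
label-shuffle test: case/control labels are permuted B times (default
1000) with the full dual-model pipeline recomputed per shuffle, and

  p = #{shuffles with |DA*| ≥ |DA|} / B,

i.e. ties count as exceedances (the standard permutation-test
convention; see §3). Subsystems with DA = 0 are assigned p = 1.
Benjamini–Hochberg adjustment yields FDR values.

Welch's unequal-variance t-test from summary statistics
(mean, SD, n per group, Welch–Satterthwaite df) and Fisher's exact
test on 2×2 tables support reproducing published cohort-level
statistics; both are validated against full-data `scipy` counterparts.

### 1.6 Perturbations

Gene knockouts zero the gene's abundance and re-derive every cap
through the GPR rules, so isozyme redundancy is respected. Reaction
inhibition scales the cap by (1 − s), s ∈ [0, 1]; activation
multiplies finite caps by a fold change; knock-in sets a cap outright
and may insert a new reaction. Whitelisted reactions are never
touched. Screens evaluate single targets or all pairs with an FBA
readout against the unperturbed baseline; infeasible perturbed models
are reported with objective 0 and flagged.

### 1.7 Benchmark protocol

Noise robustness: each gene's expression is multiplied by an
independent U[1 − λ, 1 + λ] draw, the full pipeline is rerun, and R²
between genuine and noised mean-flux vectors is reported (mean over
repeats). The sampler seed is shared between the genuine and every
noised run so Monte-Carlo noise is paired out and the reported R²
isolates the effect of expression noise. Experimental flux tables are
cleaned by dropping reactions with |median| < 10⁻³ mmol/L/min and
masking values > 3 MAD from the reaction median; predicted/measured
pairs where either side is < 10⁻⁶ in absolute value are excluded from
the Pearson correlation.

## 2. Parameters and defaults

| parameter | default | units / notes |
| --- | --- | --- |
| default finite bound | 1000 | mmol/L/min, replaces ±∞ |
| V<sub>max</sub> conversion | ·60·10⁻⁶ | k<sub>cat</sub> (s⁻¹) × [E] (nmol/L) → mmol/L/min |
| essential amino acid uptake | 0.01 | mmol/L/min |
| reduction objective fraction | 0.9 | of unconstrained optimum |
| reduction flux tolerance | 10⁻⁶ | mmol/L/min |
| FVA pruning tolerance | 10⁻⁶ | mmol/L/min |
| sampler draws / warmup / thinning | 1000 / 200 / 100 | re-projection every 500 steps |
| steady-state / bounds tolerance | 10⁻⁶ / 10⁻⁹ | on recorded draws |
| signature α | 0.05 | both linear models |
| bootstrap shuffles B | 1000 | label permutations |
| noise levels tested | 0.05, 0.10 | multiplicative, 20 repeats |

## 3. Numerical choices

- **LP solvers.** FBA/FVA/reduction use GLPK through `optlang`;
  sampler warmup LPs use `scipy`'s HiGHS. Both are deterministic.
- **LP validation.** On the test fixtures, FBA and FVA are checked to
  10⁻⁹ against a brute-force oracle that enumerates all polytope
  vertices via null-space active-set combinations — independent of any
  LP solver.
- **Permutation-test tie handling.** The shuffle p-value counts ties
  (≥, not >). With a discrete statistic like DA on 10-feature
  subsystems, the strict-inequality variant is anticonservative: a
  single spurious net call yields a small p purely from the atom at
  DA = 0, inflating the empirical type-I error several-fold. Counting
  ties restores calibration (measured type-I ≈ 0.04 at nominal 0.05
  over 50 null cohorts). A `tie_policy="strict"` option preserves the
  literal exceedance count for comparison.
- **Seeding.** All stochastic stages take explicit integer seeds and
  use `numpy.random.default_rng`; cohort pipelines derive per-sample
  seeds deterministically (mod 2³¹). Identical seeds reproduce draw
  matrices bit for bit.
- **Vectorised OLS.** The dual-model fit and the B-shuffle bootstrap
  use closed-form OLS on stacked feature matrices (one matrix solve
  per shuffle), which keeps B = 1000 shuffles on a 200 × 80 matrix
  under one second.

## 4. Generator scope — what passing tests do and do not show

All automated validation runs on synthetic fixtures:

- an 8-reaction toy network (glucose/oxygen/lactate exchanges,
  transporters, fermentation, respiration, ATP demand) whose ATP
  optimum has a closed form, checked against the vertex oracle over a
  grid of uptake caps;
- a 3-reaction chain whose flux polytope is a 1-D interval, where the
  sampler's stationary distribution is exactly uniform;
- a parallel-path network exposing the reduction contract;
- synthetic cohorts with log-normal flux noise, a planted
  multiplicative case-group shift in one subsystem, a planted age
  slope in another, and sex offsets — matching the additive-on-log
  assumptions of the linear models.

Passing these tests demonstrates correctness of the algorithms and
calibration of the statistics **on generators that satisfy the model
assumptions**. It does not show that real transcriptomes predict real
fluxes: that claim depends on genome-scale reconstructions, turnover
databases, and experimental flux measurements that require external
downloads and are deliberately outside the automated suite. Problem
sizes in the tests (≤ 8 reactions, 200 features, 80 samples) were
chosen so the oracle enumeration and 50-replicate calibration runs
complete in minutes on one CPU; they are the package's own choices,
not statements about real-data scale.

## 5. Limitations

- V<sub>max</sub> caps assume enzyme saturation; substrate affinity
  (K<sub>m</sub>) is not modelled.
- The α/γ protein-per-transcript ratio is a per-gene constant across
  samples; condition-dependent translation or degradation is ignored.
- GIMME reduction keeps a single penalty-minimising solution per
  objective; alternative-optimum flux routes may be lost.
- Mean-of-draws flux profiles summarise a distribution by one point;
  multimodal polytopes are not distinguished.
- The dual-model signature assumes linear, additive group/age/sex
  effects and calls a feature confounded only for *same-direction*
  aging effects.
- ACHR mixing is validated on low-dimensional fixtures; very
  high-dimensional polytopes may need longer thinning than the
  defaults.
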