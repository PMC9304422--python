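# Methods

This note documents the models, defaults and numerical choices behind
`flyp`, and what the synthetic-data experiments do and do not demonstrate.

## The synthetic cohort generator

The generator (`flyp.simulate`) emulates a prospective matched case-control
methylation study on blood. Its defaults are the study conditions every
test and the acceptance script run under.

**Reference profiles.** Twelve immune cell types (neutrophils, eosinophils,
basophils, monocytes, naive/memory B cells, naive/memory T helper cells,
regulatory T cells, naive/memory cytotoxic CD8 T cells, NK cells). Per CpG,
cell-type mean betas come from a bimodal prior (Beta(2,18) low mode near
0.1, Beta(18,2) high mode near 0.9, equal weights) with between-type jitter
of SD 0.02; `n_discriminative_per_type` CpGs per type (default 100) have
that type displaced by 0.5, guaranteeing a one-vs-rest gap of at least 0.3.
Every row is recentred to a common mean over non-clock CpGs, so a sample's
global mean methylation is invariant to its cell composition. This makes
the null generator exactly null at non-clock CpGs (composition shifts
cannot masquerade as global shifts) without breaking any per-CpG structure.

**Bulk mixtures.** Per-sample fractions are Dirichlet with concentration 30
around realistic blood means (neutrophils 0.50, memory T helpers 0.12,
monocytes and memory CD8 0.08, NK 0.05, down to basophils 0.01). A
concentration of 30 gives a neutrophil SD of about 0.09 across subjects,
in the range reported for healthy adults. Bulk beta is the convex mixture
`fractions @ references`.

**Mitotic clock.** A clock set (default 385 CpGs) starts at baseline beta
0.05 in every cell type and gains `clock_rate` (default 0.004) per unit of
a latent mitotic age: Normal(30, 8) for controls, shifted +10 for future
cases, plus a weak age coupling (0.2 per year of chronological age). The
package does not hard-code any published clock list; synthetic runs use the
generator's set and real runs load a user-supplied list.

**Planted case effects.** `n_causal_cpgs` (default 200) receive +/-
`delta_beta` in cases, clipped to [0.001, 0.999]; a configurable fraction
(default 0.42) is hyper-methylated. Hyper-causal CpGs start in the low mode
(Polycomb-island CpGs are lowly methylated in blood and gain methylation)
and are annotated preferentially as Island / ReprPC / TssBiv; hypo-causal
CpGs start high and sit preferentially in open sea. With
`clock_effect_coupling` in (0, 1], each case's effect scales with its
relative mitotic age, so low-clock cases carry weaker effects — the regime
in which clock stratification helps classification. A cell-type-specific
effect (`ct_effect_*`) adds a shift proportional to one cell type's
fraction, for testing the interaction model.

**Noise, batch and matching.** Batch effects (M-scale SD 0.2 per CpG per
batch, 2 batches) and measurement noise (M-scale SD 0.1) are added on the M
scale and back-transformed, keeping beta bounded. Each case receives a
rejection-sampled control matched on sex and age within +-2.5 years. A
fraction of CpGs is flagged at SNPs (MAF > 1%) or placed on sex chromosomes
so the filters have work to do; these sets are disjoint from causal, clock
and discriminative CpGs by construction.

**What the generator does not emulate:** Illumina probe chemistry (type
I/II), detection failures, SNP effects on methylation, spatial CpG
correlation, subtype-specific effect profiles (all subtypes share the
causal set by default), and genuine biological confounding of composition
with outcome (composition is independent of outcome unless
`neutrophil_alpha_case_factor` is set). Passing tests therefore show the
pipeline recovers the structure the generator plants — not that the
published effect sizes are reproducible from real cohorts.

## Preprocessing

Beta to M uses clipping at `epsilon = 1e-3` (bounding M to roughly +-10)
and is exactly invertible inside the clip range. Quantile normalization is
plain column quantile normalization (ties get the average of the reference
quantiles they span). CpG filters drop sex chromosomes and SNPs with MAF
above 1% (default), and are idempotent.

Batch correction re-implements the parametric empirical-Bayes
location/scale algorithm: per-CpG batch means and variances, estimated on
standardized data, are shrunk toward normal / inverse-gamma priors fitted
across CpGs and removed; protected covariates (outcome) stay in the design.
It matches Bioconductor `sva::ComBat` to ~1e-5 on shared inputs (tested).
Two numerical choices: degenerate priors (zero spread of the batch
location or scale estimates across CpGs) fall back to the direct estimates,
and pooled variances are floored at 1e-12. Two known, documented
properties: the shrinkage residual leaves per-CpG grand-mean deviations of
order 0.01 on noisy data (exact preservation holds only when shrinkage is
inert), and correction-then-regression is mildly anti-conservative in small
samples (about +0.004 at alpha = 0.05 with 50 samples per arm, halving as n
grows) because removing estimated batch means spends degrees of freedom the
downstream test does not see. These are properties of the algorithm, not of
this implementation.

## Moderated screening

Stage 1 fits ordinary least squares per CpG on the M scale (outcome
dummies against the control reference, plus covariates — age and sex by
default) and shrinks residual variances toward a scaled inverse-chi-square
prior whose degrees of freedom and scale are fitted by moments on the log
variances (trigamma-inverse Newton iteration). Moderated t per contrast;
for the three-level outcome the two contrasts are combined into a moderated
F with an overall p. The implementation matches Bioconductor `limma::eBayes`
to ~1e-8 on shared inputs (tested), and with prior df forced to zero it
reproduces ordinary OLS t exactly. Zero-variance CpGs are flagged and given
p = 1. Thresholding offers BH FDR and a fixed-p mode whose default, 2.4e-7,
is the permutation-derived genome-wide level for 450k data (taken as a
constant, not re-derived).

### Calibration and composition dependence

Within a single bulk cohort the per-CpG p-values are not independent: all
CpGs share the realized case/control imbalance of the ~12 latent cell
fractions, and a chance imbalance induces an O(1) noncentrality at every
composition-sensitive CpG regardless of sample size. Marginally (across
cohorts) the p-values are uniform — the composition variation enters the
within-group variance correctly — but a single-cohort KS test against
uniformity can fail by a large margin in either direction. Linear
adjustment for the true fractions does not remove this: the mixture enters
the M scale through a logit, so curvature survives. The calibration tests
therefore check the marginal distribution by pooling p-values subsampled
from many independent replicate cohorts, and check BH false-discovery
control replicate-wise. This mirrors the practical EWAS situation in which
unadjusted analyses show composition-driven inflation within any one study.

## Elastic-net condensation

Survivor M values are standardized; lambda descends a geometric path from
the data-derived maximum (30 steps to 1% by default) with warm-started saga
fits; 10-fold stratified CV multinomial deviance selects lambda by the 1-SE
rule; the final fit's union of nonzero class coefficients is the feature
set. The multinomial penalty is elementwise (each class coefficient can be
zero independently) rather than grouped across classes; the union over
classes plays the role of the grouped support. `alpha = 1` reproduces the
lasso (two-class protocol), `alpha = 0.5` is the default for the
three-class model, and `alpha = 0` keeps all survivors (ridge has no exact
zeros — documented behaviour, not an error).

## The forest and its protocols

The only tuned forest hyperparameter is the per-split feature count (mtry),
over a caret-style grid of up to `tune_budget` = 30 values, scored by
repeated stratified CV accuracy (3 repeats of 10-fold by default). Tuning
forests use 150 trees — the CV ranking of mtry stabilises well below the
final forest size — and the selected model is refit with `n_estimators`
(default 300) on the full training data. All randomness derives from one
seed. Ties in predicted probability break in the fixed class order
(control, NHL_hi, NHL_lo). The scalar risk is P(NHL_hi) + P(NHL_lo).

Stratum accuracy for NHL_hi is plain accuracy restricted to samples whose
truth is NHL_hi or control (a case predicted into the other stratum counts
as an error), and likewise for NHL_lo. Leave-one-subtype-out trains the
full selection-plus-forest pipeline on all other subtypes' cases plus a
proportional, seed-controlled share of controls. The covariate baseline
runs the identical forest protocol on age, sex, BMI and the 12 cell
fractions.

## Deconvolution

Signature construction ranks CpGs per cell type by the one-vs-rest mean
difference, keeping up to `max_per_type` (default 100) hyper and hypo
markers with |difference| >= `delta_beta_min` (default 0.2); ties break on
larger |difference| then CpG id; every type must contribute. The nu-SVR
estimator z-scores signature and mixture, fits a linear nu-SVR per sample
over nu in {0.25, 0.5, 0.75}, keeps the nu with smallest reconstruction
RMSE, clips negative coefficients and renormalises (the z-scoring scale
ambiguity cancels in the renormalisation). The RPC estimator is an
iteratively-reweighted Huber regression (k = 1.345, MAD scale, tolerance
1e-6, max 100 iterations with a convergence flag). Cell-type-specific
differential methylation uses the interaction model
`beta ~ sum_k f_k + sum_k f_k * case` without intercept (fractions sum to
one), by default restricted to island CpGs; near-constant fraction columns
are dropped with a warning. This group-level interaction model replaces
per-sample profile imputation: it answers the same question (which
compartment carries the case effect) and is verifiable by simulation.

## Enrichment

Observed category counts of a signature are compared with B = 1000 random
same-size CpG lists drawn without replacement from the universe — defined
as all post-filter CpGs on the array, the actual sampling frame of any
array signature. Extremeness is two-sided by distance from the null mean;
p carries +1 smoothing so it is never zero; BH runs within each
categorisation (15 chromatin states; 4 island relations). An exhaustive
mode enumerates all subsets when combinatorially feasible, in which case
the empirical p equals the exact enumeration fraction. Because counts are
discrete, empirical p-values live on an achievable grid; the calibration
test bins at the grid's gaps and compares with the exact hypergeometric
masses. Composition-matched sampling (matching probe type or CpG density)
is not implemented; the sampler is unmatched.

## Pipeline and reproducibility

One root seed is fanned out per stage by hashing the stage name into a
`numpy.random.SeedSequence` (31-bit child seeds). The train/test split
(default 70/30) is stratified on provisional three-class labels computed
from the all-case median purely to balance the split; the cutoff used for
the final labels is then recomputed on training cases only and frozen, so
no test statistic touches test samples (a fixed externally supplied cutoff
can be given through the `clock_cutoff` config field instead of the
training-median rule). The manifest records config (minus the
output directory), derived seeds, package version and SHA-256 checksums of
every output; wall-clock timings go to `run.log` only, so reruns with the
same config are byte-identical. Quantile normalization is off by default
for simulated cohorts (they are already on a common scale) and available
for file inputs.

## Problem sizes used in tests

The acceptance suite runs the generator at the conditions stated above:
signal recovery at 20 000 CpGs with 150 cases and 150 matched controls
(delta-beta 0.3 at 200 causal CpGs, clock-coupled), null calibration over
50 replicate cohorts of 20 000 CpGs with 100 samples per arm, deconvolution
recovery over 200 samples at M-noise 0.05, and enrichment calibration over
500 random signatures. Elastic-net and forest tuning in these runs use
reduced resampling (5-fold CV paths, 10 mtry candidates) — selection
quality and accuracy are insensitive to this, and the package defaults
remain the full 3x10/30 protocol.

## Known limitations

* Real 450k artefacts (probe type, dye bias, detection p-values) are out of
  scope; the pipeline consumes beta matrices.
* The elastic net's elementwise multinomial penalty may split a CpG's
  effect across classes where a grouped penalty would keep or drop it
  whole.
* The RPC estimator reports convergence but does not currently expose
  per-sample robust scale estimates.
* Misclassification analysis requires at least one correct and one
  incorrect case; perfect classifiers return nothing (by design).
* Missing values are accepted by the matrix containers as explicit NaN but
  quantile normalization and batch correction require complete matrices.
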