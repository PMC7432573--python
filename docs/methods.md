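# Methods

`myoclock` builds and evaluates a skeletal-muscle-specific DNA methylation
age clock and the accompanying age-EWAS. This note documents the models, the
numerical choices, and what the built-in simulator does and does not emulate.

## Data model

Methylation is represented as beta-values — per-CpG methylation fractions
`M / (M + U + 100)` computed from methylated/unmethylated array intensities,
bounded in [0, 1] — arranged probes × samples, one matrix per cohort
(dataset), with an aligned sample sheet (age, sex, dataset id, subject id for
paired designs, condition) and a probe annotation table (position, Infinium
design type, CpG-island context, 15-state chromatin segmentation, gene
symbols, probe-quality flags). For linear modelling, beta-values are mapped
to M-values (`log2(b/(1-b))`, beta clipped to `[1e-6, 1-1e-6]` so boundary
values stay finite); the clip bound is arbitrary but inconsequential — it
only affects probes already saturated at 0/1.

## Preprocessing

Filters follow standard Illumina-array practice with literal threshold
semantics: a sample is removed when **more than** 10% of its probe calls
have detection p > 0.01; a probe is removed when any beta is missing, any
detection p > 0.01, the bead count is < 3 in **at least** 5% of samples, or
the probe is non-CpG, multimapping, SNP-associated or (for mixed-sex
cohorts) on a sex chromosome. Samples are filtered before probes, and both
filters are idempotent. Missing values are imputed by k-nearest-neighbour
over samples (k = 5, NaN-aware Euclidean distance), delegating to
scikit-learn's `KNNImputer`. Dataset-level QC computes the mean pairwise
inter-sample correlation (pass: > 0.97) and the matrix maximum beta
(pass: > 0.99); failure is a flag, not a hard stop, since this screen is
meant for deciding whether externally processed data are usable at all.

Known technical batches (plate, position) are adjusted on M-values by a
parametric empirical-Bayes location/scale correction: per-probe
standardization against the batch-size-weighted grand mean and pooled
variance; per-batch per-probe means and variances shrunk toward
across-probe priors (normal for means, inverse-gamma for variances,
method-of-moments hyperparameters, the standard fixed-point iteration);
batch effects removed and the data de-standardized. Two deliberate
numerical choices: a single batch returns the input unchanged, and the
per-probe plain mean over samples is restored exactly after correction so
the adjustment never moves a probe's overall level. The non-parametric
variant of this correction is not implemented.

## Gold-standard calibration (three-state beta-mixture quantile mapping)

Beta-value distributions are modelled as a three-component beta mixture —
hypo-, hemi- and hyper-methylated states. The mixture is fitted by EM:

* deterministic initialization from the 0.2/0.75 quantile cut points of the
  input (method-of-moments within each cut), so repeated fits are identical;
* E-step responsibilities from component beta densities;
* M-step weights in closed form; shape parameters by maximizing the
  responsibility-weighted beta log-likelihood from its three sufficient
  statistics (L-BFGS in log-parameter space, warm-started from the previous
  shapes, with the previous value kept if the step fails to improve) — a
  generalized-EM step, so the log-likelihood trace is non-decreasing;
* stop when the log-likelihood changes by < 1e-6 or at 100 iterations
  (defaults). The default cap is enough for calibration purposes; parameter
  estimates at full ML accuracy need `max_iter` of a few hundred.

Components are relabelled by increasing mean; state assignment is by
maximum posterior responsibility with ties going to the lower-mean state.

A calibration map between a sample and the gold-standard reference fits
both mixtures and sends hypo-state values through beta-CDF quantile
matching into the gold hypo component (`F_gold^-1(F_sample(v))`), hyper-state
values likewise, and carries the hemi state by a linear bridge between the
images of the two state boundaries. The bridge avoids the boundary
discontinuities a direct hemi-CDF map would create; the overall transform is
continuous, non-decreasing, pins 0 to ~0 and 1 to ~1, and is rank-preserving
within a sample. The gold-standard reference is the **per-probe mean beta**
of the gold cohort (chosen over a single reference sample: the mean profile
is less noisy and always defined); the gold mixture is fitted once and
reused for every sample.

Within-dataset Infinium Type I/II design adjustment uses the same machinery
(map the Type II distribution onto Type I); re-deriving the original
reference implementation's exact code path is out of scope.

## The clock

Chronological age is transformed by the piecewise log-linear map

    t(a) = log((a+1)/(A+1))        a <= A
         = (a - A)/(A+1)           a >  A

with adult-age pivot A = 20 years (configurable): logarithmic through
development, linear in adulthood, continuous and strictly increasing. The
transformed age is regressed on CpG beta-values with an elastic net,

    min  (1/2n) ||y - b0 - X w||^2 + lambda (alpha ||w||_1 + (1-alpha)/2 ||w||_2^2),

alpha = 0.5 by default. Predictors are standardized internally and the
coefficients back-transformed. lambda is chosen by 10-fold cross-validation
on a 50-point path; folds are stratified across dataset ids so no fold
coincides with a single cohort (otherwise the fold error would measure
between-cohort transfer twice). The default rule takes the CV-minimum
lambda; a one-standard-error rule is available. Only the non-zero weights
are stored, together with the gold-standard mean beta of every model probe.

Prediction inverts the age transform and clips at 0 years. Query datasets
may lack up to 5% of the model's probes; missing probes are filled with the
stored gold-profile values (beyond 5% is an error — predictions would no
longer be comparable).

Accuracy is estimated by **leave-one-dataset-out cross-validation**: each
cohort in turn is held out entirely, the clock retrained on the rest, and
the held-out cohort scored. Two age-acceleration statistics are reported
per sample: `AA_diff = predicted - actual`, and `AA_resid`, the residual of
an OLS regression of predicted on actual age computed within the held-out
cohort (per evaluation group; a pooled-regression variant is a flag).
`AA_resid` has exactly zero mean and zero correlation with age inside each
group, making it insensitive to the cohort's mean age. Per-cohort summaries
report n, Pearson r (left uncomputed when the cohort's age is invariant or
n < 4), median |AA_diff|, mean AA_diff and median |AA_resid|. Clocks are
compared by a paired two-sided t-test on absolute accelerations with
significance at p < 0.005; identical inputs return t = 0, p = 1 before the
zero-variance check fires. The final shipped model is trained on all
cohorts with its own CV-selected lambda (not an average of the
leave-one-out models).

## Age-EWAS

Per probe, methylation (beta by default; M by flag — the choice is exposed
because effect sizes are reported on the input scale) is regressed on age
with sex and dataset id as covariates. Paired designs are handled by a
single consensus intra-block correlation: per-probe within-block residual
correlations (moment estimates over up to 500 probes) averaged on the
atanh scale, then generalized least squares with an exchangeable
within-block correlation, implemented by closed-form block whitening. This
approximates the consensus-correlation machinery of the standard
microarray linear-modelling framework; a fixed-subject-effects fallback is
available through the design-matrix covariates.

Residual variances are moderated by empirical Bayes: a scaled
inverse-chi-square prior (d0, s0²) is fitted across probes by matching the
mean and variance of log s² (digamma/trigamma inversion, Newton for the
trigamma inverse); d0 = +inf when the spread of log variances does not
exceed what the residual degrees of freedom alone produce. Posterior
variances `(d0 s0² + d s²)/(d0 + d)` give moderated t-statistics with
d0 + d degrees of freedom. BH false-discovery rates are computed per test
family with significance at FDR < 0.005 throughout (the package-wide
threshold).

DMRs are defined directly as clusters of direction-consistent significant
probes: significant probes sorted by position, merged while consecutive
gaps are ≤ 1 kb **and** the slope sign agrees, clusters of ≥ 2 probes
emitted. The kernel-smoothing DMR algorithm of the established package is
deliberately out of scope; this clustering is the definition used here.

Panel enrichment across island contexts (4 levels) and chromatin states
(15 levels) uses two-sided Fisher exact tests (p by summing all tables
with probability ≤ observed) with BH correction within each category.
Panel-overlap significance uses a Monte-Carlo null: uniform subsets drawn
without replacement from the background (Floyd's partial sampling,
numba-compiled, default 10^6 draws) with an add-one tail probability.
The gene-set test scores a gene significant when ≥ 1 of its probes is
significant and corrects the resulting probe-count bias with a Wallenius
noncentral hypergeometric tail whose odds parameter is the ratio of mean
probe counts inside vs outside the set; with equal probe counts it reduces
exactly to the central hypergeometric test. The gene universe is every gene
with ≥ 1 background probe.

## Simulator

The generator emulates the statistical structure the pipeline assumes:
12 cohorts on three platforms (HM27/HM450/HMEPIC) whose probe sets share a
common core (platform-specific extras are disjoint, so the 12-way
intersection is exactly the core); a pooled age distribution that is
bimodal by construction — strata 18–30/30–50/50–70/70–90 with full-scale
counts 242/105/275/60 over 682 samples, scalable by a sample-scale factor;
heterogeneous cohorts including a broad-range gold standard, two
age-invariant young cohorts and one n = 3 cohort; and 8 of 12 cohorts
paired, with pair members adjacent in age and sharing a latent subject
effect.

Signal is linear on the M scale: per-probe baselines drawn from a
three-component beta mixture; age-responsive CpGs (default 1,000 of the
core; 300 in the half-scale test scenario) with beta-scale slopes drawn
from a truncated half-normal (sd 0.0015/y, |slope| in [0.0005, 0.003]/y —
top slopes ~0.3%/y, i.e. ~3% per decade) converted to M-slopes by the delta
method at each baseline; i.i.d. M-scale noise (sd 3.0 by default); and a
per-cohort batch effect with a global location shift (sd 0.5 M), a global
scale distortion (sd 0.10 on log scale) and a smaller independent per-probe
component (sd 0.10 M). The global components are the part of a batch
effect that a monotone distribution-matching calibration can remove —
with a purely per-probe batch model, calibration could never help, which
would misrepresent how array batch effects behave. Ages are integers;
ground truth (age probes, slopes on both scales, batch shifts, ages, pair
structure) is returned alongside the data.

The default noise level was chosen as the highest at which the half-scale
scenario keeps held-out accuracy within the package's stated guarantees
(mean per-cohort median |AA_diff| ≤ 6 y, pooled r ≥ 0.8) with margin;
this puts pooled held-out R² near 0.85–0.9 rather than lower-noise
regimes' near-1 or the substantially noisier ~0.7 regime, where the
6-year bound no longer holds at this scale.

What the simulator does **not** emulate: raw intensities and
detection-p/bead-count structure (QC inputs are exercised with hand-built
fixtures), fibre-type composition and cell-type heterogeneity, circadian
oscillation, non-linear age trajectories, and correlated probe blocks
beyond the pair effect. Passing tests therefore demonstrate that the
machinery recovers the structure it models — not that real muscle data
meet these assumptions.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the 12-cohort scenario at
sample scale 0.5 with a 5,000-probe common core and 300 age CpGs
(~343 samples), the EWAS null at 5,000 probes × 100 samples over 20 seeds,
and the overlap null at 10^5 draws from a 19,401-probe background; these
sizes were chosen so the full end-to-end properties are exercised at
desk scale.

## Known limitations

* The calibration map is global per sample; probe-specific batch effects
  pass through it untouched (they are handled, for known batches, by the
  empirical-Bayes batch adjustment instead).
* The consensus-correlation GLS assumes one exchangeable correlation for
  all probes and blocks.
* EM defaults favour speed over final-digit ML accuracy (see above).
* The paired t-test comparison assumes approximately normal differences of
  absolute accelerations.
* Predictions are clipped at 0 years; extreme inputs can otherwise invert
  to negative ages.
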