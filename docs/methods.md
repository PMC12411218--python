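# Methods

This note records the models implemented in `ppx`, the defaults and why they
were chosen, what the synthetic cohort generator does and does not emulate,
and the numerical conventions that affect results.

## Behavioral peripersonal-space estimation

Reaction times (ms) to a tactile stimulus are collected unisensorily (T) and
with a looming visual stimulus at five distances (VT, D1 near … D5 far),
five delays each.  Trials outside a configurable 100–1000 ms window are
discarded (conventional anticipation/lapse bounds); removing *all* trials of
a participant × session × condition cell is an error rather than a silent
drop.  Per participant and session, nRT(d) = mean RT_VT(d) / mean RT_T.
Across participants, each distance gets a two-sided paired t-test of VT vs T
means; p-values are Holm–Bonferroni corrected across the five distances
(uniformly more powerful than Bonferroni, assumption-free; Bonferroni and
uncorrected are available and the choice is echoed in the output).
Significance additionally requires mean nRT < 1 — a direction gate, so
"significantly slower" never counts as facilitation without doubling the
one-sided-α ambiguity.  The PPS extent is the largest d such that D1..d are
all significant: facilitation is treated as a spatial gradient anchored at
the body, and isolated far-only significance is reported but not counted as
extent.

## Global Field Power and cluster permutation

GFP(t) is the spatial standard deviation over channels after removing the
spatial mean at each sample (average-reference convention; the subtraction
can be disabled).  It is re-reference-invariant and scales linearly with
amplitude.

Contrasts between paired GFP series use a one-dimensional (time-only)
cluster-based permutation test: sample-wise paired t, cluster-forming
threshold = two-sided t critical value at cluster-α = 0.05, cluster mass =
summed t over a contiguous same-sign run, null = max |mass| over sign-flip
permutations of the participant difference series (default 1000, seedable),
corrected p with +1 smoothing.  The distance × avatar interaction is the
per-participant series (near_A − near_B) − (far_A − far_B) tested against
zero; simple contrasts are reported inside significant windows.  Channel-
space adjacency is out of scope — the contrast series here are already
one-dimensional.

## Composite indices

Post − baseline changes are computed per feature on matched participants.
An index is the first principal component of the z-scored deltas: PCA on the
**correlation** matrix, because features mix percent-positivity and
concentrations on incommensurate scales.  Scores are projections on the
leading eigenvector; variance explained is λ₁/Σλ.  The sign is fixed by
making the largest-|loading| positive — deterministic, label-blind (it never
peeks at cohort identity), and recorded in the output; all downstream
statistics (ANOVA, correlations, network fit) are invariant to it.
Z-scoring is across all participants jointly, which is required for a
common index spanning cohorts.  Participants with any missing feature are
dropped for that index with a logged count; with n ≈ 15 per cohort any
imputation would be a stronger modeling commitment than the data support.
More features than participants is allowed (the correlation matrix is still
defined) but flagged.

## Cohort statistics

Two-sample t-tests pool variances (df = n_a + n_b − 2, the convention that
makes two 15-participant cohorts give df = 28); Welch is available by flag.
The 2×2 χ² is Pearson's without continuity correction, N(ad−bc)² /
((a+b)(c+d)(a+c)(b+d)), df = 1; Yates by flag.  Degenerate inputs follow
explicit conventions: identical constant samples give t = 0, p = 1; a zero
margin makes χ² an error.  Power analysis inverts the exact noncentral-t
power function (noncentrality d·√(n/2), df = 2n−2) by iterating n upward,
so the returned n is minimal by construction.

## Shallow network of neuro-immune cross-talk

Inputs are the three mediator indices (hormones h, eicosanoids e,
neuroinflammation nf); the target is the ILC-activation index.  The model is
a single hidden layer of tanh units (default 5) with linear output, fitted
full-batch with L-BFGS on standardized inputs/target, minimizing MSE +
λ‖W‖²; the best of 10 seeded restarts by training loss is kept, making the
fit deterministic given (data, spec, base seed).

**Weight decay defaults to λ = 0.3.**  This was selected by a sweep over
{10⁻³ … 1} at the study scale (N = 30): with weak decay the best-of-restarts
criterion picks interpolating solutions whose leave-one-out extrapolations
are wild (out-of-fold prediction SD well above the target SD), and
cross-validated R² collapses even when most target variance is recoverable.
λ = 0.3 stabilizes the LOO predictions while leaving the network expressive
enough to capture the planted Gaussian eicosanoid tuning that linear models
miss.

LOOCV refits the network N times with fold-local standardization; the
out-of-fold prediction for participant i never uses (xᵢ, yᵢ) (this exclusion
is exact and tested bitwise).  Variance explained is reported both as the
squared Pearson correlation between out-of-fold predictions and
measurements (the headline number) and as 1 − SSE/SST.  Per-cohort
regressions of measured on predicted are post hoc; cohort labels never
enter training.

The response surface evaluates the trained network over a hormone ×
eicosanoid grid (default 101×101, data range ± 0.5 SD per axis) with the
neuroinflammation input fixed at its sample mean.  The hot spot is the
region where the prediction strictly exceeds the mean measured activation
(≈ 0 in index units; the mean of grid predictions is available as an
alternative rule and both are recorded).  Membership of participant i is
evaluated at (hᵢ, eᵢ, mean nf) — the same 2-D convention as the plotted
surface — and tested by the 2×2 cohort × inside/outside χ².

Shape diagnostics are read **inside the central-95% data support of each
axis**, not over the extrapolated grid padding: monotonicity is the Spearman
correlation of predictions with one axis averaged over the other;
unimodality of the eicosanoid profile (averaged over the hormone axis) uses
a peak-prominence rule — the profile must rise to an interior maximum and
fall after it, with dips/bumps no larger than 5% of the profile range.  A
literal "count derivative sign changes above a step threshold" rule fails on
fine grids, where a smooth descent is many sub-threshold steps.

Ablation reruns LOOCV three times with one input removed and reports ΔR²
against the full model.

## Synthetic cohort generator

Defaults emulate a four-cohort design (neutral, infection, fearful,
vaccine; N = 15 each; vaccine is blood-only) with baseline and
second-session measurements and two blood draws 120 min apart.

* **RT model** — participant base RT lognormal around 400 ms, trial noise
  ≈ 40 ms SD (right-skewed, as empirical RT distributions are);
  facilitation is an additive −30 ms inside the planted boundary (baseline
  boundary D2 everywhere; second session D4 for the infection cohort).
  25 T trials and 5 distances × 5 delays × 2 VT trials per session.
* **Mediator panels** — 8 hormones, 20 eicosanoids, 13 named
  neuroinflammatory factors.  Per-family latents (h, e, nf) are standard
  normal with infection/vaccine mean shifts (+1.9, +0.15, −1.2 SD).  The
  hormone and neuroinflammation shifts are large (clearly significant at
  n = 15), the eicosanoid shift deliberately small and nonsignificant —
  the eicosanoid family matters through its nonlinear tuning, not its mean.
  Feature deltas load positively on the family latent with noise SD 0.8,
  giving first-PC indices that correlate > 0.85 with their latents.
* **Outcome** — activation = 1.2·h − 0.8·nf + 3.4·exp(−(e−0.3)²/(2·0.8²)) +
  ε (σ = 0.25): monotone-up in hormones, monotone-down in
  neuroinflammation, Gaussian-tuned in eicosanoids.  The Gaussian term
  carries ≈ 20% of the outcome variance — enough that linear baselines
  visibly underfit and each ablated input costs ≥ 0.15 R² at recovery
  scale.  Activation-marker deltas and ILC-subset composition shifts (ILC1
  down, ILC2/ILCP up, on a softmax scale so subsets always sum to 100%)
  are both driven by this activation score, which also produces the strong
  frequency–activation index correlation.
* **EEG** — 16 channels, 256 Hz, −100..400 ms; a fixed zero-mean effect
  topography of 1.5 µV is added to the far-infectious condition inside
  129–150 ms; background is a shared evoked waveform plus smoothed noise.

Effect-size defaults were calibrated so the full pipeline reproduces the
qualitative study pattern at N = 15 with power ≥ 0.8 (hot-spot χ² power
0.80 over 30 replicates; N = 30 LOOCV R² typically 0.65–0.90).  Setting
`GeneratorConfig.null(seed)` removes every planted effect for calibration
runs; identical configurations are byte-identical (single seeded RNG).

**What the generator does not emulate:** real flow-cytometry measurement
error structure (spillover, gating variability), assay floor/ceiling
effects and detection limits, within-family mediator correlations beyond a
single latent factor, circadian or session-order effects, EEG channel
covariance and volume conduction, and participant dropout.  Passing tests
therefore demonstrate that the estimators recover the structure they assume,
not that the assumptions hold in any particular empirical dataset.

## Problem sizes in the test suite

Monte-Carlo calibration uses 200–210 replicates per test (binomial 95% CI
half-width ≈ 0.03 around α = 0.05), with the network scaled to 2 restarts
and the permutation test to 200 permutations inside replicated loops.
Parameter recovery runs at N = 200 (100 per modeled cohort) with 3
restarts.  These sizes keep the default suite within a few minutes on one
CPU while leaving the acceptance margins informative.

## Known limitations

* The hot-spot membership convention (fixing nf at its mean) discards the
  neuroinflammation contribution to cohort separation; the test's power
  comes almost entirely from the hormone axis.
* The unimodality flag diagnoses the *fitted* surface; at small N a noisy
  fit can fail the flag even when the planted function is unimodal.
* Squared-correlation LOOCV R² is insensitive to calibration (slope/offset)
  of the predictions; 1 − SSE/SST is reported alongside for that reason.
* The χ² null rejection rate at n = 15 per cohort sits slightly above α in
  simulation (0.06 at 200 replicates) — the usual small-sample behavior of
  the uncorrected Pearson χ²; the Yates flag is available where that
  matters.
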