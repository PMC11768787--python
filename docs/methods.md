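# Methods

`protonet` detects rest-tremor episodes (4–7 Hz involuntary oscillation,
typical of Parkinson's disease) in tri-axial wrist-accelerometer recordings
made during unscripted daily life. The pipeline classifies non-overlapping
2-s windows as tremor / non-tremor with prototypical radial-basis-function
(RBF) networks, whose basis parameters are inferred from expert-flagged
*prototypical examples* of domain-informed sub-classes rather than learned
from bulk labels. This note records the model, its assumptions, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Signal model and preprocessing

Raw input is a 200 Hz acceleration stream in g. The device signal is the sum
of projected gravity (slowly rotating with wrist orientation), voluntary
movement, tremor, and sensor noise.

1. **Decimation.** Anti-aliasing with a 5-tap (fourth-order) symmetric
   moving-average FIR applied centred (zero phase, so annotation alignment is
   preserved), then every 4th sample is kept: 200 → 50 Hz. The closed-form
   magnitude response is `H(w) = (1 + 2cos w + 2cos 2w)/5`.
2. **Detrending.** Orientation/gravity drift is removed per axis by l1 trend
   filtering: `argmin_t ½‖x−t‖² + λ‖D₂t‖₁` with `D₂` the second-difference
   operator and `λ = 10 000`, which fits a piecewise-linear trend. The solver
   is a log-barrier interior-point method on the dual box-constrained QP
   (`min ½ν'D₂D₂'ν − ν'D₂x`, `|ν| ≤ λ`); `D₂D₂'` is penta-diagonal Toeplitz
   `[1, −4, 6, −4, 1]`, so every Newton step is one banded Cholesky solve.
   Stopping uses the primal–dual gap (`max(1e-8, 1e-6·objective)`); because
   interior-point primal iterates are not objective-monotone, the solver
   tracks the incumbent (best-so-far) trend and reports that monotone
   objective history. On 10⁴-sample axes the solve takes ≲0.5 s and closes
   the duality gap to ~1e-9 relative.
3. **Stationary segmentation.** Feature windows are cut only inside
   approximately stationary stretches to avoid spectral edge artefacts.
   Changepoints of the detrended magnitude ‖acc‖ are found by binary
   segmentation under the Gaussian mean+variance cost `n·log σ̂²`, with a
   BIC-style penalty `10·log n` per split (vectorized over split points, so
   the search is O(n log n)); segments shorter than 2 s are merged into their
   shorter neighbour. The segmenter is pluggable (`segmenter=` callback) for
   higher-fidelity replacements such as switching-autoregressive models.

## Window features (45 = 15 × 3 axes)

Per axis of each 2-s window (100 samples), in frozen order: standard
deviation; band power in 0.3–2, 4–8, 8–12, 0.2–14 Hz; dominant-peak
frequency and height in the same four bands; sample entropy; spectral
entropy. All spectral quantities come from a single Hann-tapered periodogram
(0.5 Hz bins; Welch averaging is impossible inside a single 2-s window).
Band masks are half-open `[lo, hi)` so the printed sub-bands stay disjoint
and nest inside 0.2–14 Hz. SampEn uses the field-standard `m=2,
r=0.2·SD` with Chebyshev distance and self-matches excluded; degenerate
conventions: constant window → 0 (detected by exact range, not floating
SD); no length-m+1 matches → the cap `−log(2/((N−m−1)(N−m)))`. Spectral
entropy is the Shannon entropy of the periodogram mass over 0.2–25 Hz (DC
excluded) normalized by `log(#bins)`. Features are z-scored; the default is
fold-safe (statistics fitted on training subjects only), with a
`global_normalization` switch for the global variant that pools all subjects.

Mixed windows at annotation boundaries: a window takes the class covering
>50% of its span; a sub-class tag (and the prototype flag) requires a single
sub-class covering ≥90%; windows with no majority class are excluded. This
mapping is a package decision — continuous annotations do not dictate one.

## Prototype inference (MAP-DP)

Each sub-class λ — seven tremor movement phenotypes T1–T7 and seven
daily-life activities N1–N7 — is summarised by a diagonal Gaussian Dirichlet
process mixture with a Normal-inverse-Gamma prior per dimension
(`σ² ~ InvGamma(a₀, b₀)`, `μ|σ² ~ N(m₀, σ²/κ₀)`). Inference is MAP by
iterated conditional modes on the collapsed assignments: a point joins the
cluster maximizing `log N_k` plus the Student-t posterior-predictive log
density (with the point removed), or opens a new cluster at `log α` plus the
prior predictive. Each update cannot decrease the collapsed log posterior,
so sweeps terminate at a fixed point (capped at 30 sweeps; the hot loop is
numba-compiled). The first pass assigns points sequentially, opening
clusters as the data demands — starting from a single all-points cluster is
itself an ICM fixed point on well-separated data and must be avoided. The
update order is a pinned seeded shuffle (the inference is order-dependent;
reshuffling changes the recovered K in <5% of runs on planted mixtures).

Hyperparameters are selected per sub-class by maximizing the complete-data
log-likelihood over a small grid: α ∈ {0.1, 1, 10}, b₀ ∈ {0.1, 1, 10} ×
pooled per-dimension variance, m₀ = pooled mean, κ₀ = 0.01, a₀ = 1 (ties →
smallest α). The pooled variance is floored at 1% of the global data
variance so singleton prototype groups — which carry no scale of their
own — still get a usable prior, and fitted component variances are floored
at 2% of the global variance for the same reason. Components smaller than 3
points are merged into their nearest neighbour to avoid near-singular
Mahalanobis metrics. Tremor sub-classes use prototype-flagged windows only;
non-tremor sub-classes use all labelled windows of the sub-class. Each
converged component becomes one RBF basis (center = posterior mean, scale =
MAP variance `b_n/(a_n+3/2)`), so the total basis count `K = ΣK(λ)` is
inferred, not fixed.

## The networks

An RBF basis activates as the Gaussian of the Mahalanobis distance,
`ρ(x) = exp(−d²/2)`, `d² = Σ_j (x_j−c_j)²/s_j`, bounded in (0, 1] (floored
at the smallest normal float against exp underflow).

**Basis bandwidth.** For points drawn from a component, `d²` under the raw
component variances concentrates near the dimension (a chi-square effect):
every activation collapses toward `exp(−dim/2)` and gradients vanish — the
dilution that motivates the two-layer architecture in the first place. The
basis variances are therefore multiplied by a bandwidth `3·dim` in the
metric (config-exposed), which maps within-component distances to O(1).

**Single layer.** Activations of the K bases in the 45-dim feature space are
combined linearly and passed through a softmax; weights are fitted by
l2-regularized logistic likelihood (`SingleLayerRBFNet(y, X, basis).fit()`).
The binary two-column softmax is mathematically a logistic on the score
difference; the logistic parametrization is used.

**Two layer.** `φ¹: R⁴⁵ → R^M` (M = 15) uses K(1) inducing points (default
30) as isotropic Gaussian bases with a shared small scale `s1` (median
pairwise distance of the selected points × 0.5). Inducing points are chosen
greedily by GP posterior-variance reduction under an isotropic Gaussian
kernel — a deterministic informative-vector-machine-style criterion whose
first pick is the kernel medoid and which never picks a duplicate while
distinct candidates remain. `φ²: R^M → R²` applies prototype bases refitted
by MAP-DP in the embedding space, followed by a softmax.

Training alternates, to sidestep the vanishing gradient of stacked RBF
layers:

1. gradient step on the internal embeddings, `X* ← X* − η ∂E/∂X*`, with the
   cross-entropy loss `E` and the closed-form chain rule through
   `ρ(d(X*, C²))`;
2. least-squares recovery of the first-layer weights, `W¹ = pinv(Φ¹)X*`
   (SVD-based `lstsq`, which is the Moore–Penrose solution and survives rank
   deficiency);
3. recompute `X* = Φ¹W¹`, refresh the second-layer bases every R = 10
   iterations by re-embedding the prototype rows through the updated `φ¹`
   and refitting the per-sub-class DPMs (hyperparameters selected once and
   cached), then one gradient step on `W²` with the same η. Across each
   basis refresh the learned decision function is carried over: `W²` is
   re-mapped by least squares so the new activations reproduce the
   pre-refresh scores (a change of basis must not discard the training
   progress, which a fresh random `W²` would).

`W¹` is initialized from the principal components of the inducing points
(PCA projection of X gives `X*₀`, then step 2; the eigenvectors themselves
have shape D×M and cannot literally be the K(1)×M weight matrix). `W²` is
seeded standard normal. Stopping: relative loss change < 1e-5 or 500
iterations; η defaults to 0.5 with halving backoff whenever a
(non-refresh) step increases the loss — at η = 0.05 the softmax weights
move at O(η·Φ²) per step and convergence needs thousands of iterations.
η = 0 degenerates to an immediate stop at the initialization. Divergence
(loss above 10× initial) raises with diagnostics.

## Evaluation protocol

Leave-one-subject-out: the held-out subject contributes nothing — prototype
windows included — to normalization, basis fitting, training, or threshold
selection. The decision threshold targets a training specificity of ~0.95:
among candidate thresholds (midpoints of sorted unique scores), the one with
specificity closest to 0.95 wins, ties broken toward higher sensitivity,
with a fallback flag when no candidate lands inside the (0.945, 0.955) band.
Sensitivity and AUROC aggregate over folds whose test subject has tremor
windows; specificity over all folds (mean and SD across folds). Stratified
tables report per-tremor-sub-class sensitivity (over prototype-tagged
windows of the sub-class) and per-activity specificity, with cells absent —
not zero — when a fold lacks the sub-class. Baselines: l2 logistic
regression with inverse-class-frequency weights, and a random forest with
`class_weight="balanced_subsample"` (the closest available analogue of
class-balanced bootstrap resampling). Learning curves sample training
windows cumulatively (each duration's sample is a superset of the previous)
and report mean AUROC per duration. Agreement between predicted and
annotated per-subject tremor seconds uses Pearson R with a Fisher-z 80% CI
and ICC(2,1) — two-way random effects, absolute agreement, single measure —
with McGraw–Wong F-based 80% CIs. At n = 8 and ρ = 0.8 the Fisher-z
interval over-covers its nominal level by about 2 points (small-sample bias
of the z transform); the acceptance checks measure this rather than assume
nominal coverage.

## Synthetic cohort generator

The generator emulates the statistical structure the method assumes, not
physiology. Per subject: gravity (1 g) with piecewise-linear orientation
drift; an activity schedule cycling through the non-tremor sub-classes (gait
~1.8 Hz with harmonics; broadband transitions; running 2.5–3 Hz at high
amplitude; biking ~1 Hz plus vibration; "suspicious" periodic 3–5 Hz arm
movement as a deliberate confuser; band-limited upper-limb noise bursts;
rest); for tremor subjects, episodes with a stable per-subject fundamental
in 4–7 Hz plus a 2f harmonic, amplitude-modulated by an exponentiated
Ornstein–Uhlenbeck process (correlation time 5 s — bursty episodes without
claiming kinematic fidelity), mixed across axes by fixed per-sub-class
vectors, with gait superposed for tremor-during-gait; white sensor noise.
Every interval is annotated; the first clean interval per sub-class and
subject plus a random 40% share is flagged prototypical. Cohorts are pure
functions of (config, master seed) via counter-based per-subject seeds.

Defaults mirror the study population the generator stands in for: 8
subjects with tremor, 16 without, 24 controls; tremor amplitude 0.08–0.15 g
against a 0.02 g noise floor (only relative SNR matters; no quantitative
amplitude statistics exist to match). The `easy` preset raises tremor
amplitude to 0.12–0.20 g and removes N5 confusers; `hard` lowers amplitude
to 0.035–0.06 g and draws confusers at tremor-adjacent 3.5–5 Hz.

What passing tests on this generator show: the pipeline recovers planted
oscillatory structure, separates tremor from periodic confusers when given
per-sub-class prototypes, and respects the no-leakage evaluation contract.
What they do not show: robustness to real tremor heterogeneity
(re-emergent/postural/action subtypes), real device artefacts, annotation
noise, or medication-state dynamics — none of which the generator emulates.

## Problem sizes

End-to-end checks and `scripts/acceptance.py` run reduced cohorts — 7
subjects (3 tremor / 2 without / 2 controls) × 300 s — chosen so a full
LOSO evaluation of every model completes in minutes on one core while every
sub-class still appears in several folds. The package defaults remain the
full 48-subject × 600 s configuration.

## Known limitations

- MAP-DP is a point estimate of a DPM; K is order-dependent (pinned seed)
  and no posterior uncertainty over the bases is propagated.
- The decision threshold is population-level; per-subject calibration would
  likely improve individual specificity.
- Windows are classified independently; no temporal smoothing or sequential
  model (e.g. an HMM over window states) is applied.
- The basis bandwidth multiplier is a fixed heuristic (3·dim), not learned.
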