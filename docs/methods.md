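# Methods

## Signal model and preprocessing

Segments are single-lead amplitude series in mV with sampling rate fs
(any fs ≥ 100 Hz works; 200/300/512 Hz are typical).  Preprocessing is a
cascade of a 2nd-order Butterworth high-pass at 1 Hz (baseline wander)
and a 4th-order low-pass at 40 Hz (EMG and mains residue), applied
forward–backward.  Zero-phase filtering doubles the effective order and
squares the magnitude response; the stated orders are those of the
one-pass prototypes, the standard convention.  Segments shorter than the
forward–backward warm-up length are rejected rather than padded.
Filtering is applied to whole segments before windowing, so window edges
see no filter transients.

No resampling is performed: all lag-based quantities downstream are
defined in milliseconds, which makes mixed sampling rates commensurable
without interpolation of the signal itself.

## Autocorrelation features

Windows are 5 s with 80% overlap, anchored at sample 0; a trailing
remainder shorter than one step is discarded.  Each window's ACF is the
*biased linear* autocorrelation of the mean-removed window — computed by
inverting the periodogram of the zero-padded window (Wiener–Khinchin),
which equals the direct lag sum Σₜ xₜxₜ₊τ — normalised by its lag-0
value and truncated to lags 0–250 ms.  Choices worth spelling out:

- **Linear, not circular.** Circular autocorrelation would mix opposite
  ends of the window; zero-padding to the next power of two ≥ 2n
  prevents wrap-around.
- **Mean removal** is numerical hygiene: the signal is already
  high-passed at 1 Hz, but a residual offset would otherwise leak into
  all lags.
- **Normalisation by lag 0** makes every feature invariant to positive
  amplitude scaling, so electrode gain differences between devices
  cannot move the feature point.
- **Biased estimator.** The (1 − τ/T) taper of the biased estimator is
  at most 5% over 250 ms of a 5-s window and keeps the ACF bounded by 1.

Feature definitions and degenerate cases:

- *FMin*: per window, the first interior index with a strict decrease
  from the left and non-strict increase to the right (plateaus resolve
  to their first sample); 250 ms fallback when no interior minimum
  exists.  Segment value = minimum over windows.
- *MAmp*: per window, the signed ACF value at 35 ms, linearly
  interpolated when 35 ms is off the lag grid (e.g. fs = 300 Hz);
  segment value = maximum over windows.  Signed, not absolute: the
  flat-line signature is ACF ≈ +1, which the signed maximum preserves.
- *Sim*: maximum pairwise Euclidean distance between window ACFs
  restricted to on-grid lags in [30, 115] ms (bounds inclusive, off-grid
  bounds snap inward).  Single-window segments return 0 (no pairs).
- *Flat-line convention*: an exactly constant window has no defined ACF;
  it is assigned ACF ≡ 1, the limit of perfect self-similarity, so FMin
  hits the 250 ms fallback and MAmp is 1.  A fully flat segment maps to
  (250, 1, 0).

## Base classifier

Soft-margin RBF SVM on the 3-D feature points.  Features are z-scored
with training-set statistics stored in the model; the raw axes mix
milliseconds (FMin ∈ (0, 250]) with unitless quantities (|MAmp| ≤ 1), and
an isotropic RBF kernel is meaningless across such ranges.  The same
scaler is reused for adaptation data so the base and adapted weight
vectors live in one space.

The dual box QP is solved by sequential minimal optimisation with
second-order working-set selection (maximal violating pair refined by
the largest dual decrease), stopping at a violating-pair gap of 1e-8, so
KKT conditions hold well within 1e-6.  The bias comes from free support
vectors (0 < α < C) when any exist, else from the midpoint rule.  Ties
at decision value exactly 0 map to +1 (clean).

Hyperparameters (C, γ) are tuned by a seeded scrambled-Sobol search of a
fixed budget (default 30 evaluations) over the log-uniform box
[10⁻³, 10³]², scoring mean 5-fold stratified CV balanced accuracy.  A
space-filling quasi-random design was preferred over a model-based
optimiser: at budget ~30 on a 2-D box the two perform comparably, and
the Sobol design is trivially deterministic.  Tuning is done once per
training set (not re-tuned per fold), which slightly favours optimistic
CV scores; the cross-dataset results do not depend on it since those
models are evaluated on data never seen by the search.  No per-class
weighting is applied at the base stage — class imbalance is handled at
the adaptation stage by balanced subsets.

## Transfer learning

Writing w̃ = w + v, the adaptation objective
½‖v‖² + D Σ c̃ₖ ξ̃ₖ dualises into the same box QP as the base SVM with
linear term pₖ = 1 − ỹₖ f_base(x̃ₖ) (the base decision value *without*
bias) and box [0, D·c̃ₖ]; one solver therefore serves both problems.
The adapted decision function is the base kernel expansion (without its
bias) plus the adaptation expansion plus a new bias b̃.

- b̃ is free in the optimisation (no penalty toward the base bias).  It
  is recovered from free adaptation support vectors; when none exist —
  notably in the D → 0 limit, where all α̃ collapse onto their vanishing
  box — it falls back to the base bias, which makes the adapted model
  degenerate exactly to the base model.
- Adaptation features are standardized with the **base** model's scaler;
  re-estimating the scaler would silently change the meaning of ‖w̃−w‖.
- c̃ₖ = 1 throughout (subsets are class-balanced by construction); the
  argument stays in the interface for imbalanced use.
- D defaults to 100, appropriate for adaptation sets larger than ~10
  points; no automatic D selection is attempted.

Correctness of both solvers is pinned by primal-oracle tests: on small
instances the objective value of the returned solution must match an
independent SLSQP solve of the primal (in representer form) to 1e-5.

## Entropy-based subset selection

Quadratic Rényi entropy of a point set is estimated as
Hr = −log((1/N²)·1ᵀΩ1) with Gaussian kernel entries
Ωᵢⱼ = exp(−‖xᵢ−xⱼ‖²/2σ²); Hr = 0 for identical points and → log N for
well-separated ones.  The bandwidth σ defaults to the median pairwise
distance of the pool (median heuristic) — scale-free and standard for
kernel density surrogates — and entropy is computed on standardized
features so the kernel is isotropic in the space the classifier sees.

Fixed-size selection starts from a uniform subset of size P and
repeatedly proposes swapping a uniform member against a uniform
non-member, accepting only strict entropy increases (ties rejected).
The subset kernel sum is maintained incrementally, so a proposal costs
O(P) kernel evaluations.  The loop runs at most 1000 proposals and stops
early after a run of consecutive rejections as long as
max(pool, P·(pool−P)) — a rejection window comparable to the number of
distinct exchange moves, below which "no more increase" cannot credibly
be declared.  Balanced selection runs the procedure independently per
class with size P/2.

## Evaluation harness

Stratified, seeded k-fold plans (k = 5); stratification is a deliberate
choice given prevalences as skewed as 3% noisy.  Folds are segment-level
rather than patient-level, so intra-dataset CV numbers are optimistic in
the presence of per-subject correlation; cross-dataset numbers are not
affected.  Sensitivity is the detection rate of clean (+1) segments,
specificity of noisy (−1) segments; bAcc = (Se+Sp)/2 by definition, and
the identity is asserted on every report.  Paired t-tests are two-sided
with α = 0.05; identical vectors give t = 0, p = 1, while zero-variance
non-zero differences raise instead of fabricating infinite t.  Display
rounding is one decimal, half-up; files keep raw values.

The learning-curve experiment draws, for every (subset size, sampling
method, repetition), one balanced subset of the target training pool,
adapts every source fold-model with it and evaluates on every target
test fold.  One master seed derives all subset seeds through fixed
spawn keys, so the full grid is reproducible run-to-run; folds are drawn
once and only subsets are re-drawn across repetitions.

## Synthetic data

Two tiers serve different tests:

- **Signal level.**  Clean ECG is a per-beat sum of five Gaussian waves
  (P 0.12 mV/−200 ms/25 ms; Q −0.12/−40/10; R 1.0/0/12; S −0.25/+30/10;
  T 0.30/+250/45; offsets relative to R, widths as Gaussian σ) on an RR
  grid with per-beat jitter (σ = 30 ms at 60 bpm), plus 10 µV of
  broadband noise.  Artefact classes: flat line (zeros), electrode-motion
  transients (8–20× signal SD, 20 ms narrow or 300–600 ms wide Gaussian
  pulses that *replace* the signal over their support — a transient
  drives the amplifier, so the ECG is invisible beneath it), EMG-band
  20–40 Hz noise, low-frequency baseline excursions, amplitude clipping,
  and "floating" records (AR(1), ρ = 0.995 coloured noise replacing the
  whole signal — device on, no subject).  Severity in (0, 1] scales both
  the corrupted fraction and the artefact amplitude.  Profile presets
  fix the clean fraction at 0.968 (sleep-lab-like), 0.623
  (handheld-like) and 0.195 (capacitive-like, floating-heavy artefact
  mix).
- **Feature level.**  Gaussian mixtures per class directly in
  (FMin, MAmp, Sim).  Source defaults: clean N((35, −0.45, 0.6),
  diag(8, 0.14, 0.4)²), noisy N((90, 0.15, 2.8), diag(40, 0.3, 1.1)²),
  62.3% clean.  Target defaults: clean shifted to (25, −0.55, 0.35)
  with 1.3× covariance, noisy at N((55, −0.15, 1.3),
  diag(15, 0.2, 0.6)²), 19.5% clean.  The target noisy class sits
  *between* the source classes: capacitive artefacts look far more
  clean-like in ACF features than contact artefacts, while the target
  classes remain mutually separable.  This is precisely the covariate
  shift that collapses a source-trained model's specificity yet is
  recoverable by adaptation.  Draws are clipped to the feature domain
  (FMin ∈ [1, 250], |MAmp| ≤ 1, Sim ≥ 0); n = 600 source and 3000 target
  points by default, the latter sized so a training pool holds ≥ 250
  clean points at 19.5% prevalence (enough for P = 500 balanced
  subsets).

What the generator does *not* emulate: per-subject beat-morphology
correlation (so segment-level folds carry no leakage penalty here),
arrhythmia, multi-lead structure, and real capacitive coupling physics.
Passing tests therefore demonstrate the correctness and the qualitative
transfer behaviour of the method, not clinical performance on real
recordings.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale by design: QP-oracle
comparisons on ≤ 20-point instances (SLSQP is the bottleneck, not SMO);
the covariate-shift benchmark at 600 source / 3000 target points with 10
repetitions; signal-level pipelines on tens of 10–15 s segments.  The
SMO solver handles the full 500-point adaptation sets in well under a
second.  Numerical tolerances: KKT gap 1e-8 at the solver, 1e-5
primal-objective agreement in oracle tests, 1e-6 for stationarity-based
feature identities.

## Known limitations

- The WFDB reader/writer covers a minimal single-signal format-16
  subset, enough for round-tripping generated records; it is not a
  general WFDB implementation.
- Hyperparameter search is quasi-random rather than model-based; with
  much larger budgets a Bayesian optimiser would be more
  sample-efficient.
- No probability calibration, multi-class support, or non-RBF kernels.
- Entropy-based selection favours feature-space extremes; on the
  synthetic benchmark (and in the motivating studies) it raises subset
  entropy without a matching gain in classification performance.
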