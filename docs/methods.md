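# Methods notes

This note documents the models, numerical choices and known limitations of
`pupilmem`, in the order data flow through the pipeline.

## Recall-error model and estimation

Signed errors live on (−180°, 180°], with the +180° boundary kept positive
so an exactly opposite response has a defined sign. The mixture density is

    p(e) = (1 − p_u) · exp(κ cos e) / (2π I₀(κ)) + p_u / (2π),

evaluated through the exponentially scaled Bessel function `i0e` so that
κ up to ~10⁴ neither overflows nor loses precision; κ = 0 reduces exactly
to the circular uniform. The likelihood is maximised over
(logit p_u, log κ) with L-BFGS-B from a deterministic 3 × 3 grid of starts
(p_u ∈ {0.1, 0.5, 0.9} × κ ∈ {2, 8, 32}); the transform makes the inner
problem unconstrained while raw-scale bounds κ ∈ [0.5, 500] and
p_u ∈ [10⁻⁴, 1 − 10⁻⁴] keep degenerate solutions representable (pure
guessing fits land at p_t ≈ 10⁻⁴, not at an error). Tests verify the fit
never falls below a 200 × 200 brute-force grid search on the same data.

At 42 trials per condition — the operating point of the intended study —
the MLE is noisy: across replicates the median recovered p_t carries a
small upward bias (~+0.01) and the median κ a few percent bias; the
recovery tests print the observed bias rather than hiding it. With p_u at
its bounds the crossover threshold is undefined; the classifier then
returns sentinel values (0 = nothing classed correct, ∞ = everything)
with a warning. As p_u → 0 at fixed κ the threshold grows toward the
half-circle and reaches the ∞ sentinel once the von Mises component
dominates at 180° itself (p_u below ≈ e^(−2κ)).

Trial classification uses the threshold from the fit to errors pooled
across all participants and conditions (condition-wise thresholds are
available but not the default); ties at the threshold count as correct.
Trial-level precision is 1/|error| with |error| clamped at 0.5°, so a
perfect response maps to the finite cap 2.0 deg⁻¹.

## Behavioural exclusions

Chance-level performance is a mean absolute error of 75° or more — the
threshold is inclusive — against an expectation of 90° under pure
guessing. The outlier screen on condition-wise estimates uses the sample
(n − 1) SD and flags values beyond 2.5 SDs of their condition mean; note
that in very small groups a single extreme value inflates the SD enough to
escape flagging (e.g. {1,1,1,1,100} has z ≈ 1.8). Misclassified study
trials are dropped once, centrally, before fitting and before all pupil
analyses; a participant left with fewer than 10 trials in either
condition (a configurable default — the minimum that gives the
two-parameter fit any stability) is excluded from fitting.

## Pupil preprocessing and epoching

The chain order is fixed: foreshortening hook → blink interpolation →
zero-phase low-pass → epoching → QC → baseline correction. The
foreshortening hook is a pass-through accepting an externally corrected
trace; the geometric correction for eye rotation is applied upstream of
this package and is deliberately not re-implemented.

Blink gaps (device-invalid runs) are widened by 100 ms before onset and
400 ms after offset and filled by linear interpolation between the nearest
valid neighbours; edge gaps extend the nearest valid value. Samples
outside the widened windows are bit-identical to the input, and the raw
validity mask is preserved for QC. Filtering is a 10-Hz fourth-order
Butterworth applied forward and backward (zero phase, squared magnitude
response); traces shorter than the filter's padding requirement raise an
error naming the minimum length.

Epochs are 0.2-s half-open windows [start, start + 0.2) — exactly 8
samples at 40 Hz: pre-item (before item onset), choice (after the choice
display, corrected by subtracting the trial's pre-item mean) and the
anticipation change (final 0.2 s minus first 0.2 s of the anticipation
period). An epoch with > 50% invalid raw samples (strictly greater —
exactly half survives) is excluded; surviving epochs have samples more
than 3 SDs from the epoch mean removed in a single pass, computed on the
interpolated and filtered samples (one of several defensible choices;
documented here because it is a choice). Flagged epochs carry NaN.
Carry-over covariates (previous-trial condition, current fixation
duration) are attached for use as nuisance regressors. Manual artifact
inspection has no automated equivalent here; residual artifacts are left
to the 3-SD screen.

## Statistics

Paired contrasts are classical two-tailed t-tests on differences;
zero-variance differences raise rather than returning NaN. The JZS Bayes
factor uses the Cauchy(0, r) prior on standardized effect size
(default r = 0.707), written as a normal scale mixture so BF₁₀ is a
one-dimensional integral over the variance multiplier, evaluated by
adaptive quadrature at 10⁻¹⁰ relative tolerance in a ratio form that stays
well-scaled at large |t|; tests check agreement with an independent
implementation to 10⁻⁶ relative. Evidence labels use band edges 3 / 10 /
100 (moderate / strong / decisive, for either direction).

Where the full analysis would use mixed-effects models, the package ships
a transparent two-stage analogue — per-participant OLS, then a one-sample
t-test on the slopes — and exports tidy tables so mixed models can be fit
with external tools. The RT-on-pupil summary includes condition as a
covariate: anticipatory dilation differs by condition, so a pupil-only
regression would absorb the condition RT offset into the slope.

## Synthetic-data generator

Defaults encode the study conditions the pipeline targets: 36
participants, 84 trials in six blocks, conditions balanced within block,
targets on distinct multiples of 4° with the paired dot 180° away,
fixation 3–6 s and anticipation 2–4 s uniform, 40-Hz pupillometry,
condition mixture parameters (p_t, κ) = (0.58, 13.67) reward /
(0.55, 17.02) neutral, anticipatory dilation 0.10 vs 0.03 mm, RT 378 vs
422 ms with sd 50 ms, RT coupling −30 ms per mm of anticipatory dilation,
93% study-phase classification accuracy, and a staircase targeting 70%
positive feedback.

Values the conditions do not pin down were chosen once as plausible for
this kind of recording and are documented in `SimConfig`: participant
baseline diameter 5.7 ± 0.3 mm, slow sinusoidal drift (0.05 mm at
0.05 Hz), white measurement noise 0.02 mm, trial-level dilation-amplitude
sd 0.10 mm with a 0.06-mm participant-by-condition random effect, a
0.02-mm decaying carry-over after reward trials, blinks as a 0.1-Hz
Poisson process with 100–400-ms durations (invalid samples set to NaN).
The dilation ramp is held flat over the first and last 0.2 s of the
anticipation window so the epoching change-measure equals the generative
amplitude exactly in the noise-free limit. Von Mises samples come from
numpy's generator (Best–Fisher rejection sampling).

The deadline staircase is a weighted up–down rule: after positive feedback
the deadline tightens by 10 ms, after negative it relaxes by
10 · p/(1 − p) ms, whose equilibrium hit rate is the target p (23.3 ms for
p = 0.70); deadlines are clamped to [150, 1500] ms. Feedback is +15c /
−10c on reward trials and always 0c on neutral trials.

What the generator does not emulate: real pupil dynamics (no impulse
response convolution, no luminance effects), eye-position foreshortening,
non-stationary RT effects (fatigue, learning), item memorability
structure, or recognition/confidence responses (lure trials are out of
scope). Passing tests therefore demonstrate that the analysis recovers
the generative structure it assumes, not that real data satisfy those
assumptions.

## Problem sizes and determinism

Tests and the acceptance script run at the study's own scale or below:
parameter recovery uses 35 participants × 42 trials per condition,
calibration checks use up to 10⁵ draws, and the end-to-end slope recovery
uses the full 36 × 84 study. Under these conditions some recovery
quantities have sampling variability comparable to their assessment
bands: the median recovered p_t varies with sd ≈ 0.02 across seeds, and
the group RT~pupil slope with sd ≈ 9 ms/mm (comparable to the width of the
interval the underlying trial-level estimate is known with). Fixed-seed
checks of these quantities therefore probe a single draw from a
distribution that is itself validated by the larger calibration tests.

Every random stage draws from `numpy` Generators seeded via
`SeedSequence` from a single configured seed; identical configurations
reproduce identical tables and traces bit for bit, and pipeline outputs
(CSV with fixed float formatting, JSON with sorted keys) are
byte-identical across reruns.
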