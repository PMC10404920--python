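# Methods

This note documents the models, estimators and numerical choices behind
`avcue`, and what the synthetic-data generator does and does not emulate.

## Task and units

All positions are proportions of screen width in [0, 1]; 0.5 is the screen
centre. The session is three blocks: a visual calibration block (90 trials
each of a low-variance, sd 0.05, and a high-variance, sd 0.2, four-dot
cloud; 10 repeats at each of nine locations), an audio training block
(90 trials), and a test block with 405 single-cue trials (15 × 9 locations
× 3 cues), 270 congruent double-cue trials (15 × 9 × 2 pairings) and 400
incongruent trials (10 repeats of the 20 ordered unequal pairs of the five
"intermittent" locations 0.37, 0.43, 0.5, 0.57, 0.63, for each pairing).
The nine locations are only constrained to be "approximately evenly
spaced" between 0.37 and 0.63; we default to
{0.37, 0.40, 0.43, 0.47, 0.50, 0.53, 0.57, 0.60, 0.63}, which contains the
intermittent five, and make the set configurable. Feedback (target
position, full dot cloud, and a score s = 1000·(1 − ((h−g)/0.1)²) floored
at 0) is withheld exactly on incongruent trials. The hidden location of an
incongruent trial is defined, for bookkeeping only, as the audio source.
A config switch (`left_hemisphere_only`) restricts conflict stimuli to
locations ≤ 0.5, to replicate sessions collected with a known
presentation bug; it is off by default and reduces the incongruent count
(the full design is the default deliverable).

## Stimuli

Dot clouds are drawn from a standard normal and then standardized so that
the *sample* mean equals the nominal centre and the sample s.d. (n−1
denominator) equals the nominal spread exactly, per draw — not merely in
expectation. Extrinsic noise is one shift z ~ N(0, σ_E²) per trial applied
to all dots, so the centroid (the effective visual cue location x_V) is
centre + z. Stimuli whose shifted dots would leave the screen are redrawn
whole; redraws are counted and are rare for in-range parameters. Timing
and rendering are not modelled.

## Synthetic observers

An observer has perceptual noise s.d.s (σ_vis_low, σ_vis_high, σ_aud),
central-tendency weight w_P, optional motor noise, an extrinsic
sensitivity λ ∈ [0, 1], and a strategy. Percepts are x̃ = x + noise; the
double-cue core estimate is the weighted average with

  w = σ_A² / (σ_A² + σ_vis² + λ·σ_E²·[cue is intrinsic+extrinsic])

or, under the switching strategy, with probability p_switch a single
modality's percept (visual with probability w). The response is
(1 − w_P)·core + 0.5·w_P + motor noise, clipped to [0, 1]. λ = 1 is the
optimal observer, λ = 0 one fully blind to extrinsic noise.

Motor noise defaults to zero: the perceptual/motor split is not
identifiable from single-cue data, and with σ_motor = 0 the single-cue
variable error equals the perceptual s.d., which is exactly the
reliability input the analysis uses. The central-tendency weight is
applied identically in all blocks and conditions.

Default cohort ranges (uniform draws per observer): σ_vis_low 0.03–0.05,
σ_vis_high 0.07–0.10 (so the derived σ_E² is strictly positive),
σ_aud 0.06–0.11 (auditory localization between the two visual cues),
w_P 0.10–0.35. These are plausible psychophysical magnitudes for a
localization task on this scale and give conflict-trial noise σ_n well
inside its prior support. The generator reproduces the statistical
structure the analysis assumes; it does **not** emulate learning dynamics
across the session, attention lapses, response time, or spatially
inhomogeneous (e.g. eccentricity-dependent) noise — so passing tests
validate the estimators under the model's assumptions, not those aspects
of real data.

## Calibration and the central-tendency correction

The extrinsic variance injected for the rest of a session is
σ_E² = σ_H² − σ_L², from the calibration-block variable errors; a negative
difference is a per-observer calibration failure and raises. The naive
variable error (s.d. of response − target) is biased under a central
tendency pull: the response model r = (1 − w_P)·t + 0.5·w_P + (1 − w_P)·ε
implies a regression slope b = 1 − w_P and residual s.d. (1 − w_P)·σ, so
the corrected estimator fits r on t by least squares and reports
ŵ_P = 1 − b and σ̂ = sd(residuals)/b (residual s.d. with ddof = 2; a
warning fires when b ≤ 0.1, where the rescaling is unstable). The exact
published form of this correction was not available to us; this
slope-attenuation interpretation (pull toward 0.5, noise entering before
the pull) is our design choice and is stated as such. The naive estimator
is kept behind `calibration_method="naive"` because the original study's
online calibration used it — selecting it reproduces the resulting
mis-calibration of the intrinsic+extrinsic cue downstream.

Note the naive estimator is not simply shrunk by (1 − w_P): its expectation
mixes shrunk noise with target-spread leakage,
sqrt(((1−w_P)σ)² + w_P²·Var(t)), which our tests verify.

## Conflict-trial model and sampler

Incongruent responses are modelled per observer × pairing as
r = (1 − ŵ_P)(ŵ_V x_V + (1 − ŵ_V) x_A) + 0.5 ŵ_P + ε, ε ~ N(0, σ_n²),
with x_V, x_A treated as fixed regressors (for a linear-Gaussian model,
adding percept-level noise does not change the mean estimates; a
measurement-error variant would, and is out of scope). Priors: ŵ_P, ŵ_V
uniform on [0, 1]; σ_n uniform on [0.001, 0.2]. Schedule: three
independent chains, inits ŵ_P = ŵ_V = 0.5, σ_n = 0.01, 1000 burn-in
iterations, 4000 recorded draws per chain thinned to every 5th proposal.
The point estimate is the mean of the per-chain expected values.

The sampler is an adaptive random-walk Metropolis: joint Gaussian
proposals, scales tuned toward ≈30% acceptance during burn-in only and
frozen afterwards (so the recording-phase kernel is a fixed, valid MH
kernel); proposals outside the prior support are rejected. Convergence is
monitored by split-chain R̂ (threshold 1.05) on every parameter;
non-convergence is flagged on the fit and surfaced by the pipeline, never
silent. Validation is three-fold: parameter recovery on model-generated
data, 95% credible-interval coverage over replicate fits, and agreement
with the closed-form least-squares fit of the same mean function
(reparameterised as r − 0.5 = a(x_V − 0.5) + b(x_A − 0.5) with
w_P = 1 − a − b, w_V = a/(a+b)).

The switching variant adds p_switch ~ Uniform(0, 1): with probability
p_switch the trial mean is a single modality's centrally-pulled location
((1 − ŵ_P)x + 0.5ŵ_P — central tendency is a response-stage effect, so it
applies to switched reports too), visual with probability ŵ_V; otherwise
the averaging mean. Averaging and switching produce the same mean weight
but different response variance, which is what identifies p_switch.

Credible intervals are equal-tailed (posteriors are near-symmetric here;
HDIs would add complexity without benefit). Interval summaries can carry a
reference value (the optimal weight, or 0/1 for a best-single-modality
strategy) and an exclusion indicator.

## Weight predictions and group statistics

Per observer, single-cue variable errors in the test block (corrected
estimator) give σ_I, σ_IE, σ_A; the optimal predictions are
w = σ_A²/(σ_cue² + σ_A²), and the suboptimal-insensitive prediction
substitutes the calibration-block low-cue error σ_L. Group-level
comparisons: two-sided paired t-tests (with a JZS default-prior Bayes
factor, Cauchy scale √2/2, computed by numerical integration — the choice
of Bayes-factor convention is ours), Pearson correlations, and Wilcoxon
signed-rank tests (exact p for n ≤ 25 without ties, continuity-corrected
normal approximation otherwise; zero differences dropped, ties
mid-ranked). The bimodal-advantage analysis compares each observer's
congruent double-cue variable error to the better of their two single-cue
errors; with well-matched reliabilities optimal averaging predicts up to a
1/√2 reduction, and with badly mismatched reliabilities the advantage is
often undetectable at cohort sizes of ~30 — both regimes are exercised in
tests. In synthetic cohorts with matched noise ranges the advantage is
typically significant in both pairings, which real datasets (with poorer
reliability matching) need not show.

## Problem sizes and tolerances

The validation suite uses the study's own scales where that is cheap
(n = 200 conflict trials per pairing matches 400 incongruent trials split
over two pairings; qualitative-replication cohorts use 30 observers with
λ ∈ [0.4, 0.6]), and reduced MCMC schedules (e.g. 1200 kept draws, thin 2)
for replicate-heavy checks such as interval coverage, where 30 replicates
give a binomial tolerance of ±5 percentage points around the nominal 95%.
Parameter-recovery assertions average over a few replicate datasets so
they measure estimator bias rather than single-draw noise; sampler-vs-
oracle agreement is asserted within 3 posterior s.d.

## Known limitations

- The central-tendency correction assumes the pull is toward 0.5 and that
  perceptual noise enters before the pull; other decompositions exist.
- The conflict model treats cue locations as fixed regressors; a full
  generative (measurement-error) fit is not implemented.
- Causal-inference models for large cue conflicts are out of scope; the
  weighting model presumes mandatory fusion, valid for small
  discrepancies.
- Group Bayes factors depend on the prior convention; only their
  qualitative evidence category is meaningful across conventions.
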