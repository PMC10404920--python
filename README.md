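# avcue

Audio-visual cue combination under intrinsic and extrinsic uncertainty:
experiment-design generation, synthetic observers, extrinsic-noise
calibration, Bayesian weight fitting, and group-level analysis for a
multisensory localization task.

## The scientific problem

When a location is signalled by two redundant cues — a visual dot cloud and
a co-localized sound — an ideal observer combines them by
reliability-weighted averaging, giving the visual estimate the weight

&nbsp;&nbsp;&nbsp;&nbsp; w_V = σ_A² / (σ_V² + σ_A²)

where σ_V² and σ_A² are the variances of the unimodal location estimates.
The interesting question is *which* variance observers account for.
**Intrinsic** uncertainty lives inside the perceptual system (noise in
localizing the centroid of a dot cloud or a noise burst); **extrinsic**
uncertainty lives in the world — here, a Gaussian shift z ~ N(0, σ_E²) of
the whole dot cloud away from the true target, which can only be learned
from feedback. An observer who is blind to the extrinsic component should
weight the shifted cue as if it were the reliable low-variance cloud
(the *suboptimal insensitive* prediction, w = σ_A²/(σ_L² + σ_A²)); a
partially sensitive observer lands between that and the optimal weight.

This package implements the whole analysis chain for a session consisting
of a visual calibration block (90 trials each of a low- and a high-variance
dot cloud), an audio training block (90 trials), and a test block of 405
single-cue, 270 congruent and 400 incongruent (cue-conflict) trials. The
extrinsic variance is calibrated per observer as σ_E² = σ_H² − σ_L² from
the calibration-block variable errors, with a correction for the central
tendency bias (responses pulled toward the screen centre 0.5), which
otherwise under-estimates variable error.

Empirical weights are estimated from the conflict trials by fitting

&nbsp;&nbsp;&nbsp;&nbsp; r = (1 − ŵ_P)(ŵ_V x_V + (1 − ŵ_V) x_A) + 0.5 ŵ_P + ε,&nbsp;&nbsp; ε ~ N(0, σ_n²)

per observer and cue pairing with an MCMC sampler (uniform priors, three
chains, 1000 burn-in, 4000 kept draws thinned by 5; point estimate = mean
of per-chain means), plus a mixture variant that adds a probability
``p_switch`` of reporting a single modality instead of averaging
(probability matching). A closed-form least-squares fit of the same mean
function serves as a deterministic cross-check of the sampler.

## Worked example

```python
from avcue import CohortSpec, PipelineConfig, run_pipeline

config = PipelineConfig(
    cohort=CohortSpec(n_observers=10, lambda_ext=(0.4, 0.6)),  # partially sensitive
    fit_switching=False,
    outdir="avcue_output",
    seed=11,
)
report = run_pipeline(config)
print(report.summary)
```

prints (exact output for this seed):

```
avcue pipeline report
seed: 11   observers: 10   calibration: corrected

Group contrasts (empirical minus predicted visual weight):
  I_empirical_vs_optimal: t(9)=-1.642, p=0.1349, BF10=0.853
  IE_empirical_vs_optimal: t(9)=6.992, p=6.384e-05, BF10=419
  IE_empirical_vs_insensitive: t(9)=-8.018, p=2.174e-05, BF10=1.06e+03

Correlations with predictions:
  I_corr_optimal: r=0.936, p=6.659e-05
  IE_corr_optimal: r=0.954, p=1.877e-05
  IE_corr_insensitive: r=0.824, p=0.003339

  optimal weight outside 95% CI (I): 3/10
  optimal weight outside 95% CI (IE): 9/10
  bimodal_advantage_I: W=0.0, p=0.001953, median diff=0.0188
  bimodal_advantage_IE: W=0.0, p=0.001953, median diff=0.0170
```

Reading it: observers whose extrinsic sensitivity λ is drawn from
0.4–0.6 weight the intrinsic-only visual cue indistinguishably from the
optimal prediction (first contrast, p > 0.05), but **over**-weight the
intrinsic+extrinsic cue relative to optimal (second contrast, positive t)
while still weighting it **below** the fully-insensitive prediction (third
contrast, negative t) — the signature of partial accounting for extrinsic
uncertainty. Empirical weights correlate strongly with the predictions,
and combining congruent cues reduces variable error below the best single
modality (the bimodal advantage). All artifacts (response tables,
calibration, per-observer fits, group statistics, this report) are written
to ``outdir``.

The same pipeline is available from the shell:

```bash
avcue all --seed 11 --outdir avcue_output
```

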