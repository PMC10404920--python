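"""Synthetic observers for the localization task.

An observer forms noisy percepts of the cue locations (per-modality Gaussian
perceptual noise), combines them according to a strategy — reliability-based
weighted averaging, or random switching between modalities — and responds
with a central-tendency pull toward the screen centre (0.5) plus optional
motor noise:

    g = (1 - wP) * core + 0.5 * wP + N(0, sigma_motor^2)

The weighting an observer applies to the intrinsic+extrinsic visual cue
depends on its *believed* extrinsic variance, ``lambda_ext * sigmaE2``:
``lambda_ext = 1`` is a fully (optimally) sensitive observer, ``0`` one that
is completely blind to the extrinsic noise, intermediate values are
partially sensitive.

The default partition of response variability puts everything in the
perceptual terms (``sigma_motor = 0``): single-cue variable error then
equals perceptual noise, which is the reliability input the analysis uses.
The perceptual/motor split is not identifiable from single-cue data anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import CalibrationError, calibrate_observer
from .design import (
    Block,
    Condition,
    CueKind,
    DesignConfig,
    TrialSpec,
    make_design,
)
from .stimuli import make_trial_cloud, score, visual_centroid

__all__ = [
    "ObserverParams",
    "CohortSpec",
    "draw_cohort",
    "effective_weight",
    "simulate_response",
    "simulate_study",
]


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one synthetic observer.

    All noise parameters are standard deviations in screen-width proportion
    units. ``w_p`` is the central-tendency weight, ``lambda_ext`` the
    extrinsic-sensitivity, ``p_switch`` the per-trial probability of
    reporting a single modality instead of the weighted average (used by the
    ``switching`` strategy).
    """

    sigma_vis_low: float
    sigma_vis_high: float
    sigma_aud: float
    w_p: float = 0.0
    sigma_motor: float = 0.0
    strategy: str = "weighted_average"
    lambda_ext: float = 1.0
    p_switch: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma_vis_low", "sigma_vis_high", "sigma_aud", "sigma_motor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("w_p", "lambda_ext", "p_switch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.strategy not in ("weighted_average", "switching"):
            raise ValueError(f"unknown strategy {self.strategy!r}")

    def perceptual_sd(self, visual_cue: CueKind) -> float:
        """Perceptual noise s.d. for locating a given visual cue's centroid."""
        if visual_cue is CueKind.VIS_INTRINSIC:
            return self.sigma_vis_high
        return self.sigma_vis_low

    def believed_extrinsic_variance(self, sigmaE2: float) -> float:
        """The observer's internal estimate of the extrinsic variance."""
        return self.lambda_ext * sigmaE2


def effective_weight(params: ObserverParams, visual_cue: CueKind, sigmaE2: float = 0.0) -> float:
    """Visual weight the observer applies when the cue is paired with audio.

    w = sigmaA^2 / (sigmaA^2 + sigma_vis^2 + lambda_ext * sigmaE2)

    where the extrinsic term enters only for the intrinsic+extrinsic cue.
    For ``lambda_ext = 1`` this is the reliability-optimal weight given the
    true cue variances; for ``lambda_ext = 0`` it ignores the extrinsic
    noise entirely.
    """
    sigma_vis2 = params.perceptual_sd(visual_cue) ** 2
    if visual_cue is CueKind.VIS_INTR_EXTR:
        sigma_vis2 += params.believed_extrinsic_variance(sigmaE2)
    denom = params.sigma_aud**2 + sigma_vis2
    if denom == 0:
        raise ValueError("weight undefined: all cue variances are zero")
    return params.sigma_aud**2 / denom


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def simulate_response(
    trial: TrialSpec,
    x_v: float | None,
    x_a: float | None,
    params: ObserverParams,
    rng: np.random.Generator,
    sigmaE2: float = 0.0,
) -> dict:
    """One trial's response record.

    ``x_v`` is the visual centroid actually shown (source + extrinsic shift),
    ``x_a`` the audio location. Percepts get per-modality Gaussian noise, the
    core estimate follows the observer's strategy, and the response applies
    the central-tendency transform, motor noise, and clipping to [0, 1].
    """
    vis_cue = trial.visual_cue
    if vis_cue is not None and x_v is None:
        raise ValueError("visual cue present but no visual stimulus supplied")
    if trial.has_audio and x_a is None:
        raise ValueError("audio cue present but no audio location supplied")
    if vis_cue is None and not trial.has_audio:
        raise ValueError("trial has no cues")

    percept_v = percept_a = None
    if vis_cue is not None:
        percept_v = x_v + rng.normal(0.0, params.perceptual_sd(vis_cue))
    if trial.has_audio:
        percept_a = x_a + rng.normal(0.0, params.sigma_aud)

    if percept_v is not None and percept_a is not None:
        try:
            w = effective_weight(params, vis_cue, sigmaE2)
        except ValueError:
            w = 0.5  # all variances zero: equal-variance limit
        if params.strategy == "switching" and rng.random() < params.p_switch:
            core = percept_v if rng.random() < w else percept_a
        else:
            core = w * percept_v + (1.0 - w) * percept_a
    else:
        core = percept_v if percept_v is not None else percept_a

    g = (1.0 - params.w_p) * core + 0.5 * params.w_p
    if params.sigma_motor > 0:
        g += rng.normal(0.0, params.sigma_motor)
    g = _clip01(g)

    def _num(v):
        return np.nan if v is None else v

    return dict(
        block=trial.block.value,
        trial=trial.index,
        condition=trial.condition.value,
        cues="+".join(sorted(c.value for c in trial.cues)),
        visual_cue=vis_cue.value if vis_cue is not None else np.nan,
        hidden=trial.hidden,
        visual_source=_num(trial.visual_source),
        audio_loc=_num(trial.audio_loc),
        x_v=_num(x_v),
        x_a=_num(x_a),
        percept_v=_num(percept_v),
        percept_a=_num(percept_a),
        response=g,
        score=score(trial.hidden, g),
        feedback=trial.feedback,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Uniform ranges from which observer parameters are drawn.

    The default ranges give low-cue visual noise of a few percent of screen
    width, high-cue visual noise several times larger (so the derived
    extrinsic variance is strictly positive), auditory noise between the
    two, and a moderate central-tendency pull — the regime the task design
    presumes.
    """

    n_observers: int = 30
    sigma_vis_low: tuple[float, float] = (0.03, 0.05)
    sigma_vis_high: tuple[float, float] = (0.07, 0.10)
    sigma_aud: tuple[float, float] = (0.06, 0.11)
    w_p: tuple[float, float] = (0.10, 0.35)
    lambda_ext: tuple[float, float] = (1.0, 1.0)
    p_switch: tuple[float, float] = (0.0, 0.0)
    sigma_motor: float = 0.0
    strategy: str = "weighted_average"


def draw_cohort(spec: CohortSpec, seed: int | np.random.Generator = 0) -> list[ObserverParams]:
    """Draw a cohort of observers from the spec's uniform ranges."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cohort = []
    for _ in range(spec.n_observers):
        cohort.append(
            ObserverParams(
                sigma_vis_low=rng.uniform(*spec.sigma_vis_low),
                sigma_vis_high=rng.uniform(*spec.sigma_vis_high),
                sigma_aud=rng.uniform(*spec.sigma_aud),
                w_p=rng.uniform(*spec.w_p),
                sigma_motor=spec.sigma_motor,
                strategy=spec.strategy,
                lambda_ext=rng.uniform(*spec.lambda_ext),
                p_switch=rng.uniform(*spec.p_switch),
            )
        )
    return cohort


def _simulate_block(
    trials: list[TrialSpec],
    params: ObserverParams,
    config: DesignConfig,
    sigmaE2: float,
    rng: np.random.Generator,
) -> list[dict]:
    rows = []
    for t in trials:
        x_v = x_a = None
        vis_cue = t.visual_cue
        if vis_cue is not None:
            sd = config.sd_high if vis_cue is CueKind.VIS_INTRINSIC else config.sd_low
            s2 = sigmaE2 if vis_cue is CueKind.VIS_INTR_EXTR else 0.0
            cloud, z, _ = make_trial_cloud(t.visual_source, sd, s2, config.n_dots, rng)
            x_v = visual_centroid(cloud, z)
        if t.has_audio:
            x_a = t.audio_loc
        rows.append(simulate_response(t, x_v, x_a, params, rng, sigmaE2))
    return rows


def simulate_study(
    config: DesignConfig,
    cohort: list[ObserverParams],
    seed: int = 0,
    calibration_method: str = "corrected",
    sigmaE2_override: float | list[float] | None = None,
    include_latent: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full study for a cohort of observers.

    Mirrors the experimental procedure: each observer runs the calibration
    block, their extrinsic variance sigmaE2 is derived from their own
    calibration responses (``calibration_method``: 'corrected' or 'naive' —
    the latter replicates the original online calibration, which is biased
    under central tendency), then the audio-training and test blocks are
    simulated with that sigmaE2 injected into the intrinsic+extrinsic cue.

    ``sigmaE2_override`` bypasses calibration with a known true value (one
    float, or one per observer). Returns ``(responses, calibration)`` tidy
    tables; fully reproducible from ``seed``.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if calibration_method not in ("corrected", "naive"):
        raise ValueError(f"unknown calibration method {calibration_method!r}")

    all_rows: list[dict] = []
    calib_rows: list[dict] = []
    for i, params in enumerate(cohort):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 100 + i]))
        obs_config = config.with_seed(int(np.random.default_rng(
            np.random.SeedSequence([int(seed), 200 + i])).integers(2**31)))
        blocks = make_design(obs_config)

        cal_rows = _simulate_block(blocks[Block.CALIBRATION], params, obs_config, 0.0, rng)
        cal_df = pd.DataFrame(cal_rows)
        if sigmaE2_override is not None:
            s2 = sigmaE2_override[i] if isinstance(sigmaE2_override, (list, tuple, np.ndarray)) else sigmaE2_override
            s2 = float(s2)
            result = None
        else:
            try:
                result = calibrate_observer(cal_df, method=calibration_method)
            except CalibrationError as err:
                raise CalibrationError(f"observer {i}: {err}") from err
            s2 = result.sigmaE2

        aud_rows = _simulate_block(blocks[Block.AUDIO_TRAINING], params, obs_config, 0.0, rng)
        test_rows = _simulate_block(blocks[Block.TEST], params, obs_config, s2, rng)

        for r in cal_rows + aud_rows + test_rows:
            r["observer"] = i
        all_rows.extend(cal_rows + aud_rows + test_rows)

        calib_rows.append(
            dict(
                observer=i,
                method=calibration_method if sigmaE2_override is None else "override",
                sigma_low=result.sigma_low if result else np.nan,
                sigma_high=result.sigma_high if result else np.nan,
                w_p_low=result.w_p_low if result else np.nan,
                w_p_high=result.w_p_high if result else np.nan,
                sigmaE2=s2,
            )
        )

    responses = pd.DataFrame(all_rows)
    cols = ["observer"] + [c for c in responses.columns if c != "observer"]
    responses = responses[cols]
    if not include_latent:
        responses = responses.drop(columns=["percept_v", "percept_a"])
    return responses, pd.DataFrame(calib_rows)
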