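"""End-to-end driver: simulate -> calibrate -> fit -> group statistics.

The pipeline reproduces the study's analysis chain on any cohort (synthetic
by default, or a loaded response table):

1. simulate the three-block session per observer, deriving each observer's
   extrinsic variance from their own calibration responses;
2. estimate single-cue variable errors in the test block (central-tendency
   corrected) to form optimal and suboptimal-insensitive weight predictions;
3. fit the conflict-trial model (and optionally the switching variant) per
   observer and cue pairing by MCMC;
4. compare empirical weights to the predictions at the group level and run
   the bimodal-advantage analysis.

Every artifact is written alongside the config and master seed, so a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import corrected_variable_error
from .conflict_model import (
    ConflictModelFit,
    credible_interval,
    fit_conflict_model,
    fit_switching_model,
    optimal_weight,
    suboptimal_insensitive_weight,
)
from .design import CueKind
from .io import PipelineConfig, write_response_table
from .observers import draw_cohort, simulate_study
from .stats import GroupResult, bimodal_advantage, paired_t, pearson_r

__all__ = ["PipelineReport", "run_pipeline", "compute_weight_table", "fit_cohort"]

log = logging.getLogger("avcue")

#: pairing label -> visual cue in that audio-visual pairing
PAIRINGS = {"I": CueKind.VIS_INTRINSIC, "IE": CueKind.VIS_INTR_EXTR}


@dataclass
class PipelineReport:
    responses: pd.DataFrame
    calibration: pd.DataFrame
    weights: pd.DataFrame
    fits: pd.DataFrame
    group: dict[str, GroupResult]
    summary: str
    seed: int


def _corrected_sigma(sub: pd.DataFrame) -> float:
    _, sigma = corrected_variable_error(sub["response"].to_numpy(), sub["hidden"].to_numpy())
    return sigma


def compute_weight_table(
    responses: pd.DataFrame,
    calibration: pd.DataFrame,
) -> pd.DataFrame:
    """Per-observer reliability inputs and weight predictions.

    Single-cue variable errors are estimated from the test block with the
    central-tendency correction (sigma_I, sigma_IE, sigma_A); the
    suboptimal-insensitive prediction uses the calibration-block low-cue
    error instead of the full intrinsic+extrinsic one.
    """
    test = responses[responses["block"] == "test"]
    rows = []
    for obs, obs_df in test.groupby("observer"):
        single = obs_df[obs_df["condition"] == "single"]
        sigma = {}
        for label, cue in (("I", "VIS_INTRINSIC"), ("IE", "VIS_INTR_EXTR"), ("A", None)):
            if cue is None:
                sub = single[single["cues"] == "AUD"]
            else:
                sub = single[single["visual_cue"] == cue]
            if len(sub) < 10:
                raise ValueError(f"observer {obs}: too few single-cue trials for {label}")
            sigma[label] = _corrected_sigma(sub)
        cal = calibration[calibration["observer"] == obs]
        if cal.empty:
            raise ValueError(f"observer {obs}: no calibration record")
        sigma_low = float(cal["sigma_low"].iloc[0])
        rows.append(
            dict(
                observer=obs,
                sigma_I=sigma["I"],
                sigma_IE=sigma["IE"],
                sigma_A=sigma["A"],
                sigma_low_calib=sigma_low,
                w_opt_I=optimal_weight(sigma["I"] ** 2, sigma["A"] ** 2),
                w_opt_IE=optimal_weight(sigma["IE"] ** 2, sigma["A"] ** 2),
                w_subopt_IE=suboptimal_insensitive_weight(sigma_low**2, sigma["A"] ** 2),
            )
        )
    return pd.DataFrame(rows)


def _fit_seed(master: int, observer: int, pairing: str, model: str) -> int:
    salt = {"I": 1, "IE": 2}[pairing] * 10 + {"averaging": 1, "switching": 2}[model]
    ss = np.random.SeedSequence([int(master), 400 + int(observer), salt])
    return int(ss.generate_state(1)[0] % (2**31))


def fit_cohort(responses: pd.DataFrame, config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Fit the conflict model(s) for every observer x pairing.

    Returns a tidy fits table and a dict of fit objects keyed by
    ``(observer, pairing, model)``.
    """
    incong = responses[(responses["block"] == "test") & (responses["condition"] == "incongruent")]
    rows = []
    fit_objects: dict[tuple, ConflictModelFit] = {}
    models = ["averaging"] + (["switching"] if config.fit_switching else [])
    for obs, obs_df in incong.groupby("observer"):
        for pairing, vis_cue in PAIRINGS.items():
            trials = obs_df[obs_df["visual_cue"] == vis_cue.value]
            for model in models:
                cfg = replace(config.mcmc, seed=_fit_seed(config.seed, obs, pairing, model))
                fitter = fit_conflict_model if model == "averaging" else fit_switching_model
                fit = fitter(trials, cfg)
                if not fit.converged:
                    log.warning(
                        "fit stage: observer %s pairing %s model %s did not converge (rhat=%s)",
                        obs, pairing, model, fit.rhat,
                    )
                fit_objects[(obs, pairing, model)] = fit
                cis = credible_interval(fit, config.credible_level)
                for name in fit.param_names:
                    rows.append(
                        dict(
                            observer=obs,
                            pairing=pairing,
                            model=model,
                            param=name,
                            estimate=fit.point_estimates[name],
                            sd=fit.posterior_sd[name],
                            ci_lower=cis[name].lower,
                            ci_upper=cis[name].upper,
                            rhat=fit.rhat[name],
                            converged=fit.converged,
                            n_trials=fit.n_trials,
                        )
                    )
    return pd.DataFrame(rows), fit_objects


def _congruent_variable_errors(responses: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-pairing tables (visual, audio, bimodal variable error) per observer."""
    test = responses[responses["block"] == "test"]
    out = {}
    for pairing, vis_cue in PAIRINGS.items():
        rows = []
        for obs, obs_df in test.groupby("observer"):
            single = obs_df[obs_df["condition"] == "single"]
            vis = single[single["visual_cue"] == vis_cue.value]
            aud = single[single["cues"] == "AUD"]
            cong = obs_df[(obs_df["condition"] == "congruent") & (obs_df["visual_cue"] == vis_cue.value)]
            if min(len(vis), len(aud), len(cong)) < 10:
                raise ValueError(f"observer {obs}: missing condition for bimodal analysis")
            rows.append(
                dict(
                    observer=obs,
                    visual=_corrected_sigma(vis),
                    audio=_corrected_sigma(aud),
                    bimodal=_corrected_sigma(cong),
                )
            )
        out[pairing] = pd.DataFrame(rows)
    return out


def _headline_stats(weights: pd.DataFrame, fits: pd.DataFrame, fit_objects: dict, level: float) -> tuple[dict, pd.DataFrame]:
    w_emp = (
        fits[(fits["model"] == "averaging") & (fits["param"] == "w_v")]
        .pivot(index="observer", columns="pairing", values="estimate")
        .rename(columns={"I": "w_emp_I", "IE": "w_emp_IE"})
    )
    weights = weights.merge(w_emp, on="observer")

    group: dict[str, GroupResult] = {}
    group["I_empirical_vs_optimal"] = paired_t(weights["w_emp_I"], weights["w_opt_I"])
    group["IE_empirical_vs_optimal"] = paired_t(weights["w_emp_IE"], weights["w_opt_IE"])
    group["IE_empirical_vs_insensitive"] = paired_t(weights["w_emp_IE"], weights["w_subopt_IE"])
    group["I_corr_optimal"] = pearson_r(weights["w_emp_I"], weights["w_opt_I"])
    group["IE_corr_optimal"] = pearson_r(weights["w_emp_IE"], weights["w_opt_IE"])
    group["IE_corr_insensitive"] = pearson_r(weights["w_emp_IE"], weights["w_subopt_IE"])

    # individual-level classification: is the optimal weight (or a
    # best-single-modality weight of 0/1) outside each observer's interval?
    for pairing, opt_col in (("I", "w_opt_I"), ("IE", "w_opt_IE")):
        excl_opt, excl_best = [], []
        for _, row in weights.iterrows():
            fit = fit_objects[(row["observer"], pairing, "averaging")]
            best_modality_w = 1.0 if row[f"sigma_{pairing}"] < row["sigma_A"] else 0.0
            cis = credible_interval(fit, level, references={"w_v": row[opt_col]})
            excl_opt.append(cis["w_v"].reference_excluded)
            ci_best = credible_interval(fit, level, references={"w_v": best_modality_w})
            excl_best.append(ci_best["w_v"].reference_excluded)
        weights[f"opt_outside_ci_{pairing}"] = excl_opt
        weights[f"best_single_outside_ci_{pairing}"] = excl_best
    return group, weights


def run_pipeline(config: PipelineConfig, responses: pd.DataFrame | None = None,
                 calibration: pd.DataFrame | None = None, write: bool = True) -> PipelineReport:
    """Run the full analysis; see module docstring for the stages.

    If ``responses``/``calibration`` are supplied the simulation stage is
    skipped (e.g. for externally collected data read via
    :func:`avcue.io.read_response_table`).
    """
    outdir = Path(config.outdir)
    if responses is None:
        log.info("simulate stage: %d observers", config.cohort.n_observers)
        cohort = draw_cohort(config.cohort, np.random.default_rng(
            np.random.SeedSequence([int(config.seed), 1])))
        responses, calibration = simulate_study(
            config.design, cohort, seed=config.seed,
            calibration_method=config.calibration_method,
        )
    elif calibration is None:
        raise ValueError("calibration table required when supplying responses")

    log.info("calibrate stage: weight predictions")
    weights = compute_weight_table(responses, calibration)

    log.info("fit stage: conflict model per observer x pairing")
    fits, fit_objects = fit_cohort(responses, config)

    log.info("analyze stage: group statistics")
    group, weights = _headline_stats(weights, fits, fit_objects, config.credible_level)

    errors = _congruent_variable_errors(responses)
    for pairing, table in errors.items():
        try:
            group[f"bimodal_advantage_{pairing}"] = bimodal_advantage(table)
        except ValueError as err:
            log.warning("analyze stage: bimodal advantage (%s) skipped: %s", pairing, err)

    if config.fit_switching:
        p_sw = fits[(fits["model"] == "switching") & (fits["param"] == "p_switch")]
        for pairing in PAIRINGS:
            vals = p_sw.loc[p_sw["pairing"] == pairing, "estimate"]
            group[f"mean_p_switch_{pairing}"] = GroupResult(
                "mean", int(vals.size), float(vals.mean()), float("nan"))

    summary = _render_summary(config, group, weights)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        write_response_table(responses, outdir / "responses.csv")
        calibration.to_csv(outdir / "calibration.csv", index=False)
        weights.to_csv(outdir / "weights.csv", index=False)
        fits.to_csv(outdir / "fits.csv", index=False)
        _group_frame(group).to_csv(outdir / "group_stats.csv", index=False)
        (outdir / "report.txt").write_text(summary)
        log.info("report stage: artifacts written to %s", outdir)
    return PipelineReport(
        responses=responses, calibration=calibration, weights=weights,
        fits=fits, group=group, summary=summary, seed=config.seed,
    )


def _group_frame(group: dict[str, GroupResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(name=k, test=v.test, n=v.n, statistic=v.statistic, df=v.df,
                 p_value=v.p_value, bf10=v.bf10, bf01=v.bf01,
                 median_difference=v.median_difference)
            for k, v in group.items()
        ]
    )


def _render_summary(config: PipelineConfig, group: dict[str, GroupResult], weights: pd.DataFrame) -> str:
    n = len(weights)
    lines = [
        "avcue pipeline report",
        f"seed: {config.seed}   observers: {n}   calibration: {config.calibration_method}",
        "",
        "Group contrasts (empirical minus predicted visual weight):",
    ]
    for key in ("I_empirical_vs_optimal", "IE_empirical_vs_optimal", "IE_empirical_vs_insensitive"):
        g = group[key]
        bf = f", BF10={g.bf10:.3g}" if g.bf10 is not None else ""
        lines.append(f"  {key}: t({g.df})={g.statistic:.3f}, p={g.p_value:.4g}{bf}")
    lines.append("")
    lines.append("Correlations with predictions:")
    for key in ("I_corr_optimal", "IE_corr_optimal", "IE_corr_insensitive"):
        g = group[key]
        lines.append(f"  {key}: r={g.statistic:.3f}, p={g.p_value:.4g}")
    lines.append("")
    for pairing in PAIRINGS:
        n_excl = int(weights[f"opt_outside_ci_{pairing}"].sum())
        lines.append(f"  optimal weight outside {int(config.credible_level*100)}% CI ({pairing}): {n_excl}/{n}")
    for pairing in PAIRINGS:
        key = f"bimodal_advantage_{pairing}"
        if key in group:
            g = group[key]
            lines.append(f"  {key}: W={g.statistic:.1f}, p={g.p_value:.4g}, median diff={g.median_difference:.4f}")
    for pairing in PAIRINGS:
        key = f"mean_p_switch_{pairing}"
        if key in group:
            lines.append(f"  {key}: {group[key].statistic:.3f}")
    return "\n".join(lines) + "\n"
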