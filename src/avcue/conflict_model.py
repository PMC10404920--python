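"""Cue weights: optimal predictions and Bayesian fitting of conflict trials.

On incongruent (cue-conflict) trials the visual and auditory cues signal
different locations, and the position of the response between them reveals
the empirical visual weight. Responses are modelled as

    r = (1 - wP) * (wV * xV + (1 - wV) * xA) + 0.5 * wP + eps,
    eps ~ N(0, sigma_n^2)

where ``wP`` is the central-tendency weight, ``wV`` the visual weight
(auditory weight = 1 - wV), ``xV`` the dot-cloud centroid and ``xA`` the
audio source location. A switching variant replaces the weighted average,
with probability ``p_switch``, by a single modality's (centrally-pulled)
percept — visual with probability ``wV``, auditory otherwise. Switching
mimics intermediate mean weights but inflates response variance, which is
what makes the two strategies distinguishable.

Posteriors are sampled with an adaptive random-walk Metropolis sampler run
as several independent chains under uniform priors (wP, wV, p_switch on
[0, 1]; sigma_n on [0.001, 0.2]). The default schedule keeps 4000 draws per
chain after 1000 burn-in iterations, thinning to every 5th proposal, and
the point estimate is the mean of the per-chain expected values. Since the
mean function is linear in the regressors, a closed-form least-squares fit
of the same model serves as a deterministic oracle for the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "optimal_weight",
    "suboptimal_insensitive_weight",
    "McmcConfig",
    "ConflictModelFit",
    "CredibleInterval",
    "fit_conflict_model",
    "fit_switching_model",
    "least_squares_oracle",
    "credible_interval",
]

RHAT_THRESHOLD = 1.05


def optimal_weight(sigma_vis2: float, sigma_aud2: float) -> float:
    """Reliability-optimal visual weight w = sigmaA^2 / (sigmaV^2 + sigmaA^2)."""
    if sigma_vis2 < 0 or sigma_aud2 < 0:
        raise ValueError("variances must be non-negative")
    denom = sigma_vis2 + sigma_aud2
    if denom == 0:
        raise ValueError("weight undefined: both variances are zero")
    return float(sigma_aud2 / denom)


def suboptimal_insensitive_weight(sigma_low_calib2: float, sigma_aud2: float) -> float:
    """Weight predicted for an observer blind to the extrinsic noise.

    Uses the *low-cue* variable error from the calibration block in place of
    the full intrinsic+extrinsic variance, so it always exceeds the optimal
    weight for that cue whenever sigmaE^2 > 0.
    """
    return optimal_weight(sigma_low_calib2, sigma_aud2)


@dataclass(frozen=True)
class McmcConfig:
    """Sampler schedule, initial values and prior supports."""

    n_chains: int = 3
    burn_in: int = 1000
    n_samples: int = 4000
    thin: int = 5
    init_w_p: float = 0.5
    init_w_v: float = 0.5
    init_sigma_n: float = 0.01
    init_p_switch: float = 0.5
    sigma_prior: tuple[float, float] = (0.001, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chains, self.burn_in, self.n_samples, self.thin) <= 0:
            raise ValueError("all schedule counts must be positive")
        if not self.sigma_prior[0] < self.sigma_prior[1]:
            raise ValueError("sigma prior bounds must be ordered")


@dataclass(frozen=True)
class ConflictModelFit:
    """Posterior draws and summaries for one observer x one cue pairing."""

    model: str
    param_names: tuple[str, ...]
    draws: dict  # name -> (n_chains, n_samples) array
    point_estimates: dict
    posterior_sd: dict
    rhat: dict
    converged: bool
    n_trials: int
    config: McmcConfig

    def flat(self, name: str) -> np.ndarray:
        """All chains concatenated for one parameter."""
        return self.draws[name].reshape(-1)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (via arviz)."""
    import arviz as az

    return float(az.rhat(az.convert_to_dataset(chains))["x"].values)


def _extract(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(trials, pd.DataFrame):
        x_v = trials["x_v"].to_numpy(dtype=float)
        x_a = trials["x_a"].to_numpy(dtype=float)
        r = trials["response"].to_numpy(dtype=float)
    else:
        x_v, x_a, r = (np.asarray(a, dtype=float) for a in trials)
    if x_v.size != x_a.size or x_v.size != r.size:
        raise ValueError("x_v, x_a and response must have equal length")
    if x_v.size < 10:
        raise ValueError(f"need at least 10 conflict trials, got {x_v.size}")
    if np.ptp(x_v) == 0 and np.ptp(x_a) == 0:
        raise ValueError("cue locations show no variation; weights unidentifiable")
    if np.any(np.isnan(x_v)) or np.any(np.isnan(x_a)) or np.any(np.isnan(r)):
        raise ValueError("NaN in conflict-trial inputs")
    return x_v, x_a, r


def _avg_loglik(x_v: np.ndarray, x_a: np.ndarray, r: np.ndarray):
    n = r.size

    def loglik(theta: np.ndarray) -> np.ndarray:
        w_p, w_v, s = theta[:, 0], theta[:, 1], theta[:, 2]
        mu = (1 - w_p)[:, None] * (w_v[:, None] * x_v + (1 - w_v)[:, None] * x_a) + 0.5 * w_p[:, None]
        sse = np.square(r - mu).sum(axis=1)
        return -n * np.log(s) - sse / (2.0 * s * s)

    return loglik


def _switch_loglik(x_v: np.ndarray, x_a: np.ndarray, r: np.ndarray):
    def loglik(theta: np.ndarray) -> np.ndarray:
        w_p, w_v, s, p = theta[:, 0], theta[:, 1], theta[:, 2], theta[:, 3]
        one_m_wp = (1 - w_p)[:, None]
        ct = 0.5 * w_p[:, None]
        mu_avg = one_m_wp * (w_v[:, None] * x_v + (1 - w_v)[:, None] * x_a) + ct
        mu_v = one_m_wp * x_v + ct
        mu_a = one_m_wp * x_a + ct
        inv2s2 = 1.0 / (2.0 * s * s)[:, None]
        log_s = np.log(s)[:, None]
        with np.errstate(divide="ignore"):
            la = np.log1p(-p)[:, None] - log_s - np.square(r - mu_avg) * inv2s2
            lv = np.log(p * w_v)[:, None] - log_s - np.square(r - mu_v) * inv2s2
            lw = np.log(p * (1 - w_v))[:, None] - log_s - np.square(r - mu_a) * inv2s2
        m = np.maximum(np.maximum(la, lv), lw)
        mix = m + np.log(np.exp(la - m) + np.exp(lv - m) + np.exp(lw - m))
        return mix.sum(axis=1)

    return loglik


def _run_metropolis(loglik, bounds: np.ndarray, init: np.ndarray, cfg: McmcConfig) -> np.ndarray:
    """Adaptive random-walk Metropolis, chains advanced in lockstep.

    Proposal scales are tuned toward ~30% acceptance during burn-in only,
    then frozen (so the post-burn-in kernel is a valid fixed MH kernel).
    Returns draws with shape (n_chains, n_samples, n_params).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 7]))
    n_chains, d = cfg.n_chains, init.size
    lo, hi = bounds[:, 0], bounds[:, 1]
    x = np.tile(np.clip(init, lo, hi), (n_chains, 1))
    ll = loglik(x)
    scales = np.tile(0.1 * (hi - lo), (n_chains, 1))
    draws = np.empty((n_chains, cfg.n_samples, d))
    n_iter = cfg.burn_in + cfg.n_samples * cfg.thin
    acc = np.zeros(n_chains)
    window = 0
    kept = 0
    steps = rng.standard_normal((n_iter, n_chains, d))
    log_u = np.log(rng.random((n_iter, n_chains)))
    for it in range(n_iter):
        prop = x + scales * steps[it]
        in_bounds = np.all((prop >= lo) & (prop <= hi), axis=1)
        if in_bounds.all():
            ll_prop = loglik(prop)
        else:
            ll_prop = np.full(n_chains, -np.inf)
            if in_bounds.any():
                ll_prop[in_bounds] = loglik(prop[in_bounds])
        accept = log_u[it] < ll_prop - ll
        x[accept] = prop[accept]
        ll[accept] = ll_prop[accept]
        acc += accept
        window += 1
        if it < cfg.burn_in and window == 50:
            rate = acc / window
            scales *= np.exp(0.6 * (rate - 0.3))[:, None]
            np.clip(scales, 1e-5, 1.0, out=scales)
            acc[:] = 0.0
            window = 0
        elif it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == cfg.thin - 1:
            draws[:, kept] = x
            kept += 1
    assert kept == cfg.n_samples
    return draws


def _summarise(model: str, names: tuple[str, ...], draws: np.ndarray, n_trials: int, cfg: McmcConfig) -> ConflictModelFit:
    by_name = {name: draws[:, :, j] for j, name in enumerate(names)}
    # point estimate = mean of the per-chain expected values
    point = {name: float(np.mean(arr.mean(axis=1))) for name, arr in by_name.items()}
    sd = {name: float(arr.std(ddof=1)) for name, arr in by_name.items()}
    rhat = {name: _split_rhat(arr) for name, arr in by_name.items()}
    converged = all(v < RHAT_THRESHOLD for v in rhat.values())
    return ConflictModelFit(
        model=model,
        param_names=names,
        draws=by_name,
        point_estimates=point,
        posterior_sd=sd,
        rhat=rhat,
        converged=converged,
        n_trials=n_trials,
        config=cfg,
    )


def fit_conflict_model(trials, cfg: McmcConfig | None = None) -> ConflictModelFit:
    """Fit the weighted-averaging conflict model to one observer's trials.

    ``trials`` is a DataFrame with columns ``x_v``, ``x_a``, ``response``
    (or a tuple of three arrays) for a single observer and cue pairing.
    """
    cfg = cfg or McmcConfig()
    x_v, x_a, r = _extract(trials)
    bounds = np.array([(0.0, 1.0), (0.0, 1.0), cfg.sigma_prior])
    init = np.array([cfg.init_w_p, cfg.init_w_v, cfg.init_sigma_n])
    draws = _run_metropolis(_avg_loglik(x_v, x_a, r), bounds, init, cfg)
    return _summarise("averaging", ("w_p", "w_v", "sigma_n"), draws, r.size, cfg)


def fit_switching_model(trials, cfg: McmcConfig | None = None) -> ConflictModelFit:
    """Fit the averaging/switching mixture model (adds ``p_switch``)."""
    cfg = cfg or McmcConfig()
    x_v, x_a, r = _extract(trials)
    bounds = np.array([(0.0, 1.0), (0.0, 1.0), cfg.sigma_prior, (0.0, 1.0)])
    init = np.array([cfg.init_w_p, cfg.init_w_v, cfg.init_sigma_n, cfg.init_p_switch])
    draws = _run_metropolis(_switch_loglik(x_v, x_a, r), bounds, init, cfg)
    return _summarise("switching", ("w_p", "w_v", "sigma_n", "p_switch"), draws, r.size, cfg)


def least_squares_oracle(trials) -> dict:
    """Closed-form least-squares estimates of (w_p, w_v, sigma_n).

    The mean function is linear after reparameterisation: with
    a = (1-wP) wV and b = (1-wP)(1-wV),

        r - 0.5 = a (xV - 0.5) + b (xA - 0.5) + eps

    so OLS through the origin on centred regressors recovers a and b, hence
    wP = 1 - (a + b) and wV = a / (a + b). Deterministic cross-check for the
    sampler (for a linear-Gaussian model both target the same mean).
    """
    x_v, x_a, r = _extract(trials)
    X = np.column_stack([x_v - 0.5, x_a - 0.5])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, r - 0.5, rcond=None)
    a, b = coef
    if a + b == 0:
        raise ValueError("degenerate fit: estimated total gain is zero")
    resid = (r - 0.5) - X @ coef
    sigma = float(np.std(resid, ddof=2))
    return {"w_p": float(1.0 - (a + b)), "w_v": float(a / (a + b)), "sigma_n": sigma}


@dataclass(frozen=True)
class CredibleInterval:
    lower: float
    upper: float
    level: float
    reference: float | None = None
    reference_excluded: bool | None = None


def credible_interval(
    fit: ConflictModelFit,
    level: float = 0.95,
    references: dict | None = None,
) -> dict[str, CredibleInterval]:
    """Equal-tailed posterior intervals per parameter.

    ``references`` maps parameter names to reference values (e.g. the
    optimal weight, or 0/1 for a best-single-modality strategy); the result
    records whether each reference falls outside its interval.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    alpha = (1.0 - level) / 2.0
    out = {}
    for name in fit.param_names:
        flat = fit.flat(name)
        lo, hi = np.quantile(flat, [alpha, 1.0 - alpha])
        ref = None if references is None else references.get(name)
        excluded = None if ref is None else bool(ref < lo or ref > hi)
        out[name] = CredibleInterval(float(lo), float(hi), level, ref, excluded)
    return out
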