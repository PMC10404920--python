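"""Single-cue variable error and the derived extrinsic-noise variance.

The calibration block measures how variable an observer's localization is
with the low- and high-variance visual cues (sigma_L, sigma_H). Their
squared difference defines the extrinsic noise added to the low cue for the
rest of the session:

    sigmaE^2 = sigma_H^2 - sigma_L^2

A central-tendency bias — responses pulled toward the middle of the
stimulus range (0.5) — attenuates the response-vs-target slope and makes
the naive error s.d. an *under*-estimate of perceptual variability. The
corrected estimator models the response as

    r = (1 - wP) * t + 0.5 * wP + (1 - wP) * noise

fits the slope b = 1 - wP by least squares, and rescales the residual
spread by 1/b. The naive estimator is retained behind a flag because the
original online calibration used it, which is exactly what produced the
study's variance mismatch between the intrinsic-only and
intrinsic+extrinsic conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationError",
    "CalibrationResult",
    "naive_variable_error",
    "corrected_variable_error",
    "extrinsic_variance",
    "calibrate_observer",
]


class CalibrationError(ValueError):
    """Raised when an observer's calibration cannot produce a valid sigmaE^2."""


@dataclass(frozen=True)
class CalibrationResult:
    """Per-observer calibration: corrected variable errors and sigmaE^2."""

    sigma_low: float
    sigma_high: float
    w_p_low: float
    w_p_high: float
    sigmaE2: float
    n_low: int
    n_high: int
    method: str = "corrected"


def naive_variable_error(responses, targets) -> float:
    """Sample s.d. (n-1 denominator) of response - target errors.

    A constant bias does not inflate it, but a central-tendency pull
    *deflates* it relative to true perceptual noise.
    """
    r = np.asarray(responses, dtype=float)
    t = np.asarray(targets, dtype=float)
    if r.shape != t.shape:
        raise ValueError("responses and targets must have equal length")
    if r.size < 2:
        raise ValueError("need at least 2 trials")
    return float(np.std(r - t, ddof=1))


def corrected_variable_error(responses, targets) -> tuple[float, float]:
    """Central-tendency-corrected variable error.

    Least-squares fit of r = a + b*t; returns ``(wP_hat, sigma_hat)`` with
    ``wP_hat = 1 - b`` and ``sigma_hat = s.d.(residuals) / b``. Warns when
    the slope is so shallow (b <= 0.1) that the rescaling is unstable.
    """
    r = np.asarray(responses, dtype=float)
    t = np.asarray(targets, dtype=float)
    if r.shape != t.shape:
        raise ValueError("responses and targets must have equal length")
    if np.unique(t).size < 2:
        raise ValueError("slope undefined: all targets identical")
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct target locations")
    b, a = np.polyfit(t, r, 1)
    if b <= 0.1:
        warnings.warn(
            f"response-vs-target slope b={b:.3f} <= 0.1; corrected variable "
            "error is unreliable",
            stacklevel=2,
        )
    resid = r - (a + b * t)
    sd_resid = float(np.std(resid, ddof=2)) if r.size > 2 else 0.0
    sigma_hat = sd_resid / b if b != 0 else np.inf
    return float(1.0 - b), float(sigma_hat)


def extrinsic_variance(sigmaL2: float, sigmaH2: float) -> float:
    """sigmaE^2 = sigmaH^2 - sigmaL^2; errors if the difference is negative."""
    if sigmaL2 < 0 or sigmaH2 < 0:
        raise ValueError("variances must be non-negative")
    out = sigmaH2 - sigmaL2
    if out < 0:
        raise CalibrationError(
            f"high-cue variance ({sigmaH2:.6g}) below low-cue variance "
            f"({sigmaL2:.6g}); observer cannot be calibrated"
        )
    return float(out)


def calibrate_observer(calibration_responses: pd.DataFrame, method: str = "corrected") -> CalibrationResult:
    """Calibration from one observer's calibration-block response table.

    Expects columns ``visual_cue`` (VIS_LOW / VIS_INTRINSIC), ``hidden`` and
    ``response``. ``method='corrected'`` applies the central-tendency
    correction; ``method='naive'`` uses the raw error s.d. (replicating the
    original online procedure).
    """
    if method not in ("corrected", "naive"):
        raise ValueError(f"unknown calibration method {method!r}")
    per_cue: dict[str, tuple[float, float, int]] = {}
    for cue in ("VIS_LOW", "VIS_INTRINSIC"):
        sub = calibration_responses[calibration_responses["visual_cue"] == cue]
        if len(sub) < 2:
            raise CalibrationError(f"no (or too few) calibration trials for {cue}")
        r, t = sub["response"].to_numpy(), sub["hidden"].to_numpy()
        if method == "corrected":
            w_p, sigma = corrected_variable_error(r, t)
        else:
            w_p, sigma = np.nan, naive_variable_error(r, t)
        per_cue[cue] = (w_p, sigma, len(sub))
    w_p_low, sigma_low, n_low = per_cue["VIS_LOW"]
    w_p_high, sigma_high, n_high = per_cue["VIS_INTRINSIC"]
    sigmaE2 = extrinsic_variance(sigma_low**2, sigma_high**2)
    return CalibrationResult(
        sigma_low=sigma_low,
        sigma_high=sigma_high,
        w_p_low=w_p_low,
        w_p_high=w_p_high,
        sigmaE2=sigmaE2,
        n_low=n_low,
        n_high=n_high,
        method=method,
    )
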