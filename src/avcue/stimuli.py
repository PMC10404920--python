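"""Dot-cloud stimuli, extrinsic shifts, and the trial score.

Dot clouds are standardized so that their *sample* moments are exact: the
four dot positions have sample mean equal to the nominal centre and sample
standard deviation (n-1 denominator) equal to the nominal spread, for every
draw. Extrinsic noise is a single Gaussian shift applied identically to all
dots of a trial's cloud, so the cloud centroid — the effective visual cue
location xV — is nominal centre + shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DotCloud",
    "generate_dot_cloud",
    "sample_extrinsic_shift",
    "score",
    "visual_centroid",
    "make_trial_cloud",
]

#: distance (screen-width proportion) at which the score reaches zero
SCORE_ZERO_DISTANCE = 0.1
MAX_SCORE = 1000.0


@dataclass(frozen=True)
class DotCloud:
    """A visual cue: n dot positions with exact first and second sample moments."""

    dots: tuple[float, ...]
    nominal_center: float
    nominal_sd: float

    @property
    def sample_mean(self) -> float:
        return float(np.mean(self.dots))

    @property
    def sample_sd(self) -> float:
        if len(self.dots) < 2:
            return 0.0
        return float(np.std(self.dots, ddof=1))


def generate_dot_cloud(
    center: float,
    sd: float,
    n_dots: int = 4,
    rng: np.random.Generator | None = None,
) -> DotCloud:
    """Draw standard-normal dot offsets and standardize them exactly.

    The raw draws are shifted and scaled so the sample mean is exactly
    ``center`` and the sample s.d. exactly ``sd`` (up to float rounding).
    Degenerate draws (all dots equal, standardization impossible) are
    redrawn.
    """
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    if n_dots < 2 and sd > 0:
        raise ValueError("need at least 2 dots for a non-zero spread")
    if rng is None:
        rng = np.random.default_rng()
    if sd == 0:
        return DotCloud(dots=(float(center),) * n_dots, nominal_center=center, nominal_sd=0.0)
    while True:
        raw = rng.standard_normal(n_dots)
        s = raw.std(ddof=1)
        if s > 0:
            break
    dots = (raw - raw.mean()) / s * sd + center
    return DotCloud(dots=tuple(float(d) for d in dots), nominal_center=float(center), nominal_sd=float(sd))


def sample_extrinsic_shift(sigmaE2: float, rng: np.random.Generator | None = None) -> float:
    """One Gaussian shift z ~ N(0, sigmaE2), shared by all dots of a cloud."""
    if sigmaE2 < 0:
        raise ValueError(f"extrinsic variance must be non-negative, got {sigmaE2}")
    if sigmaE2 == 0:
        return 0.0
    if rng is None:
        rng = np.random.default_rng()
    return float(rng.normal(0.0, np.sqrt(sigmaE2)))


def score(hidden: float, guessed: float) -> float:
    """Points awarded for a guess: s = 1000 (1 - ((h - g)/0.1)^2), floored at 0.

    The quadratic loss is scaled so the score is 1000 for a perfect guess and
    reaches 0 at a distance of 10% of the screen width.
    """
    h = float(hidden)
    g = float(guessed)
    if not (0.0 <= h <= 1.0 and 0.0 <= g <= 1.0):
        raise ValueError(f"positions must lie in [0, 1], got h={h}, g={g}")
    s = MAX_SCORE * (1.0 - ((h - g) / SCORE_ZERO_DISTANCE) ** 2)
    return max(0.0, s)


def visual_centroid(cloud: DotCloud, shift: float = 0.0) -> float:
    """Effective visual cue location xV: the cloud centre plus the extrinsic shift.

    By the exact-moment construction this equals the sample mean of the
    shifted dots.
    """
    return cloud.nominal_center + shift


def make_trial_cloud(
    center: float,
    sd: float,
    sigmaE2: float = 0.0,
    n_dots: int = 4,
    rng: np.random.Generator | None = None,
    max_redraws: int = 1000,
) -> tuple[DotCloud, float, int]:
    """Cloud + extrinsic shift for one trial, constrained to the screen.

    Returns ``(cloud, shift, n_redraws)``. If any shifted dot would leave
    [0, 1] the whole stimulus (cloud and shift) is redrawn, keeping the
    on-screen invariant; redraws are counted so callers can log them.
    """
    if rng is None:
        rng = np.random.default_rng()
    for attempt in range(max_redraws):
        cloud = generate_dot_cloud(center, sd, n_dots, rng)
        z = sample_extrinsic_shift(sigmaE2, rng)
        shifted = np.asarray(cloud.dots) + z
        if np.all((shifted >= 0.0) & (shifted <= 1.0)):
            return cloud, z, attempt
    raise RuntimeError(
        f"could not place a cloud at center={center} sd={sd} sigmaE2={sigmaE2} "
        f"within {max_redraws} draws"
    )
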