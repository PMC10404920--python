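"""Group-level comparisons of empirical and predicted cue weights.

Wraps the frequentist tests (paired t, Pearson correlation, Wilcoxon
signed-rank) and a default-prior (JZS) Bayes factor for the paired t-test,
and implements the bimodal-advantage analysis: does combining cues reduce
variable error below the best single modality?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

__all__ = [
    "GroupResult",
    "paired_t",
    "pearson_r",
    "bayes_factor_paired_t",
    "wilcoxon_signed_rank",
    "bimodal_advantage",
]


@dataclass(frozen=True)
class GroupResult:
    """One group-level test: statistic, p, and (where computed) Bayes factors."""

    test: str
    n: int
    statistic: float
    p_value: float
    df: int | None = None
    bf10: float | None = None
    bf01: float | None = None
    median_difference: float | None = None


def _as_diffs(x, y=None) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if y is None:
        return x
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return x - y


def paired_t(empirical, predicted, with_bf: bool = True) -> GroupResult:
    """Two-sided paired t-test on empirical - predicted differences."""
    d = _as_diffs(empirical, predicted)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            # identical vectors: no effect, p = 1 by convention
            return GroupResult("paired_t", n, 0.0, 1.0, df=n - 1,
                               median_difference=0.0)
        raise ValueError("zero variance of differences")
    t, p = sps.ttest_rel(np.asarray(empirical, float), np.asarray(predicted, float))
    bf10 = bf01 = None
    if with_bf:
        bf10, bf01 = bayes_factor_paired_t(d)
    return GroupResult(
        "paired_t", n, float(t), float(p), df=n - 1, bf10=bf10, bf01=bf01,
        median_difference=float(np.median(d)),
    )


def pearson_r(x, y) -> GroupResult:
    """Pearson correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return GroupResult("pearson_r", x.size, float(res.statistic), float(res.pvalue),
                       df=x.size - 2)


def bayes_factor_paired_t(differences, cauchy_scale: float = np.sqrt(2) / 2) -> tuple[float, float]:
    """JZS (Cauchy-prior) Bayes factor for a one-sample/paired t-test.

    Numerical integration of the Rouder et al. default-prior marginal
    likelihood ratio: the effect size gets a Cauchy(0, ``cauchy_scale``)
    prior, equivalently g ~ InverseGamma(1/2, scale^2/2) on the
    normalised effect variance. Returns ``(BF10, BF01)``.
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 differences")
    sd = np.std(d, ddof=1)
    t = 0.0 if sd == 0 else float(np.mean(d) / (sd / np.sqrt(n)))
    return _jzs_bf_from_t(t, n, cauchy_scale)


def _jzs_bf_from_t(t: float, n: int, r_scale: float) -> tuple[float, float]:
    nu = n - 1
    t2 = t * t

    def integrand(g: float) -> float:
        # prior: g ~ InvGamma(1/2, r^2/2)
        log_prior = (
            0.5 * np.log(r_scale**2 / 2.0)
            - special.gammaln(0.5)
            - 1.5 * np.log(g)
            - r_scale**2 / (2.0 * g)
        )
        log_lik = (
            -0.5 * np.log1p(n * g)
            - 0.5 * (nu + 1) * np.log1p(t2 / ((1.0 + n * g) * nu))
        )
        return float(np.exp(log_prior + log_lik))

    numerator, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    log_null = -0.5 * (nu + 1) * np.log1p(t2 / nu)
    bf10 = numerator / np.exp(log_null)
    return float(bf10), float(1.0 / bf10)


def wilcoxon_signed_rank(x, y=None) -> GroupResult:
    """Wilcoxon signed-rank test on paired differences (or raw differences).

    Zero differences are dropped; ties get mid-ranks. The p-value is exact
    for n <= 25 (no ties) and a continuity-corrected normal approximation
    otherwise, following the standard practice for this test.
    """
    d = _as_diffs(x, y)
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all differences are zero")
    if nz.size < 5:
        raise ValueError("need at least 5 non-zero differences")
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"),
                       method=method)
    return GroupResult(
        "wilcoxon", nz.size, float(res.statistic), float(res.pvalue),
        median_difference=float(np.median(d)),
    )


def bimodal_advantage(variable_errors: pd.DataFrame) -> GroupResult:
    """Does the congruent double-cue condition beat the best single cue?

    ``variable_errors`` needs per-observer columns ``visual``, ``audio`` and
    ``bimodal`` (variable errors, same units). For each observer the best
    single modality is min(visual, audio); the test is a Wilcoxon
    signed-rank on best-single minus bimodal, so positive differences mean
    a combination advantage. Optimal averaging with well-matched cue
    reliabilities predicts a reduction of up to 1/sqrt(2).
    """
    for col in ("visual", "audio", "bimodal"):
        if col not in variable_errors.columns:
            raise ValueError(f"missing per-observer column {col!r}")
        if variable_errors[col].isna().any():
            raise ValueError(f"missing values in column {col!r}")
    best_single = variable_errors[["visual", "audio"]].min(axis=1).to_numpy()
    diffs = best_single - variable_errors["bimodal"].to_numpy()
    if np.all(diffs == 0):
        # trivially no advantage in either direction
        return GroupResult("wilcoxon", diffs.size, float("nan"), 1.0, median_difference=0.0)
    return wilcoxon_signed_rank(diffs)
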