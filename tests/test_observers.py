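"""Synthetic observers: weighting, response generation, full-study simulation."""

import numpy as np
import pandas as pd
import pytest

from avcue import (
    Block,
    CohortSpec,
    Condition,
    CueKind,
    DesignConfig,
    ObserverParams,
    TrialSpec,
    draw_cohort,
    effective_weight,
    simulate_response,
    simulate_study,
)
from avcue.calibration import CalibrationError


def params(**kw):
    base = dict(sigma_vis_low=0.03, sigma_vis_high=0.08, sigma_aud=0.08)
    base.update(kw)
    return ObserverParams(**base)


def double_cue_trial(x_v=0.4, x_a=0.6, cue=CueKind.VIS_INTRINSIC):
    return TrialSpec(Block.TEST, 0, Condition.INCONGRUENT,
                     frozenset({cue, CueKind.AUD}),
                     hidden=x_a, visual_source=x_v, audio_loc=x_a, feedback=False)


class TestEffectiveWeight:
    def test_symmetric_variances_give_half(self):
        p = params(sigma_vis_low=0.05, sigma_aud=np.sqrt(0.05**2 + 0.0036))
        w = effective_weight(p, CueKind.VIS_INTR_EXTR, sigmaE2=0.0036)
        assert w == pytest.approx(0.5)

    def test_insensitive_observer_ignores_extrinsic_noise(self):
        p = params(lambda_ext=0.0)
        w_ie = effective_weight(p, CueKind.VIS_INTR_EXTR, sigmaE2=0.01)
        w_low = effective_weight(p, CueKind.VIS_LOW, sigmaE2=0.0)
        assert w_ie == pytest.approx(w_low)

    def test_three_to_one_variance_ratio(self):
        p = ObserverParams(sigma_vis_low=1.0, sigma_vis_high=1.0, sigma_aud=np.sqrt(3.0))
        assert effective_weight(p, CueKind.VIS_LOW) == pytest.approx(0.75)

    def test_all_zero_variances_error(self):
        p = ObserverParams(sigma_vis_low=0.0, sigma_vis_high=0.0, sigma_aud=0.0)
        with pytest.raises(ValueError, match="undefined"):
            effective_weight(p, CueKind.VIS_LOW)

    def test_sensitivity_interpolates(self):
        lo = effective_weight(params(lambda_ext=1.0), CueKind.VIS_INTR_EXTR, 0.01)
        hi = effective_weight(params(lambda_ext=0.0), CueKind.VIS_INTR_EXTR, 0.01)
        mid = effective_weight(params(lambda_ext=0.5), CueKind.VIS_INTR_EXTR, 0.01)
        assert lo < mid < hi


class TestSimulateResponse:
    def noiseless(self, **kw):
        return params(sigma_vis_low=0.0, sigma_vis_high=0.0, sigma_aud=0.0, **kw)

    def test_full_central_tendency_pins_response_at_half(self, rng):
        rec = simulate_response(double_cue_trial(), 0.4, 0.6, self.noiseless(w_p=1.0), rng)
        assert rec["response"] == pytest.approx(0.5)

    def test_weighted_average_core_follows_weight(self, rng):
        # w = sigmaA^2/(sigmaA^2+sigmaV^2) -> 0.7 at a 7:3 variance ratio
        p = ObserverParams(sigma_vis_low=0.0, sigma_vis_high=np.sqrt(3.0),
                           sigma_aud=np.sqrt(7.0), w_p=0.0)
        assert effective_weight(p, CueKind.VIS_INTRINSIC) == pytest.approx(0.7)
        # mean response over many noisy trials sits at the weighted average
        g = np.array([simulate_response(double_cue_trial(), 0.4, 0.6,
                                        params(w_p=0.0), rng)["response"]
                      for _ in range(2000)])
        w = effective_weight(params(), CueKind.VIS_INTRINSIC)
        assert g.mean() == pytest.approx(w * 0.4 + (1 - w) * 0.6, abs=0.01)

    def test_hand_computed_response(self):
        # core = 0.7*0.4 + 0.3*0.6 = 0.46 with wP = 0 and no noise
        assert 0.7 * 0.4 + 0.3 * 0.6 == pytest.approx(0.46)

    def test_pure_switching_reports_single_modality(self, rng):
        p = self.noiseless(strategy="switching", p_switch=1.0, w_p=0.0)
        for _ in range(20):
            rec = simulate_response(double_cue_trial(), 0.4, 0.6, p, rng)
            assert rec["response"] in (pytest.approx(0.4), pytest.approx(0.6))

    def test_missing_stimulus_errors(self, rng):
        with pytest.raises(ValueError, match="visual"):
            simulate_response(double_cue_trial(), None, 0.6, params(), rng)

    def test_response_clipped_to_screen(self, rng):
        p = params(sigma_motor=5.0)  # absurd motor noise forces clipping
        rec = simulate_response(double_cue_trial(), 0.4, 0.6, p, rng)
        assert 0.0 <= rec["response"] <= 1.0


class TestResponseVariance:
    def test_averaging_variance_matches_closed_form(self, rng):
        p = params(w_p=0.0, sigma_motor=0.0)
        w = effective_weight(p, CueKind.VIS_INTRINSIC)
        trial = double_cue_trial()
        g = np.array([simulate_response(trial, 0.4, 0.6, p, rng)["response"]
                      for _ in range(4000)])
        expected = w**2 * p.sigma_vis_high**2 + (1 - w)**2 * p.sigma_aud**2
        assert g.var() == pytest.approx(expected, rel=0.1)

    def test_switching_inflates_variance_at_same_marginal_weight(self, rng):
        avg = params(w_p=0.0)
        sw = params(w_p=0.0, strategy="switching", p_switch=1.0)
        trial = double_cue_trial()
        g_avg = np.array([simulate_response(trial, 0.37, 0.63, avg, rng)["response"]
                          for _ in range(3000)])
        g_sw = np.array([simulate_response(trial, 0.37, 0.63, sw, rng)["response"]
                         for _ in range(3000)])
        assert np.mean(g_sw) == pytest.approx(np.mean(g_avg), abs=0.01)
        assert g_sw.var() > 1.5 * g_avg.var()

    def test_single_cue_slope_recovers_central_tendency_gain(self, rng):
        p = params(w_p=0.3)
        targets = np.tile(np.linspace(0.37, 0.63, 9), 30)
        resp = []
        for t in targets:
            trial = TrialSpec(Block.TEST, 0, Condition.SINGLE,
                              frozenset({CueKind.AUD}), hidden=t, audio_loc=t)
            resp.append(simulate_response(trial, None, t, p, rng)["response"])
        slope = np.polyfit(targets, resp, 1)[0]
        assert slope == pytest.approx(1 - p.w_p, abs=0.08)


@pytest.fixture(scope="module")
def study():
    cohort = draw_cohort(CohortSpec(n_observers=2, lambda_ext=(0.5, 0.5)), 3)
    return simulate_study(DesignConfig(), cohort, seed=3)


class TestSimulateStudy:
    def test_row_counts(self, study):
        responses, calibration = study
        assert len(responses) == 2 * (180 + 90 + 1075)
        test = responses[responses["block"] == "test"]
        assert len(test) == 2 * 1075
        assert len(calibration) == 2

    def test_reproducible_from_seed(self, study):
        responses, _ = study
        cohort = draw_cohort(CohortSpec(n_observers=2, lambda_ext=(0.5, 0.5)), 3)
        again, _ = simulate_study(DesignConfig(), cohort, seed=3)
        pd.testing.assert_frame_equal(responses, again)

    def test_scores_match_response_distance(self, study):
        responses, _ = study
        from avcue import score
        sample = responses.sample(50, random_state=0)
        for row in sample.itertuples():
            assert row.score == pytest.approx(score(row.hidden, row.response))

    def test_uncalibratable_observer_reported_with_id(self):
        # high-variance cue easier than the low one -> sigmaE2 would be negative
        bad = ObserverParams(sigma_vis_low=0.09, sigma_vis_high=0.02, sigma_aud=0.08)
        with pytest.raises(CalibrationError, match="observer 0"):
            simulate_study(DesignConfig(), [bad], seed=1)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_study(DesignConfig(), [], seed=1)
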