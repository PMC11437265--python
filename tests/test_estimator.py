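import math

import numpy as np
import pytest

from neckvitals import (
    TaskConfig,
    assess_confidence,
    band_bounds,
    band_scores,
    double_peak_adjustment,
    ewma_update,
    init_state,
    prior_distribution,
    select_band,
    step,
)


def brute_band_scores(ds, cfg):
    """Independent double-loop implementation of the band-evidence sum:
    Curr_E[Rate] = sum_{r=Rate-floor(s/2)}^{Rate+ceil(s/2)} DS[r] for observed
    Rate, 0 otherwise."""
    curr = np.zeros(cfg.rate_max + 1)
    for rate in range(cfg.rate_max + 1):
        if rate not in ds:
            continue
        for r in range(rate - cfg.slack // 2, rate + math.ceil(cfg.slack / 2) + 1):
            curr[rate] += ds.get(r, 0.0)
    return curr


class TestPrior:
    def test_pulse_prior_peaks_at_80_with_unit_max(self, pulse_cfg):
        prior = prior_distribution(pulse_cfg)
        assert np.argmax(prior) == 80
        assert prior[80] == pytest.approx(1.0)

    def test_respiratory_thresholded_support(self, resp_cfg):
        """Rates above the 0.1 threshold span mu +/- sigma*sqrt(2 ln 10):
        14 +/- 8.58, i.e. integer rates 6..22."""
        prior = prior_distribution(resp_cfg)
        half = resp_cfg.sigma0 * math.sqrt(2 * math.log(10))
        lo, hi = math.ceil(14 - half), math.floor(14 + half)
        np.testing.assert_array_equal(np.flatnonzero(prior > resp_cfg.thresh),
                                      np.arange(lo, hi + 1))

    def test_symmetric_about_mean(self, pulse_cfg):
        prior = prior_distribution(pulse_cfg)
        for k in (1, 5, 20):
            assert prior[80 + k] == pytest.approx(prior[80 - k])


class TestDoublePeakAdjustment:
    def test_harmonic_above_p75_halved(self, pulse_cfg):
        """R={68,70,72,140}: median 71, P75=89; 140 is within slack of 2*71
        and min(R)=68 is within slack of the last confident 69."""
        ds = {68: 0.2, 70: 0.5, 72: 0.3, 140: 0.4}
        out = double_peak_adjustment(ds, 69, pulse_cfg)
        assert out[140] == pytest.approx(0.2)
        assert out[68] == ds[68] and out[70] == ds[70] and out[72] == ds[72]

    def test_no_candidate_untouched(self, pulse_cfg):
        ds = {68: 0.2, 70: 0.5, 72: 0.3}
        assert double_peak_adjustment(ds, 69, pulse_cfg) == pytest.approx(ds)

    def test_respiratory_task_skipped(self, resp_cfg):
        ds = {12: 0.5, 24: 0.5}
        assert double_peak_adjustment(ds, 12, resp_cfg) == pytest.approx(ds)

    def test_cold_start_harmonic_check_alone(self, pulse_cfg):
        ds = {68: 0.2, 70: 0.5, 72: 0.3, 140: 0.4}
        out = double_peak_adjustment(ds, None, pulse_cfg)
        assert out[140] == pytest.approx(0.2)

    def test_harmonic_dominated_window_halved(self, pulse_cfg):
        """When every observed rate sits near twice the last confident rate,
        the whole cluster is treated as double-peak energy."""
        out = double_peak_adjustment({99: 0.2, 100: 0.6, 101: 0.1}, 50, pulse_cfg)
        assert out == pytest.approx({99: 0.1, 100: 0.3, 101: 0.05})


class TestBandScores:
    def test_worked_respiratory_example(self, resp_cfg):
        """slack 3: the band centred at 12 spans [11,14], so Curr_E[12]
        sums DS over 11..14."""
        curr = band_scores({12: 0.5, 14: 0.2}, resp_cfg)
        assert curr[12] == pytest.approx(0.7)
        assert curr[14] == pytest.approx(0.2)
        assert curr[13] == 0.0  # 13 not an observed rate

    def test_empty_ds_all_zero(self, resp_cfg):
        np.testing.assert_array_equal(band_scores({}, resp_cfg), np.zeros(61))

    @pytest.mark.parametrize("task", ["pulse", "respiratory"])
    def test_matches_brute_force_oracle(self, task, rng):
        cfg = TaskConfig.for_task(task)
        for _ in range(25):
            rates = rng.choice(cfg.rate_max + 1, size=rng.integers(1, 8),
                               replace=False)
            ds = {int(r): float(rng.uniform(0.1, 1.0)) for r in rates}
            np.testing.assert_allclose(band_scores(ds, cfg),
                                       brute_band_scores(ds, cfg), atol=1e-12)


class TestBandArithmetic:
    def test_slack3_center12_spans_11_14(self):
        assert band_bounds(12, 3) == (11, 14)

    def test_slack5_spans_minus2_plus3(self):
        for center in (45, 72, 124):
            assert band_bounds(center, 5) == (center - 2, center + 3)


class TestEwmaUpdate:
    def test_direct_blend(self, pulse_cfg):
        prev, curr = np.zeros(241), np.zeros(241)
        curr[72] = 1.0
        out = ewma_update(prev, curr, pulse_cfg)
        assert out[72] == pytest.approx(0.3)

    def test_fixed_point(self, pulse_cfg, rng):
        v = rng.uniform(size=241)
        np.testing.assert_allclose(ewma_update(v, v, pulse_cfg), v)

    def test_impulse_influence_lasts_seven_steps(self, pulse_cfg):
        """A single observation's weight alpha*(1-alpha)^k stays above 2.5%
        for exactly 7 lags (k = 0..6): 0.3*0.7^6 = 3.5%, 0.3*0.7^7 = 2.47%."""
        ewma = np.zeros(1)
        impulse = np.ones(1)
        contributions = []
        ewma = ewma_update(ewma, impulse, pulse_cfg)
        contributions.append(ewma[0])
        for _ in range(12):
            ewma = ewma_update(ewma, np.zeros(1), pulse_cfg)
            contributions.append(ewma[0])
        n_above = int(np.sum(np.asarray(contributions) > 0.025))
        assert n_above == 7


class TestSelectBand:
    def test_first_step_takes_argmax(self, pulse_cfg):
        state = init_state(pulse_cfg)
        assert select_band(state.ewma, state, pulse_cfg) == 80

    def test_nearest_to_previous_band(self, pulse_cfg):
        state = init_state(pulse_cfg)
        state.t, state.prev_band = 5, 70
        ewma = np.zeros(241)
        ewma[[60, 72, 140]] = [0.5, 0.4, 0.9]
        assert select_band(ewma, state, pulse_cfg) == 72

    def test_tie_broken_by_larger_ewma(self, pulse_cfg):
        state = init_state(pulse_cfg)
        state.t, state.prev_band = 5, 70
        ewma = np.zeros(241)
        ewma[68], ewma[72] = 0.3, 0.5
        assert select_band(ewma, state, pulse_cfg) == 72

    def test_empty_h_rates_returns_none(self, pulse_cfg):
        state = init_state(pulse_cfg)
        state.t, state.prev_band = 5, 70
        assert select_band(np.zeros(241), state, pulse_cfg) is None


class TestConfidence:
    def test_tight_cluster_confident(self, pulse_cfg):
        ewma = np.zeros(241)
        ewma[70:74] = 0.5
        assert assess_confidence(ewma, pulse_cfg)

    def test_wide_spread_unconfident(self, pulse_cfg):
        """61 consecutive rates: median 90, quartiles 75/105, both distances
        15 > slack 5."""
        ewma = np.zeros(241)
        ewma[60:121] = 0.5
        assert not assess_confidence(ewma, pulse_cfg)

    def test_empty_unconfident(self, pulse_cfg):
        assert not assess_confidence(np.zeros(241), pulse_cfg)


class TestStep:
    def test_clean_stream_locks_to_rate(self, pulse_cfg):
        state = init_state(pulse_cfg)
        emitted = []
        for i in range(20):
            est, state = step({71: 0.05, 72: 0.9}, state, pulse_cfg, t_s=30.0 + i)
            emitted.append(est)
        final = emitted[-1]
        assert final is not None and final.confident
        assert final.band_low <= 72 <= final.band_high
        assert final.rate_value == 72

    def test_value_suppressed_outside_band(self, resp_cfg):
        """Argmax far from the selected band yields a band-only estimate."""
        state = init_state(resp_cfg)
        for i in range(10):
            est, state = step({14: 0.8}, state, resp_cfg, t_s=float(i))
        est, state = step({14: 0.5, 18: 0.9}, state, resp_cfg, t_s=11.0)
        assert est is not None and est.confident
        assert est.band_low <= 14 <= est.band_high
        assert not est.band_low <= 18 <= est.band_high
        assert est.rate_value is None

    def test_all_zero_scores_decay_to_silence(self, pulse_cfg):
        state = init_state(pulse_cfg)
        outputs = []
        for i in range(30):
            est, state = step({}, state, pulse_cfg, t_s=float(i))
            outputs.append(est)
        assert outputs[-1] is None
        assert np.all(state.ewma < pulse_cfg.thresh)

    def test_value_emission_never_exceeds_band_emission(self, resp_cfg, rng):
        state = init_state(resp_cfg)
        n_band = n_value = 0
        for i in range(100):
            r = int(rng.integers(5, 40))
            est, state = step({r: float(rng.uniform(0.2, 1.0))}, state,
                              resp_cfg, t_s=float(i))
            if est is not None:
                n_band += 1
                n_value += est.rate_value is not None
        assert n_value <= n_band
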