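import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

import betafeedback as bf
from betafeedback.synth import ConditionParams

RATE = 512.0


def _quiet_config(**kw):
    """Config with every oscillatory component switched off except as given."""
    base = dict(
        sampling_rate=RATE,
        pink_level=0.0, white_level=1.0, beta_level=0.0, gamma_level=0.0,
        theta_level=0.0, eeg_beta_level=0.0, eeg_alpha_level=0.0,
        tremor_coeff_theta=0.0, n_trials_per_condition=2, seed=5,
    )
    base.update(kw)
    return bf.default_config(**base)


class TestGenerateRest:
    def test_sample_count_is_rate_times_duration(self):
        rec = bf.generate_rest(bf.default_config(sampling_rate=2048.0), 30.0)
        assert rec.n_samples == 61_440
        assert rec.n_channels == 7

    def test_equal_seeds_give_identical_streams(self):
        cfg = bf.default_config(sampling_rate=RATE, seed=3)
        a = bf.generate_rest(cfg, 5.0)
        b = bf.generate_rest(cfg, 5.0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError):
            bf.generate_rest(bf.default_config(sampling_rate=RATE), 0.0)

    def test_white_noise_only_config_has_flat_spectrum(self):
        cfg = _quiet_config()
        rec = bf.generate_rest(cfg, 60.0)
        f, p = sps.welch(rec.channel("LFP"), fs=RATE, nperseg=int(RATE))
        sel = (f > 5) & (f < 200)
        ratio = p[sel].max() / p[sel].min()
        assert ratio < 2.5  # flat within estimation error

    def test_rest_spectrum_peaks_near_beta_center(self):
        cfg = bf.default_config(sampling_rate=RATE, beta_center=20.0, seed=7)
        rec = bf.generate_rest(cfg, 60.0)
        f, p = sps.welch(rec.channel("LFP"), fs=RATE, nperseg=int(4 * RATE))
        sel = (f >= 10) & (f <= 35)
        # local maximum of the 1/f-compensated spectrum within +-2 Hz of 20 Hz
        comp = p[sel] * f[sel]
        assert abs(f[sel][np.argmax(comp)] - 20.0) <= 2.0


class TestGenerateSession:
    def test_determinism(self):
        cfg = bf.default_config(sampling_rate=RATE, n_trials_per_condition=2, seed=9)
        r1, e1, g1 = bf.generate_session(cfg)
        r2, e2, g2 = bf.generate_session(cfg)
        np.testing.assert_array_equal(r1.data, r2.data)
        assert e1.equals(e2)
        assert g1.trials.equals(g2.trials)

    def test_channel_roster_and_events(self, small_session):
        rec, events, gt = small_session
        assert set(rec.labels) == {"LFP", "EEG", "EMG", "ACC_X", "ACC_Y", "ACC_Z", "FORCE"}
        kinds = set(events["kind"])
        assert {"rest", "block", "ready", "feedback", "precue", "go_cue"} <= kinds
        assert sorted(events[events["kind"] == "feedback"]["condition"].unique()) == \
            ["NoTraining", "Training"]

    def test_zero_burst_rate_gives_no_bursts(self):
        off = ConditionParams(0.0, 0.3, 0.1, theta_gain=0.0)
        cfg = bf.default_config(
            sampling_rate=RATE, n_trials_per_condition=2, seed=5,
            conditions={"Training": off, "NoTraining": off},
            rest_params=ConditionParams(0.0, 0.3, 0.1),
        )
        _, _, gt = bf.generate_session(cfg)
        assert all(len(iv) == 0 for iv in gt.burst_intervals)
        assert gt.rest_burst_intervals == []

    def test_burst_intervals_sorted_and_inside_feedback_phase(self, small_session):
        _, events, gt = small_session
        fb = events[events["kind"] == "feedback"].set_index("trial_id")
        for tid, intervals in enumerate(gt.burst_intervals):
            t0 = fb.loc[tid, "onset_s"]
            t1 = t0 + fb.loc[tid, "duration_s"]
            prev_end = t0
            for s, e in intervals:
                assert t0 - 1e-9 <= s <= e <= t1 + 1e-9
                assert s >= prev_end - 1e-9
                prev_end = e

    def test_config_validation(self):
        with pytest.raises(ValueError, match="feedback_duration"):
            bf.default_config(feedback_duration=3.0)
        with pytest.raises(ValueError, match="not finite"):
            bf.default_config(beta_level=np.nan)
        with pytest.raises(ValueError, match="coupling_psi"):
            bf.default_config(coupling_psi=1.5)

    def test_force_has_pinch_after_each_go_cue(self, small_session):
        rec, events, gt = small_session
        force = rec.channel("FORCE")
        for _, tr in gt.trials.iterrows():
            onset = tr["t_go"] + tr["true_rt"]
            i = int((onset + 0.25) * RATE)
            assert force[i] > 0.5  # plateau reached shortly after the latent RT


def test_latent_rt_regression_recovers_configured_slopes():
    """Across many trials, true_rt regressed on latent pre-cue beta/gamma (dB)
    recovers the configured positive/negative slopes within 2 SE."""
    frames = []
    for seed in range(25):
        cfg = bf.default_config(sampling_rate=RATE, n_trials_per_condition=10, seed=100 + seed)
        _, _, gt = bf.generate_session(cfg)
        frames.append(gt.trials)
    import pandas as pd
    import statsmodels.api as sm

    df = pd.concat(frames, ignore_index=True)
    assert len(df) >= 500
    X = sm.add_constant(np.column_stack([
        (df["condition"] == "Training").astype(float), df["beta_db"], df["gamma_db"]]))
    fit = sm.OLS(df["true_rt"], X).fit()
    cfg = bf.default_config()
    for idx, target in [(2, cfg.rt_coeff_beta), (3, cfg.rt_coeff_gamma)]:
        assert abs(fit.params.iloc[idx] - target) < 2 * fit.bse.iloc[idx]
    assert fit.params.iloc[2] > 0 and fit.params.iloc[3] < 0


def test_generate_epochs_interval_bookkeeping():
    cfg = bf.default_config(sampling_rate=RATE, seed=2)
    epochs, intervals = bf.generate_epochs(cfg, "NoTraining", 5, duration=4.0, pad=2.0)
    assert len(epochs) == len(intervals) == 5
    assert all(len(x) == int(8.0 * RATE) for x in epochs)
    for iv in intervals:
        for s, e in iv:
            assert 0.0 <= s <= e <= 4.0
    with pytest.raises(KeyError):
        bf.generate_epochs(cfg, "Sham", 1)
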