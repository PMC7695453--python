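import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import betafeedback as bf
from betafeedback.core import Recording
from betafeedback.oscillations import (TF_CYCLES, TF_FREQS, TFMap, cwt_morlet)

RATE = 512.0


def _tone(f, dur=12.0, amp=1.0, rate=RATE):
    t = np.arange(int(dur * rate)) / rate
    return amp * np.sin(2 * np.pi * f * t)


class TestPreprocess:
    def _rec(self, x):
        return Recording(x[None, :], RATE, ["LFP"], ["lfp"])

    def test_passband_amplitude_preserved(self):
        out = bf.preprocess(self._rec(_tone(20.0)))
        mid = out.data[0][int(2 * RATE):-int(2 * RATE)]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.01)

    def test_mains_notch_attenuates_50hz(self):
        out = bf.preprocess(self._rec(_tone(50.0)))
        mid = out.data[0][int(2 * RATE):-int(2 * RATE)]
        assert 20 * np.log10(1.0 / max(np.abs(mid).max(), 1e-12)) > 20.0

    def test_dc_offset_removed(self):
        out = bf.preprocess(self._rec(np.full(int(8 * RATE), 3.0)))
        assert np.abs(out.data[0][int(2 * RATE):-int(2 * RATE)]).max() < 0.1

    def test_rate_too_low(self):
        rec = Recording(np.zeros((1, 1000)), 150.0, ["LFP"], ["lfp"])
        with pytest.raises(ValueError, match="too low"):
            bf.preprocess(rec)


class TestMorletTF:
    def test_frequency_localization(self):
        tf = bf.morlet_tf(_tone(20.0), RATE)
        mag = tf.magnitude()[:, int(4 * RATE):int(8 * RATE)].mean(axis=1)
        assert tf.freqs[np.argmax(mag)] == 20.0

    def test_linearity_in_amplitude(self):
        m1 = bf.morlet_tf(_tone(20.0, amp=1.0), RATE)
        m3 = bf.morlet_tf(_tone(20.0, amp=3.0), RATE)
        mid = slice(int(4 * RATE), int(8 * RATE))
        ratio = m3.magnitude()[19, mid].mean() / m1.magnitude()[19, mid].mean()
        assert ratio == pytest.approx(3.0, rel=1e-6)

    def test_chirp_ridge_increases(self):
        t = np.arange(int(20 * RATE)) / RATE
        from scipy.signal import chirp
        x = chirp(t, f0=10.0, f1=30.0, t1=20.0)
        tf = bf.morlet_tf(x, RATE)
        sel = slice(int(3 * RATE), int(17 * RATE), int(RATE))
        ridge = tf.freqs[np.argmax(tf.magnitude()[:, sel], axis=0)]
        assert np.all(np.diff(ridge) > 0)

    def test_too_short_signal(self):
        with pytest.raises(ValueError, match="too short"):
            bf.morlet_tf(np.zeros(int(2 * RATE)), RATE)

    def test_cwt_matches_mne_reference(self, rng):
        from mne.time_frequency import tfr_array_morlet
        x = rng.standard_normal((1, int(8 * RATE)))
        ref = tfr_array_morlet(x[None], RATE, TF_FREQS, n_cycles=TF_CYCLES,
                               output="complex", verbose="error")[0, 0]
        ours = cwt_morlet(x, RATE, TF_FREQS, TF_CYCLES)[0]
        np.testing.assert_allclose(ours, ref, rtol=1e-9, atol=1e-12)


class TestNormalization:
    def test_rest_normalized_against_itself_averages_zero(self, rng):
        x = rng.standard_normal(int(20 * RATE))
        tf = bf.morlet_tf(x, RATE)
        win = [(4.0, 16.0)]
        norm = bf.normalize_percent_change(tf, rest_intervals=win)
        cols = slice(int(4 * RATE), int(16 * RATE))
        per_freq = norm[:, cols].mean(axis=1)
        assert np.abs(per_freq).max() < 1e-9

    def test_power_doubling_reads_plus_hundred_percent(self, rng):
        x = rng.standard_normal(int(20 * RATE))
        tf = bf.morlet_tf(x, RATE)
        from betafeedback.oscillations import rest_profile
        base = rest_profile(tf, [(4.0, 16.0)])
        tf2 = TFMap(coef=tf.coef * np.sqrt(2.0), freqs=tf.freqs, rate=RATE)
        norm = bf.normalize_percent_change(tf2, baseline=base)
        per_freq = norm[:, int(4 * RATE):int(16 * RATE)].mean(axis=1)
        np.testing.assert_allclose(per_freq, 100.0, atol=1e-6)

    def test_zero_baseline_is_an_error(self, rng):
        tf = bf.morlet_tf(rng.standard_normal(int(8 * RATE)), RATE)
        with pytest.raises(ValueError, match="rest"):
            bf.normalize_percent_change(tf, baseline=np.zeros(95))


class TestBandPower:
    def test_uniform_map(self, rng):
        tf = bf.morlet_tf(rng.standard_normal(int(8 * RATE)), RATE)
        values = np.full_like(tf.coef, 4.2, dtype=float)
        assert bf.band_power(values, tf, (18.0, 22.0), (2.0, 6.0)) == pytest.approx(4.2)

    def test_beta_plus_8_selects_shifted_bins(self, rng):
        tf = bf.morlet_tf(rng.standard_normal(int(8 * RATE)), RATE)
        values = np.zeros_like(tf.coef, dtype=float)
        values[tf.freqs >= 26.0, :] = 1.0  # rows 26..95
        from betafeedback.core import shift_band
        band = shift_band((18.0, 22.0), 8.0)  # -> 26..30 Hz
        assert bf.band_power(values, tf, band, (2.0, 6.0)) == pytest.approx(1.0)
        assert bf.band_power(values, tf, (18.0, 22.0), (2.0, 6.0)) == 0.0

    def test_errors(self, rng):
        tf = bf.morlet_tf(rng.standard_normal(int(8 * RATE)), RATE)
        v = tf.power()
        with pytest.raises(ValueError, match="empty"):
            bf.band_power(v, tf, (18.0, 22.0), (2.0, 2.0))
        with pytest.raises(ValueError, match="outside"):
            bf.band_power(v, tf, (90.0, 120.0), (2.0, 6.0))


def _runs_oracle(above: np.ndarray, rate: float):
    """Brute-force run-length enumeration, sample by sample."""
    runs, cur = [], 0
    for a in above:
        if a:
            cur += 1
        elif cur:
            runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return np.array(runs) / rate


class TestBurstMetrics:
    def test_constructed_square_envelope(self):
        env = np.zeros(int(4 * RATE))
        env[int(1 * RATE):int(2 * RATE)] = 2.0
        m = bf.burst_metrics(env, threshold=1.0, rate=RATE)
        assert m.accumulated_pct == pytest.approx(25.0)
        assert m.mean_duration_ms == pytest.approx(1000.0)
        assert m.rate == pytest.approx(0.25)

    def test_subthreshold_envelope(self):
        m = bf.burst_metrics(np.zeros(int(4 * RATE)), threshold=1.0, rate=RATE)
        assert m.accumulated_pct == 0.0
        assert np.isnan(m.mean_duration_ms)
        assert m.rate == 0.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_random_telegraph_matches_enumeration_oracle(self, seed):
        r = np.random.default_rng(seed)
        env = r.choice([0.0, 2.0], size=r.integers(50, 400), p=[0.7, 0.3])
        m = bf.burst_metrics(env, threshold=1.0, rate=RATE)
        runs = _runs_oracle(env > 1.0, RATE)
        assert m.rate == pytest.approx(len(runs) / (env.size / RATE))
        assert m.accumulated_pct == pytest.approx(runs.sum() / (env.size / RATE) * 100.0)
        if len(runs):
            assert m.mean_duration_ms == pytest.approx(runs.mean() * 1e3)
            # burst identity: accumulated time == mean x count, exactly
            assert runs.sum() == pytest.approx(runs.mean() * len(runs))
        assert m.n_long + m.n_short == len(runs)

    def test_online_and_envelope_bursts_agree_on_slow_envelopes(self):
        """A slowly gated beta tone: supra-threshold runs from the 250 ms
        online power updates and from the Morlet envelope agree within one hop
        per burst edge."""
        band = bf.BetaBandSpec(channel="LFP", center_f=20.0)
        t = np.arange(int(12 * RATE)) / RATE
        gate = ((t > 3.0) & (t < 5.0)) | ((t > 7.5) & (t < 9.0))
        x = np.where(gate, 2.0, 0.2) * np.sin(2 * np.pi * 20.0 * t)
        # online path over an 8 s "phase" starting at 2 s
        powers = bf.stream_powers(x, band, RATE, 2.0, 8.0)
        thr_p = bf.compute_update_power(
            np.sin(2 * np.pi * 20.0 * t[:int(0.5 * RATE)]), band, RATE)
        online_above = powers > thr_p
        online_time = online_above.mean() * 8.0
        env = bf.beta_envelope(x, RATE, band.band)
        m = bf.burst_metrics(env, threshold=np.real(env.coef[0]).max() * 0.45,
                             window=(2.0, 10.0))
        env_time = m.accumulated_pct / 100.0 * 8.0
        assert m.rate * 8.0 == 2  # two gated bursts found
        assert abs(env_time - online_time) <= 2 * 0.25 + 0.25  # one hop per edge


class TestConnectivity:
    def _pair(self, rng, coupled=True):
        x = rng.standard_normal(int(10 * RATE))
        y = x if coupled else rng.standard_normal(int(10 * RATE))
        return bf.morlet_tf(x, RATE), bf.morlet_tf(y, RATE)

    def test_identical_signals(self, rng):
        a, b = self._pair(rng, coupled=True)
        assert bf.psi(a, b, (18.0, 22.0), (2.0, 8.0)) == pytest.approx(1.0)
        assert bf.coherence(a, b, (18.0, 22.0), (2.0, 8.0)) == pytest.approx(1.0)

    def test_constant_phase_offset_gives_unit_psi(self, rng):
        a, _ = self._pair(rng)
        shifted = TFMap(coef=a.coef * np.exp(1j * np.pi / 3), freqs=a.freqs, rate=RATE)
        assert bf.psi(a, shifted, (18.0, 22.0), (2.0, 8.0)) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        a, _ = self._pair(rng)
        scaled = TFMap(coef=a.coef * 7.3, freqs=a.freqs, rate=RATE)
        assert bf.coherence(a, scaled, (18.0, 22.0), (2.0, 8.0)) == pytest.approx(1.0)
        assert bf.psi(a, scaled, (18.0, 22.0), (2.0, 8.0)) == pytest.approx(1.0)

    def test_independent_signals_decorrelate(self, rng):
        vals_psi, vals_coh = [], []
        for _ in range(5):
            a, b = self._pair(rng, coupled=False)
            vals_psi.append(bf.psi(a, b, (18.0, 22.0), (2.0, 8.0)))
            vals_coh.append(bf.coherence(a, b, (18.0, 22.0), (2.0, 8.0)))
        # wavelet autocorrelation leaves ~ (tau/T)^(1/2)-scale residuals
        assert np.mean(vals_psi) < 0.35
        assert np.mean(vals_coh) < 0.35

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_bounds_hold_for_arbitrary_pairs(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(int(8 * RATE))
        y = 0.5 * x + r.standard_normal(int(8 * RATE))
        a, b = bf.morlet_tf(x, RATE), bf.morlet_tf(y, RATE)
        for fn in (bf.psi, bf.coherence):
            v = fn(a, b, (18.0, 22.0), (2.0, 6.0))
            assert 0.0 <= v <= 1.0 + 1e-9

    def test_mismatched_grids_error(self, rng):
        a, b = self._pair(rng)
        short = TFMap(coef=b.coef[:, :100], freqs=b.freqs, rate=RATE)
        with pytest.raises(ValueError, match="share"):
            bf.psi(a, short, (18.0, 22.0))


def test_estimated_psi_monotone_in_generator_coupling():
    """Estimated PSI increases with the generator's coupling parameter; with
    backgrounds present the estimate is attenuated by in-band noise, so the
    perfect-locking check uses a beta-dominated configuration."""
    import dataclasses
    levels = {0.0: [], 0.5: [], 1.0: []}
    base = bf.default_config(sampling_rate=RATE)
    for psi_true in levels:
        for seed in range(12):
            cfg = dataclasses.replace(base, coupling_psi=psi_true, seed=300 + seed)
            rec = bf.generate_rest(cfg, 8.0)
            a = bf.morlet_tf(rec.channel("LFP"), RATE)
            b = bf.morlet_tf(rec.channel("EEG"), RATE)
            levels[psi_true].append(bf.psi(a, b, (18.0, 22.0), (2.0, 6.0)))
    means = {k: np.mean(v) for k, v in levels.items()}
    sems = {k: np.std(v, ddof=1) / np.sqrt(len(v)) for k, v in levels.items()}
    assert means[0.5] - means[0.0] > 2 * (sems[0.5] + sems[0.0])
    assert means[1.0] - means[0.5] > 2 * (sems[1.0] + sems[0.5])

    # beta-dominated channels: perfect phase locking recovered within sampling error
    clean = bf.default_config(
        sampling_rate=RATE, coupling_psi=1.0, pink_level=0.05, white_level=0.01,
        eeg_pink_level=0.05, eeg_white_level=0.01,
        gamma_level=0.0, theta_level=0.0, eeg_alpha_level=0.0, seed=4)
    rec = bf.generate_rest(clean, 8.0)
    a = bf.morlet_tf(rec.channel("LFP"), RATE)
    b = bf.morlet_tf(rec.channel("EEG"), RATE)
    assert bf.psi(a, b, (18.0, 22.0), (2.0, 6.0)) > 0.97
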