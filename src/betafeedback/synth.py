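"""Synthetic neurofeedback sessions with controllable ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, for a single subthalamic hemisphere:

* a bipolar STN LFP channel: 1/f background with a white floor, a narrowband
  beta oscillation whose amplitude is modulated by a stochastic burst process
  (renewal gaps, gamma-distributed durations, lognormal per-burst amplitudes,
  raised-cosine on/off ramps), broadband 55-95 Hz gamma, and a theta/tremor
  band oscillation with a slowly drifting envelope;
* an EEG channel over motor cortex whose beta component is phase-coupled to
  the LFP beta carrier at a configurable phase-synchrony level;
* surface EMG (band-limited noise, condition-independent);
* a tri-axial accelerometer whose tremor-band oscillation scales with the
  LFP theta envelope;
* a pinch-force channel with an onset at a latent reaction time after each
  Go cue.  Latent reaction times are drawn from an inverse-Gaussian whose
  mean depends positively on pre-cue beta power (dB) and negatively on
  pre-cue gamma power (dB), plus a direct condition effect.

The burst process during the task's "No Training" blocks defaults to the
burst statistics of a passively observing patient (0.531 bursts/s, 377 ms
mean duration); rest periods are busier (0.61 bursts/s, 410 ms), so that a
75th-percentile rest threshold reproduces the empirical finding that
task-phase accumulated burst time sits below the rest-calibrated 25 %.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sstats

from .core import CONDITIONS, Recording, make_event_table

__all__ = [
    "ConditionParams",
    "SessionConfig",
    "GroundTruth",
    "generate_session",
    "generate_rest",
    "generate_epochs",
    "default_config",
]


@dataclass
class ConditionParams:
    """Burst-process and band-gain parameters for one experimental condition."""

    burst_rate: float  # bursts per second
    burst_duration_mean: float  # s
    burst_duration_sd: float  # s
    gamma_gain: float = 1.0  # amplitude multiplier on broadband gamma
    theta_gain: float = 1.0  # amplitude multiplier on theta / tremor drive


def _default_conditions() -> dict[str, ConditionParams]:
    return {
        # Volitional suppression: fewer, shorter bursts; more gamma; more theta
        # (tremor-prone hemispheres worsen during beta suppression).
        "Training": ConditionParams(0.446, 0.3196, 0.18, gamma_gain=1.12, theta_gain=1.35),
        # Passive observation: natural ongoing burst dynamics.
        "NoTraining": ConditionParams(0.531, 0.3772, 0.20),
    }


def _default_rest() -> ConditionParams:
    return ConditionParams(0.61, 0.41, 0.22)


@dataclass
class SessionConfig:
    """Everything needed to generate one session deterministically."""

    sampling_rate: float = 2048.0
    n_trials_per_condition: int = 10
    feedback_duration: float = 6.0  # s, within [4, 8]
    ready_duration: float = 2.5  # s, within [2, 3]
    precue_gap: float = 2.5  # s, within [2, 3]
    rest_duration: float = 30.0  # s
    response_window: float = 3.0  # s after the Go cue
    inter_trial_gap: float = 1.5  # s
    instruction_duration: float = 10.0  # s before each block

    conditions: dict[str, ConditionParams] = field(default_factory=_default_conditions)
    rest_params: ConditionParams = field(default_factory=_default_rest)

    # LFP composition (amplitudes relative to a unit-RMS 1/f background)
    beta_center: float = 20.0  # Hz
    beta_level: float = 0.8  # continuous beta amplitude
    beta_burst_gain: float = 5.0  # burst plateau amplitude, x beta_level
    burst_amp_sigma: float = 0.3  # lognormal spread of per-burst amplitudes
    burst_ramp: float = 0.05  # s raised-cosine on/off ramps
    beta_carrier_bw: float = 1.3  # Hz, carrier linewidth
    beta_am_sigma: float = 0.25  # slow AM depth of the continuous beta
    beta_am_tau: float = 0.7  # s, slow AM correlation time
    pink_level: float = 1.0
    white_level: float = 0.15
    gamma_level: float = 0.35
    theta_level: float = 0.4
    theta_freq: float = 5.0  # Hz, inside the 3-7 Hz tremor band
    trial_gain_sigma: float = 0.2  # lognormal trial-to-trial gamma/theta spread

    # EEG composition
    eeg_pink_level: float = 0.9
    eeg_white_level: float = 0.15
    eeg_beta_level: float = 0.5
    eeg_burst_coupling: float = 0.4  # how strongly EEG beta tracks LFP bursts
    eeg_alpha_level: float = 0.6
    coupling_psi: float = 0.6  # target STN-cortex beta phase synchrony in [0, 1]

    # behavior
    rt_base: float = 0.511  # s, No-Training baseline reaction time
    rt_condition_effect: float = -0.0154  # s, direct Training effect
    rt_coeff_beta: float = 0.0061  # s/dB, pre-cue beta slope (positive)
    rt_coeff_gamma: float = -0.0085  # s/dB, pre-cue gamma slope (negative)
    rt_ig_shape: float = 20.0  # inverse-Gaussian shape lambda (s)
    tremor_coeff_theta: float = 1.0  # accelerometer gain per unit theta amplitude
    accel_noise: float = 0.2
    force_noise: float = 0.008
    force_rise: float = 0.15  # s to plateau (raised-cosine)

    seed: int = 0

    def validate(self) -> "SessionConfig":
        numeric = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if isinstance(getattr(self, f.name), (int, float))
        }
        for name, value in numeric.items():
            if not np.isfinite(value):
                raise ValueError(f"config field {name} is not finite")
        if not 4.0 <= self.feedback_duration <= 8.0:
            raise ValueError("feedback_duration must lie in [4, 8] s")
        if not 2.0 <= self.ready_duration <= 3.0:
            raise ValueError("ready_duration must lie in [2, 3] s")
        if not 2.0 <= self.precue_gap <= 3.0:
            raise ValueError("precue_gap must lie in [2, 3] s")
        if not 0.0 <= self.coupling_psi <= 1.0:
            raise ValueError("coupling_psi must lie in [0, 1]")
        for name in ("sampling_rate", "rest_duration", "rt_ig_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_trials_per_condition < 0:
            raise ValueError("n_trials_per_condition must be >= 0")
        for cname, cp in {**self.conditions, "rest": self.rest_params}.items():
            if cp.burst_rate < 0:
                raise ValueError(f"{cname}: burst_rate must be >= 0")
            if cp.burst_duration_mean <= 0 or cp.burst_duration_sd <= 0:
                raise ValueError(f"{cname}: burst durations must be positive")
        return self


def default_config(**overrides) -> SessionConfig:
    return dataclasses.replace(SessionConfig(), **overrides).validate()


@dataclass
class GroundTruth:
    """Latent state of one generated session (oracle for recovery tests)."""

    trials: pd.DataFrame  # trial_id, condition, timing, latent powers, true_rt
    burst_intervals: list[list[tuple[float, float]]]  # per trial, clipped to feedback phase
    all_burst_intervals: list[tuple[float, float, float]]  # (start, end, amplitude), session clock
    rest_burst_intervals: list[tuple[float, float, float]]
    coupling_psi_true: float
    block_order: list[str]

    def __post_init__(self) -> None:
        for k, iv in enumerate(self.burst_intervals):
            for (s0, e0), (s1, e1) in zip(iv, iv[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping burst intervals in trial {k}")
        if len(self.trials) and (self.trials["true_rt"].dropna() < 0).any():
            raise ValueError("true_rt must be nonnegative")


# ---------------------------------------------------------------------------
# elementary signal builders (all take an explicit Generator)

def _spectral_noise(n: int, rate: float, shaper, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with amplitude spectrum shaped by ``shaper(f)``, unit RMS."""
    spec = rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    h = shaper(f)
    h[0] = 0.0
    x = np.fft.irfft(spec * h, n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _pink(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-power background (amplitude ∝ f^-1/2), flattened below 0.5 Hz."""
    return _spectral_noise(n, rate, lambda f: 1.0 / np.sqrt(np.maximum(f, 0.5)), rng)


def _band_noise(n: int, rate: float, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    return _spectral_noise(n, rate, lambda f: ((f >= lo) & (f <= hi)).astype(float), rng)


def _phase_carrier(n: int, rate: float, fc: float, bw: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-modulus complex carrier with narrowband phase dynamics around fc."""
    f = np.fft.rfftfreq(n, 1.0 / rate)
    h = np.exp(-0.5 * ((f - fc) / bw) ** 2)
    re = np.fft.irfft((rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)) * h, n)
    im = np.fft.irfft((rng.standard_normal(n // 2 + 1) + 1j * rng.standard_normal(n // 2 + 1)) * h, n)
    z = re + 1j * im
    mag = np.abs(z)
    mag[mag == 0] = 1.0
    return z / mag


def _slow_am(n: int, rate: float, tau: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Slowly varying positive amplitude modulation, mean ~1."""
    if sigma == 0:
        return np.ones(n)
    x = _spectral_noise(n, rate, lambda f: 1.0 / np.sqrt(1.0 + (2 * np.pi * f * tau) ** 2), rng)
    return np.maximum(1.0 + sigma * x, 0.2)


def _burst_process(
    t_start: float,
    t_stop: float,
    params: ConditionParams,
    gain: float,
    amp_sigma: float,
    rng: np.random.Generator,
) -> list[tuple[float, float, float]]:
    """Renewal burst process on [t_start, t_stop): (onset, offset, amplitude).

    Gaps (from burst end to next onset) are exponential with mean chosen so the
    long-run burst rate equals ``params.burst_rate``; durations are gamma with
    the configured mean/sd; per-burst plateau amplitudes are
    ``gain * lognormal(sigma=amp_sigma)``.  Bursts never overlap.
    """
    if params.burst_rate <= 0:
        return []
    cycle = 1.0 / params.burst_rate
    gap_mean = max(cycle - params.burst_duration_mean, 0.05)
    shape = (params.burst_duration_mean / params.burst_duration_sd) ** 2
    scale = params.burst_duration_sd**2 / params.burst_duration_mean
    out: list[tuple[float, float, float]] = []
    # start the process before the segment so it is stationary at t_start
    t = t_start + rng.exponential(gap_mean) - rng.uniform(0, gap_mean + params.burst_duration_mean)
    while t < t_stop:
        d = rng.gamma(shape, scale)
        amp = gain * np.exp(amp_sigma * rng.standard_normal())
        s, e = t, t + d
        if e > t_start:
            out.append((max(s, t_start), min(e, t_stop), amp))
        t = e + rng.exponential(gap_mean)
    return out


def _render_burst_envelope(
    n: int, rate: float, bursts: list[tuple[float, float, float]], ramp: float
) -> np.ndarray:
    """Raised-cosine-ramped envelope; plateau value = burst amplitude."""
    env = np.zeros(n)
    for s, e, amp in bursts:
        i0, i1 = int(round(s * rate)), min(int(round(e * rate)), n)
        if i1 <= i0:
            continue
        t = np.arange(i0, i1) / rate
        v = np.ones(i1 - i0)
        r = min(ramp, (e - s) / 2)
        if r > 0:
            up = t < s + r
            dn = t > e - r
            v[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - s) / r))
            v[dn] = 0.5 * (1 - np.cos(np.pi * (e - t[dn]) / r))
        env[i0:i1] = np.maximum(env[i0:i1], amp * v)
    return env


def _coupled_phase(
    n: int, rate: float, psi: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Slow phase offset process whose circular concentration gives PSI=psi."""
    if psi >= 1.0:
        return np.zeros(n)
    if psi <= 0.0:
        # fully independent phase: uniform random walk dominated offset
        sigma = 20.0
    else:
        sigma = np.sqrt(-2.0 * np.log(psi))
    x = _spectral_noise(n, rate, lambda f: 1.0 / np.sqrt(1.0 + (2 * np.pi * f * tau) ** 2), rng)
    return sigma * x


# ---------------------------------------------------------------------------
# channel assembly

_CHANNELS = ["LFP", "EEG", "EMG", "ACC_X", "ACC_Y", "ACC_Z", "FORCE"]
_MODALITIES = ["lfp", "eeg", "emg", "accel", "accel", "accel", "force"]


def _assemble(
    config: SessionConfig,
    n: int,
    rng: np.random.Generator,
    bursts: list[tuple[float, float, float]],
    gamma_gain_t: np.ndarray,
    theta_gain_t: np.ndarray,
) -> tuple[np.ndarray, dict]:
    """Render all channels given the burst list and per-sample band gains."""
    rate = config.sampling_rate
    burst_env = _render_burst_envelope(n, rate, bursts, config.burst_ramp)
    beta_am = _slow_am(n, rate, config.beta_am_tau, config.beta_am_sigma, rng)
    carrier = _phase_carrier(n, rate, config.beta_center, config.beta_carrier_bw, rng)
    beta_amp = config.beta_level * (beta_am + burst_env)

    gamma = _band_noise(n, rate, 55.0, min(95.0, rate / 2 - 1), rng)
    theta_am = _slow_am(n, rate, 1.5, 0.3, rng)
    theta_phase = 2 * np.pi * config.theta_freq * np.arange(n) / rate + rng.uniform(0, 2 * np.pi)
    theta_amp = config.theta_level * theta_am * theta_gain_t

    lfp = (
        config.pink_level * _pink(n, rate, rng)
        + config.white_level * rng.standard_normal(n)
        + beta_amp * np.real(carrier)
        + config.gamma_level * gamma_gain_t * gamma
        + theta_amp * np.cos(theta_phase)
    )

    dphi = _coupled_phase(n, rate, config.coupling_psi, 0.5, rng)
    eeg_carrier = np.real(carrier * np.exp(1j * dphi))
    eeg_beta_am = _slow_am(n, rate, config.beta_am_tau, config.beta_am_sigma, rng)
    eeg = (
        config.eeg_pink_level * _pink(n, rate, rng)
        + config.eeg_white_level * rng.standard_normal(n)
        + config.eeg_beta_level * (eeg_beta_am + config.eeg_burst_coupling * burst_env) * eeg_carrier
        + config.eeg_alpha_level * _slow_am(n, rate, 1.0, 0.3, rng) * np.cos(
            2 * np.pi * 10.0 * np.arange(n) / rate + rng.uniform(0, 2 * np.pi)
        )
    )

    emg = _band_noise(n, rate, 20.0, min(400.0, rate / 2 - 1), rng)

    tremor_amp = config.tremor_coeff_theta * theta_amp
    loadings = np.array([1.0, 0.7, 0.4])
    acc = np.empty((3, n))
    for ax in range(3):
        acc[ax] = (
            config.accel_noise * rng.standard_normal(n)
            + loadings[ax] * tremor_amp * np.cos(theta_phase + rng.uniform(0, 2 * np.pi))
        )

    force = config.force_noise * sps.sosfiltfilt(
        sps.butter(2, 10.0 / (rate / 2), output="sos"), rng.standard_normal(n)
    )

    data = np.vstack([lfp, eeg, emg, acc, force])
    latents = {"burst_env": burst_env, "beta_am": beta_am, "theta_amp": theta_amp}
    return data, latents


def _add_pinch(data: np.ndarray, rate: float, onset_s: float, rise: float, hold: float = 0.8) -> None:
    """Add one pinch (raised-cosine rise to a unit plateau, then release)."""
    n = data.shape[1]
    i0 = int(round(onset_s * rate))
    n_r = int(round(rise * rate))
    n_h = int(round(hold * rate))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_r) / n_r))
    pulse = np.concatenate([ramp, np.ones(n_h), ramp[::-1]])
    i1 = min(i0 + len(pulse), n)
    if i0 < n:
        data[-1, i0:i1] += pulse[: i1 - i0]


# ---------------------------------------------------------------------------
# public generators

def generate_rest(config: SessionConfig, duration: float | None = None) -> Recording:
    """Rest-only recording (no events, no pinches), spectrally like the session."""
    config.validate()
    if duration is None:
        duration = config.rest_duration
    if not np.isfinite(duration) or duration <= 0:
        raise ValueError("rest duration must be positive")
    rate = config.sampling_rate
    n = int(round(duration * rate))
    rng = np.random.default_rng(config.seed)
    bursts = _burst_process(
        0.0, duration, config.rest_params, config.beta_burst_gain, config.burst_amp_sigma, rng
    )
    data, _ = _assemble(config, n, rng, bursts, np.ones(n), np.ones(n))
    return Recording(data, rate, list(_CHANNELS), list(_MODALITIES), montage="bipolar")


def _trial_schedule(config: SessionConfig, rng: np.random.Generator):
    """Lay out rest, two blocks and their trials on the session clock."""
    order = list(CONDITIONS)
    if rng.random() < 0.5:
        order = order[::-1]
    t = config.rest_duration
    rows = [dict(onset_s=0.0, duration_s=config.rest_duration, kind="rest", condition="", trial_id=-1)]
    trials = []
    trial_id = 0
    blocks = []
    for cond in order:
        block_start = t
        t += config.instruction_duration
        for _ in range(config.n_trials_per_condition):
            t_ready = t
            t_fb = t_ready + config.ready_duration
            t_go = t_fb + config.feedback_duration + config.precue_gap
            rows += [
                dict(onset_s=t_ready, duration_s=config.ready_duration, kind="ready",
                     condition=cond, trial_id=trial_id),
                dict(onset_s=t_fb, duration_s=config.feedback_duration, kind="feedback",
                     condition=cond, trial_id=trial_id),
                dict(onset_s=t_fb + config.feedback_duration, duration_s=config.precue_gap,
                     kind="precue", condition=cond, trial_id=trial_id),
                dict(onset_s=t_go, duration_s=0.0, kind="go_cue", condition=cond, trial_id=trial_id),
            ]
            trials.append(dict(trial_id=trial_id, condition=cond, t_ready=t_ready,
                               t_feedback=t_fb, t_go=t_go))
            t = t_go + config.response_window + config.inter_trial_gap
            trial_id += 1
        blocks.append((cond, block_start, t))
        rows.append(dict(onset_s=block_start, duration_s=t - block_start, kind="block",
                         condition=cond, trial_id=-1))
    return rows, trials, blocks, order, t + 2.0


def generate_session(config: SessionConfig):
    """Generate one full session.

    Returns ``(recording, events, ground_truth)``.  The recording holds one
    bipolar LFP, one EEG, one EMG, three accelerometer axes and one force
    channel; the event table encodes rest, blocks, and per-trial ready /
    feedback / precue / Go-cue markers; the ground truth records burst
    intervals, latent band powers (dB), latent reaction times and tremor
    amplitudes per trial.
    """
    config.validate()
    rate = config.sampling_rate
    rng = np.random.default_rng(config.seed)
    rows, trials, blocks, order, total = _trial_schedule(config, rng)
    n = int(round(total * rate))

    # burst process: rest statistics outside blocks, condition statistics inside
    rest_bursts = _burst_process(
        0.0, config.rest_duration, config.rest_params,
        config.beta_burst_gain, config.burst_amp_sigma, rng,
    )
    all_bursts = list(rest_bursts)
    for cond, b0, b1 in blocks:
        all_bursts += _burst_process(
            b0, b1, config.conditions[cond], config.beta_burst_gain, config.burst_amp_sigma, rng
        )
    gap_bursts = _burst_process(  # post-block tail
        blocks[-1][2], total, config.rest_params, config.beta_burst_gain, config.burst_amp_sigma, rng
    )
    all_bursts += gap_bursts
    all_bursts.sort()

    # per-sample gamma/theta gains: condition value with trial-to-trial jitter
    gamma_gain_t = np.ones(n)
    theta_gain_t = np.ones(n)
    trial_factors = []
    for tr in trials:
        cp = config.conditions[tr["condition"]]
        jg = float(np.exp(config.trial_gain_sigma * rng.standard_normal()))
        jt = float(np.exp(config.trial_gain_sigma * rng.standard_normal()))
        i0 = int(round(tr["t_ready"] * rate))
        i1 = int(round((tr["t_go"] + config.response_window) * rate))
        gamma_gain_t[i0:i1] = cp.gamma_gain * jg
        theta_gain_t[i0:i1] = cp.theta_gain * jt
        trial_factors.append((cp.gamma_gain * jg, cp.theta_gain * jt))

    data, latents = _assemble(config, n, rng, all_bursts, gamma_gain_t, theta_gain_t)

    # latent per-trial quantities -> reaction times -> force pinches
    burst_env = latents["burst_env"]
    beta_am = latents["beta_am"]
    beta_db, gamma_db, theta_db, tremor_amp, per_trial_bursts = [], [], [], [], []
    for tr, (gfac, tfac) in zip(trials, trial_factors):
        pre0 = int(round((tr["t_go"] - 2.0) * rate))
        pre1 = int(round(tr["t_go"] * rate))
        amp = config.beta_level * (beta_am[pre0:pre1] + burst_env[pre0:pre1])
        floor = 1e-12  # silent components read as a -120 dB floor, not -inf
        beta_db.append(10 * np.log10(max(np.mean(amp**2) / 2, floor)))
        gamma_db.append(20 * np.log10(max(config.gamma_level * gfac, 1e-6)))
        theta_db.append(20 * np.log10(max(config.theta_level * tfac, 1e-6)))
        fb0, fb1 = tr["t_feedback"], tr["t_feedback"] + config.feedback_duration
        iv = [(max(s, fb0), min(e, fb1)) for s, e, _ in all_bursts if e > fb0 and s < fb1]
        per_trial_bursts.append(iv)
        i0, i1 = int(round(fb0 * rate)), int(round(fb1 * rate))
        tremor_amp.append(float(np.mean(latents["theta_amp"][i0:i1])) * config.tremor_coeff_theta)

    beta_db = np.array(beta_db)
    gamma_db = np.array(gamma_db)
    b_ref = beta_db.mean() if beta_db.size else 0.0
    g_ref = gamma_db.mean() if gamma_db.size else 0.0
    true_rt = []
    for tr, b, g in zip(trials, beta_db, gamma_db):
        mu = (
            config.rt_base
            + (config.rt_condition_effect if tr["condition"] == "Training" else 0.0)
            + config.rt_coeff_beta * (b - b_ref)
            + config.rt_coeff_gamma * (g - g_ref)
        )
        mu = max(mu, 0.05)
        rt = float(sstats.invgauss.rvs(mu / config.rt_ig_shape, scale=config.rt_ig_shape,
                                       random_state=rng))
        true_rt.append(rt)
        _add_pinch(data, rate, tr["t_go"] + rt, config.force_rise)

    trial_df = pd.DataFrame(trials)
    trial_df["true_rt"] = true_rt
    trial_df["beta_db"] = beta_db
    trial_df["gamma_db"] = gamma_db
    trial_df["theta_db"] = theta_db
    trial_df["tremor_amp"] = tremor_amp

    events = make_event_table(rows)
    rec = Recording(data, rate, list(_CHANNELS), list(_MODALITIES), montage="bipolar")
    gt = GroundTruth(
        trials=trial_df,
        burst_intervals=per_trial_bursts,
        all_burst_intervals=all_bursts,
        rest_burst_intervals=rest_bursts,
        coupling_psi_true=config.coupling_psi,
        block_order=order,
    )
    return rec, events, gt


def generate_epochs(
    config: SessionConfig,
    condition: str,
    n_epochs: int,
    duration: float = 4.0,
    pad: float = 2.0,
    rng: np.random.Generator | None = None,
):
    """LFP-only feedback-phase epochs from one condition's burst preset.

    Each epoch is ``pad + duration + pad`` seconds of LFP; the analysis window
    is the central ``duration`` seconds (the padding absorbs wavelet edges).
    Returns ``(epochs, intervals)`` where ``intervals`` holds the ground-truth
    burst intervals clipped to the analysis window, on the epoch clock.
    Used for burst-statistics recovery studies at scale, where rendering the
    full seven-channel session per epoch would be wasteful.
    """
    config.validate()
    if condition not in config.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rate = config.sampling_rate
    total = duration + 2 * pad
    n = int(round(total * rate))
    params = config.conditions[condition]
    epochs, intervals = [], []
    for _ in range(n_epochs):
        bursts = _burst_process(0.0, total, params, config.beta_burst_gain,
                                config.burst_amp_sigma, rng)
        burst_env = _render_burst_envelope(n, rate, bursts, config.burst_ramp)
        beta_am = _slow_am(n, rate, config.beta_am_tau, config.beta_am_sigma, rng)
        carrier = _phase_carrier(n, rate, config.beta_center, config.beta_carrier_bw, rng)
        x = (
            config.pink_level * _pink(n, rate, rng)
            + config.white_level * rng.standard_normal(n)
            + config.beta_level * (beta_am + burst_env) * np.real(carrier)
        )
        epochs.append(x)
        iv = [(max(s - pad, 0.0), min(e - pad, duration)) for s, e, _ in bursts
              if e > pad and s < pad + duration]
        intervals.append(iv)
    return epochs, intervals
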