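"""Desk-scale validation experiments.

These run the package end to end on its own synthetic data to measure the
quantities the method is built around: the resting threshold-exceedance rate
of the online estimator, and recovery of the burst statistics of the
passive-observation ("No Training") preset by the offline burst quantifier.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .calibration import calibrate_threshold
from .core import BetaBandSpec
from .neurofeedback import stream_powers
from .oscillations import beta_envelope, burst_metrics
from .synth import SessionConfig, default_config, generate_epochs, generate_rest

__all__ = ["rest_exceedance_experiment", "burst_recovery_experiment"]


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def rest_exceedance_experiment(
    config: SessionConfig | None = None,
    n_updates: int = 10_000,
    n_calibrations: int = 100,
    seed: int = 0,
) -> dict:
    """Exceedance rate of the 75th-percentile rest threshold on held-out rest.

    A large pool of online band-power updates is simulated from the rest
    generator; thresholds are then calibrated repeatedly on independent
    30 s rest periods (119 updates each, as in the online protocol) and each
    is applied to the pool.  Returns the mean exceedance percentage, which
    should sit at the design value of 25 %.
    """
    if config is None:
        config = default_config()
    band = BetaBandSpec(channel="LFP", center_f=config.beta_center)
    # many independent rest stretches, so the pool averages over
    # session-level variability rather than a handful of long realizations
    chunk_s = 65.0
    updates_per_chunk = int(np.floor((chunk_s - 0.5) / 0.25)) + 1

    pool = []
    k = 0
    while len(pool) < n_updates:
        cfg = dataclasses.replace(config, seed=(seed * 1_000_003 + k) % (2**31))
        rec = generate_rest(cfg, chunk_s)
        pool.extend(stream_powers(rec.channel(band.channel), band, rec.rate,
                                  0.0, chunk_s, mode="calibration")[:updates_per_chunk])
        k += 1
    pool = np.asarray(pool[:n_updates])

    exceedances = []
    for c in range(n_calibrations):
        cfg = dataclasses.replace(config, seed=(seed * 2_000_003 + 500_000 + c) % (2**31))
        rec = generate_rest(cfg, 30.0)
        cal = stream_powers(rec.channel(band.channel), band, rec.rate,
                            0.0, 30.0, mode="calibration")
        assert len(cal) == 119
        thr = calibrate_threshold(cal)
        exceedances.append(np.mean(pool > thr) * 100.0)
    exceedances = np.asarray(exceedances)
    pool_threshold = calibrate_threshold(pool)
    return {
        "mean_exceedance_pct": float(exceedances.mean()),
        "sem_pct": _sem(exceedances),
        # exceedance of the pool against its own 75th percentile: the
        # large-sample statement of the threshold semantics
        "pool_exceedance_pct": float(np.mean(pool > pool_threshold) * 100.0),
        "n_updates": int(n_updates),
        "n_calibrations": int(n_calibrations),
    }


def burst_recovery_experiment(
    config: SessionConfig | None = None,
    n_sessions: int = 100,
    epochs_per_session: int = 2,
    condition: str = "NoTraining",
    seed: int = 1,
) -> dict:
    """Recover the feedback-phase burst statistics of one condition preset.

    Mirrors the experimental protocol: every simulated session contributes a
    30 s rest period from which the session's envelope threshold is calibrated
    (75th percentile of the smoothed Morlet band envelope), followed by 4 s
    feedback-phase epochs quantified against that threshold.  Ground-truth
    burst intervals give the oracle statistics for the same epochs.
    """
    if config is None:
        config = default_config()
    band = (config.beta_center - 2.0, config.beta_center + 2.0)
    rate = config.sampling_rate
    meas_rate, meas_dur, meas_acc = [], [], []
    gt_rate, gt_dur, gt_acc = [], [], []
    for s in range(n_sessions):
        s_seed = (seed * 100_003 + s) % (2**31)
        rest = generate_rest(dataclasses.replace(config, seed=s_seed), 32.0)
        env = np.real(beta_envelope(rest.channel("LFP"), rate, band).coef[0])
        pad = int(rate)
        thr = float(np.percentile(env[pad:-pad], 75.0))
        ep_seed = (s_seed + 7_919) % (2**31)
        epochs, intervals = generate_epochs(
            dataclasses.replace(config, seed=ep_seed), condition,
            epochs_per_session, duration=4.0, pad=2.0,
            rng=np.random.default_rng(ep_seed),
        )
        for x, iv in zip(epochs, intervals):
            m = burst_metrics(beta_envelope(x, rate, band), thr, window=(2.0, 6.0))
            meas_rate.append(m.rate)
            if np.isfinite(m.mean_duration_ms):
                meas_dur.append(m.mean_duration_ms)
            meas_acc.append(m.accumulated_pct)
            gd = np.array([e - s0 for s0, e in iv])
            gt_rate.append(len(gd) / 4.0)
            if len(gd):
                gt_dur.append(gd.mean() * 1e3)
            gt_acc.append(gd.sum() / 4.0 * 100.0)
    meas_rate, meas_dur, meas_acc = map(np.asarray, (meas_rate, meas_dur, meas_acc))
    params = config.conditions[condition]
    return {
        "n_epochs": int(len(meas_rate)),
        "rate_per_s": float(meas_rate.mean()),
        "rate_sem": _sem(meas_rate),
        "mean_duration_ms": float(meas_dur.mean()),
        "duration_sem_ms": _sem(meas_dur),
        "accumulated_pct": float(meas_acc.mean()),
        "accumulated_sem_pct": _sem(meas_acc),
        "gt_rate_per_s": float(np.mean(gt_rate)),
        "gt_mean_duration_ms": float(np.mean(gt_dur)),
        "gt_accumulated_pct": float(np.mean(gt_acc)),
        "configured_rate_per_s": params.burst_rate,
        "configured_duration_ms": params.burst_duration_mean * 1e3,
    }
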