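"""Motor performance measures: reaction time from pinch force, trial
exclusion, tremor-band accelerometry and rectified EMG amplitude."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import THETA_BAND

__all__ = ["detect_rt", "filter_trials", "tremor_power", "emg_amplitude", "TrialRecord"]

RT_MIN_S = 0.2
RT_MAX_S = 2.0
SUSTAIN_S = 0.1
BASELINE_S = 0.5


@dataclass
class TrialRecord:
    """One analyzed trial; rows of the tidy trial table."""

    hemisphere: str
    day: int
    condition: str
    trial_id: int
    rt: float | None
    valid: bool
    exclusion_reason: str | None


def detect_rt(
    force: np.ndarray,
    rate: float,
    cue_time: float,
    max_rt: float = RT_MAX_S,
) -> float | None:
    """Reaction time from the pinch-force trace, or None when missed.

    The force is low-pass filtered at 20 Hz (4th-order, zero-phase) and
    epoched from 1 s before to 3 s after the cue.  The onset threshold is the
    mean plus three standard deviations of the 500 ms pre-cue segment; the RT
    is the first post-cue crossing that stays above threshold for at least
    100 ms.  No qualifying crossing within ``max_rt`` counts as a miss.
    """
    force = np.asarray(force, dtype=float)
    i_cue = int(round(cue_time * rate))
    i0, i1 = i_cue - int(round(rate)), i_cue + int(round(3 * rate))
    if i0 < 0 or i1 > force.size:
        raise ValueError("force trace must cover cue-1 s .. cue+3 s")
    sos = sps.butter(4, 20.0 / (rate / 2), btype="low", output="sos")
    epoch = sps.sosfiltfilt(sos, force[i0:i1])
    cue = int(round(rate))  # cue index within epoch
    base = epoch[cue - int(round(BASELINE_S * rate)) : cue]
    thr = base.mean() + 3.0 * base.std()
    above = epoch[cue:] > thr
    n_sustain = int(round(SUSTAIN_S * rate))
    # first run of >= n_sustain consecutive supra-threshold samples
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= n_sustain:
            onset = (i - run + 1) / rate
            return onset if onset <= max_rt else None
    return None


def filter_trials(records: pd.DataFrame) -> pd.DataFrame:
    """Apply the exclusion rules; idempotent and order-independent.

    A trial is invalid when the pinch was missed, the RT is implausibly fast
    (< 200 ms, anticipation), or the trial was flagged as artifactual.
    Exactly one reason is recorded per invalid trial.
    """
    out = records.copy()
    rt = out["rt"]
    artifact = out["artifact"] if "artifact" in out else pd.Series(False, index=out.index)
    reason = np.where(
        artifact.fillna(False), "artifact",
        np.where(rt.isna(), "missed", np.where(rt < RT_MIN_S, "too_fast", "")),
    )
    out["exclusion_reason"] = reason
    out["valid"] = reason == ""
    return out


def _axis_band_power(x: np.ndarray, rate: float, band: tuple[float, float]) -> float:
    sos = sps.butter(4, [band[0] / (rate / 2), band[1] / (rate / 2)],
                     btype="bandpass", output="sos")
    y = sps.sosfiltfilt(sos, np.asarray(x, dtype=float))
    return float(np.mean(y**2))


def tremor_power(
    accel: np.ndarray,
    rate: float,
    window: tuple[float, float] | None = None,
    rest_reference: float | None = None,
    band: tuple[float, float] = THETA_BAND,
) -> float:
    """Tremor-band (3-7 Hz) power of a tri-axial accelerometer trace.

    Band power is computed per axis and averaged across the three axes; with a
    rest reference the result is expressed as percent change versus rest
    (the same normalization convention as the LFP power maps).
    """
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[0] != 3:
        raise ValueError("accel must be (3, n_samples): three axes required")
    if window is not None:
        i0, i1 = (int(round(w * rate)) for w in window)
        if not 0 <= i0 < i1 <= accel.shape[1]:
            raise ValueError("window outside trace")
        accel = accel[:, i0:i1]
    p = np.mean([_axis_band_power(ax, rate, band) for ax in accel])
    if rest_reference is None:
        return float(p)
    if rest_reference <= 0:
        raise ValueError("rest reference power must be positive")
    return float((p - rest_reference) / rest_reference * 100.0)


def emg_amplitude(emg: np.ndarray, rate: float,
                  window: tuple[float, float] | None = None) -> float:
    """Mean rectified EMG (after a 20 Hz high-pass) over the window."""
    emg = np.asarray(emg, dtype=float)
    if window is not None:
        i0, i1 = (int(round(w * rate)) for w in window)
        if not 0 <= i0 < i1 <= emg.size:
            raise ValueError("window outside trace")
        emg = emg[i0:i1]
    if emg.size == 0:
        raise ValueError("empty window")
    sos = sps.butter(4, 20.0 / (rate / 2), btype="high", output="sos")
    return float(np.mean(np.abs(sps.sosfiltfilt(sos, emg))))
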