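"""Deterministic re-implementation of the online neurofeedback loop.

Every 250 ms the band power of the trailing 500 ms of the selected bipolar
LFP is computed (mean subtraction, 5-85 Hz band pass, FFT power spectrum,
average over the five 1 Hz bins of the patient's beta band).  During the
feedback phase the basketball moves right at constant speed and drops one
step whenever the update exceeds the session threshold T; the step is sized
so that crossing on 25 % of updates lands the ball at the bottom exactly at
phase end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import BetaBandSpec

__all__ = ["FeedbackTrace", "compute_update_power", "stream_powers", "simulate_ball"]

WINDOW_S = 0.5
HOP_S = 0.25


@dataclass
class FeedbackTrace:
    """Per-update state of the ball during one feedback phase."""

    update_times: np.ndarray  # s, one per 250 ms update
    powers: np.ndarray
    threshold: float
    crossings: np.ndarray  # bool
    ball_x: np.ndarray
    ball_y: np.ndarray  # in [0, 1], 1 = top of screen
    drop_step: float

    @property
    def final_y(self) -> float:
        return float(self.ball_y[-1])

    def __post_init__(self) -> None:
        if np.any(np.diff(self.ball_y) > 1e-12):
            raise ValueError("ball_y must be nonincreasing")
        if np.any(self.ball_y < -1e-12):
            raise ValueError("ball_y must stay above the bottom of the screen")


_sos_cache: dict[tuple[float, float, float], np.ndarray] = {}


def _bandpass_sos(rate: float, lo: float = 5.0, hi: float = 85.0) -> np.ndarray:
    key = (rate, lo, hi)
    if key not in _sos_cache:
        _sos_cache[key] = sps.butter(4, [lo / (rate / 2), hi / (rate / 2)],
                                     btype="bandpass", output="sos")
    return _sos_cache[key]


def compute_update_power(window: np.ndarray, band: BetaBandSpec, rate: float) -> float:
    """Band power of one 500 ms window, as the online estimator computes it.

    Mean subtraction, zero-phase 4th-order 5-85 Hz band pass, one-sided FFT
    power spectrum, then the average of the bins whose centre frequencies lie
    in [center_f - 2, center_f + 2] (bin spacing 2 Hz for a 500 ms window).
    """
    window = np.asarray(window, dtype=float)
    n_expect = int(round(rate * WINDOW_S))
    if window.size != n_expect:
        raise ValueError(f"window must hold {n_expect} samples ({WINDOW_S * 1e3:.0f} ms)")
    if not np.all(np.isfinite(window)):
        raise ValueError("window contains non-finite samples")
    x = window - window.mean()
    if np.any(x != 0.0):
        x = sps.sosfiltfilt(_bandpass_sos(rate), x)
    spec = np.fft.rfft(x)
    n = x.size
    power = (np.abs(spec) ** 2) * 2.0 / n**2
    power[0] /= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    lo, hi = band.band
    sel = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    return float(power[sel].mean())


def stream_powers(
    signal: np.ndarray,
    band: BetaBandSpec,
    rate: float,
    phase_start: float,
    phase_duration: float,
    mode: str = "feedback",
) -> np.ndarray:
    """Sequence of 250 ms band-power updates over one phase.

    ``mode="feedback"``: one update per 250 ms of phase (16 for 4 s, 32 for
    8 s), each on the trailing 500 ms, so the first window reaches back
    before the phase onset.  ``mode="calibration"``: only windows fully
    inside the phase are used, giving floor((duration - 0.5) / 0.25) + 1
    updates (119 for the 30 s rest period).
    """
    signal = np.asarray(signal, dtype=float)
    n_win = int(round(rate * WINDOW_S))
    n_hop = int(round(rate * HOP_S))
    if mode == "feedback":
        n_updates = int(round(phase_duration / HOP_S))
        first_end = int(round(phase_start * rate)) + n_hop
        if first_end - n_win < 0 or phase_start < WINDOW_S:
            raise ValueError("need at least 500 ms of signal before the phase start")
        ends = first_end + n_hop * np.arange(n_updates)
    elif mode == "calibration":
        n_updates = int(math.floor((phase_duration - WINDOW_S) / HOP_S)) + 1
        if n_updates < 1:
            raise ValueError("phase too short for a single 500 ms window")
        start = int(round(phase_start * rate))
        ends = start + n_win + n_hop * np.arange(n_updates)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if ends[-1] > signal.size:
        raise ValueError("signal too short for the requested phase")
    return np.array(
        [compute_update_power(signal[e - n_win : e], band, rate) for e in ends]
    )


def simulate_ball(
    powers: np.ndarray,
    threshold: float,
    phase_duration: float,
    y0: float = 1.0,
    x_span: float = 1.0,
) -> FeedbackTrace:
    """Run the basketball state machine over one feedback phase.

    The drop step is y0 / ceil(0.25 * n_updates): crossing the threshold on a
    quarter of the updates (the resting expectation) brings the ball exactly
    to the bottom.  The ball never goes below the bottom and x advances by a
    constant increment per update.
    """
    powers = np.asarray(powers, dtype=float)
    if powers.size == 0:
        raise ValueError("empty power sequence")
    n = powers.size
    if n != int(round(phase_duration / HOP_S)):
        raise ValueError("power count does not match phase duration / 250 ms")
    drop_step = y0 / math.ceil(0.25 * n)
    crossings = powers > threshold
    y = np.empty(n)
    cur = y0
    for i, c in enumerate(crossings):
        if c:
            cur = max(cur - drop_step, 0.0)
        y[i] = cur
    x = x_span * np.arange(1, n + 1) / n
    times = HOP_S * np.arange(1, n + 1)
    return FeedbackTrace(
        update_times=times,
        powers=powers,
        threshold=float(threshold),
        crossings=crossings,
        ball_x=x,
        ball_y=y,
        drop_step=drop_step,
    )
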