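"""Channel re-montaging, beta-band selection and rest threshold calibration.

Before each experiment the monopolar STN contacts are re-referenced to
adjacent bipolar pairs; the bipolar channel with the largest movement-related
beta (13-30 Hz) desynchronization is selected, and a patient-specific 5 Hz
band [f-2, f+2] is centred on the frequency of maximal modulation.  At the
start of every session the burst threshold T is set to the 75th percentile of
the online band-power updates computed while the patient rests.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps

from .core import BETA_SEARCH_BAND, BetaBandSpec, Recording

__all__ = ["remontage_bipolar", "select_target", "calibrate_threshold"]


def remontage_bipolar(rec: Recording, adjacency: list[tuple[str, str]]) -> Recording:
    """Subtract adjacent contact pairs: one bipolar channel per (a, b) pair."""
    if rec.montage != "monopolar":
        raise ValueError("remontage_bipolar expects a monopolar recording")
    seen = set()
    rows, labels, modality = [], [], []
    for a, b in adjacency:
        if (a, b) in seen:
            raise ValueError(f"duplicate pair {(a, b)}")
        seen.add((a, b))
        rows.append(rec.channel(a) - rec.channel(b))  # KeyError on unknown label
        labels.append(f"{a}-{b}")
        modality.append(rec.modality[rec.labels.index(a)])
    return Recording(np.vstack(rows), rec.rate, labels, modality, montage="bipolar")


def _psd_1hz(x: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD on a 1 Hz grid (1 s segments, 50 % overlap)."""
    nper = int(round(rate))
    f, p = sps.welch(x, fs=rate, nperseg=min(nper, len(x)), noverlap=min(nper, len(x)) // 2)
    return f, p


def select_target(rest: Recording, move_epochs: list[Recording]) -> BetaBandSpec:
    """Select the bipolar channel and 5 Hz band with maximal movement-related
    beta desynchronization.

    For every channel the percent change ((move - rest) / rest * 100) of the
    Welch power on a 1 Hz grid is averaged over 13-30 Hz; the channel with the
    most negative average is selected.  Within it, the band is centred on the
    integer frequency of the most negative modulation, clipped so the centre
    stays inside 13-30 Hz.  If no channel desynchronizes, a warning is raised
    and the channel with the largest absolute modulation is returned.
    """
    if rest.montage != "bipolar":
        raise ValueError("select_target expects bipolar LFP channels")
    if not move_epochs:
        raise ValueError("at least one movement epoch required")
    lo, hi = BETA_SEARCH_BAND
    best = None
    for ci, label in enumerate(rest.labels):
        f, p_rest = _psd_1hz(rest.data[ci], rest.rate)
        p_move = np.mean(
            [_psd_1hz(ep.channel(label), ep.rate)[1] for ep in move_epochs], axis=0
        )
        sel = (f >= lo) & (f <= hi)
        if p_rest[sel].min() <= 0:
            raise ValueError(f"nonpositive rest power in channel {label}")
        mod = (p_move[sel] - p_rest[sel]) / p_rest[sel] * 100.0
        score = mod.mean()
        if best is None or score < best[0]:
            best = (score, label, f[sel], mod)
    score, label, freqs, mod = best
    if score >= 0:
        warnings.warn(
            "no channel shows a movement-related beta reduction; "
            "returning the maximal-modulation channel anyway",
            stacklevel=2,
        )
    if np.allclose(mod, 0.0):
        warnings.warn("degenerate input: rest and movement spectra identical", stacklevel=2)
    center = float(freqs[int(np.argmin(mod))])
    center = float(np.clip(center, lo, hi))
    return BetaBandSpec(channel=label, center_f=center)


def calibrate_threshold(rest_powers) -> float:
    """Burst threshold T: 75th percentile (linear interpolation) of rest updates.

    With many rest updates the fraction of updates above T converges to 25 %,
    the design target for the resting ball-drop rate.
    """
    x = np.asarray(rest_powers, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 rest power values to calibrate")
    if not np.all(np.isfinite(x)):
        raise ValueError("rest powers must be finite")
    if (x < 0).any():
        raise ValueError("rest powers must be nonnegative")
    return float(np.percentile(x, 75.0))
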