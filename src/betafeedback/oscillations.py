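"""Offline spectral pipeline.

Filtering, complex Morlet time-frequency maps on a 1-95 Hz grid (cycle count
linear from 4 to 8 across the grid), rest normalization to percent change,
windowed band powers, beta-burst characteristics against the session
threshold, and STN-cortex connectivity (phase synchrony index and spectral
coherence computed from the wavelet coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from mne.time_frequency import morlet as _mne_morlet
from scipy import fft as sp_fft
from scipy import signal as sps

from .core import Recording

__all__ = [
    "TFMap",
    "BurstMetrics",
    "preprocess",
    "morlet_tf",
    "rest_profile",
    "normalize_percent_change",
    "band_power",
    "beta_envelope",
    "burst_metrics",
    "psi",
    "coherence",
]

TF_FREQS = np.arange(1.0, 96.0)  # 1..95 Hz, 1 Hz resolution
TF_CYCLES = np.linspace(4.0, 8.0, TF_FREQS.size)  # linear in frequency
ENVELOPE_SMOOTH_S = 0.2  # moving-average window applied before burst thresholding


def _cycles_for(freqs: np.ndarray) -> np.ndarray:
    """Cycle counts for arbitrary frequencies, from the same linear 4-8 map."""
    return 4.0 + (np.asarray(freqs, float) - TF_FREQS[0]) * 4.0 / (TF_FREQS[-1] - TF_FREQS[0])


def _max_wavelet_samples(rate: float, freqs: np.ndarray) -> int:
    # wavelets live on +-5 sigma_t, sigma_t = n_cycles / (2 pi f)
    sigma_t = _cycles_for(freqs) / (2 * np.pi * np.asarray(freqs, float))
    return int(np.ceil(10.0 * sigma_t.max() * rate)) + 1


_wavelet_cache: dict = {}
_bank_cache: dict = {}


def cwt_morlet(data: np.ndarray, rate: float, freqs: np.ndarray,
               n_cycles: np.ndarray) -> np.ndarray:
    """Batched continuous Morlet transform via FFT convolution.

    Wavelets are the standard zero-mean, L2-normalized complex Morlets (built
    with MNE's constructor); the convolution is vectorized over frequencies,
    which keeps long multi-window sessions tractable.  ``data`` is
    (n_channels, n_samples); returns (n_channels, n_freqs, n_samples).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[-1]
    key0 = (rate, tuple(np.asarray(freqs, float)), tuple(np.asarray(n_cycles, float)))
    ws = _wavelet_cache.get(key0)
    if ws is None:
        ws = _mne_morlet(rate, np.asarray(freqs, float), n_cycles=np.asarray(n_cycles, float),
                         zero_mean=True)
        if len(_wavelet_cache) > 16:
            _wavelet_cache.clear()
        _wavelet_cache[key0] = ws
    max_w = max(len(w) for w in ws)
    if n < max_w:
        raise ValueError(f"signal too short for the longest wavelet ({n} < {max_w} samples)")
    nfft = sp_fft.next_fast_len(n + max_w - 1)
    bank_key = (key0, nfft)
    bank = _bank_cache.get(bank_key)
    if bank is None:
        bank = np.stack([sp_fft.fft(w, nfft) for w in ws])
        if len(_bank_cache) > 8:
            _bank_cache.clear()
        _bank_cache[bank_key] = bank
    out = np.empty((data.shape[0], len(ws), n), dtype=complex)
    for ci in range(data.shape[0]):
        full = sp_fft.ifft(sp_fft.fft(data[ci], nfft)[None, :] * bank, axis=-1)
        for k, w in enumerate(ws):
            start = (len(w) - 1) // 2  # center the 'full' convolution
            out[ci, k] = full[k, start : start + n]
    return out


@dataclass
class TFMap:
    """Complex Morlet coefficients, shape (n_freqs, n_times)."""

    coef: np.ndarray
    freqs: np.ndarray
    rate: float
    t0: float = 0.0  # time of the first sample on the caller's clock

    def __post_init__(self) -> None:
        if self.coef.ndim != 2 or self.coef.shape[0] != self.freqs.size:
            raise ValueError("coef must be (n_freqs, n_times)")
        if not np.all(np.isfinite(self.coef)):
            raise ValueError("non-finite wavelet coefficients")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.coef.shape[1]) / self.rate

    def magnitude(self) -> np.ndarray:
        return np.abs(self.coef)

    def phase(self) -> np.ndarray:
        return np.angle(self.coef)

    def power(self) -> np.ndarray:
        return np.abs(self.coef) ** 2

    def trim(self, start_s: float, stop_s: float) -> "TFMap":
        i0 = int(round((start_s - self.t0) * self.rate))
        i1 = int(round((stop_s - self.t0) * self.rate))
        if not 0 <= i0 < i1 <= self.coef.shape[1]:
            raise ValueError("trim window outside map")
        return replace(self, coef=self.coef[:, i0:i1], t0=start_s)

    def _window_slice(self, window: tuple[float, float] | None) -> slice:
        if window is None:
            return slice(None)
        i0 = int(round((window[0] - self.t0) * self.rate))
        i1 = int(round((window[1] - self.t0) * self.rate))
        if not 0 <= i0 <= i1 <= self.coef.shape[1]:
            raise ValueError("window outside map")
        if i1 == i0:
            raise ValueError("empty analysis window")
        return slice(i0, i1)

    def _band_rows(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        if lo < self.freqs[0] - 1e-9 or hi > self.freqs[-1] + 1e-9:
            raise ValueError(f"band {band} outside the {self.freqs[0]:.0f}-"
                             f"{self.freqs[-1]:.0f} Hz grid")
        rows = np.where((self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9))[0]
        if rows.size == 0:
            raise ValueError(f"no grid frequencies inside band {band}")
        return rows


def preprocess(rec: Recording) -> Recording:
    """Zero-phase 4th-order 0.5-100 Hz band pass plus 50 Hz notch, per channel."""
    if rec.rate <= 200.0:
        raise ValueError("sampling rate too low for a 100 Hz band edge")
    nyq = rec.rate / 2
    bp = sps.butter(4, [0.5 / nyq, 100.0 / nyq], btype="bandpass", output="sos")
    notch = sps.butter(4, [48.0 / nyq, 52.0 / nyq], btype="bandstop", output="sos")
    data = sps.sosfiltfilt(notch, sps.sosfiltfilt(bp, rec.data, axis=1), axis=1)
    return Recording(data, rec.rate, list(rec.labels), list(rec.modality), rec.montage)


def morlet_tf(signal: np.ndarray, rate: float, t0: float = 0.0) -> TFMap:
    """Continuous complex Morlet transform on the 1-95 Hz grid."""
    signal = np.asarray(signal, dtype=float)
    need = _max_wavelet_samples(rate, TF_FREQS[:1])
    if signal.size < need:
        raise ValueError(
            f"signal too short for the 1 Hz wavelet ({signal.size} < {need} samples)"
        )
    out = cwt_morlet(signal[np.newaxis, :], rate, TF_FREQS, TF_CYCLES)
    return TFMap(coef=out[0], freqs=TF_FREQS.copy(), rate=rate, t0=t0)


def rest_profile(tf: TFMap, rest_intervals: list[tuple[float, float]]) -> np.ndarray:
    """Per-frequency mean power over the rest intervals (normalization baseline)."""
    if not rest_intervals:
        raise ValueError("rest intervals must be nonempty")
    chunks = [tf.power()[:, tf._window_slice(w)] for w in rest_intervals]
    return np.concatenate(chunks, axis=1).mean(axis=1)


def normalize_percent_change(
    tf: TFMap,
    rest_intervals: list[tuple[float, float]] | None = None,
    baseline: np.ndarray | None = None,
) -> np.ndarray:
    """Percent change of power relative to the rest baseline, per frequency.

    The baseline may be given directly (per-frequency rest power from another
    segment of the same experiment) or computed from intervals of this map.
    """
    if baseline is None:
        if rest_intervals is None:
            raise ValueError("need rest_intervals or a precomputed baseline")
        baseline = rest_profile(tf, rest_intervals)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != (tf.freqs.size,):
        raise ValueError("baseline must hold one value per grid frequency")
    if np.any(baseline <= 0):
        raise ValueError("zero or negative rest power at some frequency")
    return (tf.power() - baseline[:, None]) / baseline[:, None] * 100.0


def band_power(
    values: np.ndarray,
    tf: TFMap,
    band: tuple[float, float],
    window: tuple[float, float] | None = None,
    db: bool = False,
) -> float:
    """Mean of ``values`` (a per-freq x time map aligned with ``tf``) over the
    band's grid bins and the time window.  With ``db=True`` the mean is
    10*log10-transformed (used for raw power entering the mixed models)."""
    values = np.asarray(values, dtype=float)
    if values.shape != tf.coef.shape:
        raise ValueError("values must align with the TF map")
    rows = tf._band_rows(band)
    cols = tf._window_slice(window)
    m = float(values[rows, cols].mean())
    if db:
        if m <= 0:
            raise ValueError("nonpositive power cannot be dB-transformed")
        return float(10.0 * np.log10(m))
    return m


def beta_envelope(
    signal: np.ndarray,
    rate: float,
    band: tuple[float, float],
    smooth: float = ENVELOPE_SMOOTH_S,
    t0: float = 0.0,
) -> TFMap:
    """Smoothed band amplitude envelope for burst analysis.

    Morlet magnitudes on the integer frequencies of the 5 Hz band (cycle
    counts from the same linear 4-8 map) are averaged across bins and smoothed
    with a moving average, following standard practice for beta-burst
    quantification.  Returned as a single-row TFMap-like carrier so windowing
    helpers can be reused; the row holds the envelope.
    """
    freqs = np.arange(np.ceil(band[0] - 1e-9), np.floor(band[1] + 1e-9) + 1)
    out = cwt_morlet(np.asarray(signal, float)[np.newaxis, :], rate, freqs, _cycles_for(freqs))
    env = np.abs(out[0]).mean(axis=0)
    if smooth and smooth > 0:
        k = max(int(round(smooth * rate)), 1)
        env = np.convolve(env, np.ones(k) / k, mode="same")
    return TFMap(coef=env[np.newaxis, :].astype(complex), freqs=np.array([np.mean(band)]),
                 rate=rate, t0=t0)


@dataclass
class BurstMetrics:
    """Supra-threshold run statistics of a band envelope within a window."""

    accumulated_pct: float  # % of window above threshold
    mean_duration_ms: float  # nan when no burst
    rate: float  # bursts / s
    durations_s: np.ndarray
    histogram: np.ndarray  # counts per duration bin
    bin_edges_s: np.ndarray
    n_long: int  # bursts > 400 ms
    n_short: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.accumulated_pct <= 100.0 + 1e-9:
            raise ValueError("accumulated_pct must lie in [0, 100]")


def burst_metrics(
    envelope: TFMap | np.ndarray,
    threshold: float,
    rate: float | None = None,
    window: tuple[float, float] | None = None,
    hist_bin_s: float = 0.1,
    long_cutoff_s: float = 0.4,
) -> BurstMetrics:
    """Quantify supra-threshold bursts of an amplitude envelope.

    A burst is a maximal contiguous run above ``threshold``; runs truncated by
    the window edges are counted with their truncated lengths.  The histogram
    uses ``hist_bin_s`` bins and the long/short split at 400 ms follows the
    observation that long bursts respond most consistently to training.
    """
    if isinstance(envelope, TFMap):
        rate = envelope.rate
        env = np.real(envelope.coef[0, envelope._window_slice(window)])
    else:
        if rate is None:
            raise ValueError("rate required for a bare envelope array")
        env = np.asarray(envelope, dtype=float)
        if window is not None:
            i0, i1 = (int(round(w * rate)) for w in window)
            if not 0 <= i0 < i1 <= env.size:
                raise ValueError("window outside envelope")
            env = env[i0:i1]
    if env.size < 1:
        raise ValueError("window shorter than one sample")
    above = env > threshold
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    durs = (ends - starts) / rate
    window_s = env.size / rate
    acc = float(above.mean() * 100.0)
    edges = np.arange(0.0, max(durs.max() if durs.size else 0.0, long_cutoff_s) + 2 * hist_bin_s,
                      hist_bin_s)
    hist, _ = np.histogram(durs, bins=edges)
    return BurstMetrics(
        accumulated_pct=acc,
        mean_duration_ms=float(durs.mean() * 1e3) if durs.size else float("nan"),
        rate=float(durs.size / window_s),
        durations_s=durs,
        histogram=hist,
        bin_edges_s=edges,
        n_long=int((durs > long_cutoff_s).sum()),
        n_short=int((durs <= long_cutoff_s).sum()),
    )


def _check_aligned(a: TFMap, b: TFMap) -> None:
    if a.coef.shape != b.coef.shape or not np.allclose(a.freqs, b.freqs) or a.rate != b.rate:
        raise ValueError("time-frequency maps must share grid and window")


def psi(
    tf_lfp: TFMap,
    tf_eeg: TFMap,
    band: tuple[float, float],
    window: tuple[float, float] | None = None,
) -> float:
    """Phase synchrony index between two channels, averaged over band bins.

    Per frequency: | n^-1 sum_t exp(i (phi_lfp - phi_eeg)) | over the n window
    time points; invariant to any per-channel amplitude scaling.
    """
    _check_aligned(tf_lfp, tf_eeg)
    rows = tf_lfp._band_rows(band)
    cols = tf_lfp._window_slice(window)
    dphi = tf_lfp.phase()[rows, cols] - tf_eeg.phase()[rows, cols]
    return float(np.abs(np.exp(1j * dphi).mean(axis=1)).mean())


def coherence(
    tf_lfp: TFMap,
    tf_eeg: TFMap,
    band: tuple[float, float],
    window: tuple[float, float] | None = None,
) -> float:
    """Spectral coherence from wavelet coefficients, averaged over band bins.

    Per frequency: |<m1 m2 e^{i dphi}>|^2 / (<m1^2><m2^2>), the
    amplitude-weighted phase consistency normalized by both powers.
    """
    _check_aligned(tf_lfp, tf_eeg)
    rows = tf_lfp._band_rows(band)
    cols = tf_lfp._window_slice(window)
    a = tf_lfp.coef[rows, cols]
    b = tf_eeg.coef[rows, cols]
    p1 = (np.abs(a) ** 2).mean(axis=1)
    p2 = (np.abs(b) ** 2).mean(axis=1)
    if np.any(p1 == 0) or np.any(p2 == 0):
        raise ValueError("zero-power window in a band bin")
    cross = (np.abs(a) * np.abs(b) * np.exp(1j * (np.angle(a) - np.angle(b)))).mean(axis=1)
    return float((np.abs(cross) ** 2 / (p1 * p2)).mean())
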