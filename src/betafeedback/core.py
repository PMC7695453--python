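"""Core containers shared across the package.

A :class:`Recording` is a plain multichannel time series (channels x samples)
with per-channel modality labels, as produced by a DBS-externalization
recording setup: bipolar subthalamic LFP, EEG over motor cortex, EMG,
tri-axial accelerometer and pinch force, all sampled at a common rate.

Events are kept in a tidy :class:`pandas.DataFrame` (one row per marker) with
the columns ``onset_s, duration_s, kind, condition, trial_id``; helper
functions below construct and validate that frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: canonical analysis bands (Hz); the beta band is patient-specific instead
ALPHA_BAND = (8.0, 12.0)
THETA_BAND = (3.0, 7.0)  # also the Parkinsonian tremor band
GAMMA_BAND = (55.0, 95.0)
BETA_SEARCH_BAND = (13.0, 30.0)

EVENT_COLUMNS = ["onset_s", "duration_s", "kind", "condition", "trial_id"]

#: event kinds emitted by the session generator / expected by the pipeline
EVENT_KINDS = ("rest", "block", "ready", "feedback", "precue", "go_cue")

CONDITIONS = ("Training", "NoTraining")


@dataclass
class Recording:
    """Multichannel recording: ``data`` has shape (n_channels, n_samples)."""

    data: np.ndarray
    rate: float
    labels: list[str]
    modality: list[str]
    montage: str = "monopolar"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if len(self.modality) != len(self.labels):
            raise ValueError("one modality per channel required")
        if self.montage not in ("monopolar", "bipolar"):
            raise ValueError(f"unknown montage {self.montage!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by label (a view, not a copy)."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None
        return self.data[idx]

    def pick(self, labels: list[str]) -> "Recording":
        idx = [self.labels.index(l) for l in labels]
        return Recording(
            self.data[idx].copy(),
            self.rate,
            [self.labels[i] for i in idx],
            [self.modality[i] for i in idx],
            self.montage,
        )

    def segment(self, start_s: float, stop_s: float) -> "Recording":
        """Time slice [start_s, stop_s) as a new Recording."""
        i0, i1 = int(round(start_s * self.rate)), int(round(stop_s * self.rate))
        if not 0 <= i0 < i1 <= self.n_samples:
            raise ValueError("segment outside recording")
        return replace(self, data=self.data[:, i0:i1].copy())


def make_event_table(rows: list[dict]) -> pd.DataFrame:
    """Build a validated event table from row dicts."""
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return validate_event_table(df)


def validate_event_table(df: pd.DataFrame) -> pd.DataFrame:
    if list(df.columns) != EVENT_COLUMNS:
        raise ValueError(f"event table must have columns {EVENT_COLUMNS}")
    if len(df) and (df["onset_s"] < 0).any():
        raise ValueError("event onsets must be nonnegative")
    unknown = set(df["kind"]) - set(EVENT_KINDS)
    if unknown:
        raise ValueError(f"unknown event kinds: {sorted(unknown)}")
    return df.sort_values("onset_s", kind="stable").reset_index(drop=True)


def events_of_kind(events: pd.DataFrame, kind: str, condition: str | None = None) -> pd.DataFrame:
    out = events[events["kind"] == kind]
    if condition is not None:
        out = out[out["condition"] == condition]
    return out.reset_index(drop=True)


@dataclass
class BetaBandSpec:
    """Selected bipolar LFP channel and its patient-specific 5 Hz beta band.

    ``band`` spans [center_f - 2, center_f + 2]: five one-Hz bins on the
    integer analysis grid.  ``threshold`` is the session's burst threshold in
    the band-power units of the online estimator (set at calibration time).
    """

    channel: str
    center_f: float
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not (BETA_SEARCH_BAND[0] <= self.center_f <= BETA_SEARCH_BAND[1]):
            raise ValueError(
                f"beta center {self.center_f} Hz outside the "
                f"{BETA_SEARCH_BAND[0]:.0f}-{BETA_SEARCH_BAND[1]:.0f} Hz search range"
            )

    @property
    def band(self) -> tuple[float, float]:
        return (self.center_f - 2.0, self.center_f + 2.0)


def shift_band(band: tuple[float, float], delta: float) -> tuple[float, float]:
    """Shift a (lo, hi) band by ``delta`` Hz (used for the Beta±8 controls)."""
    return (band[0] + delta, band[1] + delta)
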