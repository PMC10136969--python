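"""Shared in-memory containers for the EEG analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RawRecording:
    """Continuous multichannel EEG with response event markers.

    data : (n_channels, n_samples) array, microvolts
    sfreq : sampling rate in Hz
    ch_names : 10-20 channel labels, one per row of ``data``
    events : one row per *responded* trial, with columns
        ``sample`` (response sample index), ``block``, ``trial_index``,
        ``outcome`` ('hit' or 'false_alarm')
    blink_ref : optional ground-truth blink time course (n_samples,), used
        as the reference trace for artifact-component removal
    """

    data: np.ndarray
    sfreq: float
    ch_names: tuple
    events: pd.DataFrame
    blink_ref: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match data rows")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if len(self.events) and (
            (self.events["sample"] < 0).any()
            or (self.events["sample"] >= self.data.shape[1]).any()
        ):
            raise ValueError("event samples outside recording bounds")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "RawRecording":
        return RawRecording(
            data=self.data.copy(),
            sfreq=self.sfreq,
            ch_names=tuple(self.ch_names),
            events=self.events.copy(),
            blink_ref=None if self.blink_ref is None else self.blink_ref.copy(),
        )


@dataclass
class EpochSet:
    """Response-locked trials x channels x samples on a common time axis.

    Rejected epochs are flagged in ``rejected``, never silently dropped.
    ``event_rows`` holds, for each epoch, the index of the originating row
    in the events table; ``edge_excluded`` lists event rows whose full
    window did not fit inside the recording.
    """

    data: np.ndarray                 # (n_epochs, n_channels, n_times)
    times_ms: np.ndarray             # common axis, 0 = button press
    ch_names: tuple
    event_rows: np.ndarray           # (n_epochs,) indices into events table
    rejected: np.ndarray = None      # (n_epochs,) bool
    edge_excluded: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.rejected is None:
            self.rejected = np.zeros(len(self.data), dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D")
        if self.data.shape[2] != len(self.times_ms):
            raise ValueError("time axis length mismatch")

    @property
    def n_epochs(self) -> int:
        return len(self.data)

    @property
    def n_retained(self) -> int:
        return int((~self.rejected).sum())

    def retained(self) -> np.ndarray:
        return self.data[~self.rejected]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times_ms=self.times_ms.copy(),
            ch_names=tuple(self.ch_names),
            event_rows=self.event_rows.copy(),
            rejected=self.rejected.copy(),
            edge_excluded=self.edge_excluded.copy(),
        )


@dataclass
class RoiSeries:
    """A single ROI-averaged time series (amplitude in uV or power in dB)."""

    times_ms: np.ndarray
    values: np.ndarray
    condition: str = ""
    subject: object = None
    n_epochs: int = 0
    units: str = "uV"

    def __post_init__(self) -> None:
        if len(self.times_ms) != len(self.values):
            raise ValueError("times and values length mismatch")
        if self.n_epochs < 1:
            raise ValueError("a ROI series needs at least one epoch")
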