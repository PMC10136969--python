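"""Plain-text readers and writers for recordings, events, and epochs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet, RawRecording

__all__ = [
    "write_eeg_csv",
    "read_eeg_csv",
    "write_events_tsv",
    "read_events_tsv",
    "export_epochs",
    "load_epochs",
]

EVENT_COLUMNS = [
    "onset_ms", "block", "trial_index", "stimulus", "response", "rt_ms", "outcome",
]


def write_eeg_csv(raw: RawRecording, path) -> None:
    """Continuous EEG as CSV: one column per channel, 10-20 labels header."""
    pd.DataFrame(raw.data.T, columns=list(raw.ch_names)).to_csv(path, index=False)


def read_eeg_csv(path, sfreq: float = 128.0,
                 events: pd.DataFrame | None = None) -> RawRecording:
    df = pd.read_csv(path)
    if events is None:
        events = pd.DataFrame(
            {"sample": pd.Series(dtype=int), "block": pd.Series(dtype=int),
             "trial_index": pd.Series(dtype=int), "outcome": pd.Series(dtype=object)}
        )
    return RawRecording(
        data=df.to_numpy().T, sfreq=sfreq, ch_names=tuple(df.columns), events=events
    )


def write_events_tsv(behavior: pd.DataFrame, path) -> None:
    """Trial/event table as TSV in the package's interchange dialect."""
    out = pd.DataFrame(
        {
            "onset_ms": behavior["onset_ms"],
            "block": behavior["block"],
            "trial_index": behavior["trial_index"],
            "stimulus": behavior["stimulus"].replace({"nogo": "no-go"}),
            "response": behavior["responded"].astype(int),
            "rt_ms": behavior["rt_ms"],
            "outcome": behavior["outcome"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    df["stimulus"] = df["stimulus"].replace({"no-go": "nogo"})
    df["responded"] = df["response"].astype(bool)
    return df.drop(columns=["response"])


def export_epochs(epochs: EpochSet, basepath) -> tuple:
    """Epoch array to .npy with a JSON sidecar (axis, labels, masks)."""
    basepath = Path(basepath)
    npy = basepath.with_suffix(".npy")
    meta = basepath.with_suffix(".json")
    np.save(npy, epochs.data)
    with open(meta, "w") as fh:
        json.dump(
            {
                "times_ms": epochs.times_ms.tolist(),
                "ch_names": list(epochs.ch_names),
                "event_rows": epochs.event_rows.tolist(),
                "rejected": epochs.rejected.tolist(),
                "edge_excluded": epochs.edge_excluded.tolist(),
            },
            fh,
        )
    return npy, meta


def load_epochs(basepath) -> EpochSet:
    basepath = Path(basepath)
    data = np.load(basepath.with_suffix(".npy"))
    with open(basepath.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return EpochSet(
        data=data,
        times_ms=np.array(meta["times_ms"]),
        ch_names=tuple(meta["ch_names"]),
        event_rows=np.array(meta["event_rows"], dtype=int),
        rejected=np.array(meta["rejected"], dtype=bool),
        edge_excluded=np.array(meta["edge_excluded"], dtype=int),
    )
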