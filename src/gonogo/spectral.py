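"""Event-related spectral perturbations via a 1-Hz Hilbert filter bank.

The power path mirrors the amplitude path up to component removal, then:
re-reference the continuous signal, narrowband-filter it in 1-Hz steps,
take the squared Hilbert envelope per step, average steps into the band
of interest, segment the power around the response, average power over
retained trials *first*, and only then convert to decibels against the
pre-response baseline.  Normalizing the trial average (rather than
averaging single-trial dB) keeps the estimate unbiased for heterogeneous
trial power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .containers import EpochSet, RawRecording, RoiSeries
from .preprocess import (
    REFERENCE_CHANNELS,
    ROI_CHANNELS,
    fir_bandpass,
    remove_artifact_components,
    segment_epochs,
)

__all__ = [
    "band_bins",
    "hilbert_band_power",
    "db_normalize_trial_average",
    "ersp_roi",
    "tf_power_map",
]


def band_bins(band_lo: float, band_hi: float, bin_width: float = 1.0,
              mode: str = "centered") -> list:
    """1-Hz analysis bins covering [band_lo, band_hi].

    'centered' (default): one bin [f - w/2, f + w/2] per integer frequency
    f in the closed range — the 4-7 Hz theta band uses four bins centered
    at 4, 5, 6 and 7 Hz.  'edges': contiguous [k, k + w) bins fully inside
    the range — theta uses [4,5), [5,6), [6,7).
    """
    if not 1.0 <= band_lo < band_hi <= 30.0:
        raise ValueError("band must lie within [1, 30] Hz")
    half = bin_width / 2.0
    if mode == "centered":
        centers = np.arange(np.ceil(band_lo), np.floor(band_hi) + 1)
        return [(float(c - half), float(c + half)) for c in centers]
    if mode == "edges":
        edges = np.arange(band_lo, band_hi, bin_width)
        return [(float(e), float(e + bin_width)) for e in edges]
    raise ValueError(f"unknown bin mode {mode!r}")


def hilbert_band_power(
    data,
    band_lo: float = 4.0,
    band_hi: float = 7.0,
    sfreq: float | None = None,
    bin_width: float = 1.0,
    bin_mode: str = "centered",
    transition_hz: float = 0.5,
) -> np.ndarray:
    """Instantaneous band power from a Hilbert filter bank (uV^2).

    For each 1-Hz bin the continuous signal is narrowband FIR-filtered
    (zero-phase) and the squared magnitude of the analytic signal taken;
    the band power series is the mean across bins.  Computed on the
    continuous recording, before any segmentation, so that filter and
    Hilbert edge effects stay outside the epochs.
    """
    if isinstance(data, RawRecording):
        sfreq = data.sfreq
        data = data.data
    if sfreq is None:
        raise ValueError("sfreq required for array input")
    x = np.atleast_2d(np.asarray(data, dtype=float))
    bins = band_bins(band_lo, band_hi, bin_width, bin_mode)
    power = np.zeros_like(x)
    for lo, hi in bins:
        nb = fir_bandpass(x, lo, hi, sfreq=sfreq, transition_hz=transition_hz)
        power += np.abs(hilbert(nb, axis=-1)) ** 2
    power /= len(bins)
    return power if data.ndim == 2 else power[0]


def db_normalize_trial_average(
    power_epochs: EpochSet, baseline_ms=(-450.0, -350.0)
) -> np.ndarray:
    """Decibel-normalize the trial-average power (channels x times).

    Retained epochs are averaged first; dB(t) = 10*log10(avg power /
    mean avg power over the baseline window), per channel.
    """
    if power_epochs.n_retained == 0:
        raise ValueError("no retained epochs to average")
    pbar = power_epochs.retained().mean(axis=0)  # channels x times
    mask = (power_epochs.times_ms >= baseline_ms[0]) & (
        power_epochs.times_ms <= baseline_ms[1]
    )
    base = pbar[:, mask].mean(axis=1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("baseline power is zero — degenerate input")
    return 10.0 * np.log10(pbar / base)


def ersp_roi(
    power_epochs: EpochSet,
    baseline_ms=(-450.0, -350.0),
    roi=ROI_CHANNELS,
    condition: str = "",
    subject=None,
    epoch_mask: np.ndarray | None = None,
) -> RoiSeries | None:
    """ROI-averaged dB time course for a condition subset of epochs."""
    sub = power_epochs.copy()
    if epoch_mask is not None:
        sub.rejected = sub.rejected | ~epoch_mask
    if sub.n_retained == 0:
        return None
    db = db_normalize_trial_average(sub, baseline_ms)
    idx = [sub.ch_names.index(ch) for ch in roi]
    return RoiSeries(
        times_ms=sub.times_ms,
        values=db[idx].mean(axis=0),
        condition=condition,
        subject=subject,
        n_epochs=sub.n_retained,
        units="dB",
    )


@dataclass
class ErspResult:
    """Per-subject power-path output: epoched band power + rejection mask."""

    power_epochs: EpochSet
    events: object
    baseline_ms: tuple = (-450.0, -350.0)

    def roi_series(self, condition: str, epoch_mask=None, roi=ROI_CHANNELS,
                   subject=None):
        return ersp_roi(
            self.power_epochs, self.baseline_ms, roi=roi,
            condition=condition, subject=subject, epoch_mask=epoch_mask,
        )


def ersp_pipeline(
    raw: RawRecording,
    band=(4.0, 7.0),
    filter_band=(0.5, 30.0),
    window_ms=(-450.0, 550.0),
    baseline_ms=(-450.0, -350.0),
    ica: bool = True,
    bin_mode: str = "centered",
    ref_channels=REFERENCE_CHANNELS,
    reject_from: EpochSet | None = None,
    seed: int = 0,
) -> ErspResult:
    """Run the power path on one recording.

    ``reject_from`` carries the +/-110 uV rejection mask computed on the
    amplitude epochs of the same events (the rejection criterion is
    defined on voltages, not on power).
    """
    filt = fir_bandpass(raw, filter_band[0], filter_band[1])
    if ica:
        filt, _ = remove_artifact_components(filt, seed=seed)
    # re-reference the continuous signal (linear, so valid before filtering
    # into narrow bands)
    idx = [filt.ch_names.index(ch) for ch in ref_channels]
    filt.data = filt.data - filt.data[idx].mean(axis=0, keepdims=True)
    power = hilbert_band_power(
        filt.data, band[0], band[1], sfreq=filt.sfreq, bin_mode=bin_mode
    )
    epochs = segment_epochs(
        power, filt.sfreq, filt.events["sample"].to_numpy(), filt.ch_names,
        window_ms=window_ms, baseline_ms=None,
        event_rows=filt.events.index.to_numpy(),
    )
    if reject_from is not None:
        # align by event row ids; power epochs inherit the amplitude mask
        mask_map = dict(zip(reject_from.event_rows, reject_from.rejected))
        epochs.rejected = np.array(
            [bool(mask_map.get(r, False)) for r in epochs.event_rows]
        )
    events = filt.events.loc[epochs.event_rows]
    return ErspResult(power_epochs=epochs, events=events, baseline_ms=tuple(baseline_ms))


def tf_power_map(
    data,
    sfreq: float | None = None,
    freqs=None,
    transition_hz: float = 0.5,
) -> tuple:
    """Full-range time-frequency power: one envelope series per 1-Hz bin.

    A convenience for difference-panel style figures; not part of the
    theta analysis path.  Returns (freqs, power) with power shaped
    (n_freqs, n_channels, n_samples).
    """
    if isinstance(data, RawRecording):
        sfreq = data.sfreq
        data = data.data
    if freqs is None:
        freqs = np.arange(2.0, 26.0)
    x = np.atleast_2d(np.asarray(data, dtype=float))
    out = np.zeros((len(freqs), *x.shape))
    for i, f in enumerate(freqs):
        nb = fir_bandpass(x, f - 0.5, f + 0.5, sfreq=sfreq,
                          transition_hz=transition_hz)
        out[i] = np.abs(hilbert(nb, axis=-1)) ** 2
    return np.asarray(freqs), out
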