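"""Preprocessing: filtering, ICA artifact removal, epoching, rejection,
re-referencing, ROI averaging — each against closed-form or constructed
oracles, plus an independent-library cross-check of the filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from gonogo.containers import RawRecording
from gonogo.params import CHANNELS
from gonogo.preprocess import (
    design_fir,
    fir_bandpass,
    pseudo_average_reference,
    reject_epochs,
    remove_artifact_components,
    roi_waveform,
    segment_epochs,
)

FS = 128.0


def _sine(freq, seconds=20.0):
    t = np.arange(int(seconds * FS)) / FS
    return np.sin(2 * np.pi * freq * t)


def test_passband_preserves_amplitude():
    x = _sine(10.0)
    y = fir_bandpass(x[None, :], 0.5, 30.0, sfreq=FS)[0]
    mid = slice(int(5 * FS), int(15 * FS))
    assert abs(np.abs(y[mid]).max() - 1.0) < 0.05


def test_stopband_attenuation_from_frequency_response():
    taps = design_fir(0.5, 30.0, FS)
    w, h = signal.freqz(taps, worN=4096, fs=FS)
    gain_40 = np.abs(h)[np.argmin(np.abs(w - 40.0))]
    # single-pass response; the zero-phase double pass doubles this in dB
    assert 20 * np.log10(gain_40 + 1e-12) < -20.0


def test_dc_removed_and_bad_band_raises():
    x = np.full((1, 2000), 5.0)
    y = fir_bandpass(x, 0.5, 30.0, sfreq=FS)
    assert np.abs(y).max() < 0.05
    with pytest.raises(ValueError):
        fir_bandpass(x, 0.5, 70.0, sfreq=FS)


def test_filter_agrees_with_mne_oracle():
    mne = pytest.importorskip("mne")
    rng = np.random.default_rng(0)
    x = rng.standard_normal((1, int(30 * FS)))
    ours = fir_bandpass(x, 0.5, 30.0, sfreq=FS)[0]
    theirs = mne.filter.filter_data(
        x, FS, 0.5, 30.0, l_trans_bandwidth=0.5, h_trans_bandwidth=0.5,
        verbose="error",
    )[0]
    mid = slice(int(5 * FS), int(25 * FS))
    r = np.corrcoef(ours[mid], theirs[mid])[0, 1]
    assert r > 0.99


def _raw_from(data, events=None):
    ev = events if events is not None else pd.DataFrame(
        {"sample": [], "block": [], "trial_index": [], "outcome": []}
    )
    return RawRecording(data=data, sfreq=FS, ch_names=tuple(CHANNELS), events=ev)


def test_epoch_window_sample_count_and_baseline():
    rng = np.random.default_rng(1)
    data = rng.standard_normal((14, 4000))
    ep = segment_epochs(data, FS, np.array([1000, 2000]), CHANNELS)
    # round(-450*128/1000) = -58 ... round(550*128/1000) = 70, inclusive
    assert ep.data.shape == (2, 14, 129)
    tmask = (ep.times_ms >= -450) & (ep.times_ms <= -50)
    assert np.allclose(ep.data[:, :, tmask].mean(axis=2), 0.0, atol=1e-10)


def test_epoch_at_recording_edge_flagged():
    data = np.zeros((14, 2000))
    ep = segment_epochs(data, FS, np.array([0, 1000]), CHANNELS)
    assert ep.n_epochs == 1
    assert list(ep.edge_excluded) == [0]


def test_rejection_threshold_inclusive_of_110():
    data = np.zeros((2, 2, 129))
    data[0, 0, 64] = 111.0
    data[1, 1, 64] = 109.0
    ep = segment_epochs(np.zeros((2, 4000)), FS, np.array([1000, 2000]),
                        ("F3", "F4"), baseline_ms=None)
    ep.data = data
    out = reject_epochs(ep, threshold_uv=110.0)
    assert out.rejected.tolist() == [True, False]
    assert out.n_retained + out.rejected.sum() == out.n_epochs


def test_pseudo_average_reference_properties():
    rng = np.random.default_rng(2)
    ep = segment_epochs(rng.standard_normal((14, 4000)), FS,
                        np.array([1000]), CHANNELS, baseline_ms=None)
    ref = pseudo_average_reference(ep)
    idx = [CHANNELS.index(ch) for ch in ("O1", "O2", "T7", "T8", "AF3", "AF4")]
    assert np.allclose(ref.data[:, idx, :].mean(axis=1), 0.0, atol=1e-10)
    # adding a constant to all channels leaves the referenced signal unchanged
    shifted = ep.copy()
    shifted.data = shifted.data + 17.3
    assert np.allclose(pseudo_average_reference(shifted).data, ref.data)
    # one nonzero reference channel of value 6v shifts every channel by -v
    lone = ep.copy()
    lone.data = np.zeros_like(lone.data)
    lone.data[:, CHANNELS.index("O1"), :] = 6.0
    out = pseudo_average_reference(lone)
    assert np.allclose(out.data[:, CHANNELS.index("F3"), :], -1.0)
    missing = ep.copy()
    missing.ch_names = tuple(c for c in CHANNELS if c != "O1")
    missing.data = missing.data[:, 1:, :][:, : len(missing.ch_names), :]
    with pytest.raises(ValueError):
        pseudo_average_reference(
            segment_epochs(np.zeros((13, 4000)), FS, np.array([1000]),
                           [c for c in CHANNELS if c != "O1"], baseline_ms=None)
        )


def test_roi_waveform_linearity():
    data = np.zeros((14, 4000))
    data[CHANNELS.index("F3")] = 3.0
    data[CHANNELS.index("F4")] = 3.0
    ep = segment_epochs(data, FS, np.array([1000]), CHANNELS, baseline_ms=None)
    s = roi_waveform(ep)
    assert np.allclose(s.values, 3.0)
    # epochs v and -v average to zero
    two = segment_epochs(data, FS, np.array([1000, 2000]), CHANNELS, baseline_ms=None)
    two.data[1] *= -1
    assert np.allclose(roi_waveform(two).values, 0.0)
    # all epochs rejected -> absent
    two.rejected[:] = True
    assert roi_waveform(two) is None


def test_ica_removes_synthetic_blinks():
    rng = np.random.default_rng(3)
    n = 6000
    data = rng.standard_normal((14, n)) * 5.0
    blink_ref = np.zeros(n)
    blen = 38
    for s0 in range(500, n - blen, 700):
        blink_ref[s0 : s0 + blen] += np.hanning(blen)
    for ch, w in (("AF3", 1.0), ("AF4", 1.0), ("F7", 0.3), ("F8", 0.3)):
        data[CHANNELS.index(ch)] += 120.0 * w * blink_ref
    raw = _raw_from(data)
    clean, report = remove_artifact_components(raw, reference_trace=blink_ref, seed=0)
    assert len(report.removed) >= 1
    af3 = CHANNELS.index("AF3")
    win = blink_ref > 0.5
    var_before = data[af3, win].var()
    var_after = clean.data[af3, win].var()
    assert var_after < 0.2 * var_before


@pytest.mark.filterwarnings("ignore::sklearn.exceptions.ConvergenceWarning")
def test_ica_identity_when_nothing_removed():
    # on pure Gaussian noise ICA has no components to find and may not
    # converge; the contract under test is only reconstruction fidelity
    rng = np.random.default_rng(4)
    data = rng.standard_normal((14, 4000)) * 5.0
    raw = _raw_from(data)
    clean, report = remove_artifact_components(
        raw, reference_trace=np.zeros(4000), seed=0
    )
    assert report.removed == []
    assert np.allclose(clean.data, data, atol=1e-6)
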