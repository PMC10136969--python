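"""Generator contracts: sequence statistics, behavioral mechanics,
EEG shape and injected-effect monotonicity."""

import numpy as np
import pandas as pd
import pytest

from gonogo import SynthParams, generate_behavior, generate_eeg, generate_sequence
from gonogo.behavior import compute_rsi
from gonogo.preprocess import erp_roi_pipeline
from gonogo.stats import waveform_area


def test_sequence_layout_and_go_probability():
    p = SynthParams(blocks_per_subject=1)
    seq = generate_sequence(p, seed=0)
    assert len(seq) == 90
    assert (seq.groupby("block").size() == 90).all()
    onsets = seq["onset_ms"].to_numpy()
    assert np.allclose(np.diff(onsets), p.soa_ms)

    all_go = generate_sequence(SynthParams(p_go=1.0), seed=0)
    assert (all_go["stimulus"] == "go").all()


def test_sequence_deterministic_given_seed():
    p = SynthParams(blocks_per_subject=3)
    a = generate_sequence(p, seed=5)
    b = generate_sequence(p, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_invalid_probability_raises():
    with pytest.raises(ValueError):
        SynthParams(p_go=1.5)


def test_consecutive_nogo_fraction_matches_design():
    # under P(go)=0.7 the nogo/nogo pair probability is 0.09
    p = SynthParams(n_subjects=1, blocks_per_subject=1, trials_per_block=200_000)
    seq = generate_sequence(p, seed=3)
    nogo = (seq["stimulus"] == "nogo").to_numpy()
    frac = (nogo[:-1] & nogo[1:]).mean()
    se = np.sqrt(0.09 * 0.91 / (len(nogo) - 1))
    assert abs(frac - 0.09) < 3 * se


def test_behavior_no_commission_means_no_false_alarms():
    p = SynthParams(p_commission=0.0, blocks_per_subject=2)
    b = generate_behavior(generate_sequence(p, seed=1), p, seed=2)
    assert (b["outcome"] != "false_alarm").all()


def test_behavior_empty_sequence_gives_empty_table():
    p = SynthParams()
    empty = generate_sequence(p, seed=0).iloc[:0]
    b = generate_behavior(empty, p, seed=0)
    assert len(b) == 0
    assert {"responded", "rt_ms", "outcome"} <= set(b.columns)


def test_behavior_rt_censored_below_soa():
    p = SynthParams(blocks_per_subject=4)
    b = generate_behavior(generate_sequence(p, seed=9), p, seed=10)
    rts = b.loc[b["responded"], "rt_ms"]
    assert (rts > 0).all() and (rts < p.soa_ms).all()


def test_behavior_errors_faster_than_corrects():
    p = SynthParams(blocks_per_subject=8)
    b = generate_behavior(generate_sequence(p, seed=21), p, seed=22)
    err = b.loc[b["outcome"] == "false_alarm", "rt_ms"].median()
    cor = b.loc[b["outcome"] == "hit", "rt_ms"].median()
    assert err < cor


def test_rsi_identity_exact(subject, small_params):
    """RSI + RT = SOA holds exactly by the 400 + 800 ms design."""
    trials = subject.behavior
    rsi = compute_rsi(trials, soa_ms=small_params.soa_ms)
    rt = trials.loc[rsi.index, "rt_ms"]
    assert np.allclose(rsi + rt, small_params.soa_ms)


def test_eeg_shape_rate_and_determinism(small_params):
    p = small_params
    b = generate_behavior(generate_sequence(p, seed=4), p, seed=5)
    raw1 = generate_eeg(b, p, seed=6)
    raw2 = generate_eeg(b, p, seed=6)
    assert raw1.data.shape[0] == 14
    assert raw1.sfreq == 128.0
    assert np.array_equal(raw1.data, raw2.data)
    assert (raw1.events["sample"] < raw1.n_samples).all()


def test_eeg_mismatched_behavior_raises(small_params):
    bad = pd.DataFrame({"block": [0], "trial_index": [0]})
    with pytest.raises(ValueError):
        generate_eeg(bad, small_params, seed=0)


def test_blink_reference_stored_only_when_blinks_enabled():
    p = SynthParams(blocks_per_subject=1, blink_rate_hz=0.3)
    b = generate_behavior(generate_sequence(p, seed=1), p, seed=2)
    raw = generate_eeg(b, p, seed=3)
    assert raw.blink_ref is not None and raw.blink_ref.max() > 0
    p0 = SynthParams(blocks_per_subject=1, blink_rate_hz=0.0)
    raw0 = generate_eeg(b, p0, seed=3)
    assert raw0.blink_ref is None


def test_ern_injection_monotonic_in_amplitude():
    """Error-minus-correct negative area over [0, 150] ms grows with the
    injected ERN amplitude (fixed seeds, three levels)."""
    areas = []
    for amp in (0.0, 4.0, 8.0):
        p = SynthParams(
            blocks_per_subject=2, blink_rate_hz=0.0,
            ern_amp_uv=amp, theta_gain_db=0.0,
        )
        b = generate_behavior(generate_sequence(p, seed=31), p, seed=32)
        raw = generate_eeg(b, p, seed=33)
        res = erp_roi_pipeline(raw, ica=False)
        diff = res.series["error"].values - res.series["correct"].values
        areas.append(waveform_area(diff, res.epochs.times_ms, (0.0, 150.0)))
    assert areas[0] > areas[1] > areas[2]
    assert areas[2] < 0
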