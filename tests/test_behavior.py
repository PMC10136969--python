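"""Behavioral measures: definitions, matching machinery, splits, inclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from gonogo.behavior import (
    classify_outcomes,
    compute_rsi,
    inclusion_filter,
    post_accuracy,
    post_slowing_pairs,
    rt_matched_pcs,
    rt_summaries,
    subject_summary,
    tertile_split,
)


def _trials(rows):
    df = pd.DataFrame(
        rows, columns=["block", "trial_index", "stimulus", "responded", "rt_ms"]
    )
    df["onset_ms"] = df["trial_index"] * 1200.0
    return classify_outcomes(df)


@pytest.mark.parametrize(
    "stimulus,responded,expected",
    [
        ("go", True, "hit"),
        ("go", False, "omission"),
        ("nogo", True, "false_alarm"),
        ("nogo", False, "correct_rejection"),
    ],
)
def test_outcome_classification(stimulus, responded, expected):
    df = _trials([[0, 0, stimulus, responded, 500.0 if responded else np.nan]])
    assert df.loc[0, "outcome"] == expected


def test_unknown_stimulus_raises():
    df = pd.DataFrame(
        {"block": [0], "trial_index": [0], "stimulus": ["maybe"],
         "responded": [True], "rt_ms": [500.0]}
    )
    with pytest.raises(ValueError):
        classify_outcomes(df)


def test_outcome_partition_sums_to_total(subject):
    counts = subject.behavior["outcome"].value_counts()
    assert counts.sum() == len(subject.behavior)


def test_rt_summaries_small_sets():
    df = _trials(
        [[0, i, "nogo", True, rt] for i, rt in enumerate([400.0, 480.0, 500.0])]
    )
    s = rt_summaries(df)
    assert s["error"]["median"] == 480.0
    single = _trials([[0, 0, "go", True, 512.0]])
    s = rt_summaries(single)
    assert s["correct"]["median"] == s["correct"]["q25"] == s["correct"]["q75"] == 512.0
    none = _trials([[0, 0, "go", False, np.nan]])
    assert rt_summaries(none)["overall"]["n"] == 0


def test_post_slowing_pair_arithmetic():
    df = _trials(
        [[0, 0, "nogo", True, 500.0], [0, 1, "go", True, 650.0]]
    )
    pairs = post_slowing_pairs(df, "false_alarm")
    assert len(pairs) == 1
    assert pairs.loc[0, "slowing_ms"] == 150.0
    assert pairs.loc[0, "next_outcome"] == "hit"


def test_post_slowing_unresponded_successor_kept_with_nan():
    df = _trials(
        [[0, 0, "nogo", True, 500.0], [0, 1, "go", False, np.nan]]
    )
    pairs = post_slowing_pairs(df, "false_alarm")
    assert len(pairs) == 1
    assert np.isnan(pairs.loc[0, "slowing_ms"])
    assert not pairs.loc[0, "next_responded"]


def test_post_slowing_does_not_cross_blocks():
    df = _trials(
        [[0, 89, "nogo", True, 500.0], [1, 0, "go", True, 650.0]]
    )
    assert len(post_slowing_pairs(df, "false_alarm")) == 0


def test_constant_rt_sequence_gives_zero_slowing():
    df = _trials([[0, i, "nogo" if i % 2 else "go", True, 500.0] for i in range(8)])
    pairs = post_slowing_pairs(df, "false_alarm")
    assert (pairs["slowing_ms"] == 0.0).all()


def _pairs_from(rts_cur, rts_next, outcome="hit"):
    return pd.DataFrame(
        {
            "block": 0,
            "current_index": np.arange(len(rts_cur)),
            "next_index": np.arange(len(rts_cur)) + 1,
            "current_rt": rts_cur,
            "next_rt": rts_next,
            "slowing_ms": np.asarray(rts_next) - np.asarray(rts_cur),
            "next_outcome": outcome,
            "next_responded": True,
        }
    )


def test_matched_pcs_identical_pool_rts_equals_plain_mean():
    # matching cannot discriminate identical current RTs: with a pool the
    # same size as the target list the selection is the whole pool
    pes = _pairs_from([400.0, 450.0, 500.0], [550.0, 600.0, 650.0])
    pcs = _pairs_from([480.0] * 3, [500.0, 520.0, 540.0])
    res = rt_matched_pcs(pes, pcs, n_repeats=5, seed=0)
    assert res.mean == pytest.approx(pcs["slowing_ms"].mean())
    assert np.allclose(res.per_repeat, res.mean)


def test_matched_pcs_deterministic_and_replacement_flag():
    rng = np.random.default_rng(0)
    pes = _pairs_from(rng.normal(480, 40, 20), rng.normal(600, 40, 20))
    pcs = _pairs_from(rng.normal(580, 60, 50), rng.normal(590, 60, 50))
    a = rt_matched_pcs(pes, pcs, seed=11)
    b = rt_matched_pcs(pes, pcs, seed=11)
    assert a.mean == b.mean and not a.with_replacement
    small = rt_matched_pcs(pes, pcs.iloc[:5], seed=11)
    assert small.with_replacement


def test_matching_reduces_current_rt_mismatch():
    """With fast errors and slow corrects, the matched control pool's
    current RTs are closer (KS distance) to the error currents than the
    full pool is."""
    rng = np.random.default_rng(7)
    pes = _pairs_from(rng.normal(450, 30, 60), rng.normal(600, 30, 60))
    pcs = _pairs_from(rng.normal(590, 60, 400), rng.normal(600, 60, 400))
    from gonogo.behavior import _match_indices

    idx = _match_indices(np.random.default_rng(1), pes["current_rt"].to_numpy(),
                         pcs["current_rt"].to_numpy(), False)
    matched = pcs["current_rt"].to_numpy()[idx]
    d_matched = ks_2samp(matched, pes["current_rt"]).statistic
    d_unmatched = ks_2samp(pcs["current_rt"], pes["current_rt"]).statistic
    assert d_matched < d_unmatched


def test_post_accuracy_counts():
    pairs = _pairs_from([1, 2, 3, 4], [2, 3, 4, 5])
    pairs["next_outcome"] = ["hit", "hit", "false_alarm", "hit"]
    assert post_accuracy(pairs) == 75.0
    pairs["next_responded"] = False
    assert np.isnan(post_accuracy(pairs))


def test_tertile_split_boundaries():
    s = tertile_split(np.arange(1, 10))
    assert s.sizes == (3, 3, 3)
    assert s.medians == (2.0, 5.0, 8.0)
    s10 = tertile_split(np.arange(10))
    assert s10.sizes == (4, 3, 3)
    with pytest.raises(ValueError):
        tertile_split([1.0, 2.0])


def test_tertile_assignment_ordered_by_value():
    v = np.array([5.0, 1.0, 9.0, 3.0, 7.0, 2.0])
    s = tertile_split(v)
    assert v[s.assignments == 1].max() <= v[s.assignments == 2].min()
    assert v[s.assignments == 2].max() <= v[s.assignments == 3].min()


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.lists(
        st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        min_size=3, max_size=40,
    )
)
def test_tertile_split_invariants(values):
    """Sizes differ by at most one and the split respects the value order
    for every finite input."""
    s = tertile_split(values)
    assert max(s.sizes) - min(s.sizes) <= 1
    assert sum(s.sizes) == len(values)
    v = np.asarray(values)
    for lo, hi in ((1, 2), (2, 3)):
        assert v[s.assignments == lo].max() <= v[s.assignments == hi].min()


def test_rsi_values_and_edges():
    df = _trials(
        [[0, 0, "go", True, 500.0], [0, 1, "go", True, 1200.0],
         [0, 2, "go", True, 600.0]]
    )
    rsi = compute_rsi(df, soa_ms=1200.0)
    assert rsi.iloc[0] == 700.0
    assert rsi.iloc[1] == pytest.approx(0.0)
    assert len(rsi) == 2  # last trial of the block has no upcoming stimulus


def test_inclusion_filter_threshold():
    res = inclusion_filter({"a": 6, "b": 7, "c": 40}, min_trials=7)
    assert res.retained == ["b", "c"] and res.excluded == ["a"]
    all_in = inclusion_filter({"a": 8, "b": 9}, min_trials=7)
    assert all_in.excluded == []
    # per-tertile rule: >= 7 in each of three tertiles needs >= 21 overall
    assert inclusion_filter({"a": 20 // 3}, min_trials=7).excluded == ["a"]


def test_subject_summary_fields(subject):
    s = subject_summary(subject.behavior, seed=0)
    assert 0 <= s["hits_pct"] <= 100 and 0 <= s["false_alarms_pct"] <= 100
    assert s["error_rt_ms"] < s["correct_rt_ms"]
    assert np.isfinite(s["pes_ms"]) and np.isfinite(s["pcs_ms"])
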