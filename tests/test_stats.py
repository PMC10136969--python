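"""Inferential layer against closed forms and enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from gonogo.stats import (
    bonferroni_alpha,
    effect_size_r,
    friedman_test,
    oneway_anova,
    paired_t_test,
    samplewise_permutation_test,
    waveform_area,
    wilcoxon_signed_rank,
)
from gonogo.stats import _significant_runs


TIMES = np.arange(-6, 20) * 1000.0 / 128.0  # 26 samples spanning [-46.9, 148.4]


def test_identical_conditions_nothing_significant():
    rng = np.random.default_rng(0)
    a = rng.standard_normal((9, len(TIMES)))
    res = samplewise_permutation_test(a, a.copy(), TIMES, n_perm=500, seed=1)
    assert res.mask.sum() == 0 and res.runs == []


def test_exact_sign_flip_matches_hand_enumeration():
    """Eight subjects, constant positive difference: only the identity and
    the global flip tie the observed |t|, so each sample's exact p is
    2/256, below alpha=0.01, giving one full-window run."""
    rng = np.random.default_rng(2)
    base = rng.standard_normal((8, len(TIMES)))
    diff = 5.0 + 0.1 * rng.standard_normal((8, len(TIMES)))
    res = samplewise_permutation_test(base + diff, base, TIMES, exact=True)
    # independent brute-force oracle over all 2^8 sign assignments
    for j in (0, len(TIMES) // 2, len(TIMES) - 1):
        col = diff[:, j]  # (a - b) column
        t_obs = sps.ttest_1samp(col, 0.0).statistic
        count = 0
        for signs in itertools.product((1, -1), repeat=8):
            t = sps.ttest_1samp(np.array(signs) * col, 0.0).statistic
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
        assert res.p[j] == pytest.approx(count / 256)
        assert count == 2
    assert len(res.runs) == 1
    assert res.runs[0][2] == len(TIMES)


def test_short_stretch_below_min_consec_not_reported():
    mask = np.zeros(26, dtype=bool)
    mask[4:8] = True  # 4 consecutive significant samples
    assert _significant_runs(mask, TIMES, min_consec=5) == []
    mask[4:9] = True
    runs = _significant_runs(mask, TIMES, min_consec=5)
    assert len(runs) == 1 and runs[0][2] == 5


def test_permutation_requires_paired_input():
    with pytest.raises(ValueError):
        samplewise_permutation_test(
            np.zeros((3, 5)), np.zeros((4, 5)), np.arange(5.0)
        )


def test_wilcoxon_closed_form_and_symmetry():
    x = np.arange(1.0, 11.0)  # ten positive differences, no ties
    res = wilcoxon_signed_rank(x)
    assert res.W == 55.0
    assert res.Z == pytest.approx((55 - 27.5) / math.sqrt(96.25))
    neg = wilcoxon_signed_rank(-x)
    assert neg.Z == pytest.approx(-res.Z)
    assert wilcoxon_signed_rank(np.zeros(6)) is None


def test_wilcoxon_exact_p_matches_sign_flip_enumeration():
    d = np.array([1.3, -0.4, 2.2, 0.9, -1.7, 0.6])
    res = wilcoxon_signed_rank(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    null = []
    for signs in itertools.product((1, -1), repeat=len(d)):
        null.append(ranks[np.array(signs) > 0].sum())
    null = np.array(null)
    mu = len(d) * (len(d) + 1) / 4
    p_exact = np.mean(np.abs(null - mu) >= abs(w_obs - mu) - 1e-12)
    assert res.p == pytest.approx(p_exact)


def test_friedman_closed_form_cases():
    consistent = np.array([[1.0, 2.0, 3.0]] * 3)
    res = friedman_test(consistent, method="chi2")
    assert res.chi2 == pytest.approx(6.0)
    flat = friedman_test(np.ones((4, 3)))
    assert flat.chi2 == 0.0 and flat.p == 1.0
    with pytest.raises(ValueError):
        friedman_test(np.array([[1.0, np.nan, 2.0]]))


def test_friedman_exact_p_matches_rank_table_enumeration():
    m = np.array([[3.1, 1.0, 2.2], [1.5, 2.9, 2.0], [0.4, 1.1, 3.3]])
    res = friedman_test(m, method="exact")
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    n, k = m.shape
    obs = 12.0 / (n * k * (k + 1)) * (ranks.sum(axis=0) ** 2).sum() - 3 * n * (k + 1)
    null = []
    for table in itertools.product(
        *[list(itertools.permutations(row)) for row in ranks]
    ):
        cols = np.array(table).sum(axis=0)
        null.append(12.0 / (n * k * (k + 1)) * (cols ** 2).sum() - 3 * n * (k + 1))
    p_exact = np.mean(np.array(null) >= obs - 1e-12)
    assert res.chi2 == pytest.approx(obs)
    assert res.p == pytest.approx(p_exact)


def test_waveform_area_oracles():
    t = np.linspace(-50.0, 150.0, 201)
    assert waveform_area(np.ones_like(t), t, (-50, 150)) == pytest.approx(200.0)
    odd = t - 50.0  # antisymmetric about the window center
    assert waveform_area(odd, t, (-50, 150)) == pytest.approx(0.0, abs=1e-9)
    smooth = np.sin(t / 40.0) + 0.3 * t / 100.0
    fine_t = np.linspace(-50.0, 150.0, 100001)
    fine = np.sin(fine_t / 40.0) + 0.3 * fine_t / 100.0
    rect = fine[:-1].sum() * (fine_t[1] - fine_t[0])
    assert waveform_area(smooth, t, (-50, 150)) == pytest.approx(rect, rel=0.01)
    with pytest.raises(ValueError):
        waveform_area(odd, t, (-100, 150))


def test_anova_df_and_sums_of_squares():
    rng = np.random.default_rng(5)
    groups = [rng.standard_normal(58) + mu for mu in (0.0, 0.3, 0.8)]
    res = oneway_anova(groups)
    assert (res.df1, res.df2) == (2, 171)
    # closed-form sum-of-squares oracle
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    f_oracle = (ss_b / 2) / (ss_w / 171)
    assert res.F == pytest.approx(f_oracle)
    equal = oneway_anova([np.ones(5), np.ones(5)])
    assert equal.F == 0.0


def test_anova_monotonic_in_group_separation():
    rng = np.random.default_rng(6)
    noise = [rng.standard_normal(30) for _ in range(3)]
    fs = []
    for scale in (0.0, 0.5, 1.0, 2.0):
        groups = [noise[k] + scale * k for k in range(3)]
        fs.append(oneway_anova(groups).F)
    assert all(b >= a for a, b in zip(fs, fs[1:]))


def test_paired_t_closed_form():
    assert paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).t == 0.0
    res = paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
    assert res.t == pytest.approx(2.0 / (1.0 / math.sqrt(3)))
    assert res.df == 2
    flip = paired_t_test([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
    assert flip.t == pytest.approx(-res.t)
    with pytest.raises(ValueError):
        paired_t_test([2.0, 2.0], [1.0, 1.0])


def test_effect_size_and_bonferroni_conventions():
    assert effect_size_r(0.0, 10) == 0.0
    assert round(effect_size_r(-3.0, 36), 2) == 0.5
    with pytest.raises(ValueError):
        effect_size_r(1.0, 0)
    assert bonferroni_alpha(0.05, 3) == 0.0167
    assert bonferroni_alpha(0.04, 1) == 0.04
    assert bonferroni_alpha(0.05, 5) == 0.01
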