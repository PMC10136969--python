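"""Inferential layer: sample-wise paired permutation waveform tests with a
consecutive-sample criterion, rank tests with small-sample exact options,
ANOVA on waveform areas, r effect sizes, and Bonferroni control.

The permutation null for the paired waveform contrast is built from
whole-series sign flips of each subject's difference waveform, which
preserves the temporal autocorrelation of the data under the null.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "samplewise_permutation_test",
    "wilcoxon_signed_rank",
    "friedman_test",
    "waveform_area",
    "oneway_anova",
    "paired_t_test",
    "effect_size_r",
    "bonferroni_alpha",
    "PermTestResult",
]


@dataclass
class PermTestResult:
    """Sample-wise paired permutation test output over an analysis window."""

    times_ms: np.ndarray
    t_obs: np.ndarray
    p: np.ndarray
    mask: np.ndarray                      # p < alpha
    runs: list                            # [(start_ms, end_ms, n_samples)]
    t_range: tuple                        # (min, max) observed t in window
    t_range_significant: tuple | None     # t range over significant samples
    alpha: float
    min_consec: int
    n_permutations: int
    seed: int | None = None

    @property
    def any_significant_run(self) -> bool:
        return len(self.runs) > 0


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Per-sample paired t over subjects (rows) of a difference matrix."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    degenerate = sd == 0
    if degenerate.any():
        t = t.copy()
        t[degenerate & (mean > 0)] = np.inf
        t[degenerate & (mean < 0)] = -np.inf
        t[degenerate & (mean == 0)] = 0.0
    return t


def _significant_runs(mask: np.ndarray, times: np.ndarray, min_consec: int) -> list:
    runs = []
    start = None
    for i, m in enumerate(np.append(mask, False)):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_consec:
                runs.append((float(times[start]), float(times[i - 1]), i - start))
            start = None
    return runs


def samplewise_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple | None = None,
    alpha: float = 0.01,
    min_consec: int = 5,
    n_perm: int = 2000,
    seed: int | None = None,
    exact: bool = False,
) -> PermTestResult:
    """Paired, sample-wise permutation t-test of two subject x time arrays.

    Per sample, the observed statistic is the paired t of the
    within-subject differences.  The null flips the sign of each
    subject's *entire* difference series; two-sided p per sample is
    (#{|t*| >= |t_obs|} + 1) / (n_perm + 1), or the exact proportion over
    all 2^n flips when ``exact``.  Samples with p < alpha form the
    significance mask; maximal runs of at least ``min_consec``
    consecutive significant samples are reported with their ms endpoints.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    times = np.asarray(times_ms, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != len(times):
        raise ValueError("conditions must be paired (n_subjects x n_times) on one axis")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if window_ms is not None:
        sel = (times >= window_ms[0]) & (times <= window_ms[1])
        if not sel.any():
            raise ValueError("analysis window outside the time axis")
        a, b, times = a[:, sel], b[:, sel], times[sel]

    diff = a - b
    n = diff.shape[0]
    t_obs = _paired_t(diff)

    if exact:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
    # with fixed |diff|, per-permutation sd follows from the flipped mean
    flipped_mean = signs @ diff / n
    sq = (diff ** 2).sum(axis=0)
    var = (sq[None, :] - n * flipped_mean ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = flipped_mean / np.sqrt(var / n)
    t_null = np.nan_to_num(t_null, nan=0.0, posinf=np.inf, neginf=-np.inf)

    # relative tolerance: the identity flip must always count as >= observed
    thresh = np.abs(t_obs) * (1.0 - 1e-9)
    exceed = (np.abs(t_null) >= thresh[None, :]).sum(axis=0)
    if exact:
        p = exceed / signs.shape[0]
    else:
        p = (exceed + 1.0) / (signs.shape[0] + 1.0)
    mask = p < alpha
    runs = _significant_runs(mask, times, min_consec)
    t_sig = (
        (float(t_obs[mask].min()), float(t_obs[mask].max())) if mask.any() else None
    )
    return PermTestResult(
        times_ms=times,
        t_obs=t_obs,
        p=p,
        mask=mask,
        runs=runs,
        t_range=(float(t_obs.min()), float(t_obs.max())),
        t_range_significant=t_sig,
        alpha=alpha,
        min_consec=min_consec,
        n_permutations=signs.shape[0],
        seed=seed,
    )


@dataclass
class WilcoxonResult:
    W: float
    Z: float
    p: float
    n: int


def wilcoxon_signed_rank(x, y=None) -> WilcoxonResult | None:
    """Wilcoxon signed-rank test on paired samples (or differences).

    Zero differences are discarded; the Z statistic uses the normal
    approximation with tie-corrected variance, signed so that positive
    differences give positive Z.  The p value is exact for small
    tie-free samples and normal-approximate otherwise (scipy's 'auto'
    policy).  Returns None when every difference is zero.
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return None
    ranks = sps.rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48.0
    Z = (W - mu) / math.sqrt(var) if var > 0 else 0.0
    p = float(sps.wilcoxon(d, correction=False, method="auto").pvalue)
    return WilcoxonResult(W=W, Z=float(Z), p=p, n=n)


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    method: str


def _friedman_chi2(ranksums: np.ndarray, n: int, k: int, tie_correction: float):
    stat = 12.0 / (n * k * (k + 1)) * (ranksums ** 2).sum(axis=-1) - 3.0 * n * (k + 1)
    return stat / tie_correction


def friedman_test(matrix, method: str = "auto") -> FriedmanResult:
    """Friedman rank test over a complete subjects x conditions matrix.

    ``method='exact'`` (or 'auto' with small samples) enumerates all
    within-row rank permutations for the reference distribution, which is
    the appropriate null for tiny cohorts where the chi-square
    approximation is rough.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 3:
        raise ValueError("need a 2-D matrix with at least 3 conditions")
    if not np.all(np.isfinite(m)):
        raise ValueError("incomplete rows are not allowed")
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)
    # scipy-compatible tie correction
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += (counts ** 3 - counts).sum()
    correction = 1.0 - ties / (n * k * (k ** 2 - 1))
    if correction <= 0:
        return FriedmanResult(chi2=0.0, df=k - 1, p=1.0, method="degenerate")
    chi2 = float(_friedman_chi2(ranks.sum(axis=0), n, k, correction))

    exact_feasible = math.factorial(k) ** n <= 200_000
    if method == "exact" or (method == "auto" and n <= 6 and exact_feasible):
        perms = np.array(list(itertools.permutations(range(k))))
        total = np.zeros((1, k))
        for row in ranks:
            row_perms = row[perms]                      # k! x k
            total = (total[:, None, :] + row_perms[None, :, :]).reshape(-1, k)
        null = _friedman_chi2(total, n, k, correction)
        p = float((null >= chi2 - 1e-12).mean())
        return FriedmanResult(chi2=chi2, df=k - 1, p=p, method="exact")
    p = float(sps.chi2.sf(chi2, k - 1))
    return FriedmanResult(chi2=chi2, df=k - 1, p=p, method="chi2")


def waveform_area(values, times_ms, window_ms) -> float:
    """Signed trapezoidal integral of a series over a time window (value*ms)."""
    t = np.asarray(times_ms, dtype=float)
    v = np.asarray(values, dtype=float)
    if window_ms[0] < t[0] or window_ms[1] > t[-1]:
        raise ValueError("window outside the series time axis")
    sel = (t >= window_ms[0]) & (t <= window_ms[1])
    return float(np.trapezoid(v[sel], t[sel]))


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def oneway_anova(groups) -> AnovaResult:
    """Classical one-way ANOVA over k groups of pooled observations."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    k = len(groups)
    N = sum(len(g) for g in groups)
    within_var = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    means = [g.mean() for g in groups]
    if within_var == 0 and len(set(np.round(means, 12))) > 1:
        raise ValueError("zero within-group variance with unequal means: F undefined")
    if within_var == 0:
        return AnovaResult(F=0.0, df1=k - 1, df2=N - k, p=1.0)
    res = sps.f_oneway(*groups)
    return AnovaResult(F=float(res.statistic), df1=k - 1, df2=N - k, p=float(res.pvalue))


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


def paired_t_test(x, y) -> TTestResult:
    """Two-sided paired t-test (t on within-pair differences, df = n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = x - y
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return TTestResult(t=0.0, df=len(d) - 1, p=1.0)
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = sps.ttest_rel(x, y)
    return TTestResult(t=float(res.statistic), df=len(x) - 1, p=float(res.pvalue))


def effect_size_r(statistic: float, n: int) -> float:
    """r = |statistic| / sqrt(n) for a Z or t statistic over n paired units."""
    if n <= 0:
        raise ValueError("n must be positive")
    return abs(float(statistic)) / math.sqrt(n)


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison alpha for m tests, rounded to 4 decimals for display."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return round(family_alpha / m, 4)
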