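"""Behavioral measures for go/no-go performance monitoring.

Outcome classification, RT summaries, single-trial post-error /
post-correct slowing with an RT-matched control, post-error /
post-correct accuracy, tertile splits, the response-stimulus interval,
and subject-inclusion filtering.

Conventions
-----------
"Next trial" always means the immediate successor within the same block;
pairs never span blocks.  Successors of any stimulus class are eligible;
accuracy denominators count only responded successors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "classify_outcomes",
    "rt_summaries",
    "post_slowing_pairs",
    "rt_matched_pcs",
    "rt_matched_accuracy",
    "post_accuracy",
    "tertile_split",
    "compute_rsi",
    "inclusion_filter",
    "subject_summary",
    "MatchResult",
    "TertileSplit",
]

_OUTCOMES = {
    ("go", True): "hit",
    ("go", False): "omission",
    ("nogo", True): "false_alarm",
    ("nogo", False): "correct_rejection",
}


def classify_outcomes(trials: pd.DataFrame) -> pd.DataFrame:
    """Label each trial hit / omission / false_alarm / correct_rejection."""
    unknown = set(trials["stimulus"].unique()) - {"go", "nogo"}
    if unknown:
        raise ValueError(f"unknown stimulus class(es): {sorted(unknown)}")
    out = trials.copy()
    out["outcome"] = [
        _OUTCOMES[(s, bool(r))]
        for s, r in zip(out["stimulus"], out["responded"])
    ]
    return out


def _quartiles(values: np.ndarray) -> dict:
    if len(values) == 0:
        return {"median": np.nan, "q25": np.nan, "q75": np.nan, "n": 0}
    return {
        "median": float(np.median(values)),
        "q25": float(np.percentile(values, 25)),
        "q75": float(np.percentile(values, 75)),
        "n": int(len(values)),
    }


def rt_summaries(trials: pd.DataFrame) -> dict:
    """Median and quartiles of RT for hits, false alarms, and both pooled."""
    hits = trials.loc[trials["outcome"] == "hit", "rt_ms"].dropna().to_numpy()
    errs = trials.loc[trials["outcome"] == "false_alarm", "rt_ms"].dropna().to_numpy()
    pooled = np.concatenate([hits, errs])
    return {
        "correct": _quartiles(hits),
        "error": _quartiles(errs),
        "overall": _quartiles(pooled),
    }


def post_slowing_pairs(
    trials: pd.DataFrame,
    current_outcome: str,
    exclude_post_error: bool = False,
) -> pd.DataFrame:
    """Consecutive-trial pairs whose current trial has the given outcome.

    One row per current-outcome trial with an immediate successor in the
    same block.  ``slowing_ms`` (next RT minus current RT) is defined only
    when the successor was responded; a pair with an unresponded successor
    is retained (it still identifies the following trial) with NaN slowing.

    ``exclude_post_error`` drops pairs whose *current* trial immediately
    follows a responded false alarm.  For the post-correct control this
    keeps error-recovery dynamics (the slowed post-error hit and the
    speed-up after it) out of the regression-to-the-mean baseline.
    """
    if current_outcome not in {"false_alarm", "hit"}:
        raise ValueError("current_outcome must be 'false_alarm' or 'hit'")
    t = trials.sort_values(["block", "trial_index"]).reset_index(drop=True)
    cur = t.iloc[:-1].reset_index(drop=True) if len(t) else t
    nxt = t.iloc[1:].reset_index(drop=True) if len(t) else t
    if len(t) < 2:
        return pd.DataFrame(
            columns=[
                "block", "current_index", "next_index", "current_rt",
                "next_rt", "slowing_ms", "next_outcome", "next_responded",
            ]
        )
    ok = (
        (cur["outcome"] == current_outcome)
        & cur["responded"]
        & (cur["block"] == nxt["block"])
        & (nxt["trial_index"] == cur["trial_index"] + 1)
    )
    if exclude_post_error:
        prv = t.shift(1)
        post_err = (
            (prv["outcome"] == "false_alarm")
            & prv["responded"].eq(True)
            & (prv["block"] == t["block"])
        ).to_numpy()[:-1]
        ok &= ~post_err
    pairs = pd.DataFrame(
        {
            "block": cur["block"],
            "current_index": cur["trial_index"],
            "next_index": nxt["trial_index"],
            "current_rt": cur["rt_ms"],
            "next_rt": nxt["rt_ms"],
            "slowing_ms": nxt["rt_ms"] - cur["rt_ms"],
            "next_outcome": nxt["outcome"],
            "next_responded": nxt["responded"],
        }
    )[ok.to_numpy()]
    return pairs.reset_index(drop=True)


@dataclass
class MatchResult:
    """Outcome of RT-matched control selection."""

    mean: float
    per_repeat: np.ndarray
    with_replacement: bool = False


def _match_indices(rng, target_rts, pool_rts, with_replacement):
    """Nearest-current-RT assignment, ties broken uniformly at random."""
    chosen = []
    available = np.ones(len(pool_rts), dtype=bool)
    order = rng.permutation(len(target_rts))
    for i in order:
        cand = np.flatnonzero(available) if not with_replacement else np.arange(len(pool_rts))
        d = np.abs(pool_rts[cand] - target_rts[i])
        best = cand[d == d.min()]
        pick = best[rng.integers(len(best))] if len(best) > 1 else best[0]
        chosen.append(pick)
        if not with_replacement:
            available[pick] = False
    return np.array(chosen, dtype=int)


def rt_matched_pcs(
    pes_pairs: pd.DataFrame,
    pcs_pairs: pd.DataFrame,
    n_repeats: int = 20,
    seed: int | None = None,
) -> MatchResult:
    """Post-correct slowing from PCS pairs RT-matched to PES pairs.

    For each repeat, every error pair is matched (without replacement) to
    the correct pair whose current-trial RT is nearest; the repeat mean of
    the matched slowings is taken, and the final value is the mean over
    ``n_repeats`` repeats.  This controls the raw slowing contrast for
    regression toward the mean.  If fewer correct pairs than error pairs
    exist, matching samples with replacement and flags it.
    """
    pes = pes_pairs.dropna(subset=["slowing_ms"])
    pcs = pcs_pairs.dropna(subset=["slowing_ms"])
    if len(pes) == 0 or len(pcs) == 0:
        raise ValueError("matching requires non-empty pair lists with defined slowing")
    rng = np.random.default_rng(seed)
    with_replacement = len(pcs) < len(pes)
    t_rts = pes["current_rt"].to_numpy()
    p_rts = pcs["current_rt"].to_numpy()
    p_slow = pcs["slowing_ms"].to_numpy()
    means = np.empty(n_repeats)
    for r in range(n_repeats):
        idx = _match_indices(rng, t_rts, p_rts, with_replacement)
        means[r] = p_slow[idx].mean()
    return MatchResult(
        mean=float(means.mean()), per_repeat=means, with_replacement=with_replacement
    )


def post_accuracy(pairs: pd.DataFrame) -> float:
    """Percent of responded successors that are hits (NaN if none)."""
    responded = pairs[pairs["next_responded"].astype(bool)]
    n_hit = int((responded["next_outcome"] == "hit").sum())
    n_fa = int((responded["next_outcome"] == "false_alarm").sum())
    if n_hit + n_fa == 0:
        return float("nan")
    return 100.0 * n_hit / (n_hit + n_fa)


def rt_matched_accuracy(
    pea_pairs: pd.DataFrame,
    pca_pairs: pd.DataFrame,
    n_repeats: int = 20,
    seed: int | None = None,
) -> MatchResult:
    """Post-correct accuracy over correct pairs RT-matched to error pairs.

    Same matching machinery as :func:`rt_matched_pcs`, applied to pair
    selection: per repeat, the accuracy of the matched correct pairs is
    computed, and repeat accuracies are averaged.
    """
    pea = pea_pairs[pea_pairs["next_responded"].astype(bool)]
    pca = pca_pairs[pca_pairs["next_responded"].astype(bool)]
    if len(pea) == 0 or len(pca) == 0:
        raise ValueError("matching requires non-empty responded-successor pairs")
    rng = np.random.default_rng(seed)
    with_replacement = len(pca) < len(pea)
    t_rts = pea["current_rt"].to_numpy()
    p_rts = pca["current_rt"].to_numpy()
    p_hit = (pca["next_outcome"] == "hit").to_numpy()
    accs = np.empty(n_repeats)
    for r in range(n_repeats):
        idx = _match_indices(rng, t_rts, p_rts, with_replacement)
        accs[r] = 100.0 * p_hit[idx].mean()
    return MatchResult(
        mean=float(accs.mean()), per_repeat=accs, with_replacement=with_replacement
    )


@dataclass
class TertileSplit:
    """Rank-based split of a variable into thirds."""

    assignments: np.ndarray          # 1 | 2 | 3, in input order
    medians: tuple                   # per-tertile median of the variable
    sizes: tuple

    def indices(self, tertile: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == tertile)


def tertile_split(values) -> TertileSplit:
    """Split values at rank cuts ceil(n/3), ceil(2n/3); ties keep input order."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3 or not np.all(np.isfinite(v)):
        raise ValueError("tertile split needs at least 3 finite values")
    n = len(v)
    order = np.argsort(v, kind="stable")
    c1, c2 = math.ceil(n / 3), math.ceil(2 * n / 3)
    assign = np.empty(n, dtype=int)
    assign[order[:c1]] = 1
    assign[order[c1:c2]] = 2
    assign[order[c2:]] = 3
    medians = tuple(float(np.median(v[assign == k])) for k in (1, 2, 3))
    sizes = tuple(int((assign == k).sum()) for k in (1, 2, 3))
    return TertileSplit(assignments=assign, medians=medians, sizes=sizes)


def compute_rsi(trials: pd.DataFrame, soa_ms: float = 1200.0) -> pd.Series:
    """Response-stimulus interval (``soa_ms - rt_ms``) per responded trial.

    Defined only for responded trials with a successor in the same block
    (the last trial of a block has no upcoming stimulus).
    """
    t = trials.sort_values(["block", "trial_index"])
    last_idx = t.groupby("block")["trial_index"].transform("max")
    ok = t["responded"] & (t["trial_index"] < last_idx)
    return (soa_ms - t.loc[ok, "rt_ms"]).rename("rsi_ms")


@dataclass
class InclusionResult:
    retained: list
    excluded: list
    log: pd.DataFrame = field(default_factory=pd.DataFrame)


def inclusion_filter(counts: dict, min_trials: int = 7) -> InclusionResult:
    """Retain subjects with at least ``min_trials`` qualifying trials.

    ``counts`` maps subject id to its minimum relevant trial count for the
    analysis context (e.g. artifact-free error epochs, or the smallest
    per-tertile count for tertile analyses).
    """
    retained, excluded, rows = [], [], []
    for sid, n in counts.items():
        ok = n >= min_trials
        (retained if ok else excluded).append(sid)
        rows.append({"subject": sid, "count": n, "retained": ok})
    return InclusionResult(
        retained=retained, excluded=excluded, log=pd.DataFrame(rows)
    )


def subject_summary(
    trials: pd.DataFrame,
    n_match_repeats: int = 20,
    seed: int | None = None,
    exclude_post_error_controls: bool = True,
) -> dict:
    """All behavioral measures for one subject's classified trial table.

    Returns hit/false-alarm percentages, RT medians, mean single-trial
    PES with its RT-matched PCS control, and PEA with its matched PCA
    control.  Fields whose defining trial set is empty come back NaN.
    By default both slowing pools exclude current trials that themselves
    immediately follow an error: such trials already carry the post-error
    adjustment, so they are contaminated both as error baselines (double
    errors) and as correct controls (see :func:`post_slowing_pairs`).
    """
    n_go = int((trials["stimulus"] == "go").sum())
    n_nogo = int((trials["stimulus"] == "nogo").sum())
    n_hit = int((trials["outcome"] == "hit").sum())
    n_fa = int((trials["outcome"] == "false_alarm").sum())
    rts = rt_summaries(trials)
    pes_pairs = post_slowing_pairs(
        trials, "false_alarm", exclude_post_error=exclude_post_error_controls
    )
    pcs_pairs = post_slowing_pairs(
        trials, "hit", exclude_post_error=exclude_post_error_controls
    )
    pes_slow = pes_pairs["slowing_ms"].dropna()
    out = {
        "hits_pct": 100.0 * n_hit / n_go if n_go else float("nan"),
        "false_alarms_pct": 100.0 * n_fa / n_nogo if n_nogo else float("nan"),
        "overall_rt_ms": rts["overall"]["median"],
        "correct_rt_ms": rts["correct"]["median"],
        "error_rt_ms": rts["error"]["median"],
        "pes_ms": float(pes_slow.mean()) if len(pes_slow) else float("nan"),
        "pcs_ms": float("nan"),
        "pea_pct": post_accuracy(pes_pairs) if len(pes_pairs) else float("nan"),
        "pca_pct": float("nan"),
        "n_error_pairs": int(len(pes_pairs)),
    }
    if len(pes_slow) and len(pcs_pairs.dropna(subset=["slowing_ms"])):
        out["pcs_ms"] = rt_matched_pcs(
            pes_pairs, pcs_pairs, n_repeats=n_match_repeats, seed=seed
        ).mean
    pea_resp = pes_pairs[pes_pairs["next_responded"].astype(bool)]
    pca_resp = pcs_pairs[pcs_pairs["next_responded"].astype(bool)]
    if len(pea_resp) and len(pca_resp):
        out["pca_pct"] = rt_matched_accuracy(
            pes_pairs, pcs_pairs, n_repeats=n_match_repeats, seed=seed
        ).mean
    return out
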