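"""Cohort-level orchestration of the five error-monitoring analyses.

A1  error vs correct contrasts (ERP amplitude and theta ERSP) via
    sample-wise paired permutation tests;
A2  successful vs failed error recovery (error followed by a hit vs by
    another responded false alarm), same machinery;
A3  PES-tertile split of error-preceding-hit trials: ERN and theta
    waveform areas, one-way ANOVA plus paired-t post hocs at the
    Bonferroni-adjusted alpha;
A4  behavioral contrasts: error vs correct RT, PES vs RT-matched PCS,
    PEA vs matched PCA (Wilcoxon), PEA across PES tertiles (Friedman +
    post hocs);
A5  response-stimulus interval across PES tertiles, in the behavioral
    and the neural (error-before-hit) samples.

Per-analysis subject pools are recomputed against the >= 7 qualifying
trials rule (per tertile where applicable), so the reported n varies by
analysis exactly as it does with real cohorts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as beh
from . import stats as st
from .params import SynthParams
from .preprocess import REFERENCE_CHANNELS, ROI_CHANNELS, erp_roi_pipeline, roi_waveform
from .simulate import Subject, simulate_cohort
from .spectral import ersp_pipeline

__all__ = ["AnalysisConfig", "CohortReport", "run_analyses", "write_report"]


@dataclass
class AnalysisConfig:
    """Every numeric constant of the analysis in one place."""

    synth: SynthParams = field(default_factory=SynthParams)

    # preprocessing
    erp_band: tuple = (0.5, 30.0)
    epoch_window_ms: tuple = (-450.0, 550.0)
    erp_baseline_ms: tuple = (-450.0, -50.0)
    ersp_baseline_ms: tuple = (-450.0, -350.0)
    reject_uv: float = 110.0
    roi: tuple = ROI_CHANNELS
    reference_channels: tuple = REFERENCE_CHANNELS
    theta_band: tuple = (4.0, 7.0)
    theta_bin_mode: str = "centered"
    ica: bool = True

    # statistics
    erp_test_window_ms: tuple = (-50.0, 150.0)
    ersp_test_window_ms: tuple = (-350.0, 450.0)
    alpha: float = 0.01
    min_consec: int = 5
    n_perm: int = 2000
    n_match_repeats: int = 20
    family_alpha: float = 0.05
    n_posthoc: int = 3

    # inclusion
    min_error_trials: int = 7

    analyses: tuple = ("A1", "A2", "A3", "A4", "A5")
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            d["synth"] = SynthParams(**d["synth"])
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)


def _plain(obj):
    """Recursively convert numpy scalars/arrays and tuples for serialization."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# per-subject feature extraction
# ---------------------------------------------------------------------------

@dataclass
class _SubjectFeatures:
    subject_id: int
    summary: dict
    n_error_clean: int = 0
    erp: dict = field(default_factory=dict)       # condition -> RoiSeries
    ersp: dict = field(default_factory=dict)
    tertile_ern_area: np.ndarray | None = None    # (3,) uV*ms
    tertile_theta_area: np.ndarray | None = None  # (3,) dB*ms
    tertile_ok: bool = False
    pea_tertiles: np.ndarray | None = None        # (3,) percent
    rsi_tertiles: np.ndarray | None = None        # (3,) ms, behavioral pool
    rsi_neural_tertiles: np.ndarray | None = None
    beh_tertile_ok: bool = False


def _next_trial_info(subject_beh: pd.DataFrame) -> pd.DataFrame:
    t = subject_beh.sort_values(["block", "trial_index"]).reset_index(drop=True)
    nxt = t.shift(-1)
    same = nxt["block"] == t["block"]
    t["next_outcome"] = np.where(same, nxt["outcome"], None)
    t["next_responded"] = np.where(same, nxt["responded"].astype(bool), False)
    t["slowing_ms"] = np.where(
        same & t["responded"] & nxt["responded"].eq(True),
        nxt["rt_ms"] - t["rt_ms"],
        np.nan,
    )
    return t


def _extract_subject(subject: Subject, cfg: AnalysisConfig, seed: int,
                     need_eeg: bool) -> _SubjectFeatures:
    trials = subject.behavior
    summary = beh.subject_summary(
        trials, n_match_repeats=cfg.n_match_repeats, seed=seed
    )
    feats = _SubjectFeatures(subject_id=subject.subject_id, summary=summary)

    # behavioral tertiles (A4/A5): error pairs with responded successors
    pairs = beh.post_slowing_pairs(trials, "false_alarm")
    pairs = pairs[pairs["next_responded"].astype(bool)].dropna(subset=["slowing_ms"])
    if len(pairs) >= 3 * cfg.min_error_trials:
        split = beh.tertile_split(pairs["slowing_ms"].to_numpy())
        if min(split.sizes) >= cfg.min_error_trials:
            feats.beh_tertile_ok = True
            hit = (pairs["next_outcome"] == "hit").to_numpy()
            rsi = cfg.synth.soa_ms - pairs["current_rt"].to_numpy()
            feats.pea_tertiles = np.array(
                [100.0 * hit[split.indices(k)].mean() for k in (1, 2, 3)]
            )
            feats.rsi_tertiles = np.array(
                [float(np.median(rsi[split.indices(k)])) for k in (1, 2, 3)]
            )

    if not need_eeg or subject.raw is None:
        return feats

    erp = erp_roi_pipeline(
        subject.raw,
        band=cfg.erp_band,
        window_ms=cfg.epoch_window_ms,
        baseline_ms=cfg.erp_baseline_ms,
        reject_uv=cfg.reject_uv,
        ica=cfg.ica,
        roi=cfg.roi,
        ref_channels=cfg.reference_channels,
        seed=seed,
    )
    ersp = ersp_pipeline(
        subject.raw,
        band=cfg.theta_band,
        filter_band=cfg.erp_band,
        window_ms=cfg.epoch_window_ms,
        baseline_ms=cfg.ersp_baseline_ms,
        ica=cfg.ica,
        bin_mode=cfg.theta_bin_mode,
        ref_channels=cfg.reference_channels,
        reject_from=erp.epochs,
        seed=seed,
    )

    info = _next_trial_info(trials)
    ev = erp.events.merge(
        info[["block", "trial_index", "next_outcome", "next_responded", "slowing_ms"]],
        on=["block", "trial_index"],
        how="left",
    )
    outcome = ev["outcome"].to_numpy()
    is_err = outcome == "false_alarm"
    is_corr = outcome == "hit"
    err_hit = is_err & (ev["next_outcome"] == "hit").to_numpy()
    err_err = is_err & (ev["next_outcome"] == "false_alarm").to_numpy()

    retained = ~erp.epochs.rejected
    feats.n_error_clean = int((is_err & retained).sum())

    masks = {
        "error": is_err,
        "correct": is_corr,
        "recovery_success": err_hit,
        "recovery_failure": err_err,
    }
    for cond, m in masks.items():
        s = roi_waveform(
            erp.epochs, roi=cfg.roi, condition=cond,
            subject=subject.subject_id, epoch_mask=m,
        )
        if s is not None:
            feats.erp[cond] = s
        s = ersp.roi_series(
            cond, epoch_mask=m, roi=cfg.roi, subject=subject.subject_id
        )
        if s is not None:
            feats.ersp[cond] = s

    # A3: tertile split of retained error-preceding-hit epochs by slowing
    sel = err_hit & retained & np.isfinite(ev["slowing_ms"].to_numpy())
    if sel.sum() >= 3 * cfg.min_error_trials:
        slow = ev.loc[sel, "slowing_ms"].to_numpy()
        split = beh.tertile_split(slow)
        if min(split.sizes) >= cfg.min_error_trials:
            sel_idx = np.flatnonzero(sel)
            ern_area, theta_area, rsi_med = [], [], []
            for k in (1, 2, 3):
                m = np.zeros(len(ev), dtype=bool)
                m[sel_idx[split.indices(k)]] = True
                erp_s = roi_waveform(erp.epochs, roi=cfg.roi, epoch_mask=m)
                ersp_s = ersp.roi_series(f"tertile{k}", epoch_mask=m, roi=cfg.roi)
                if erp_s is None or ersp_s is None:
                    break
                ern_area.append(
                    st.waveform_area(erp_s.values, erp_s.times_ms, cfg.erp_test_window_ms)
                )
                theta_area.append(
                    st.waveform_area(ersp_s.values, ersp_s.times_ms, cfg.ersp_test_window_ms)
                )
                rts = subject.behavior.merge(
                    ev.loc[m, ["block", "trial_index"]], on=["block", "trial_index"]
                )["rt_ms"].to_numpy()
                rsi_med.append(float(np.median(cfg.synth.soa_ms - rts)))
            if len(ern_area) == 3:
                feats.tertile_ok = True
                feats.tertile_ern_area = np.array(ern_area)
                feats.tertile_theta_area = np.array(theta_area)
                feats.rsi_neural_tertiles = np.array(rsi_med)
    return feats


# ---------------------------------------------------------------------------
# cohort report
# ---------------------------------------------------------------------------

@dataclass
class CohortReport:
    config: AnalysisConfig
    tables: dict = field(default_factory=dict)      # name -> DataFrame
    results: dict = field(default_factory=dict)     # name -> rich result objects
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)


def _stack_series(features, domain, cond_a, cond_b):
    """Paired subject x time matrices for two conditions (both present)."""
    ids, rows_a, rows_b = [], [], []
    for f in features:
        store = f.erp if domain == "erp" else f.ersp
        if cond_a in store and cond_b in store:
            ids.append(f.subject_id)
            rows_a.append(store[cond_a].values)
            rows_b.append(store[cond_b].values)
    if not rows_a:
        return ids, None, None, None
    times = next(
        (f.erp if domain == "erp" else f.ersp)[cond_a].times_ms
        for f in features
        if cond_a in (f.erp if domain == "erp" else f.ersp)
    )
    return ids, np.array(rows_a), np.array(rows_b), times


def _perm_row(name, result, n):
    row = {
        "analysis": name,
        "n_subjects": n,
        "n_significant_samples": int(result.mask.sum()),
        "n_runs": len(result.runs),
        "t_min": result.t_range[0],
        "t_max": result.t_range[1],
        "alpha": result.alpha,
        "n_permutations": result.n_permutations,
    }
    if result.runs:
        row["first_run_start_ms"] = result.runs[0][0]
        row["last_run_end_ms"] = result.runs[-1][1]
    return row


def _wilcoxon_row(label, x, y, n_for_r=None):
    res = st.wilcoxon_signed_rank(np.asarray(x), np.asarray(y))
    if res is None:
        return {"comparison": label, "n": 0}
    n = n_for_r or res.n
    return {
        "comparison": label,
        "Z": res.Z,
        "p": res.p,
        "r": round(st.effect_size_r(res.Z, n), 2),
        "n": n,
    }


def run_analyses(config: AnalysisConfig, cohort: list | None = None) -> CohortReport:
    """Execute the enabled analyses over a cohort.

    When ``cohort`` is None a synthetic cohort is generated from
    ``config.synth`` with the config seed; the whole computation is a
    pure function of (config, cohort).
    """
    cfg = config
    todo = set(cfg.analyses)
    # A5's neural-sample variant reuses the A3 error-before-hit epochs, so
    # EEG is only processed when an EEG analysis is itself enabled
    need_eeg = bool(todo & {"A1", "A2", "A3"})
    if cohort is None:
        cohort = simulate_cohort(cfg.synth, seed=cfg.seed, eeg=need_eeg)

    ss = np.random.SeedSequence(cfg.seed)
    sub_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(cohort) + 4)]
    features = [
        _extract_subject(s, cfg, sub_seeds[i], need_eeg)
        for i, s in enumerate(cohort)
    ]

    report = CohortReport(config=cfg)
    excl_rows = []
    if not todo:  # nothing enabled: only the config echo and exclusion log
        report.exclusions = pd.DataFrame(excl_rows)
        return report

    # cohort behavioral summary (Table-2 style measure list)
    summaries = pd.DataFrame([{"subject": f.subject_id, **f.summary} for f in features])
    measures = [
        ("Hits (%)", "hits_pct"),
        ("False Alarms (%)", "false_alarms_pct"),
        ("Overall RT (ms)", "overall_rt_ms"),
        ("Correct-trial RT (ms)", "correct_rt_ms"),
        ("Error-trial RT (ms)", "error_rt_ms"),
        ("Post-correct slowing (ms)", "pcs_ms"),
        ("Post-error slowing (ms)", "pes_ms"),
        ("Post-correct accuracy (%)", "pca_pct"),
        ("Post-error accuracy (%)", "pea_pct"),
    ]
    rows = []
    for label, col in measures:
        v = summaries[col].dropna()
        rows.append(
            {
                "Measure": label,
                "Median": float(v.median()) if len(v) else np.nan,
                "Q25": float(v.quantile(0.25)) if len(v) else np.nan,
                "Q75": float(v.quantile(0.75)) if len(v) else np.nan,
                "n": int(len(v)),
            }
        )
    report.tables["behavior_summary"] = pd.DataFrame(rows)
    report.tables["behavior_subjects"] = summaries

    test_seed = sub_seeds[len(cohort)]

    if "A1" in todo and need_eeg:
        pool = [f for f in features if f.n_error_clean >= cfg.min_error_trials]
        excl_rows += [
            {"analysis": "A1", "subject": f.subject_id, "n": f.n_error_clean,
             "retained": f.n_error_clean >= cfg.min_error_trials}
            for f in features
        ]
        rows = []
        for domain, window in (
            ("erp", cfg.erp_test_window_ms),
            ("ersp", cfg.ersp_test_window_ms),
        ):
            ids, a, b, times = _stack_series(pool, domain, "error", "correct")
            if a is None or len(ids) < 2:
                continue
            res = st.samplewise_permutation_test(
                a, b, times, window_ms=window, alpha=cfg.alpha,
                min_consec=cfg.min_consec, n_perm=cfg.n_perm, seed=test_seed,
            )
            report.results[f"a1_{domain}"] = res
            rows.append(_perm_row(f"A1 error vs correct ({domain})", res, len(ids)))
        report.tables["a1_contrasts"] = pd.DataFrame(rows)

    if "A2" in todo and need_eeg:
        rows = []
        for domain, window in (
            ("erp", cfg.erp_test_window_ms),
            ("ersp", cfg.ersp_test_window_ms),
        ):
            pool = []
            for f in features:
                store = f.erp if domain == "erp" else f.ersp
                if (
                    "recovery_success" in store
                    and "recovery_failure" in store
                    and store["recovery_success"].n_epochs >= cfg.min_error_trials
                    and store["recovery_failure"].n_epochs >= cfg.min_error_trials
                ):
                    pool.append(f)
            ids, a, b, times = _stack_series(
                pool, domain, "recovery_success", "recovery_failure"
            )
            if a is None or len(ids) < 2:
                continue
            res = st.samplewise_permutation_test(
                a, b, times, window_ms=window, alpha=cfg.alpha,
                min_consec=cfg.min_consec, n_perm=cfg.n_perm, seed=test_seed,
            )
            report.results[f"a2_{domain}"] = res
            rows.append(
                _perm_row(f"A2 successful vs failed recovery ({domain})", res, len(ids))
            )
        report.tables["a2_contrasts"] = pd.DataFrame(rows)

    if "A3" in todo and need_eeg:
        pool = [f for f in features if f.tertile_ok]
        excl_rows += [
            {"analysis": "A3", "subject": f.subject_id, "retained": f.tertile_ok}
            for f in features
        ]
        if len(pool) >= 2:
            bonf = st.bonferroni_alpha(cfg.family_alpha, cfg.n_posthoc)
            anova_rows, posthoc_rows = [], []
            for label, attr in (
                ("theta area (dB*ms)", "tertile_theta_area"),
                ("ERN area (uV*ms)", "tertile_ern_area"),
            ):
                mat = np.array([getattr(f, attr) for f in pool])
                res = st.oneway_anova([mat[:, k] for k in range(3)])
                anova_rows.append(
                    {"measure": label, "F": res.F, "df1": res.df1,
                     "df2": res.df2, "p": res.p, "n_subjects": len(pool)}
                )
                report.results[f"a3_anova_{attr}"] = res
                for i, j in ((2, 1), (2, 0), (1, 0)):
                    t = st.paired_t_test(mat[:, i], mat[:, j])
                    posthoc_rows.append(
                        {
                            "measure": label,
                            "comparison": f"tertile {i+1} vs {j+1}",
                            "t": t.t, "df": t.df, "p": t.p,
                            "r": round(st.effect_size_r(t.t, len(pool)), 2),
                            "significant": t.p < bonf,
                            "bonferroni_alpha": bonf,
                        }
                    )
            report.tables["a3_anova"] = pd.DataFrame(anova_rows)
            report.tables["a3_posthoc"] = pd.DataFrame(posthoc_rows)

    if "A4" in todo:
        rows = []
        s = summaries.dropna(subset=["error_rt_ms", "correct_rt_ms"])
        rows.append(_wilcoxon_row(
            "error-trial RT vs correct-trial RT", s["error_rt_ms"], s["correct_rt_ms"]
        ))
        s = summaries.dropna(subset=["pes_ms", "pcs_ms"])
        rows.append(_wilcoxon_row("PES vs matched PCS", s["pes_ms"], s["pcs_ms"]))
        s = summaries.dropna(subset=["pea_pct", "pca_pct"])
        rows.append(_wilcoxon_row("PEA vs matched PCA", s["pea_pct"], s["pca_pct"]))
        report.tables["a4_tests"] = pd.DataFrame(rows)

        pool = [f for f in features if f.beh_tertile_ok]
        excl_rows += [
            {"analysis": "A4-tertiles", "subject": f.subject_id,
             "retained": f.beh_tertile_ok}
            for f in features
        ]
        if len(pool) >= 3:
            mat = np.array([f.pea_tertiles for f in pool])
            fr = st.friedman_test(mat, method="auto" if len(pool) <= 6 else "chi2")
            report.results["a4_friedman"] = fr
            bonf = st.bonferroni_alpha(cfg.family_alpha, cfg.n_posthoc)
            ph = [
                {**_wilcoxon_row(f"PEA tertile {i+1} vs {j+1}",
                                 mat[:, i], mat[:, j], n_for_r=len(pool)),
                 "significant": None, "bonferroni_alpha": bonf}
                for i, j in ((2, 1), (2, 0), (1, 0))
            ]
            for row in ph:
                if "p" in row:
                    row["significant"] = row["p"] < bonf
            report.tables["a4_tertiles"] = pd.DataFrame(
                [{"test": "Friedman", "chi2": fr.chi2, "df": fr.df, "p": fr.p,
                  "n_subjects": len(pool)}]
            )
            report.tables["a4_posthoc"] = pd.DataFrame(ph)
            report.tables["a4_tertile_medians"] = pd.DataFrame(
                {"tertile": [1, 2, 3],
                 "pea_median_pct": np.median(mat, axis=0)}
            )

    if "A5" in todo:
        bonf = st.bonferroni_alpha(cfg.family_alpha, cfg.n_posthoc)
        for name, attr in (
            ("behavioral", "rsi_tertiles"),
            ("neural", "rsi_neural_tertiles"),
        ):
            pool = [f for f in features if getattr(f, attr) is not None]
            if len(pool) < 3:
                continue
            mat = np.array([getattr(f, attr) for f in pool])
            fr = st.friedman_test(mat, method="auto" if len(pool) <= 6 else "chi2")
            report.results[f"a5_{name}_friedman"] = fr
            ph = [
                _wilcoxon_row(f"RSI tertile {i+1} vs {j+1}",
                              mat[:, i], mat[:, j], n_for_r=len(pool))
                for i, j in ((2, 1), (2, 0), (1, 0))
            ]
            for row in ph:
                if "p" in row:
                    row["significant"] = row["p"] < bonf
                    row["bonferroni_alpha"] = bonf
            report.tables[f"a5_{name}"] = pd.DataFrame(
                [{"test": "Friedman", "chi2": fr.chi2, "df": fr.df, "p": fr.p,
                  "n_subjects": len(pool),
                  "tertile_rsi_medians_ms": list(np.median(mat, axis=0))}]
            )
            report.tables[f"a5_{name}_posthoc"] = pd.DataFrame(ph)

    report.exclusions = pd.DataFrame(excl_rows)
    return report


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def write_report(report: CohortReport, outdir, plots: bool = False) -> list:
    """Write CSV tables, a JSON summary, a JSONL exclusion log, the config
    echo, and a checksum manifest.  Returns the list of files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    report.config.to_yaml(outdir / "config.yaml")
    written.append(outdir / "config.yaml")

    for name, table in report.tables.items():
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False)
        written.append(path)

    summary = {
        name: _plain(
            dataclasses.asdict(res) if dataclasses.is_dataclass(res) else res
        )
        for name, res in report.results.items()
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    written.append(outdir / "summary.json")

    with open(outdir / "exclusions.jsonl", "w") as fh:
        for rec in report.exclusions.to_dict(orient="records"):
            fh.write(json.dumps(_plain(rec)) + "\n")
    written.append(outdir / "exclusions.jsonl")

    if plots:
        written += _quicklook_plots(report, outdir)

    manifest = {}
    for path in written:
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return written + [outdir / "manifest.json"]


def _quicklook_plots(report: CohortReport, outdir: Path) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if "a4_tertile_medians" in report.tables:
        t = report.tables["a4_tertile_medians"]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(t["tertile"], t["pea_median_pct"], color="tab:blue")
        ax.set_xlabel("PES tertile")
        ax.set_ylabel("post-error accuracy (%)")
        fig.tight_layout()
        path = outdir / "pea_by_tertile.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
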