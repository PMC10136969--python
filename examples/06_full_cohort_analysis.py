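"""The full five-analysis pipeline on a synthetic cohort.

Runs behavioral contrasts, the error-vs-correct ERP and theta-ERSP
permutation tests, the PES-tertile neural analysis, and the RSI
analysis, with per-analysis inclusion filtering, then writes the report
tables to ./cohort_report/.
"""

from gonogo import SynthParams
from gonogo.pipeline import AnalysisConfig, run_analyses, write_report

config = AnalysisConfig(
    synth=SynthParams(n_subjects=10, blocks_per_subject=4),
    analyses=("A1", "A3", "A4", "A5"),
    ica=False,          # no blink removal needed with blink-free synthesis
    seed=42,
)
config.synth.blink_rate_hz = 0.0

report = run_analyses(config)

print(report.tables["behavior_summary"].to_string(index=False))
print()
print(report.tables["a1_contrasts"][
    ["analysis", "n_subjects", "n_runs", "t_min", "t_max"]
].to_string(index=False))
print()
print(report.tables["a4_tests"].to_string(index=False))

files = write_report(report, "cohort_report")
print(f"\nwrote {len(files)} report files to cohort_report/")
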