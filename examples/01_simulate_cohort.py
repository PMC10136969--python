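"""Simulate a small go/no-go cohort and look at its raw ingredients.

Each subject gets a trial sequence (70 % go), responses with fast
commission errors and ~150 ms post-error slowing, and a 14-channel
128 Hz EEG recording with an error negativity and induced theta bursts.
"""

from gonogo import SynthParams, simulate_cohort

params = SynthParams(n_subjects=3, blocks_per_subject=2, seed=1)
cohort = simulate_cohort(params, eeg=True)

for s in cohort:
    b = s.behavior
    n_fa = (b["outcome"] == "false_alarm").sum()
    n_hit = (b["outcome"] == "hit").sum()
    print(
        f"subject {s.subject_id}: {len(b)} trials, {n_hit} hits, "
        f"{n_fa} false alarms, EEG {s.raw.data.shape[0]} ch x "
        f"{s.raw.data.shape[1]} samples at {s.raw.sfreq:.0f} Hz"
    )

b = cohort[0].behavior
err = b.loc[b.outcome == "false_alarm", "rt_ms"].median()
cor = b.loc[b.outcome == "hit", "rt_ms"].median()
print(f"\nsubject 0 RT medians: errors {err:.0f} ms < corrects {cor:.0f} ms")
print("(commission errors happen in fast, impulsive moments, so error RTs")
print(" are reliably faster than correct RTs — as in real go/no-go data)")
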