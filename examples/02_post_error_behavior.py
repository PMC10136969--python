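"""Post-error slowing and accuracy with the RT-matched control.

Prints one subject's behavioral summary: raw post-error slowing (PES),
the RT-matched post-correct slowing control (PCS), and the accuracy
analogues (PEA/PCA).  PES minus matched PCS estimates the strategic
slowing over and above regression to the mean.
"""

from gonogo import SynthParams, simulate_subject
from gonogo.behavior import subject_summary

params = SynthParams(blocks_per_subject=8, seed=3)
subject = simulate_subject(params, eeg=False)
s = subject_summary(subject.behavior, seed=0)

print(f"hit rate            {s['hits_pct']:.1f} %")
print(f"false-alarm rate    {s['false_alarms_pct']:.1f} %")
print(f"correct-trial RT    {s['correct_rt_ms']:.0f} ms")
print(f"error-trial RT      {s['error_rt_ms']:.0f} ms")
print(f"PES                 {s['pes_ms']:.1f} ms")
print(f"matched PCS         {s['pcs_ms']:.1f} ms")
print(f"PES - matched PCS   {s['pes_ms'] - s['pcs_ms']:.1f} ms "
      f"(the generator injected {params.pes_shift_ms:.0f} ms)")
print(f"PEA                 {s['pea_pct']:.1f} %")
print(f"matched PCA         {s['pca_pct']:.1f} %")
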