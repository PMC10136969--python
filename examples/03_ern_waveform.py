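"""Response-locked ERN at the frontal ROI.

Runs the amplitude path (0.5-30 Hz FIR, ICA, [-450, 550] ms epochs with
[-450, -50] ms baseline, pseudo-average reference, +/-110 uV rejection,
F3/F4 average) on one subject and prints where the error-minus-correct
waveform peaks.
"""

import numpy as np

from gonogo import SynthParams, simulate_subject
from gonogo.preprocess import erp_roi_pipeline

subject = simulate_subject(SynthParams(blocks_per_subject=3, seed=7))
res = erp_roi_pipeline(subject.raw, seed=0)

err = res.series["error"]
cor = res.series["correct"]
diff = err.values - cor.values
peak = np.argmin(diff)
print(f"error epochs: {err.n_epochs}, correct epochs: {cor.n_epochs}")
print(f"error-minus-correct minimum: {diff[peak]:.2f} uV "
      f"at {err.times_ms[peak]:.0f} ms after the button press")
print("a fronto-central negativity within ~100 ms of the erroneous press")
print("is the error-related negativity (ERN)")
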