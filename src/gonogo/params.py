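"""Parameter containers for the synthetic go/no-go cohort generator.

The defaults encode the study conditions the package is designed around:
90-trial blocks with P(go) = 0.70, 1200 ms onset-to-onset timing (400 ms
stimulus + 800 ms fixation cross), fast commission errors (~36 % of no-go
trials), a ~74 % hit rate, and ~150 ms of post-error slowing coupled to
post-error accuracy.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass


#: Emotiv EPOC 14-channel 10-20 montage, in cap order.
CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Frontal-dominant volume-conduction template for the error-monitoring
#: sources (ERN and midfrontal theta).  No head model: a fixed channel-weight
#: map is sufficient for ROI-level analyses.
FRONTAL_WEIGHTS = {
    "F3": 1.0, "F4": 1.0,
    "AF3": 0.55, "AF4": 0.55,
    "FC5": 0.55, "FC6": 0.55,
    "F7": 0.40, "F8": 0.40,
    "T7": 0.15, "T8": 0.15,
    "P7": 0.05, "P8": 0.05,
    "O1": 0.05, "O2": 0.05,
}

#: Blink topography: dominated by the two most anterior sites.
BLINK_WEIGHTS = {
    "AF3": 1.0, "AF4": 1.0,
    "F7": 0.35, "F8": 0.35,
    "F3": 0.12, "F4": 0.12,
}


@dataclass
class SynthParams:
    """Generative settings for a synthetic go/no-go EEG cohort.

    Reaction times follow a lognormal model with a slowly drifting
    within-block "tempo" state (AR(1) on log-RT).  Commission errors are
    more likely in fast tempo states, which is what makes error-trial RTs
    faster than correct-trial RTs and makes RT-matching of post-correct
    pairs meaningful.  ``pes_shift_ms`` is an additive, single-trial
    strategic slowing applied to the trial after a responded false alarm.
    """

    # cohort layout
    n_subjects: int = 30
    blocks_per_subject: int = 8
    trials_per_block: int = 90
    p_go: float = 0.70
    soa_ms: float = 1200.0          # 400 ms stimulus + 800 ms cross

    # reaction-time model (lognormal; medians parameterized directly)
    rt_correct_median_ms: float = 587.0
    rt_correct_spread: float = 0.29      # total log-sd of correct-trial RT
    rt_error_median_ms: float = 481.0    # target error-trial RT median
    rt_error_spread: float = 0.29
    rt_autocorr: float = 0.96            # AR(1) coefficient of the slow tempo drift
    rt_transient_share: float = 0.30     # variance share of the transient
                                         # (single-trial) impulsivity component
    rt_resid_sd: float = 0.05            # trial-wise log-RT noise given tempo

    # response probabilities
    p_commission: float = 0.36           # response on no-go (marginal)
    p_omission: float = 0.26             # no response on go

    # post-error dynamics
    pes_shift_ms: float = 150.0          # additive slowing after a false alarm
    pes_noise_ms: float = 50.0           # sd of the trial-wise slowing noise
    pea_coupling: float = 0.30           # logit of next-trial accuracy per
                                         # 100 ms of realized slowing

    # EEG model
    sfreq: float = 128.0
    ern_amp_uv: float = 6.0              # peak error negativity at F3/F4
    ern_correct_fraction: float = 0.2    # CRN amplitude as a fraction of ERN
    theta_gain_db: float = 3.0           # peak induced theta gain on errors
    theta_pes_coupling: float = 0.005    # extra dB per ms of realized slowing
    noise_exponent: float = 1.0          # 1/f^a background slope
    noise_rms_uv: float = 10.0
    blink_rate_hz: float = 0.2
    blink_amp_uv: float = 120.0
    block_pad_s: float = 2.0             # noise-only padding around blocks

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_go", "p_commission", "p_omission"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be >= 1")
        if self.blocks_per_subject < 1:
            raise ValueError("blocks_per_subject must be >= 1")
        if self.soa_ms <= 0:
            raise ValueError("soa_ms must be positive")
        if not 0.0 <= self.rt_autocorr < 1.0:
            raise ValueError("rt_autocorr must be in [0, 1)")
        if self.rt_resid_sd >= self.rt_correct_spread:
            raise ValueError("rt_resid_sd must be below rt_correct_spread")
        if not 0.0 <= self.rt_transient_share < 1.0:
            raise ValueError("rt_transient_share must be in [0, 1)")

    @property
    def tempo_sd(self) -> float:
        """Total sd of the tempo state (drift + transient) on the log-RT scale."""
        return math.sqrt(self.rt_correct_spread ** 2 - self.rt_resid_sd ** 2)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthParams":
        return cls(**d)
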