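"""Study-condition presets for the S0-S3 stretch-conditioning groups.

Each preset bundles the group-level values the analyses target: daily
distension increments, electrophysiology (resting potential, AP
amplitude, upstroke velocity), the residual force after a 2-minute
medium-agitation cessation, sarcomere lengths, the force-frequency
table, the isometric length-force protocol, and the specific-force
inputs.  Intermediate groups (S1, S2) are reported for the endpoints
only where the study quantified them; the presets cover the two
endpoint groups S0 (static) and S3 (high stretch) plus the stretch
increments for all four.
"""

from __future__ import annotations

import numpy as np

from .synthetic import APParams, HypoxiaWindow

# Daily post distension, mm/day.
STRETCH_INCREMENT_MM_PER_DAY = {"S0": 0.0, "S1": 0.08, "S2": 0.16, "S3": 0.32}

# Intracellular electrophysiology (group means).
AP_PRESETS = {
    "S0": dict(rmp=-52.5, amplitude=68.3, upstroke_velocity=7.79),
    "S3": dict(rmp=-72.4, amplitude=99.7, upstroke_velocity=13.47),
}

# Residual twitch force (%) after 2 min without medium agitation.
HYPOXIA_RESIDUAL_PERCENT = {"S0": 77.6, "S3": 64.0}

# Sarcomere length, um.
SARCOMERE_LENGTH_UM = {"S0": 1.87, "S3": 2.19}

# Twitch force (mN) by pacing rate; S3 peaks 1.25-fold at 3 Hz, S0 is negative.
FFR_FORCES_MN = {
    "S0": {1.0: 2.0, 2.0: 1.8, 3.0: 1.5, 4.0: 1.3},
    "S3": {1.0: 2.0, 2.0: 2.3, 3.0: 2.5, 4.0: 2.4},
}

# Isometric length-step protocol (fractions of slack length) with the S3
# optimum-preload forces: systolic 11.37 mN over diastolic 1.20 mN.
FRANK_STARLING_S3 = dict(
    relative_length=(1.0, 1.2, 1.4, 1.6, 1.8),
    twitch_amplitude=(2.5, 5.0, 8.0, 10.17, 8.5),  # mN
    diastolic_force=(0.12, 0.30, 0.60, 1.20, 2.40),  # mN
)

# Passive stress-strain points giving the S3 elastic modulus of 4.5 kPa.
STRESS_STRAIN_S3 = ((0.0, 0.0), (0.2, 0.9), (0.4, 1.8))  # (strain, kPa)

# Specific force: S3 twitch force (mN) over actinin+ cross-section (mm^2).
SPECIFIC_FORCE_INPUTS = {"S3": dict(twitch_mn=2.82, actinin_cross_section_mm2=0.25)}

# Fraction of differentiated cells double-positive for cTnT/alpha-actinin.
MYOCYTE_FRACTION = 0.69

# Adult-gene-set expression fold, S3 over S0.
MATURATION_FOLD_S3_VS_S0 = 2.1


def hypoxia_decline_tau(group: str) -> float:
    """Decline constant (s) whose 120 s endpoint matches the group residual."""
    residual = HYPOXIA_RESIDUAL_PERCENT[group] / 100.0
    return -120.0 / float(np.log(residual))


def hypoxia_window(group: str, start: float = 300.0) -> HypoxiaWindow:
    """A 2-minute agitation-cessation window calibrated to the group preset."""
    return HypoxiaWindow(start=start, duration=120.0, decline_tau=hypoxia_decline_tau(group))


def ap_params(group: str, **overrides) -> APParams:
    """AP-train generator parameters for a conditioning group."""
    kw = dict(AP_PRESETS[group])
    kw.setdefault("apd90", 0.3)
    kw.update(overrides)
    return APParams(**kw)
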