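"""Protocol-level EHT mechanics.

Frank-Starling (length-force) analysis at isometric length steps, the
passive elastic modulus from diastolic stress vs strain, specific force
normalized to the alpha-actinin-positive cross-section, the
force-frequency relationship (FFR), and drug-response fold changes.

Conventions: forces in mN, cross-sections in mm^2, so stresses come out
in mN/mm^2 = kPa.  Systolic force is diastolic plus twitch amplitude
(peak total force); strain is engineering strain (L - L_slack)/L_slack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LengthForceCurve",
    "TissueGeometry",
    "FFRCurve",
    "frank_starling",
    "elastic_modulus",
    "specific_force",
    "ffr",
    "drug_response",
]


@dataclass
class TissueGeometry:
    """Slack length and cross-sections of one EHT."""

    slack_length: float = 3.0  # mm
    actinin_cross_section: float = 0.25  # mm^2
    tissue_cross_section: float | None = None  # mm^2

    def __post_init__(self):
        if not self.actinin_cross_section > 0:
            raise ValueError("actinin cross-section must be positive")
        if (
            self.tissue_cross_section is not None
            and self.actinin_cross_section > self.tissue_cross_section
        ):
            raise ValueError("actinin cross-section cannot exceed tissue cross-section")


@dataclass
class LengthForceCurve:
    """Per-length-step diastolic and twitch forces of an isometric protocol."""

    relative_length: np.ndarray  # fraction of slack length (>= 1 at/above slack)
    diastolic_force: np.ndarray  # mN
    twitch_amplitude: np.ndarray  # mN
    absolute_length: np.ndarray | None = None  # mm
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.relative_length = np.asarray(self.relative_length, dtype=float)
        self.diastolic_force = np.asarray(self.diastolic_force, dtype=float)
        self.twitch_amplitude = np.asarray(self.twitch_amplitude, dtype=float)
        n = self.relative_length.size
        if self.diastolic_force.size != n or self.twitch_amplitude.size != n:
            raise ValueError("all per-step arrays must have equal length")

    @property
    def systolic_force(self) -> np.ndarray:
        """Peak total force: diastolic + twitch amplitude."""
        return self.diastolic_force + self.twitch_amplitude

    @property
    def strain(self) -> np.ndarray:
        """(L - L_slack) / L_slack."""
        return self.relative_length - 1.0


def frank_starling(curve: LengthForceCurve, *, diastolic_floor_frac: float = 0.01) -> dict:
    """Optimum preload and systolic/diastolic ratio of a length-force curve.

    The optimum length is the step of maximal twitch amplitude; the
    systolic/diastolic ratio is evaluated there.  A diastolic force below
    ``diastolic_floor_frac`` of the maximum systolic force makes the
    ratio undefined (NaN with a warning) rather than near-infinite.  A
    per-step ratio curve is also returned.
    """
    rl = curve.relative_length
    if rl.size < 3:
        raise ValueError("need at least 3 length steps")
    if np.any(np.diff(rl) <= 0):
        raise ValueError("length steps must be strictly increasing")
    i_opt = int(np.argmax(curve.twitch_amplitude))
    sys_f = curve.systolic_force
    floor = diastolic_floor_frac * float(np.max(sys_f))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_curve = np.where(curve.diastolic_force > floor, sys_f / curve.diastolic_force, np.nan)
    dia_opt = float(curve.diastolic_force[i_opt])
    if dia_opt > floor:
        ratio = float(sys_f[i_opt] / dia_opt)
    else:
        warnings.warn(
            "diastolic force at optimum preload is below the floor; "
            "systolic/diastolic ratio undefined",
            stacklevel=2,
        )
        ratio = np.nan
    return dict(
        optimum_relative_length=float(rl[i_opt]),
        max_twitch=float(curve.twitch_amplitude[i_opt]),
        sys_dia_ratio=ratio,
        ratio_curve=ratio_curve,
    )


def elastic_modulus(
    curve: LengthForceCurve,
    geometry: TissueGeometry,
    *,
    strain_window: tuple[float, float] | None = None,
    use_tissue_cross_section: bool = False,
    mode: str = "fit",
) -> dict:
    """Passive elastic modulus (kPa): slope of diastolic stress vs strain.

    Diastolic stress is diastolic force divided by the actinin-positive
    cross-section (or the whole-tissue cross-section on request).  By
    default a least-squares line is fitted over all points up to the
    optimum length; ``strain_window`` restricts the fit, and
    ``mode="chord"`` uses the end-point chord slope instead.
    """
    area = (
        geometry.tissue_cross_section
        if use_tissue_cross_section
        else geometry.actinin_cross_section
    )
    if not area or not area > 0:
        raise ValueError("cross-section must be positive")
    strain = curve.strain
    stress = curve.diastolic_force / area  # mN/mm^2 = kPa
    if strain_window is None:
        i_opt = int(np.argmax(curve.twitch_amplitude))
        sel = np.arange(strain.size) <= i_opt
    else:
        lo, hi = strain_window
        sel = (strain >= lo) & (strain <= hi)
    x, y = strain[sel], stress[sel]
    if np.unique(x).size < 2:
        raise ValueError("degenerate fit: need at least two distinct strains")
    if mode == "chord":
        slope = float((y[-1] - y[0]) / (x[-1] - x[0]))
        residual = np.nan
    else:
        coef, res, *_ = np.polyfit(x, y, 1, full=True)
        slope = float(coef[0])
        residual = float(res[0]) if len(res) else 0.0
    return dict(modulus_kpa=slope, fit_residual=residual, n_points=int(sel.sum()))


def specific_force(twitch: float, geometry: TissueGeometry) -> float:
    """Twitch force normalized to actinin-positive cross-section (mN/mm^2)."""
    if not geometry.actinin_cross_section > 0:
        raise ValueError("cross-section must be positive")
    return float(twitch) / geometry.actinin_cross_section


def ffr(forces_by_rate: dict, *, flat_tol: float = 0.02) -> dict:
    """Force-frequency relationship normalized to the 1 Hz value.

    Returns the normalized curve, the peak fold and its pacing rate, and
    a positive/negative/flat classification by the sign of the
    least-squares slope of normalized force vs rate (|slope| below
    ``flat_tol`` fold/Hz counts as flat).
    """
    rates = np.array(sorted(forces_by_rate), dtype=float)
    if not np.any(np.isclose(rates, 1.0)):
        raise ValueError("missing 1 Hz reference entry")
    forces = np.array([forces_by_rate[r] for r in sorted(forces_by_rate)], dtype=float)
    ref = float(forces[np.isclose(rates, 1.0)][0])
    if not ref > 0:
        raise ValueError("1 Hz reference force must be positive")
    norm = forces / ref
    i_pk = int(np.argmax(norm))
    slope = float(np.polyfit(rates, norm, 1)[0])
    classification = "flat" if abs(slope) < flat_tol else ("positive" if slope > 0 else "negative")
    table = pd.DataFrame(
        {"frequency_hz": rates, "force_mn": forces, "normalized_force": norm}
    )
    return dict(
        curve=table,
        peak_rate=float(rates[i_pk]),
        peak_fold=float(norm[i_pk]),
        classification=classification,
        slope=slope,
    )


def drug_response(pre_beats: pd.DataFrame, post_beats: pd.DataFrame) -> dict:
    """Post/pre fold changes of twitch force, relaxation rate and duration.

    Both inputs are beat tables from :func:`ehtkit.force_trace.detect_beats`
    (pre- and post-treatment windows, e.g. around isoprenaline exposure).
    """
    if pre_beats.empty or post_beats.empty:
        raise ValueError("both pre- and post-treatment windows must contain beats")
    out = {}
    for col, name in [
        ("twitch_amplitude", "twitch_force_fold"),
        ("relaxation_rate", "relaxation_rate_fold"),
        ("contraction_duration", "contraction_duration_fold"),
    ]:
        pre = float(pre_beats[col].mean())
        if pre == 0 or not np.isfinite(pre):
            raise ValueError(f"zero or invalid pre-treatment mean for {col}")
        out[name] = float(post_beats[col].mean()) / pre
    return out
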