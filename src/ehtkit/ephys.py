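"""Feature extraction from Ca2+ fluorescence transients and intracellular
action-potential recordings.

Ca2+ transients (e.g. Fluo-4) are summarized by their amplitude (dF/F0),
transient durations at 50% and 90% return, and the monoexponential decay
constant tau fitted between the peak and 10% above baseline.  Action
potentials yield resting membrane potential, amplitude, maximum upstroke
velocity (max dV/dt) and APD90 (duration to 90% repolarization from
upstroke onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FluorescenceTrace",
    "VoltageTrace",
    "ca_features",
    "ap_features",
]


@dataclass
class FluorescenceTrace:
    """Uniformly sampled fluorescence intensity (arbitrary units)."""

    time: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.size != self.intensity.size or self.time.size < 2:
            raise ValueError("time and intensity must be equal-length, >= 2 samples")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane potential in mV."""

    time: np.ndarray
    voltage: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.size != self.voltage.size or self.time.size < 2:
            raise ValueError("time and voltage must be equal-length, >= 2 samples")

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])


def _stim_grid(time, stim_times, rate):
    if stim_times is not None:
        stim = np.asarray(stim_times, dtype=float)
    elif rate is not None:
        stim = np.arange(time[0] + 1.0 / rate, time[-1], 1.0 / rate)
    else:
        raise ValueError("need stim_times or rate")
    if stim.size == 0:
        raise ValueError("no stimulation times inside the trace")
    period = float(np.median(np.diff(stim))) if stim.size > 1 else float(
        time[-1] - stim[0]
    )
    return stim, period


def _cross_time(t, y, level, rising):
    """First linear-interpolated crossing of ``level`` in the stated direction."""
    if rising:
        hits = np.nonzero((y[:-1] < level) & (y[1:] >= level))[0]
    else:
        hits = np.nonzero((y[:-1] > level) & (y[1:] <= level))[0]
    if hits.size == 0:
        return np.nan
    i = hits[0]
    frac = (level - y[i]) / (y[i + 1] - y[i]) if y[i + 1] != y[i] else 0.5
    return float(t[i] + frac * (t[i + 1] - t[i]))


def ca_features(
    trace: FluorescenceTrace,
    stim_times=None,
    rate: float | None = None,
    *,
    onset_frac: float = 0.1,
    baseline_frac: float = 0.2,
    fit_window: str = "peak_to_10",
) -> pd.DataFrame:
    """Per-transient Ca2+ features.

    For each stimulation interval: F0 is the mean over the pre-upstroke
    window (last ``baseline_frac`` of the preceding interval), amplitude
    is (peak - F0)/F0, durations run from upstroke onset (crossing of
    ``onset_frac`` of amplitude) to 50% and 90% return, and tau comes from
    a least-squares monoexponential fit between the peak and 10% above
    baseline (``fit_window="half_to_10"`` starts the fit at 50% return
    instead).  A non-decaying transient gets tau = NaN.
    """
    t, F = trace.time, trace.intensity
    stim, period = _stim_grid(t, stim_times, rate)
    rows = []
    for i, s in enumerate(stim):
        s_end = stim[i + 1] if i + 1 < stim.size else s + period
        i0, i1 = np.searchsorted(t, [s, min(s_end, t[-1] + 1e-12)])
        if i1 - i0 < 5:
            continue
        b0, b1 = np.searchsorted(t, [s - baseline_frac * period, s])
        if b1 - b0 < 1:  # first transient: use the tail of its own interval
            b0, b1 = np.searchsorted(t, [s_end - baseline_frac * period, s_end])
        f0 = float(np.mean(F[b0:b1]))
        if not f0 > 0:
            raise ValueError("non-positive baseline fluorescence F0")
        seg, tseg = F[i0:i1], t[i0:i1]
        ipk = int(np.argmax(seg))
        peak = float(seg[ipk])
        amp_abs = peak - f0
        amplitude = amp_abs / f0
        onset = _cross_time(tseg[: ipk + 1], seg[: ipk + 1], f0 + onset_frac * amp_abs, True)
        t50 = _cross_time(tseg[ipk:], seg[ipk:], f0 + 0.5 * amp_abs, False)
        t90 = _cross_time(tseg[ipk:], seg[ipk:], f0 + 0.1 * amp_abs, False)
        dur50 = t50 - onset if np.isfinite(t50) else np.nan
        dur90 = t90 - onset if np.isfinite(t90) else np.nan
        tau, r2 = _fit_tau(tseg, seg, ipk, f0, amp_abs, fit_window)
        rows.append(
            dict(
                time=float(s),
                f0=f0,
                amplitude=amplitude,
                duration_50=dur50,
                duration_90=dur90,
                tau=tau,
                fit_r2=r2,
            )
        )
    if not rows:
        raise ValueError("no complete transient inside the trace")
    return pd.DataFrame(rows)


def _fit_tau(tseg, seg, ipk, f0, amp_abs, fit_window):
    stop_level = f0 + 0.1 * amp_abs
    start = ipk
    if fit_window == "half_to_10":
        below = np.nonzero(seg[ipk:] <= f0 + 0.5 * amp_abs)[0]
        if below.size:
            start = ipk + below[0]
    below = np.nonzero(seg[start:] <= stop_level)[0]
    stop = start + below[0] + 1 if below.size else seg.size
    tt = tseg[start:stop] - tseg[start]
    yy = seg[start:stop] - f0
    if tt.size < 4 or np.all(yy <= 0):
        return np.nan, np.nan
    # log-linear initialization, nonlinear refinement
    pos = yy > 0
    slope, intercept = np.polyfit(tt[pos], np.log(yy[pos]), 1)
    if slope >= 0:
        return np.nan, np.nan
    try:
        popt, _ = curve_fit(
            lambda x, b, tau: b * np.exp(-x / tau),
            tt,
            yy,
            p0=[np.exp(intercept), -1.0 / slope],
            maxfev=2000,
        )
    except RuntimeError:
        return np.nan, np.nan
    b, tau = popt
    if tau <= 0:
        return np.nan, np.nan
    pred = b * np.exp(-tt / tau)
    ss_res = float(np.sum((yy - pred) ** 2))
    ss_tot = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return float(tau), r2


def ap_features(
    trace: VoltageTrace,
    stim_times=None,
    rate: float | None = None,
    *,
    rest_frac: float = 0.2,
    onset_frac: float = 0.1,
    min_depolarization: float = 10.0,
) -> pd.DataFrame:
    """Per-action-potential features.

    The resting potential is the mean over the diastolic window (the last
    ``rest_frac`` of the interval preceding each upstroke), amplitude is
    peak minus resting, upstroke velocity the maximum central-difference
    dV/dt between upstroke onset and peak (V/s), and APD90 the time from
    upstroke onset (crossing ``onset_frac`` of amplitude) to 90%
    repolarization.  Raises if no AP exceeds ``min_depolarization`` mV.
    """
    t, V = trace.time, trace.voltage
    stim, period = _stim_grid(t, stim_times, rate)
    dt = trace.sampling_interval
    rows = []
    for i, s in enumerate(stim):
        s_end = stim[i + 1] if i + 1 < stim.size else s + period
        i0, i1 = np.searchsorted(t, [s, min(s_end, t[-1] + 1e-12)])
        if i1 - i0 < 5:
            continue
        b0, b1 = np.searchsorted(t, [s - rest_frac * period, s])
        if b1 - b0 < 1:
            b0, b1 = np.searchsorted(t, [s_end - rest_frac * period, s_end])
        rest = float(np.mean(V[b0:b1]))
        seg, tseg = V[i0:i1], t[i0:i1]
        ipk = int(np.argmax(seg))
        peak = float(seg[ipk])
        amp = peak - rest
        if amp < min_depolarization:
            continue
        onset = _cross_time(
            tseg[: ipk + 1], seg[: ipk + 1], rest + onset_frac * amp, True
        )
        # max central-difference dV/dt during depolarization (mV/s -> V/s)
        j0 = max(int(np.searchsorted(tseg, onset)) - 1, 1) if np.isfinite(onset) else 1
        dvdt = (seg[2:] - seg[:-2]) / (2 * dt)
        up = float(np.max(dvdt[j0 - 1 : ipk])) / 1000.0 if ipk > j0 - 1 else np.nan
        t90 = _cross_time(tseg[ipk:], seg[ipk:], rest + 0.1 * amp, False)
        apd90 = t90 - onset if np.isfinite(t90) and np.isfinite(onset) else np.nan
        rows.append(
            dict(
                time=float(s),
                resting_potential=rest,
                amplitude=amp,
                upstroke_velocity=up,
                apd90=apd90,
            )
        )
    if not rows:
        raise ValueError("no depolarization detected")
    return pd.DataFrame(rows)
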