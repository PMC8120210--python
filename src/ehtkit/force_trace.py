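"""Twitch-force trace analytics for engineered heart tissue (EHT).

Converts raw displacement/force logs into per-beat features and
protocol-level summaries: conditioning time courses, acute stretch-step
responses, residual force during simulated hypoxia (cessation of medium
agitation), and the electrical stimulation threshold.

Forces are in mN throughout, times in seconds.  The recording hardware
measures the displacement of a calibrated spring (compliance 71 mm/N by
default), so ``displacement_to_force`` is the entry point for raw logs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "ForceTrace",
    "SpringModel",
    "displacement_to_force",
    "detect_beats",
    "conditioning_timecourse",
    "stretch_step_response",
    "hypoxia_residual",
    "stimulation_threshold",
]


@dataclass
class ForceTrace:
    """A uniformly sampled force recording.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing and uniform.
    force : ndarray
        Force in mN, same length as ``time``.
    stim_times : ndarray, optional
        Stimulation timestamps in seconds.
    post_distance : ndarray, optional
        Post (holding-hook) distance in mm, piecewise constant over time.
    group : str, optional
        Conditioning group label (S0-S3).
    """

    time: np.ndarray
    force: np.ndarray
    stim_times: np.ndarray | None = None
    post_distance: np.ndarray | None = None
    group: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("trace needs at least two samples")
        if self.time.size != self.force.size:
            raise ValueError("time and force must have equal length")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("force contains non-finite values")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 + 1e-9 * dt[0]:
            raise ValueError("time grid is not uniform")
        if self.stim_times is not None:
            self.stim_times = np.asarray(self.stim_times, dtype=float)

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class SpringModel:
    """Elastic mounting spring: force = displacement / compliance."""

    compliance: float = 71.0  # mm/N

    def __post_init__(self):
        if not self.compliance > 0:
            raise ValueError("compliance must be positive")


def displacement_to_force(displacement, model: SpringModel | None = None):
    """Convert spring displacement (mm) to force (mN).

    Linear and sign-preserving; negative displacements (compression)
    trigger a warning but are converted.
    """
    model = model or SpringModel()
    d = np.asarray(displacement, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite displacement")
    if np.any(d < 0):
        warnings.warn("negative displacement: spring in compression", stacklevel=2)
    force = d / model.compliance * 1000.0  # mm / (mm/N) = N -> mN
    if np.isscalar(displacement):
        return float(force)
    return force


def _crossings(t, y, level):
    """All linearly interpolated crossing times of ``level``."""
    above = y >= level
    idx = np.nonzero(above[1:] != above[:-1])[0]
    out = []
    for i in idx:
        y0, y1 = y[i], y[i + 1]
        frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.5
        out.append(t[i] + frac * (t[i + 1] - t[i]))
    return np.asarray(out)


def detect_beats(
    trace: ForceTrace,
    pacing_rate: float | None = None,
    stim_times=None,
    *,
    diastolic_window_frac: float = 0.2,
    capture_k: float = 4.0,
    duration_threshold_frac: float = 0.1,
    smooth_window: int = 21,
    smooth_poly: int = 3,
    use_smoothed: bool | None = None,
) -> pd.DataFrame:
    """Segment a paced force trace into per-beat features.

    One record is produced per stimulation interval.  The diastolic force
    is the minimum within the pre-upstroke window (the last
    ``diastolic_window_frac`` of the pacing interval before the stimulus);
    the peak force is the maximum within the interval, and the twitch
    amplitude their difference.  Beats whose amplitude does not exceed a
    robust noise floor (``capture_k`` times the MAD of the detrended
    signal) are marked non-captured, supporting all-or-nothing response
    and stimulation-threshold analyses.

    When the trace is noisy the extremes are read from a lightly smoothed
    (Savitzky-Golay) copy; on effectively noiseless traces the raw samples
    are used so that round trips against the generator are exact.  Set
    ``use_smoothed`` to force either behaviour.

    Returns a DataFrame with columns ``time, diastolic_force, peak_force,
    twitch_amplitude, time_to_peak, relaxation_rate, contraction_duration,
    captured``.
    """
    t, f = trace.time, trace.force
    if stim_times is not None:
        stim = np.asarray(stim_times, dtype=float)
    elif pacing_rate is not None:
        if not pacing_rate > 0:
            raise ValueError("pacing_rate must be positive")
        stim = np.arange(t[0], t[-1], 1.0 / pacing_rate)
    elif trace.stim_times is not None:
        stim = trace.stim_times
    else:
        raise ValueError("need pacing_rate or stimulation timestamps")
    if stim.size == 0:
        raise ValueError("no stimulation times inside the trace")
    dt = trace.sampling_interval
    period = float(np.median(np.diff(stim))) if stim.size > 1 else float(
        1.0 / pacing_rate if pacing_rate else t[-1] - stim[0]
    )
    if period / dt < 8:
        raise ValueError(
            "pacing interval covers fewer than 8 samples; beat kinetics "
            "are unresolvable at this sampling rate"
        )

    win = min(smooth_window, f.size - 1)
    if win % 2 == 0:
        win -= 1
    win = max(win, smooth_poly + 2 if (smooth_poly + 2) % 2 == 1 else smooth_poly + 3)
    smooth = savgol_filter(f, win, smooth_poly)
    deriv = savgol_filter(f, win, smooth_poly, deriv=1, delta=dt)
    resid = f - smooth
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    floor = capture_k * sigma
    span = float(f.max() - f.min())
    if use_smoothed is None:
        use_smoothed = sigma > 1e-3 * max(span, 1e-12)
    sig = smooth if use_smoothed else f
    # keep the pre-upstroke window clear of the filter's edge undershoot
    guard = (win // 2) * dt if use_smoothed else 0.0

    rows = []
    for i, s in enumerate(stim):
        s_end = stim[i + 1] if i + 1 < stim.size else s + period
        if t[-1] + dt - s < 0.9 * period:
            break  # interval truncated by the end of the trace
        i0, i1 = np.searchsorted(t, [s, s_end])
        if i1 - i0 < 4:
            continue
        seg = sig[i0:i1]
        tseg = t[i0:i1]
        # pre-upstroke window; first beat falls back to its own tail
        p0, p1 = np.searchsorted(t, [s - diastolic_window_frac * period, s - guard])
        if p1 - p0 < 1:
            p0, p1 = np.searchsorted(
                t, [s_end - diastolic_window_frac * period, s_end - guard]
            )
        dia = float(np.min(sig[p0:p1]))
        ipk = int(np.argmax(seg))
        peak = float(seg[ipk])
        amp = peak - dia
        captured = amp > max(floor, 1e-9)
        time_to_peak = float(tseg[ipk] - s)
        # duration above the configured fraction of amplitude
        thr = dia + duration_threshold_frac * amp
        cross = _crossings(tseg, seg, thr)
        duration = float(cross[-1] - cross[0]) if cross.size >= 2 else np.nan
        # relaxation: steepest descent after the peak, normalized by amplitude
        relax = deriv[i0 + ipk : i1]
        rate = float(np.max(-relax) / amp) if (amp > 0 and relax.size) else np.nan
        rows.append(
            dict(
                time=float(s),
                diastolic_force=dia,
                peak_force=peak,
                twitch_amplitude=amp,
                time_to_peak=time_to_peak,
                relaxation_rate=rate,
                contraction_duration=duration,
                captured=bool(captured),
            )
        )
    if not rows:
        raise ValueError("no complete stimulation interval inside the trace")
    return pd.DataFrame(rows)


def conditioning_timecourse(
    beats: pd.DataFrame,
    bin_width: float,
    *,
    exclude_noncaptured: bool = True,
    t0: float | None = None,
) -> pd.DataFrame:
    """Time-binned mean twitch and diastolic force over a conditioning run.

    Medium-change breaks appear as stretches of non-captured (zero-force)
    beats; these are excluded from the bins when ``exclude_noncaptured``
    is set, and bins left empty are reported with ``n_beats == 0`` and NaN
    means.
    """
    if beats.empty:
        raise ValueError("empty beat table")
    if not bin_width > 0:
        raise ValueError("bin width must be positive")
    start = float(beats["time"].min()) if t0 is None else t0
    used = beats[beats["captured"]] if exclude_noncaptured else beats
    n_bins = int(np.floor((beats["time"].max() - start) / bin_width)) + 1
    rows = []
    for b in range(n_bins):
        lo, hi = start + b * bin_width, start + (b + 1) * bin_width
        sel = used[(used["time"] >= lo) & (used["time"] < hi)]
        n_all = int(((beats["time"] >= lo) & (beats["time"] < hi)).sum())
        rows.append(
            dict(
                bin_start=lo,
                bin_end=hi,
                twitch_mean=float(sel["twitch_amplitude"].mean()) if len(sel) else np.nan,
                diastolic_mean=float(sel["diastolic_force"].mean()) if len(sel) else np.nan,
                n_beats=len(sel),
                n_excluded=n_all - len(sel),
            )
        )
    return pd.DataFrame(rows)


def _window_mean(beats, lo, hi, col, name):
    sel = beats[(beats["time"] >= lo) & (beats["time"] < hi) & beats["captured"]]
    if sel.empty:
        raise ValueError(f"no captured beats in {name} window [{lo:g}, {hi:g}) s")
    return float(sel[col].mean())


def stretch_step_response(
    beats: pd.DataFrame,
    event_time: float,
    *,
    pre_window: float = 60.0,
    acute_window: float = 60.0,
    persist_at: float = 86400.0,
    persist_window: float = 3600.0,
) -> dict:
    """Acute and 24 h persistent response to a single distension step.

    Returns ``acute_gain`` (mean post/pre twitch amplitude), the analogous
    ``persistent_gain_24h`` evaluated ``persist_at`` seconds after the
    event, and ``diastolic_jump`` (difference of window-mean diastolic
    forces across the event).
    """
    pre_amp = _window_mean(
        beats, event_time - pre_window, event_time, "twitch_amplitude", "pre"
    )
    post_amp = _window_mean(
        beats, event_time, event_time + acute_window, "twitch_amplitude", "acute post"
    )
    per_amp = _window_mean(
        beats,
        event_time + persist_at,
        event_time + persist_at + persist_window,
        "twitch_amplitude",
        "24 h persistence",
    )
    pre_dia = _window_mean(
        beats, event_time - pre_window, event_time, "diastolic_force", "pre"
    )
    post_dia = _window_mean(
        beats, event_time, event_time + acute_window, "diastolic_force", "acute post"
    )
    return dict(
        acute_gain=post_amp / pre_amp,
        persistent_gain_24h=per_amp / pre_amp,
        diastolic_jump=post_dia - pre_dia,
    )


def hypoxia_residual(
    beats: pd.DataFrame,
    cessation_start: float,
    duration: float = 120.0,
    *,
    n_ref: int = 3,
) -> float:
    """Residual twitch force (%) after a medium-agitation cessation.

    100 x (mean amplitude of the last ``n_ref`` beats inside the
    cessation window) / (mean amplitude of the ``n_ref`` beats immediately
    before cessation).
    """
    end = cessation_start + duration
    last_beat = float(beats["time"].max())
    if end > last_beat + 1.0:
        raise ValueError("cessation window extends past the end of the trace")
    ref = beats[(beats["time"] < cessation_start) & beats["captured"]].tail(n_ref)
    fin = beats[
        (beats["time"] >= cessation_start) & (beats["time"] < end) & beats["captured"]
    ].tail(n_ref)
    if len(ref) < n_ref or len(fin) < n_ref:
        raise ValueError(f"need at least {n_ref} captured beats before and inside the window")
    return 100.0 * float(fin["twitch_amplitude"].mean()) / float(
        ref["twitch_amplitude"].mean()
    )


def stimulation_threshold(response_table) -> float:
    """Capture threshold (mA) from (current, captured) pairs.

    With a monotone capture pattern the threshold is the smallest tested
    current that captured.  Non-monotone tables are flagged with a warning
    and resolved as the midpoint of the ambiguous range (between the first
    capturing current and the last non-capturing one).
    """
    if isinstance(response_table, dict):
        pairs = sorted(response_table.items())
    else:
        pairs = sorted((float(c), bool(r)) for c, r in response_table)
    currents = np.array([p[0] for p in pairs])
    captured = np.array([bool(p[1]) for p in pairs])
    if captured.all() or not captured.any():
        raise ValueError("threshold outside tested range")
    first_yes = currents[captured][0]
    last_no = currents[~captured][-1]
    if first_yes > last_no:
        return float(first_yes)
    warnings.warn(
        "non-monotone capture pattern; threshold resolved as midpoint of "
        f"the ambiguous range [{first_yes:g}, {last_no:g}] mA",
        stacklevel=2,
    )
    return float((first_yes + last_no) / 2.0)
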