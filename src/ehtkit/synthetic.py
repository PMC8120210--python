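"""Seeded synthetic-data generators with exact ground truth.

These generators emulate the statistical structure of the three data
modalities the analysis stages consume:

* paced twitch-force recordings with stretch steps, baseline drift and a
  hypoxia (agitation-cessation) window,
* parametric Ca2+ transients and action-potential trains,
* three-channel confocal tissue scans (DAPI / WGA / alpha-actinin) of
  elongated striated cells in an orientation field with controllable
  dispersion.

Every generator draws all randomness from a single integer seed through
an explicit ``numpy.random.Generator`` and returns, next to the rendered
data, a ground-truth table (one row per entity-parameter) holding exactly
the values used during rendering.  Identical seeds and parameters yield
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .force_trace import ForceTrace
from .ephys import FluorescenceTrace, VoltageTrace

__all__ = [
    "StretchEvent",
    "HypoxiaWindow",
    "TraceParams",
    "CaParams",
    "APParams",
    "ImageParams",
    "generate_force_trace",
    "generate_ca_transient",
    "generate_action_potential",
    "generate_tissue_image",
    "amplitude_gain",
    "diastolic_baseline",
]


def _gt(rows):
    return pd.DataFrame(rows, columns=["entity", "parameter", "value", "units"])


# ---------------------------------------------------------------------------
# force traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StretchEvent:
    """A single distension step.

    The twitch amplitude is multiplied by ``step_gain`` at ``time`` and
    relaxes exponentially (constant ``relaxation_tau``) toward a plateau
    retaining ``persist_frac`` of the step; the diastolic force receives
    ``diastolic_jump`` mN relaxing the same way.
    """

    time: float
    step_gain: float = 1.0
    diastolic_jump: float = 0.0
    relaxation_tau: float = 3600.0
    persist_frac: float = 0.5


@dataclass(frozen=True)
class HypoxiaWindow:
    """Medium-agitation cessation: amplitudes decline as exp(-t/decline_tau)."""

    start: float
    duration: float = 120.0
    decline_tau: float = 300.0


@dataclass
class TraceParams:
    """Parameters of a synthetic paced force recording."""

    sampling_interval: float = 0.002  # s
    duration: float = 60.0  # s
    pacing_rate: float = 1.0  # Hz
    twitch_amplitude: float = 2.0  # mN
    diastolic_force: float = 0.5  # mN
    rise_tau: float = 0.04  # s
    decay_tau: float = 0.12  # s
    noise_sd: float = 0.0  # mN
    drift_rate: float = 0.0  # mN/hour
    stretch_events: tuple = ()
    hypoxia_window: HypoxiaWindow | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be positive")
        if not self.pacing_rate > 0:
            raise ValueError("pacing_rate must be positive")
        if self.twitch_amplitude < 0:
            raise ValueError("twitch_amplitude must be non-negative")
        if not self.decay_tau > 0 or not self.rise_tau > 0:
            raise ValueError("kinetic time constants must be positive")


def _alpha_pulse(rise_tau, decay_tau, cut_frac=0.01):
    """Compactified alpha-function pulse.

    The raw shape (1 - exp(-t/rise)) * exp(-t/decay) is shifted and
    rescaled so the maximum is exactly 1 and the pulse is identically zero
    beyond the point where the raw shape falls to ``cut_frac`` of its
    peak.  Returns (shape function, support duration, time of peak).
    """
    t_peak = rise_tau * np.log1p(decay_tau / rise_tau)
    peak = (1 - np.exp(-t_peak / rise_tau)) * np.exp(-t_peak / decay_tau)

    def raw(x):
        return (1 - np.exp(-x / rise_tau)) * np.exp(-x / decay_tau)

    hi = t_peak + decay_tau * (np.log(1.0 / cut_frac) + 5.0)
    support = brentq(lambda x: raw(x) - cut_frac * peak, t_peak, hi)

    def shape(x):
        return np.clip(raw(x) - cut_frac * peak, 0.0, None) / (peak * (1 - cut_frac))

    return shape, support, t_peak


def amplitude_gain(params: TraceParams, times):
    """Multiplicative twitch-amplitude modulation at the given times.

    Combines all stretch-event gains (with their exponential relaxation
    toward the persistent plateau) and the hypoxia decline.  This is the
    exact model the renderer evaluates at each stimulation time, exposed
    so tests and analyses can evaluate the generator truth at any time.
    """
    t = np.asarray(times, dtype=float)
    g = np.ones_like(t)
    for ev in params.stretch_events:
        m = t >= ev.time
        rel = np.exp(-(t[m] - ev.time) / ev.relaxation_tau)
        g[m] *= 1.0 + (ev.step_gain - 1.0) * (
            ev.persist_frac + (1.0 - ev.persist_frac) * rel
        )
    hw = params.hypoxia_window
    if hw is not None:
        m = (t >= hw.start) & (t < hw.start + hw.duration)
        g[m] *= np.exp(-(t[m] - hw.start) / hw.decline_tau)
    return g


def diastolic_baseline(params: TraceParams, times):
    """Diastolic force (mN) at the given times: base + drift + step jumps."""
    t = np.asarray(times, dtype=float)
    base = params.diastolic_force + params.drift_rate * t / 3600.0
    for ev in params.stretch_events:
        m = t >= ev.time
        rel = np.exp(-(t[m] - ev.time) / ev.relaxation_tau)
        base[m] += ev.diastolic_jump * (
            ev.persist_frac + (1.0 - ev.persist_frac) * rel
        )
    return base


def generate_force_trace(params: TraceParams):
    """Render a paced force trace; returns (ForceTrace, ground truth).

    The trace is the diastolic baseline (with drift and step jumps) plus
    one twitch pulse per pacing interval whose height equals the
    configured amplitude times the modulation at its stimulation time;
    Gaussian noise is added last.
    """
    dt = params.sampling_interval
    n = int(round(params.duration / dt))
    t = np.arange(n) * dt
    period = 1.0 / params.pacing_rate
    shape, support, _ = _alpha_pulse(params.rise_tau, params.decay_tau)
    if support > period:
        raise ValueError(
            f"pacing interval ({period:g} s) is shorter than the twitch pulse "
            f"support ({support:.3g} s); slow the pacing or speed up kinetics"
        )
    stim = np.arange(0.0, params.duration - 1e-12, period)
    force = diastolic_baseline(params, t)
    gains = amplitude_gain(params, stim)
    n_sup = int(np.ceil(support / dt)) + 1
    for s, g in zip(stim, gains):
        i0 = int(np.searchsorted(t, s))
        i1 = min(i0 + n_sup, n)
        if i1 <= i0:
            continue
        force[i0:i1] += params.twitch_amplitude * g * shape(t[i0:i1] - s)
    rng = np.random.default_rng(params.rng_seed)
    if params.noise_sd > 0:
        force = force + rng.normal(0.0, params.noise_sd, n)
    trace = ForceTrace(t, force, stim_times=stim, meta={"params": params})

    rows = [
        ("trace", "twitch_amplitude", params.twitch_amplitude, "mN"),
        ("trace", "diastolic_force", params.diastolic_force, "mN"),
        ("trace", "rise_tau", params.rise_tau, "s"),
        ("trace", "decay_tau", params.decay_tau, "s"),
        ("trace", "pacing_rate", params.pacing_rate, "Hz"),
        ("trace", "drift_rate", params.drift_rate, "mN/hour"),
        ("trace", "n_beats", float(stim.size), "count"),
    ]
    for k, ev in enumerate(params.stretch_events):
        rows += [
            (f"stretch_{k}", "time", ev.time, "s"),
            (f"stretch_{k}", "step_gain", ev.step_gain, ""),
            (f"stretch_{k}", "diastolic_jump", ev.diastolic_jump, "mN"),
            (f"stretch_{k}", "relaxation_tau", ev.relaxation_tau, "s"),
            (f"stretch_{k}", "persist_frac", ev.persist_frac, ""),
        ]
    hw = params.hypoxia_window
    if hw is not None:
        rows += [
            ("hypoxia", "start", hw.start, "s"),
            ("hypoxia", "duration", hw.duration, "s"),
            ("hypoxia", "decline_tau", hw.decline_tau, "s"),
            (
                "hypoxia",
                "residual_percent",
                100.0 * float(np.exp(-hw.duration / hw.decline_tau)),
                "%",
            ),
        ]
    return trace, _gt(rows)


# ---------------------------------------------------------------------------
# Ca2+ transients
# ---------------------------------------------------------------------------


@dataclass
class CaParams:
    """Parameters of a synthetic Ca2+ fluorescence transient train."""

    f0: float = 100.0  # baseline fluorescence, a.u.
    amplitude: float = 1.5  # dF/F0
    tau: float = 0.3  # s, monoexponential decay constant
    rise_time: float = 0.05  # s, upstroke duration
    rate: float = 0.4  # Hz
    duration: float = 12.5  # s
    sampling_interval: float = 0.002  # s
    noise_sd: float = 0.0  # a.u.
    cut_frac: float = 2e-3  # decay truncated below this fraction of amplitude
    rng_seed: int = 0

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if not self.f0 > 0:
            raise ValueError("baseline fluorescence F0 must be positive")
        if not self.rise_time > 0 or self.rise_time >= 1.0 / self.rate:
            raise ValueError("rise_time must be positive and shorter than the period")


def generate_ca_transient(params: CaParams):
    """Render a Ca2+ transient train; returns (FluorescenceTrace, truth).

    Each transient rises as F0 * (1 + a * sin^2) to its exact peak
    F0 * (1 + a) over ``rise_time`` and then decays exactly
    monoexponentially with constant ``tau`` (truncated once it falls below
    ``cut_frac`` of the amplitude, so the pre-upstroke baseline of the
    following transient is clean).
    """
    dt = params.sampling_interval
    n = int(round(params.duration / dt))
    t = np.arange(n) * dt
    period = 1.0 / params.rate
    stim = np.arange(period, params.duration - 1e-12, period)
    F = np.full(n, params.f0)
    a = params.amplitude
    for s in stim:
        rel = t - s
        up = (rel >= 0) & (rel < params.rise_time)
        F[up] += params.f0 * a * np.sin(np.pi * rel[up] / (2 * params.rise_time)) ** 2
        down = (rel >= params.rise_time) & (rel < period)
        dec = np.exp(-(rel[down] - params.rise_time) / params.tau)
        dec[dec < params.cut_frac] = 0.0
        F[down] += params.f0 * a * dec
    rng = np.random.default_rng(params.rng_seed)
    if params.noise_sd > 0:
        F = F + rng.normal(0.0, params.noise_sd, n)
    trace = FluorescenceTrace(t, F, meta={"params": params})
    gt = _gt(
        [
            ("ca", "f0", params.f0, "a.u."),
            ("ca", "amplitude", a, "dF/F0"),
            ("ca", "tau", params.tau, "s"),
            ("ca", "rise_time", params.rise_time, "s"),
            ("ca", "rate", params.rate, "Hz"),
            ("ca", "n_transients", float(stim.size), "count"),
        ]
    )
    return trace, gt


# ---------------------------------------------------------------------------
# action potentials
# ---------------------------------------------------------------------------


@dataclass
class APParams:
    """Parameters of a synthetic action-potential train."""

    rmp: float = -70.0  # mV, resting membrane potential
    amplitude: float = 100.0  # mV
    upstroke_velocity: float = 10.0  # V/s
    apd90: float = 0.3  # s, from upstroke onset to 90% repolarization
    rate: float = 1.0  # Hz
    duration: float = 10.0  # s
    sampling_interval: float = 0.001  # s
    plateau_power: float = 3.0  # stretched-exponential repolarization shape
    noise_sd: float = 0.0  # mV
    rng_seed: int = 0

    def __post_init__(self):
        if not self.amplitude > 0:
            raise ValueError("amplitude must be positive")
        if not self.upstroke_velocity > 0:
            raise ValueError("upstroke_velocity must be positive")
        if self.apd90 >= 1.0 / self.rate:
            raise ValueError("apd90 must be shorter than the pacing interval")
        t_up = self.amplitude / (self.upstroke_velocity * 1000.0)
        if t_up >= self.apd90:
            raise ValueError("upstroke outlasts apd90; increase upstroke_velocity")


def generate_action_potential(params: APParams):
    """Render an AP train; returns (VoltageTrace, ground truth).

    Each AP is a linear upstroke with slope ``upstroke_velocity`` from the
    resting potential to its peak, followed by a plateau-then-fall
    stretched-exponential repolarization solved so that the trace crosses
    90% repolarization exactly ``apd90`` after upstroke onset.  Residuals
    below 1e-9 of the amplitude are clamped to zero so the diastolic
    minimum equals the resting potential exactly.
    """
    dt = params.sampling_interval
    n = int(round(params.duration / dt))
    t = np.arange(n) * dt
    period = 1.0 / params.rate
    stim = np.arange(period, params.duration - 1e-12, period)
    slope = params.upstroke_velocity * 1000.0  # mV/s
    t_up = params.amplitude / slope
    p = params.plateau_power
    theta = (params.apd90 - t_up) / np.log(10.0) ** (1.0 / p)
    V = np.full(n, params.rmp)
    for s in stim:
        rel = t - s
        up = (rel >= 0) & (rel < t_up)
        V[up] += slope * rel[up]
        down = (rel >= t_up) & (rel < period)
        g = np.exp(-(((rel[down] - t_up) / theta) ** p))
        g[g < 1e-9] = 0.0
        V[down] += params.amplitude * g
    rng = np.random.default_rng(params.rng_seed)
    if params.noise_sd > 0:
        V = V + rng.normal(0.0, params.noise_sd, n)
    trace = VoltageTrace(t, V, meta={"params": params})
    gt = _gt(
        [
            ("ap", "rmp", params.rmp, "mV"),
            ("ap", "amplitude", params.amplitude, "mV"),
            ("ap", "peak", params.rmp + params.amplitude, "mV"),
            ("ap", "upstroke_velocity", params.upstroke_velocity, "V/s"),
            ("ap", "apd90", params.apd90, "s"),
            ("ap", "rate", params.rate, "Hz"),
            ("ap", "n_aps", float(stim.size), "count"),
        ]
    )
    return trace, gt


# ---------------------------------------------------------------------------
# tissue images
# ---------------------------------------------------------------------------


@dataclass
class ImageParams:
    """Parameters of a synthetic 3-channel confocal tissue scan.

    Cells are elongated ellipses placed without overlap on a jittered
    anisotropic (brick) lattice aligned with ``orientation_mean``; each
    cell's own axis deviates by an axially wrapped normal of SD
    ``orientation_sd``.  The WGA channel renders membranes (cell
    outlines), DAPI one nucleus per cell, and alpha-actinin sinusoidal
    striations of period ``sarcomere_period`` perpendicular to the cell
    axis, in myocyte cells only.
    """

    canvas_size: tuple[int, int] = (512, 512)  # pixels (rows, cols)
    pixel_size: float = 0.1  # um/px
    n_cells: int | None = None  # None: fill the lattice
    mean_cell_length: float = 12.0  # um
    mean_cell_width: float = 6.0  # um
    cell_size_cv: float = 0.1  # fractional SD of length/width
    orientation_mean: float = 0.0  # degrees, axial
    orientation_sd: float = 10.0  # degrees
    myocyte_fraction: float = 0.69
    sarcomere_period: float = 2.19  # um
    nucleus_area_mean: float = 25.0  # um^2
    membrane_thickness: float = 0.5  # um
    background_level: float = 10.0  # intensity units
    dapi_amplitude: float = 150.0
    wga_amplitude: float = 120.0
    actinin_amplitude: float = 100.0
    blur_sd: float = 0.15  # um
    noise_sd: float = 0.0  # intensity units
    rng_seed: int = 0

    def __post_init__(self):
        if isinstance(self.canvas_size, int):
            self.canvas_size = (self.canvas_size, self.canvas_size)
        if not (0.0 <= self.myocyte_fraction <= 1.0):
            raise ValueError("myocyte_fraction must lie in [0, 1]")
        if not self.sarcomere_period > 0:
            raise ValueError("sarcomere_period must be positive")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        max_dim = max(self.canvas_size) * self.pixel_size
        if self.mean_cell_length * 1.5 > max_dim:
            raise ValueError("cells do not fit the canvas")


def _ellipse_mask(h, w, cy, cx, a_px, b_px, theta_rad, margin=0.0):
    """Boolean ellipse inside a bounding box; returns (mask, r0, c0)."""
    ext = int(np.ceil(max(a_px, b_px) + margin)) + 2
    r0, r1 = int(np.floor(cy)) - ext, int(np.floor(cy)) + ext + 1
    c0, c1 = int(np.floor(cx)) - ext, int(np.floor(cx)) + ext + 1
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        return None, 0, 0
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx = cc - cx
    dy = rr - cy
    ca, sa = np.cos(theta_rad), np.sin(theta_rad)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    mask = (u / (a_px + margin)) ** 2 + (v / (b_px + margin)) ** 2 <= 1.0
    return mask, r0, c0


def generate_tissue_image(params: ImageParams):
    """Render a synthetic tissue scan.

    Returns ``(channels, labels, ground_truth)`` where ``channels`` is a
    float32 array of shape (3, H, W) ordered (dapi, wga, actinin),
    ``labels`` the int32 ground-truth cell label map (0 = background, one
    positive label per cell covering exactly its rendered pixels), and
    ``ground_truth`` a per-entity table of every rendered parameter.
    """
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.canvas_size
    px = params.pixel_size
    theta_m = np.deg2rad(params.orientation_mean)
    u_dir = np.array([np.cos(theta_m), np.sin(theta_m)])  # (x, y) = (col, row)
    v_dir = np.array([-np.sin(theta_m), np.cos(theta_m)])
    su = params.mean_cell_length * 1.3 / px  # lattice spacing along the fiber axis, px
    sv = params.mean_cell_width * 1.5 / px
    cx0, cy0 = (w - 1) / 2.0, (h - 1) / 2.0
    reach = int(np.ceil(np.hypot(h, w) / 2.0))
    ni = int(np.ceil(reach / su)) + 1
    nj = int(np.ceil(reach / sv)) + 1
    sites = []
    for j in range(-nj, nj + 1):
        for i in range(-ni, ni + 1):
            off = (i + 0.5 * (j % 2)) * su
            x = cx0 + off * u_dir[0] + j * sv * v_dir[0]
            y = cy0 + off * u_dir[1] + j * sv * v_dir[1]
            sites.append((y, x))
    sites = np.array(sites)
    rng.shuffle(sites)

    labels = np.zeros((h, w), dtype=np.int32)
    dapi = np.zeros((h, w), dtype=np.float64)
    wga = np.zeros((h, w), dtype=np.float64)
    actinin = np.zeros((h, w), dtype=np.float64)
    mem_px = max(params.membrane_thickness / px, 1.0)
    records = []
    target = params.n_cells
    cid = 0
    for sy, sx in sites:
        if target is not None and cid >= target:
            break
        placed = False
        for _ in range(8):
            L = float(
                np.clip(
                    rng.normal(params.mean_cell_length, params.cell_size_cv * params.mean_cell_length),
                    0.5 * params.mean_cell_length,
                    1.5 * params.mean_cell_length,
                )
            )
            Wd = float(
                np.clip(
                    rng.normal(params.mean_cell_width, params.cell_size_cv * params.mean_cell_width),
                    0.5 * params.mean_cell_width,
                    min(1.5 * params.mean_cell_width, L),
                )
            )
            theta = float((params.orientation_mean + rng.normal(0.0, params.orientation_sd)) % 180.0)
            jy = rng.uniform(-0.08, 0.08) * sv
            jx = rng.uniform(-0.08, 0.08) * su
            cy = sy + jy * v_dir[1] + jx * u_dir[1]
            cx = sx + jy * v_dir[0] + jx * u_dir[0]
            a_px, b_px = L / 2.0 / px, Wd / 2.0 / px
            th = np.deg2rad(theta)
            margin = 1.0
            ext = int(np.ceil(max(a_px, b_px) + margin)) + 2
            r0, r1 = int(np.floor(cy)) - ext, int(np.floor(cy)) + ext + 1
            c0, c1 = int(np.floor(cx)) - ext, int(np.floor(cx)) + ext + 1
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                break  # site too close to the border; next site
            rr, cc = np.mgrid[r0:r1, c0:c1]
            ca, sa = np.cos(th), np.sin(th)
            uu = (cc - cx) * ca + (rr - cy) * sa
            vv = -(cc - cx) * sa + (rr - cy) * ca
            big = (uu / (a_px + margin)) ** 2 + (vv / (b_px + margin)) ** 2 <= 1.0
            sub = labels[r0:r1, c0:c1]
            if np.any(sub[big] > 0):
                continue  # overlap; retry with fresh jitter/size
            mask = (uu / a_px) ** 2 + (vv / b_px) ** 2 <= 1.0
            ai, bi = max(a_px - mem_px, 0.5), max(b_px - mem_px, 0.5)
            inner = (uu / ai) ** 2 + (vv / bi) ** 2 <= 1.0
            cid += 1
            sub[mask] = cid
            wsub = wga[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
            wsub[mask & ~inner] = params.wga_amplitude
            is_myocyte = bool(rng.random() < params.myocyte_fraction)
            if is_myocyte:
                phase = rng.uniform(0.0, 2 * np.pi)
                stripes = 0.5 + 0.5 * np.cos(
                    2 * np.pi * uu * px / params.sarcomere_period + phase
                )
                asub = actinin[r0:r1, c0:c1]
                asub[inner] = params.actinin_amplitude * stripes[inner]
            # nucleus: 2:1 ellipse along the cell axis, area >= mean/2
            n_area = float(
                np.clip(
                    rng.normal(params.nucleus_area_mean, 0.15 * params.nucleus_area_mean),
                    params.nucleus_area_mean / 2.0,
                    1.5 * params.nucleus_area_mean,
                )
            )
            bn = np.sqrt(n_area / (2 * np.pi)) / px
            nmask, nr0, nc0 = _ellipse_mask(h, w, cy, cx, 2 * bn, bn, th)
            nucleus_px = 0
            if nmask is not None:
                dsub = dapi[nr0 : nr0 + nmask.shape[0], nc0 : nc0 + nmask.shape[1]]
                dsub[nmask] = params.dapi_amplitude
                nucleus_px = int(nmask.sum())
            records.append(
                dict(
                    cell_id=cid,
                    orientation_deg=theta,
                    length_um=L,
                    width_um=Wd,
                    area_um2=float(mask.sum()) * px * px,
                    nucleus_area_um2=nucleus_px * px * px,
                    is_myocyte=is_myocyte,
                    sarcomere_period_um=params.sarcomere_period if is_myocyte else np.nan,
                    center_row=float(cy),
                    center_col=float(cx),
                )
            )
            placed = True
            break
        if not placed:
            continue
    if target is not None and cid < target:
        raise ValueError(
            f"could only place {cid} of {target} requested cells: the "
            "jittered lattice is exhausted (canvas too small for the "
            "requested cell count at this cell size)"
        )
    if cid == 0:
        raise ValueError("no cells could be placed on the canvas")

    coverage = float((actinin > 0.5 * params.actinin_amplitude).mean())
    blur_px = params.blur_sd / px
    channels = np.stack([dapi, wga, actinin])
    if blur_px > 0:
        channels = np.stack([gaussian_filter(c, blur_px) for c in channels])
    channels += params.background_level
    if params.noise_sd > 0:
        channels = channels + rng.normal(0.0, params.noise_sd, channels.shape)
    channels = channels.astype(np.float32)

    cells = pd.DataFrame(records)
    rows = []
    for rec in records:
        e = f"cell_{rec['cell_id']}"
        for key, unit in [
            ("orientation_deg", "deg"),
            ("length_um", "um"),
            ("width_um", "um"),
            ("area_um2", "um^2"),
            ("nucleus_area_um2", "um^2"),
            ("is_myocyte", "bool"),
            ("sarcomere_period_um", "um"),
        ]:
            rows.append((e, key, float(rec[key]), unit))
    rows += [
        ("image", "n_cells", float(cid), "count"),
        ("image", "myocyte_fraction_realized", float(cells["is_myocyte"].mean()), ""),
        ("image", "actinin_coverage", coverage, "fraction"),
        ("image", "orientation_mean", params.orientation_mean, "deg"),
        ("image", "orientation_sd", params.orientation_sd, "deg"),
        ("image", "sarcomere_period", params.sarcomere_period, "um"),
        ("image", "pixel_size", px, "um"),
    ]
    gt = _gt(rows)
    gt.attrs["cells"] = cells
    return channels, labels, gt
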