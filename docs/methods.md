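# Methods

This note documents the models behind `ehtkit`'s synthetic generators,
the estimator definitions used by the analyzers, the numerical choices,
and what the round-trip validation does and does not establish.

## Synthetic force traces

A paced recording is modelled as a diastolic baseline plus one twitch
pulse per stimulation interval plus additive Gaussian noise. The pulse
family is a two-parameter α-function,
`f(t) ∝ (1 − e^(−t/τ_rise)) · e^(−t/τ_decay)`, rescaled so its maximum
equals the configured amplitude. The raw α-function never reaches zero,
so it is *compactified*: shifted and rescaled to be identically zero
beyond the point where it falls to 1 % of its peak. This keeps the
pre-upstroke window of every beat free of the previous beat's tail, so
noiseless round trips through the beat detector are exact to sample
quantization. Pacing faster than the pulse support is rejected.
Defaults: 2 ms sampling, 1 Hz pacing, τ_rise 40 ms, τ_decay 120 ms,
2 mN twitch over 0.5 mN diastolic — magnitudes matching the
conditioned-tissue range of the study system.

Stretch steps multiply subsequent twitch amplitudes by `step_gain` and
add a diastolic jump; both relax exponentially (`relaxation_tau`)
toward a plateau retaining `persist_frac` (default 0.5) of the step.
The study system reports only that acute enhancements "partially
persist" over 24 h, so the plateau fraction is an explicit free
parameter. A hypoxia (agitation-cessation) window multiplies amplitudes
by `e^(−Δt/τ_decline)`; the presets solve τ_decline analytically from
the group endpoint residuals (77.6 % for S0, 64 % for S3 at 120 s).
Amplitude modulation is evaluated at each stimulation time and exposed
as `amplitude_gain` so tests can query the generator truth at any time.

## Synthetic Ca²⁺ transients and action potentials

Ca²⁺ transients rise as `F₀(1 + a·sin²)` to an exact peak `F₀(1 + a)`
over `rise_time`, then decay *exactly* monoexponentially with constant
τ (truncated below 2·10⁻³ of the amplitude so the next baseline window
is clean). This guarantees the decay-fit oracle (log-linear regression)
is exact on noiseless data.

Action potentials are a linear upstroke at the configured dV/dt from
the resting potential to peak, followed by a stretched-exponential
repolarization `g(t) = e^(−(t/θ)^p)` (plateau exponent p = 3). θ is
solved so the trace crosses 90 % repolarization exactly `apd90` after
upstroke onset; residuals below 10⁻⁹ are clamped so the diastolic
minimum equals the resting potential exactly. The zero-slope plateau at
the peak makes the sampled maximum insensitive to grid placement. AP
trains are sampled at 1 ms; upstrokes of ~7 ms therefore span several
samples and the central-difference max dV/dt reproduces the configured
slope exactly on noiseless data.

## Synthetic tissue scans

Cells are elongated ellipses placed without overlap on a jittered
anisotropic brick lattice aligned with the mean fiber direction; this
is deliberately a *statistical* stand-in for tissue, not a physical
packing simulation — it provides controlled orientation fields,
membrane-bounded segments and striations, which is what the
segmentation and statistics stages consume. Per-cell axes deviate from
the mean by an axially wrapped normal (`orientation_sd`), drawn on
doubled angles because cell axes are 180°-periodic. Channels: WGA =
membrane rings at the configured thickness; DAPI = one 2:1 nuclear
ellipse per cell with area clipped to ≥ half the mean; α-actinin =
sinusoidal stripes of the configured sarcomere period, perpendicular to
the cell axis, rendered only in cells drawn as myocytes
(Bernoulli(`myocyte_fraction`), default 0.69 matching the
double-positive fraction of the differentiation protocol). Gaussian
blur (0.15 µm) and optional noise are applied last; the label map and
ground-truth table describe the rendered geometry exactly. Defaults use
0.1 µm pixels; cell sizes (12 × 6 µm) are kept modest so that a few
hundred cells fit test-sized canvases — the pipeline itself is
size-agnostic.

What the generator does *not* emulate: optics (no PSF), 3D sectioning,
intensity calibration, irregular cell shapes, touching membranes shared
between neighbors, and non-myocyte nuclei. Passing round trips
therefore demonstrate correctness of the estimators under the stated
model, not segmentation performance on real confocal data.

## Estimator definitions and numerical choices

* **Beat detection.** Diastolic force = minimum in the pre-upstroke
  window (last 20 % of the pacing interval; the first beat falls back
  to its own tail). Extremes are read from the raw samples when the
  robust noise floor (4·MAD of the Savitzky–Golay residual) is
  negligible, otherwise from the smoothed signal (window 21, order 3);
  the window preceding each stimulus is kept clear of the filter's
  half-window to avoid its edge undershoot. Derivatives always come
  from the smoothed signal. Contraction duration = time above 10 % of
  amplitude; relative relaxation rate = max |dF/dt| during relaxation ÷
  amplitude (1/s). Beats below the noise floor are non-captured,
  supporting all-or-nothing threshold analysis; non-monotone capture
  tables resolve to the midpoint of the ambiguous range with a warning.
* **Hypoxia residual** compares the mean of the last n_ref = 3 captured
  in-window beats against the 3 beats before cessation. Under an
  exponential decline this sits a few tenths of a percentage point
  above the instantaneous 120 s endpoint (beats average over the final
  seconds); the presets are calibrated to the endpoint, not to the
  estimator.
* **Biomechanics.** Systolic force = diastolic + twitch (peak total).
  The systolic/diastolic ratio is evaluated at optimum preload, with a
  floor (1 % of max systolic) below which it is undefined rather than
  near-infinite. The modulus is the least-squares slope of diastolic
  stress vs engineering strain over points up to the optimum length
  (window configurable; chord mode available); stress uses the
  α-actinin⁺ cross-section by default with a whole-tissue option. FFR
  classification uses the sign of the fitted slope of normalized force
  vs rate with a ±0.02 fold/Hz flat band.
* **Ca²⁺/AP features.** F₀ and resting potential are means over the
  pre-upstroke 20 % window; onsets at 10 % of amplitude; crossings
  linearly interpolated. τ is fitted by nonlinear least squares seeded
  from a log-linear fit (window peak → 10 % above baseline; a 50 % → 10 %
  option exists); non-decaying transients yield NaN. Ca amplitudes are
  ΔF/F₀. Durations are reported at both 50 % and 90 % return.
* **Morphometry.** DAPI threshold is Otsu ("histogram-based"); closing
  disk radius 0.3 µm; nuclei < 5 µm² removed (bound inclusive). The
  watershed floods the raw WGA intensity (membranes are ridges), with a
  gradient-magnitude option; the foreground mask is hole-filled,
  closed, thresholded WGA support plus nuclei. The actinin threshold is
  histogram mode (1-unit bins) + 1 whole-image SD (background-window SD
  optional). Myocyte filters are inclusive at 0.07 / 5 µm². Geometry
  comes from PCA of pixel coordinates; orientations are axial in
  [0, 180); near-isotropic cells are flagged. Neighbor adjacency is
  4-connected label contact; `analyze_tissue` expands labels by 2.5 µm
  to bridge membrane-scale background gaps before building the graph.
  Dispersion is the sample SD (ddof = 1, flag available) of
  doubled-angle circular deviations over {self} ∪ 1st ∪ 2nd-degree
  neighbors, requiring ≥ 3 members. Sarcomere periods come from
  overlap-normalized autocorrelations of ≥ 5 parallel profiles along
  the principal axis, peak within 1.2–3.0 µm, parabolic sub-pixel
  refinement, with a prominence gate (0.1) as the "clear striations"
  criterion; cells shorter than 3 maximal periods are missing with a
  reason. The overlap normalization matters: the unnormalized
  autocorrelation's taper biases periods low by ~1 %.
* **Summaries.** The maturation score is the ratio of arithmetic
  set-mean abundances (geometric option), with a pseudocount fallback
  for zero denominators; the adult-specific gene list is user input.
  Group aggregation reports mean, SD, SEM = SD/√n and fold vs S0.

## Validation scale

Round-trip suites run on desk-scale problems: 10 s AP/Ca trains,
30–450 s force traces, and tissue tiles of 0.6–3.3 · 10⁴ µm²
(768²–1792² px), containing ~30–200 cells — two orders of magnitude
below the 1–3 mm² stitched scans of a full experiment but large enough
for every statistic tested (binomial errors on myocyte fractions,
≥ 200-cell dispersion fields). All tolerances used in tests are stated
inline: 1 % for deterministic trace round trips, 1 percentage point for
hypoxia residuals, 0.05 µm for sarcomere length, 15 % for dispersion
recovery, mean Jaccard ≥ 0.9 for segmentation overlap.

## Known limitations

* The watershed's segment extents include the blurred membrane halo, so
  recovered cell lengths run ~3–4 % above the rendered ellipse axes.
* The dispersion statistic's doubled-angle SD is a consistent but not
  unbiased estimator for small neighbor sets; fields with SD ≫ 30°
  approach the axial uniform limit where recovery degrades.
* Sarcomere gating assumes stripes perpendicular to the principal axis;
  strongly curved or branched myocytes (present in real tissue) are out
  of the generator's vocabulary and would need profile re-sampling
  along curved centerlines.
* Upstream expression normalization (TMM) is accepted as given; the
  maturation score does not re-normalize.
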