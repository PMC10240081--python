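# Methods

This note documents the models, estimators, defaults and numerical choices
behind `cardiomap`, and what the synthetic recordings do and do not show
about real data.

## Geometry and coordinates

Dishes are circular (default 35 mm) or rectangular strips on a
`grid_rows x grid_cols` camera grid. Coordinates are 0-based `(row, col)`
with the origin top-left; all physical distances are computed between pixel
centers, in mm, via `pixel_pitch_mm`. The default calibration, 0.2
mm/superpixel on a 180x180 grid, makes a 35 mm dish span ~175 of the 180
superpixels of that sensor mode; it is configurable because the true
magnification of any given rig varies. A pixel belongs to the dish mask iff
its center lies strictly inside the footprint.

## Kinematic wave ground truth

`simulate_planar_wave` assigns every masked pixel the activation time

    t_act(p) = t_beat + d(p) / v

where `d` is the projection onto the propagation axis (planar waves) or the
Euclidean distance from the stimulation site (target waves) and `v` is the
wave speed. This is exact by construction — the `WaveTruth` field is the
reference against which the analysis chain is validated. Stimulation
defaults to the dish edge on the central row, propagating toward the dish
center, with beats at `k / pacing_hz`. Drug effects on speed rescale the
per-beat activation delays by exactly `1/s`, so the modified truth stays
exact.

## Transient template and rendering

The transient waveform is unit-amplitude with a raised-cosine upstroke of
duration `rise_ms` and an exponential decay `tau_ms` tapered smoothly to
zero at `end_ms` after the peak. Two alignment choices matter:

* **The 50% point of the upstroke sits at t = 0.** The rendered movie's
  50%-rise time therefore equals the ground-truth activation time exactly,
  making truth and measurement directly comparable without waveform-specific
  offsets.
* **Finite duration.** A pure exponential never returns to baseline, which
  would make the diastolic level — and hence measured amplitude — depend on
  pacing rate everywhere. The taper gives the calcium transient a realistic
  total duration of ~435 ms (rise 30, tau 200, end 405, taper 120), so at
  2 Hz pacing the diastole genuinely reaches baseline, while at 3 Hz
  transients overlap (a warning is emitted) exactly as real calcium
  transients do at fast rates. The action-potential template uses rise 5 ms,
  tau 150 ms, end 280 ms. Only the upstroke timing affects the timing
  endpoints; a uniform diastolic residual shifts all activation times
  equally and cancels in the conduction-velocity slope.

Rendering: masked pixels get `F0 · (1 + s · dff_true · w(t − t_act))`
(`s` = polarity sign; GEVIs are negative by default since ASAP1 dims on
depolarization), unmasked pixels get dark counts (default 10). Noise is
`shot` (counts = gain · Poisson(mean/gain), so variance = gain · mean;
default gain 1) or `gaussian(sigma)`. Quantization is round-half-up with
clipping to the bit depth (16-bit default); clipping emits a saturation
warning with the affected fraction. Every stochastic operation takes an
explicit seed. Defaults F0 = 1000 counts and dff_true = 0.1143 represent a
typical well-stained NRVM monolayer at moderate illumination; shot noise at
this baseline gives per-pixel, per-frame dF/F noise of ~0.03, which is why
the analysis defaults lean on temporal smoothing and regional averaging.

## Reaction–diffusion fibrillation surrogate

Fibrillation-like movies come from the two-variable Barkley excitable-media
model, `du/dt = u(1−u)(u−(v+b)/a)/ε + D∇²u`, `dv/dt = u − v`, with a = 0.75,
b = 0.06, ε = 0.02, D = 1, one model length unit per pixel, explicit Euler
stepping (dt = 0.2, enforced ≤ dx²/4D with an error naming the bound), a
five-point Laplacian with no-flux boundaries at the mask edge, and 25 ms per
model time unit (re-entrant cycle length ≈ 150–190 ms). Cross-field
initiation (S1 planar wave, S2 half-field stimulus at 16 t.u.) produces
sustained, meandering re-entry on dishes of ≥ ~60 px; point stimulation
produces a single target wave that extinguishes. This is a phenomenological
surrogate: real NRVM fibrillation arises spontaneously from tissue
heterogeneity, which is not modeled, and the Barkley fast variable is
dimensionless, so reaction–diffusion runs carry no closed-form speed
(`speed_scale` refuses them). The regime is labeled fibrillatory only when
re-entry actually sustains (activity in the last 10% of the run and a median
of ≥ 3 upstrokes per pixel).

## Baseline, ΔF/F and masks

F0 defaults to the 10th percentile of each pixel's time series (90th for
negative polarity, whose resting level is bright); a pre-stimulus mean is
available when a quiescent window is known (≥ 3 samples enforced). The
percentile estimator assumes the diastole occupies ≥ ~10% of the record,
which holds for the pacing protocols used here. ΔF/F is polarity-corrected
so upstrokes are positive for every reporter; it is exactly invariant to
camera gain. Dish masks come from Otsu (or quantile) thresholding of the
temporal mean, intersected with a declared geometry when available.

## Activation detection

Per beat window, base = pre-peak minimum, peak = window maximum, and the
activation time is the first upward crossing of base + 0.5·(peak − base),
linearly interpolated between the bracketing frames. Two robustness rules:

* **Rising-limb restriction (hysteresis).** Crossings count only after the
  last pre-peak sample below base + 0.25·amp. Without this, the previous
  beat's slow decay through the 50% level (at 3 Hz pacing) plus noise
  produces spurious early activation times; with it, a noise-split upstroke
  still resolves to its first crossing.
* **Window pre-margin.** The analysis window extends 25 ms before the beat
  start so pixels at the stimulation site, whose upstroke straddles the
  stimulus instant, are fully captured.

Validity requires peak change ≥ max(5 × robust noise SD, 0.01 ΔF/F), with
noise from the median absolute successive difference. Maps with < 10% valid
pixels raise an unmappable-beat error. Default temporal smoothing is a
3-frame boxcar (symmetric, so it does not shift the 50% point of the
symmetric upstroke); for exact-recovery checks it is disabled. For shot
noise at F0 = 1000 the recommended settings are a boxcar of roughly half the
upstroke (≈ 15–20 ms) and 2x2 analysis binning (`spatial_bin=2`, mirroring
the camera's own superpixel binning), which brings the 95th-percentile
timing error under two frame periods.

## Conduction velocity

Activation times are sampled at nearest pixels every 0.5 mm along the dish
diameter through the stimulation site (decoupling fit density from the pixel
grid) and fitted by ordinary least squares, time vs distance. Speed is
100/slope (slope in ms/mm) — the exact mm/ms → cm/s conversion. One pass of
outlier removal beyond 3 robust SDs of the residuals, then a refit; on
noise-free data the robust SD is zero and nothing is trimmed. A slope so
shallow that the wave would cross the whole line within one frame is
returned as a signed speed with a `near_zero_slope` flag (and negative
slopes as `negative_slope`), never silently rectified.

## Transient amplitude

Per-beat amplitude is peak − base on the site's regional-mean ΔF/F trace
(sites default to 3 mm squares). The default estimator (`ensemble`) first
averages the aligned beat windows into an ensemble waveform, takes its
peak − base amplitude, and then scales that waveform to each beat by least
squares. The per-beat scale is linear in the data and therefore unbiased
under zero-mean noise, unlike a per-beat max/min, whose extreme-value bias
at these noise levels reaches several percent; on noise-free data both
estimators agree exactly. `mean_dff` is always the mean of the per-beat
values. Whether amplitudes should be averaged over all beats or taken from
one beat is a free choice; this package averages all beats in the record.

## Rhythm classification

Five sample sites (centroid + four off-center) provide inter-activation
intervals; events must clear max(5 × robust noise, 0.01 ΔF/F), so pure-noise
recordings yield no cycles and the label `undetermined` (< 3 cycles).
`cycle_length_cv` is the median over sites of SD/mean of intervals; the
recording is fibrillatory when it exceeds 0.1 or when activation maps of
consecutive auto-detected cycles correlate below 0.8 (both configurable —
there is no standard criterion, and the thresholds were chosen to separate
metronomic pacing, whose cycle CV is ~0, from meandering re-entry, whose
site-level cycle CV is several tenths). `paced` additionally requires the
dominant frequency (spectral peak of the spatially averaged trace,
0.5–20 Hz band) to match the declared pacing rate within 15%. The
classifier is a reproducible surrogate for the by-eye exclusion of
fibrillating dishes, not a claim about how any particular lab did it.

## Treatment comparison

`compare_treatment` reports group means, SD (labeled as such, with SEM also
exported — "±" dispersions in the literature are often ambiguous), paired
differences and the ratio of group means. No hypothesis tests are computed;
the endpoints here are descriptive. The synthetic drug study
(`cardiomap demo`, `cardiomap.experiment`) draws per-dish control levels
(ΔF/F log-normal with CV 0.15 around 0.1143; speed normal, SD 1.6 cm/s
around 22.9 cm/s — dispersions typical of NRVM monolayer preparations),
applies multiplicative drug effects (amplitude ratio 0.517, speed ratio
0.782, vehicle 1.0), renders pre/post movies with shot noise, and measures
both with the identical pipeline. Demo recordings use a 120x120 grid at
0.3 mm/px, 3 s at 2 Hz for amplitude arms and 1 s at 3 Hz for CV arms —
sizes chosen so a full study runs in well under a minute while leaving ≥ 6
beats per amplitude measurement and ≥ 3 per map.

## Determinism and problem sizes

All randomness flows through explicit integer seeds or
`numpy.random.Generator` instances; derived seeds use `SeedSequence.spawn`.
Seeded runs are byte-reproducible, including CSV outputs (fixed float
formatting; manifests carry timestamps but metric files do not). The
acceptance study uses the full 180x180, 300 fps sensor mode with 1 s
recordings at 3 Hz for CV and 4 s at 2 Hz for amplitude.

## What passing tests do and do not show

The generator validates the *analysis*: unit conversions, estimator
bias/variance under shot noise, exclusion logic, and end-to-end parameter
recovery. It does not emulate photobleaching, motion, optical blur/PSF,
spatial heterogeneity of staining or conduction, ratiometric artifacts, or
real fibrillation dynamics; robustness to those must be established on real
recordings. Known limitations: at pacing periods shorter than the transient
(3 Hz calcium) measured amplitudes are diastole-referenced and hence smaller
than `dff_true` — by design the amplitude endpoints are measured at 2 Hz;
the rectangular-strip geometry is supported throughout but the default
study conditions are circular dishes.
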