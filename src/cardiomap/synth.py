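"""Synthetic monolayer excitation waves and camera-realistic rendering.

Two wave generators are provided:

* a *kinematic* generator (:func:`simulate_planar_wave`) whose activation
  times are exact by construction — the ground truth used to validate the
  analysis chain; and
* a *reaction-diffusion* generator (:func:`simulate_reaction_diffusion`)
  based on the two-variable Barkley excitable-media model, used to produce
  fibrillation-like re-entrant activity for rhythm-triage testing.

:func:`render_movie` turns either ground truth into a 16-bit camera movie:
``counts = F0 * (1 + sign * dff_true * w(t - t_act))`` with an optional shot
(Poisson) or Gaussian noise stage and round-half-up quantization.  The
transient waveform ``w`` is aligned so that its 50%-of-peak upstroke crossing
sits exactly at the activation time, which makes the rendered movie directly
comparable to the 50%-rise activation maps recovered by the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import DishGeometry
from .signals import MovieStack

__all__ = [
    "TransientTemplate", "calcium_template", "action_potential_template",
    "OpticsModel", "WaveTruth", "BarkleyKinetics",
    "simulate_planar_wave", "simulate_reaction_diffusion",
    "render_movie", "apply_drug_effect", "scale_amplitude", "scale_speed",
]


@dataclass
class TransientTemplate:
    """Unit-amplitude transient waveform.

    Time is measured relative to the activation instant, defined as the 50%
    point of the upstroke.  The upstroke is a raised cosine of duration
    ``rise_ms`` (so it is symmetric about the activation instant and crosses
    0.5 exactly at t = 0); the decay is exponential with time constant
    ``tau_ms``, tapered smoothly to zero over the last ``taper_ms`` so the
    transient has finite duration ``end_ms`` after the peak and the diastolic
    level genuinely returns to baseline between beats.
    """

    kind: str = "calcium"
    rise_ms: float = 30.0
    tau_ms: float = 200.0
    end_ms: float = 405.0
    taper_ms: float = 120.0

    @property
    def support_ms(self) -> float:
        """Total transient duration from upstroke foot to return-to-zero."""
        return self.rise_ms + self.end_ms

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Waveform value at time(s) ``t_ms`` relative to activation."""
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        r = self.rise_ms
        up = (t >= -r / 2) & (t <= r / 2)
        out[up] = 0.5 * (1.0 + np.sin(np.pi * t[up] / r))
        tp = t - r / 2
        dec = (tp > 0) & (tp <= self.end_ms)
        td = tp[dec]
        val = np.exp(-td / self.tau_ms)
        t0 = self.end_ms - self.taper_ms
        tap = td > t0
        val[tap] *= 0.5 * (1.0 + np.cos(np.pi * (td[tap] - t0) / self.taper_ms))
        out[dec] = val
        return out

    def waveform(self, fps: float) -> np.ndarray:
        """The waveform sampled at the camera clock (starts at 0, peaks at 1)."""
        tt = np.arange(-self.rise_ms / 2, self.rise_ms / 2 + self.end_ms,
                       1000.0 / fps)
        return self.evaluate(tt)


def calcium_template() -> TransientTemplate:
    """Calcium-dye transient: 30 ms upstroke, ~200 ms decay."""
    return TransientTemplate(kind="calcium", rise_ms=30.0, tau_ms=200.0,
                             end_ms=405.0, taper_ms=120.0)


def action_potential_template() -> TransientTemplate:
    """Optical action potential: 5 ms upstroke, ~150 ms repolarization."""
    return TransientTemplate(kind="action_potential", rise_ms=5.0,
                             tau_ms=150.0, end_ms=280.0, taper_ms=100.0)


@dataclass
class OpticsModel:
    """Reporter and camera parameters for rendering.

    ``polarity`` defaults by modality: GEVI (ASAP1) dims on depolarization
    and is negative-going; calcium dyes and VSDs are positive-going.
    ``noise='shot'`` draws Poisson counts with variance ``noise_gain * mean``;
    ``noise='gaussian'`` adds N(0, noise_sigma).
    """

    modality: str = "calcium_dye"
    polarity: str | None = None
    F0: float = 1000.0
    dff_true: float = 0.1143
    rise_ms: float | None = None
    decay_ms: float | None = None
    fps: float = 300.0
    bit_depth: int = 16
    noise: str = "none"
    noise_gain: float = 1.0
    noise_sigma: float = 0.0
    dark_counts: float = 10.0

    def __post_init__(self):
        if self.modality not in ("calcium_dye", "vsd", "gevi"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.polarity is None:
            self.polarity = "negative" if self.modality == "gevi" else "positive"
        if self.noise not in ("none", "shot", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.F0 <= 0 or self.dff_true < 0:
            raise ValueError("F0 must be positive and dff_true non-negative")

    @property
    def polarity_sign(self) -> int:
        return 1 if self.polarity == "positive" else -1

    def default_template(self) -> TransientTemplate:
        base = calcium_template() if self.modality == "calcium_dye" \
            else action_potential_template()
        if self.rise_ms is not None:
            base.rise_ms = self.rise_ms
        if self.decay_ms is not None:
            base.tau_ms = self.decay_ms
        return base


@dataclass
class WaveTruth:
    """Simulator ground truth for one recording.

    ``activation_field`` has shape (n_beats, H, W) and holds the true
    activation time (ms) of every masked pixel for every beat (NaN outside
    the mask).  ``speed_cm_s`` is the exact wave speed for kinematic waves
    and None for reaction-diffusion runs, which have no closed-form speed.
    """

    activation_field: np.ndarray = field(repr=False)
    beat_times_ms: np.ndarray
    origin: tuple[int, int]
    regime: str = "paced"
    speed_cm_s: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return self.activation_field.shape[0]


def _default_origin(geometry: DishGeometry) -> tuple[int, int]:
    # stimulation site at the right edge of the dish, on the central row
    r = geometry.grid_rows // 2
    row = geometry.mask[r]
    if not row.any():
        rows = np.where(geometry.mask.any(axis=1))[0]
        r = rows[len(rows) // 2]
        row = geometry.mask[r]
    return (int(r), int(np.where(row)[0].max()))


def simulate_planar_wave(
    geometry: DishGeometry,
    speed_cm_s: float = 22.9,
    pacing_hz: float = 3.0,
    duration_s: float = 1.0,
    origin: tuple[int, int] | None = None,
    wave: str = "planar",
    direction: tuple[float, float] | None = None,
) -> WaveTruth:
    """Exact kinematic wave train launched from a point-stimulation site.

    For ``wave='planar'`` the activation time grows linearly with the
    projection of each pixel onto the propagation axis (distance from the
    origin, divided by the speed); for ``wave='target'`` with the Euclidean
    distance.  Beats are stimulated at ``k / pacing_hz`` for the whole
    duration.
    """
    if speed_cm_s <= 0:
        raise ValueError("speed_cm_s must be positive")
    if pacing_hz <= 0 or duration_s <= 0:
        raise ValueError("pacing_hz and duration_s must be positive")
    if origin is None:
        origin = _default_origin(geometry)
    if not geometry.contains(origin):
        raise ValueError(f"origin {origin} lies outside the dish mask")

    y, x = geometry.pixel_coords_mm()
    oy = (origin[0] + 0.5) * geometry.pixel_pitch_mm
    ox = (origin[1] + 0.5) * geometry.pixel_pitch_mm

    if wave == "planar":
        if direction is None:
            yy, xx = np.nonzero(geometry.mask)
            cy = (yy.mean() + 0.5) * geometry.pixel_pitch_mm
            cx = (xx.mean() + 0.5) * geometry.pixel_pitch_mm
            direction = (cy - oy, cx - ox)
        d = np.asarray(direction, dtype=float)
        n = np.hypot(*d)
        if n == 0:
            raise ValueError("direction must be non-zero")
        d /= n
        dist = np.clip((y - oy) * d[0] + (x - ox) * d[1], 0.0, None)
    elif wave == "target":
        dist = np.hypot(y - oy, x - ox)
    else:
        raise ValueError(f"unknown wave kind {wave!r}")

    v_mm_ms = speed_cm_s / 100.0
    duration_ms = duration_s * 1000.0
    period_ms = 1000.0 / pacing_hz
    n_beats = int(np.ceil(duration_ms / period_ms - 1e-9))
    onsets = np.arange(n_beats) * period_ms

    field_ = onsets[:, None, None] + dist[None] / v_mm_ms
    field_ = np.where(geometry.mask[None], field_, np.nan)

    return WaveTruth(
        activation_field=field_, beat_times_ms=onsets, origin=origin,
        regime="paced", speed_cm_s=speed_cm_s,
        meta={"wave": wave, "pacing_hz": pacing_hz, "duration_s": duration_s},
    )


@dataclass
class BarkleyKinetics:
    """Two-variable excitable-media kinetics (Barkley model).

    du/dt = u(1-u)(u - (v+b)/a) / eps + D lap(u);  dv/dt = u - v.

    The grid spacing is ``dx`` model units per pixel and ``ms_per_tu``
    converts model time units to milliseconds (default 25 ms/t.u., which
    puts the re-entrant cycle length near 150-200 ms).
    """

    a: float = 0.75
    b: float = 0.06
    eps: float = 0.02
    D: float = 1.0
    dx: float = 1.0
    dt: float | None = None
    ms_per_tu: float = 25.0

    def resolved_dt(self) -> float:
        bound = self.dx ** 2 / (4.0 * self.D) if self.D > 0 else np.inf
        dt = min(0.8 * bound, 0.2) if self.dt is None else self.dt
        if dt > bound:
            raise ValueError(
                f"time step dt={dt} violates the diffusion stability bound "
                f"dx^2/(4 D) = {bound}"
            )
        return dt


def simulate_reaction_diffusion(
    geometry: DishGeometry,
    kinetics: BarkleyKinetics | None = None,
    init: str = "point_stim",
    duration_s: float = 2.5,
    record_fps: float = 300.0,
    origin: tuple[int, int] | None = None,
    s2_time_tu: float = 16.0,
) -> tuple[WaveTruth, np.ndarray]:
    """Excitable-media simulation with no-flux boundaries at the mask edge.

    ``init='point_stim'`` excites a small disc (a single outward target wave
    that extinguishes); ``init='cross_field'`` applies an S1 planar wave from
    the left edge followed by an S2 half-field stimulus at ``s2_time_tu``,
    which wraps around the S1 wave-back and starts sustained re-entry.

    Returns ``(truth, state_movie)`` where ``state_movie`` is the fast
    variable sampled at ``record_fps`` (T x H x W, values in [0, 1]) and
    ``truth.activation_field`` holds each pixel's first upstroke crossing.
    Upstroke counts per pixel are in ``truth.meta['upstroke_counts']``.
    """
    kin = kinetics or BarkleyKinetics()
    dt = kin.resolved_dt()
    mask = geometry.mask
    H, W = mask.shape
    if init == "point_stim" and origin is None:
        origin = (H // 2, W // 2)
        if not mask[origin]:
            origin = _default_origin(geometry)

    u = np.zeros((H, W))
    v = np.zeros((H, W))
    if init == "point_stim":
        if not geometry.contains(origin):
            raise ValueError(f"origin {origin} lies outside the dish mask")
        yy, xx = np.mgrid[0:H, 0:W]
        u[(yy - origin[0]) ** 2 + (xx - origin[1]) ** 2 <= 9] = 1.0
    elif init == "cross_field":
        u[:, :4] = 1.0
        origin = origin or _default_origin(geometry)
    else:
        raise ValueError(f"unknown init {init!r}")

    nbr = sum(np.roll(mask, s, axis=ax) for ax in (0, 1) for s in (1, -1))
    dx2 = kin.dx ** 2

    duration_tu = duration_s * 1000.0 / kin.ms_per_tu
    n_steps = int(np.ceil(duration_tu / dt))
    n_frames = int(round(duration_s * record_fps))
    frame_times_tu = np.arange(n_frames) * 1000.0 / (record_fps * kin.ms_per_tu)

    state = np.empty((n_frames, H, W), dtype=np.float32)
    first_cross = np.full((H, W), np.nan)
    counts = np.zeros((H, W), dtype=np.int32)
    prev_above = (u > 0.5) & mask
    # pixels stimulated at t=0 count as activated at time zero
    counts[prev_above] = 1
    first_cross[prev_above] = 0.0
    fired_s2 = init != "cross_field"
    next_frame = 0
    alive_tail = False
    tail_start = 0.9 * n_steps

    t = 0.0
    for step in range(n_steps):
        while next_frame < n_frames and frame_times_tu[next_frame] <= t + 1e-12:
            state[next_frame] = np.clip(np.where(mask, u, 0.0), 0.0, 1.0)
            next_frame += 1
        if not fired_s2 and t >= s2_time_tu:
            u[H // 2:, :W // 2] = np.maximum(u[H // 2:, :W // 2], 1.0)
            fired_s2 = True
        um = np.where(mask, u, 0.0)
        lap = (np.roll(um, 1, 0) + np.roll(um, -1, 0)
               + np.roll(um, 1, 1) + np.roll(um, -1, 1) - nbr * um) / dx2
        du = u * (1.0 - u) * (u - (v + kin.b) / kin.a) / kin.eps + kin.D * lap
        dv = u - v
        u = np.where(mask, np.clip(u + dt * du, 0.0, 1.5), 0.0)
        v = np.where(mask, v + dt * dv, 0.0)
        t += dt
        above = u > 0.5
        new = above & ~prev_above & mask
        if new.any():
            tm = t * kin.ms_per_tu
            first_cross[new & np.isnan(first_cross)] = tm
            counts[new] += 1
        prev_above = above
        if step >= tail_start and above.any():
            alive_tail = True
    while next_frame < n_frames:
        state[next_frame] = np.clip(np.where(mask, u, 0.0), 0.0, 1.0)
        next_frame += 1

    sustained = (init == "cross_field" and alive_tail
                 and np.median(counts[mask]) >= 3)
    regime = "fibrillatory" if sustained else "paced"

    truth = WaveTruth(
        activation_field=first_cross[None],
        beat_times_ms=np.array([0.0]),
        origin=tuple(origin), regime=regime, speed_cm_s=None,
        meta={
            "upstroke_counts": counts, "init": init,
            "kinetics": {k: getattr(kin, k) for k in
                         ("a", "b", "eps", "D", "dx", "ms_per_tu")},
            "dt_tu": dt, "record_fps": record_fps,
        },
    )
    return truth, state


def render_movie(
    truth: WaveTruth,
    optics: OpticsModel,
    geometry: DishGeometry,
    template: TransientTemplate | None = None,
    duration_s: float | None = None,
    state_movie: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> MovieStack:
    """Render ground truth into a quantized camera movie.

    Masked pixels follow ``F0 * (1 + sign * dff_true * w(t - t_act))`` with
    the transient template ``w`` (kinematic truth) or the reaction-diffusion
    fast variable (``state_movie``); pixels outside the dish get dark counts.
    Noise is applied per the optics model, then counts are quantized
    round-half-up and clipped to the camera bit depth (a warning reports the
    fraction of saturated pixels, if any).  Rendering is deterministic for a
    given seed.
    """
    mask = geometry.mask
    fps = optics.fps

    if state_movie is not None:
        signal = np.clip(np.asarray(state_movie, dtype=float), 0.0, 1.0)
        n_frames = signal.shape[0]
    else:
        tmpl = template or optics.default_template()
        if tmpl.rise_ms * fps / 1000.0 < 2.0:
            raise ValueError(
                f"fps={fps} does not resolve the {tmpl.rise_ms} ms upstroke "
                "with at least 2 frames"
            )
        onsets = np.asarray(truth.beat_times_ms, dtype=float)
        if onsets.size > 1:
            min_period = float(np.diff(onsets).min())
            if min_period < tmpl.support_ms:
                warnings.warn(
                    f"pacing period {min_period:.0f} ms is shorter than the "
                    f"transient duration {tmpl.support_ms:.0f} ms; transients "
                    "will overlap"
                )
        if duration_s is None:
            period = float(np.diff(onsets).min()) if onsets.size > 1 \
                else tmpl.support_ms + 100.0
            duration_s = (onsets[-1] + period) / 1000.0
        n_frames = int(round(duration_s * fps))
        times = np.arange(n_frames) * 1000.0 / fps
        fp = 1000.0 / fps
        signal = np.zeros((n_frames,) + mask.shape)
        for b in range(truth.n_beats):
            act = truth.activation_field[b]
            lo = np.nanmin(act) - tmpl.rise_ms / 2
            hi = np.nanmax(act) + tmpl.rise_ms / 2 + tmpl.end_ms
            k0 = max(0, int(np.floor(lo / fp)))
            k1 = min(n_frames, int(np.ceil(hi / fp)) + 1)
            if k0 >= k1:
                continue
            tt = times[k0:k1, None, None] - act[None]
            np.maximum(signal[k0:k1], tmpl.evaluate(tt), out=signal[k0:k1])

    clean = optics.F0 * (1.0 + optics.polarity_sign * optics.dff_true * signal)
    clean = np.where(mask[None], clean, optics.dark_counts)

    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if optics.noise == "shot":
        g = optics.noise_gain
        noisy = g * rng.poisson(clean / g).astype(float)
    elif optics.noise == "gaussian":
        noisy = clean + rng.normal(0.0, optics.noise_sigma, clean.shape)
    else:
        noisy = clean

    maxval = 2 ** optics.bit_depth - 1
    quant = np.floor(noisy + 0.5)
    n_sat = int(np.count_nonzero(quant > maxval) + np.count_nonzero(quant < 0))
    if n_sat:
        warnings.warn(
            f"saturation: {n_sat / quant.size:.2%} of samples clipped to the "
            f"{optics.bit_depth}-bit range"
        )
    quant = np.clip(quant, 0, maxval)

    return MovieStack(
        frames=quant.astype(np.uint16 if optics.bit_depth <= 16 else np.uint32),
        fps=fps, pixel_pitch_mm=geometry.pixel_pitch_mm,
        polarity=optics.polarity, modality=optics.modality, mask=mask,
        kind="raw",
        meta={
            "dff_true": optics.dff_true, "F0": optics.F0,
            "dark_counts": optics.dark_counts,
            "beat_times_ms": list(np.asarray(truth.beat_times_ms, float)),
            "speed_cm_s": truth.speed_cm_s, "origin": list(truth.origin),
            "regime": truth.regime, "noise": optics.noise,
            "seed": None if isinstance(seed, np.random.Generator) else int(seed),
            "bit_depth": optics.bit_depth,
        },
    )


def scale_amplitude(optics: OpticsModel, factor: float) -> OpticsModel:
    """Drug effect on transient amplitude: multiply dff_true by ``factor``."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return replace(optics, dff_true=optics.dff_true * factor)


def scale_speed(truth: WaveTruth, factor: float) -> WaveTruth:
    """Drug effect on conduction: multiply the kinematic wave speed by ``factor``."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    if truth.speed_cm_s is None:
        raise ValueError(
            "speed_scale applies only to kinematic truths with a closed-form "
            "speed; for reaction-diffusion runs change the kinetics instead"
        )
    onsets = truth.beat_times_ms[:, None, None]
    field_ = onsets + (truth.activation_field - onsets) / factor
    return WaveTruth(
        activation_field=field_, beat_times_ms=truth.beat_times_ms.copy(),
        origin=truth.origin, regime=truth.regime,
        speed_cm_s=truth.speed_cm_s * factor, meta=dict(truth.meta),
    )


def apply_drug_effect(target, effect: str, factor: float):
    """Apply a named drug effect: ``amplitude_scale`` or ``speed_scale``."""
    if effect == "amplitude_scale":
        if not isinstance(target, OpticsModel):
            raise TypeError("amplitude_scale applies to an OpticsModel")
        return scale_amplitude(target, factor)
    if effect == "speed_scale":
        if not isinstance(target, WaveTruth):
            raise TypeError("speed_scale applies to a WaveTruth")
        return scale_speed(target, factor)
    raise ValueError(f"unknown drug effect {effect!r}")
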