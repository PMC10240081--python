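"""Beat segmentation, 50%-rise activation times, activation maps, rhythm triage.

The activation time of a pixel is the instant its fluorescence upstroke
first crosses 50% of the beat's peak change, with linear interpolation
between the two bracketing frames.  "Peak change" is measured from the
pre-peak minimum within the beat window, which keeps the definition robust
when the diastolic level has not fully returned to baseline between beats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .signals import MovieStack, Trace, compute_dff, estimate_baseline, smooth_trace

__all__ = [
    "BeatWindow", "ActivationMap", "RhythmLabel",
    "segment_beats", "activation_time", "build_activation_map",
    "classify_rhythm",
]

#: peak change below this dF/F is never trusted, whatever the noise estimate
DEFAULT_ABS_FLOOR = 0.01
#: peak change must exceed this multiple of the robust noise SD
DEFAULT_SNR_FLOOR = 5.0


@dataclass
class BeatWindow:
    start_ms: float
    end_ms: float
    source: str = "stimulus_times"

    def __post_init__(self):
        if self.end_ms <= self.start_ms:
            raise ValueError("beat window must have end_ms > start_ms")


@dataclass
class ActivationMap:
    """Per-pixel activation times (ms, relative to beat start) for one beat."""

    times_ms: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)
    frame_period_ms: float
    beat_index: int = 0
    meta: dict = field(default_factory=dict)


@dataclass
class RhythmLabel:
    label: str  # paced | spontaneous_regular | fibrillatory | undetermined
    dominant_freq_hz: float
    cycle_length_cv: float
    meta: dict = field(default_factory=dict)


def _window_slice(win: BeatWindow, fps: float, n_frames: int) -> tuple[int, int]:
    fp = 1000.0 / fps
    i0 = max(0, int(np.ceil(win.start_ms / fp - 1e-9)))
    i1 = min(n_frames, int(np.ceil(win.end_ms / fp - 1e-9)))
    return i0, i1


def segment_beats(
    source: MovieStack | Trace,
    stimulus_times_ms=None,
    min_separation_ms: float = 100.0,
) -> list[BeatWindow]:
    """Delimit beats either from the pacing protocol or from the signal.

    With known stimulus times the windows are ``[t_i, t_{i+1})`` (the last
    one runs to the end of the record).  Otherwise peaks of the spatially
    averaged dF/F trace above half its global maximum define cycles, with
    window boundaries midway between consecutive peaks.
    """
    if isinstance(source, MovieStack):
        fps = source.fps
        end_ms = source.n_frames * 1000.0 / fps
        mask = source.mask if source.mask is not None \
            else np.ones(source.frames.shape[1:], bool)
        if source.kind == "dff":
            mean_trace = source.frames[:, mask].mean(axis=1)
        else:
            f0 = estimate_baseline(source)
            mean_trace = compute_dff(source, f0).frames[:, mask].mean(axis=1)
    else:
        fps = source.fps
        end_ms = source.values.size * 1000.0 / fps
        mean_trace = source.values

    if stimulus_times_ms is not None:
        st = np.asarray(stimulus_times_ms, dtype=float)
        if st.size == 0 or np.any(np.diff(st) <= 0):
            raise ValueError("stimulus times must be non-empty and increasing")
        edges = np.append(st, end_ms)
        return [BeatWindow(edges[i], edges[i + 1], source="stimulus_times")
                for i in range(st.size) if edges[i + 1] > edges[i]]

    x = smooth_trace(mean_trace, 10.0, fps=fps)
    rng = x.max() - x.min()
    if rng < DEFAULT_ABS_FLOOR:
        warnings.warn("no activity detected; returning no beat windows")
        return []
    dist = max(1, int(min_separation_ms * fps / 1000.0))
    peaks, _ = find_peaks(x, height=x.min() + 0.5 * rng, distance=dist)
    if peaks.size == 0:
        warnings.warn("no activity detected; returning no beat windows")
        return []
    pt = peaks * 1000.0 / fps
    if peaks.size == 1:
        return [BeatWindow(0.0, end_ms, source="auto_detected")]
    mid = (pt[:-1] + pt[1:]) / 2.0
    ival = float(np.median(np.diff(pt)))
    starts = np.concatenate([[max(0.0, pt[0] - 0.5 * ival)], mid])
    ends = np.concatenate([mid, [end_ms]])
    return [BeatWindow(s, e, source="auto_detected")
            for s, e in zip(starts, ends) if e > s]


def _first_crossings(win: np.ndarray, fps: float, frac: float = 0.5,
                     snr_floor: float = DEFAULT_SNR_FLOOR,
                     abs_floor: float = DEFAULT_ABS_FLOOR):
    """Vectorized first-crossing search on a (T, N) window stack.

    Returns ``(times_ms, valid, amplitude)`` where times are relative to the
    first sample of the window.  The crossing is the first time the trace
    reaches base + frac * (peak - base) on the rising limb before the
    absolute peak, linearly interpolated between the bracketing frames.
    """
    win = np.asarray(win, dtype=float)
    T, N = win.shape
    cols = np.arange(N)
    peak_idx = np.argmax(win, axis=0)
    prefix_min = np.minimum.accumulate(win, axis=0)
    base = prefix_min[peak_idx, cols]
    peak = win[peak_idx, cols]
    amp = peak - base

    # robust per-trace noise from successive differences
    if T > 2:
        noise = 1.4826 * np.median(np.abs(np.diff(win, axis=0)), axis=0) / np.sqrt(2.0)
    else:
        noise = np.zeros(N)
    valid = amp >= np.maximum(snr_floor * noise, abs_floor)

    level = base + frac * amp
    # Hysteresis: the rising limb is the final approach to the peak, i.e.
    # everything after the last pre-peak sample below base + 0.25*amp.
    # Crossings earlier in the window (the previous beat's decay passing
    # through the level, or noise spikes riding the diastole) are not
    # upstroke crossings.  Within that limb the *first* upward crossing
    # wins, so a noise-split upstroke resolves to its earlier crossing.
    idx = np.arange(T)[:, None]
    lo = base + 0.25 * amp
    below_lo = (win < lo[None]) & (idx <= peak_idx[None])
    has_foot = below_lo.any(axis=0)
    foot = T - 1 - np.argmax(below_lo[::-1], axis=0)
    above = win >= level[None]
    crossing = np.zeros_like(above)
    crossing[1:] = above[1:] & ~above[:-1]
    crossing &= (idx > foot[None]) & (idx <= peak_idx[None])
    has = crossing.any(axis=0) & has_foot
    first = np.argmax(crossing, axis=0)
    valid &= has

    prev = np.maximum(first - 1, 0)
    w_prev = win[prev, cols]
    w_at = win[first, cols]
    denom = w_at - w_prev
    step = np.where(denom > 0, (level - w_prev) / np.where(denom > 0, denom, 1.0), 0.0)
    t_frames = np.where(first == 0, 0.0, prev + step)
    times_ms = t_frames * 1000.0 / fps
    return times_ms, valid, amp


def activation_time(
    source: Trace | np.ndarray,
    fps: float | None = None,
    frac: float = 0.5,
    snr_floor: float = DEFAULT_SNR_FLOOR,
    abs_floor: float = DEFAULT_ABS_FLOOR,
) -> float:
    """50%-rise activation time (ms) of a single dF/F beat window.

    Returns NaN when the peak change does not clear the noise floor.
    """
    if isinstance(source, Trace):
        arr, fps = source.values, source.fps
    else:
        arr = np.asarray(source, dtype=float)
        if fps is None:
            raise ValueError("fps required for a bare array")
    t, valid, _ = _first_crossings(arr[:, None], fps, frac=frac,
                                   snr_floor=snr_floor, abs_floor=abs_floor)
    return float(t[0]) if valid[0] else float("nan")


def build_activation_map(
    movie: MovieStack,
    beat: BeatWindow,
    beat_index: int = 0,
    smooth_ms: float | None = None,
    snr_floor: float = DEFAULT_SNR_FLOOR,
    abs_floor: float = DEFAULT_ABS_FLOOR,
    baseline_percentile: float = 10.0,
    min_valid_fraction: float = 0.10,
    pre_margin_ms: float = 25.0,
    spatial_bin: int = 1,
) -> ActivationMap:
    """Per-pixel 50%-rise activation map for one beat.

    Raw movies are converted to dF/F with a low-percentile baseline first.
    ``smooth_ms=None`` applies the default 3-frame boxcar; pass 0 to disable
    smoothing entirely.  ``spatial_bin`` pools n x n pixel blocks before
    timing (analysis-side binning, like the camera's own superpixels); every
    member pixel then carries its block's time.  Times are relative to the
    beat window start.

    The analysis window is extended ``pre_margin_ms`` before the beat start
    so that upstrokes straddling the stimulus instant (pixels at the
    stimulation site activate essentially at the stimulus) are fully
    captured; their times can come out slightly negative.

    Raises
    ------
    ValueError
        If fewer than ``min_valid_fraction`` of masked pixels yield a valid
        activation time (unmappable beat).
    """
    mask = movie.mask if movie.mask is not None \
        else np.ones(movie.frames.shape[1:], bool)
    if movie.kind == "dff":
        dffm = movie
    else:
        f0 = estimate_baseline(movie, percentile=baseline_percentile)
        dffm = compute_dff(movie, f0)

    widened = BeatWindow(max(0.0, beat.start_ms - pre_margin_ms),
                         beat.end_ms, source=beat.source)
    i0, i1 = _window_slice(widened, movie.fps, movie.n_frames)
    if i1 - i0 < 3:
        raise ValueError("beat window contains fewer than 3 frames")
    frames_w = dffm.frames[i0:i1]

    if spatial_bin > 1:
        b = spatial_bin
        H, W = mask.shape
        Hc, Wc = (H // b) * b, (W // b) * b
        fw = frames_w[:, :Hc, :Wc]
        mk = mask[:Hc, :Wc]
        cnt = mk.reshape(Hc // b, b, Wc // b, b).sum(axis=(1, 3))
        ok_blocks = cnt > 0
        vals = (fw * mk).reshape(fw.shape[0], Hc // b, b, Wc // b, b)
        vals = vals.sum(axis=(2, 4))
        win = vals[:, ok_blocks] / cnt[ok_blocks]
    else:
        win = frames_w[:, mask]

    if smooth_ms is None:
        w = 3
    else:
        w = int(round(smooth_ms * movie.fps / 1000.0))
        if w % 2 == 0 and w > 0:
            w += 1
    if w > 1:
        from scipy.ndimage import uniform_filter1d
        win = uniform_filter1d(win, size=w, axis=0, mode="nearest")

    t_rel, valid, amp = _first_crossings(win, movie.fps, snr_floor=snr_floor,
                                         abs_floor=abs_floor)
    # window slicing may start off the beat start: shift to beat-relative time
    t_rel = t_rel + (i0 * 1000.0 / movie.fps - beat.start_ms)

    times = np.full(mask.shape, np.nan)
    vmap = np.zeros(mask.shape, dtype=bool)
    if spatial_bin > 1:
        tb = np.full(ok_blocks.shape, np.nan)
        vb = np.zeros(ok_blocks.shape, dtype=bool)
        tb[ok_blocks] = np.where(valid, t_rel, np.nan)
        vb[ok_blocks] = valid
        times[:Hc, :Wc] = np.repeat(np.repeat(tb, b, axis=0), b, axis=1)
        vmap[:Hc, :Wc] = np.repeat(np.repeat(vb, b, axis=0), b, axis=1)
        times[~mask] = np.nan
        vmap[~mask] = False
    else:
        times[mask] = np.where(valid, t_rel, np.nan)
        vmap[mask] = valid

    n_mask = int(mask.sum())
    if vmap.sum() < min_valid_fraction * n_mask:
        raise ValueError(
            f"unmappable beat: only {int(vmap.sum())} of {n_mask} masked "
            "pixels produced a valid activation time"
        )
    return ActivationMap(
        times_ms=times, valid=vmap, frame_period_ms=1000.0 / movie.fps,
        beat_index=beat_index,
        meta={"snr_floor": snr_floor, "abs_floor": abs_floor,
              "smooth_frames": w, "spatial_bin": spatial_bin,
              "beat_start_ms": beat.start_ms, "beat_end_ms": beat.end_ms},
    )


def _site_events_ms(x_raw: np.ndarray, fps: float,
                    min_separation_ms: float = 80.0) -> np.ndarray:
    """Activation events of one site trace; empty when nothing clears noise."""
    noise = 1.4826 * np.median(np.abs(np.diff(x_raw))) / np.sqrt(2.0)
    x = smooth_trace(x_raw, 10.0, fps=fps)
    rng = x.max() - x.min()
    if rng < max(5.0 * noise, DEFAULT_ABS_FLOOR):
        return np.array([])
    dist = max(1, int(min_separation_ms * fps / 1000.0))
    peaks, _ = find_peaks(x, height=x.min() + 0.5 * rng,
                          prominence=0.25 * rng, distance=dist)
    return peaks * 1000.0 / fps


def classify_rhythm(
    movie: MovieStack,
    pacing_hz: float | None = None,
    cv_threshold: float = 0.1,
    corr_threshold: float = 0.8,
    freq_tol: float = 0.15,
    min_cycles: int = 3,
) -> RhythmLabel:
    """Label a recording paced / spontaneous_regular / fibrillatory.

    Cycle-length variability is the median over a handful of sample sites of
    SD/mean of inter-activation intervals; re-entrant activity also shows up
    as mutually inconsistent activation maps across consecutive cycles
    (pairwise correlation below ``corr_threshold``).  A movie with fewer
    than ``min_cycles`` detected cycles is labeled ``undetermined``.
    """
    mask = movie.mask if movie.mask is not None \
        else np.ones(movie.frames.shape[1:], bool)
    if movie.kind == "dff":
        dffm = movie
    else:
        dffm = compute_dff(movie, estimate_baseline(movie))

    fps = movie.fps
    mean_trace = smooth_trace(dffm.frames[:, mask].mean(axis=1), 10.0, fps=fps)

    # sample sites: mask centroid and 4 off-center points
    yy, xx = np.nonzero(mask)
    r0, r1, c0, c1 = yy.min(), yy.max(), xx.min(), xx.max()
    rc = [(int((r0 + r1) / 2), int((c0 + c1) / 2))]
    for fr, fc in ((0.3, 0.3), (0.3, 0.7), (0.7, 0.3), (0.7, 0.7)):
        rc.append((int(r0 + fr * (r1 - r0)), int(c0 + fc * (c1 - c0))))

    site_cvs, n_cycles = [], 0
    for (r, c) in rc:
        sl = dffm.frames[:, max(0, r - 2):r + 3, max(0, c - 2):c + 3]
        m = mask[max(0, r - 2):r + 3, max(0, c - 2):c + 3]
        if not m.any():
            continue
        ev = _site_events_ms(sl[:, m].mean(axis=1), fps)
        n_cycles = max(n_cycles, ev.size)
        if ev.size >= 4:
            iv = np.diff(ev)
            site_cvs.append(float(iv.std() / iv.mean()))

    # dominant frequency from the spatially averaged trace
    x = mean_trace - mean_trace.mean()
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fps)
    power = np.abs(np.fft.rfft(x)) ** 2
    band = (freqs >= 0.5) & (freqs <= 20.0)
    dominant = float(freqs[band][np.argmax(power[band])]) if band.any() and \
        power[band].max() > 0 else float("nan")

    if n_cycles < min_cycles:
        return RhythmLabel(label="undetermined", dominant_freq_hz=dominant,
                           cycle_length_cv=float("nan"),
                           meta={"n_cycles": n_cycles})

    cl_cv = float(np.median(site_cvs)) if site_cvs else float("nan")

    # activation-map consistency across consecutive auto-detected cycles
    map_corr = None
    try:
        beats = segment_beats(dffm)
        maps = []
        for i, b in enumerate(beats[1:4]):
            maps.append(build_activation_map(dffm, b, beat_index=i + 1))
        corrs = []
        for i in range(len(maps) - 1):
            common = maps[i].valid & maps[i + 1].valid
            if common.sum() >= 50:
                a = maps[i].times_ms[common]
                b_ = maps[i + 1].times_ms[common]
                if a.std() > 0 and b_.std() > 0:
                    corrs.append(float(np.corrcoef(a, b_)[0, 1]))
        if corrs:
            map_corr = min(corrs)
    except ValueError:
        map_corr = 0.0  # cycles exist but maps cannot be built consistently

    fib = (np.isfinite(cl_cv) and cl_cv > cv_threshold) or \
        (map_corr is not None and map_corr < corr_threshold)
    if fib:
        label = "fibrillatory"
    elif pacing_hz is not None and np.isfinite(dominant) and \
            abs(dominant - pacing_hz) <= freq_tol * pacing_hz:
        label = "paced"
    else:
        label = "spontaneous_regular"
    return RhythmLabel(
        label=label, dominant_freq_hz=dominant, cycle_length_cv=cl_cv,
        meta={"n_cycles": n_cycles, "map_correlation": map_corr,
              "site_cvs": site_cvs},
    )
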