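"""Raw-count movies, masks, baselines, dF/F and normalized frames.

The reporter polarity convention runs through everything here: calcium dyes
and voltage-sensitive dyes brighten on activation (positive polarity), while
the GEVI ASAP1 dims on depolarization (negative polarity).  ``compute_dff``
always returns a positive-going upstroke regardless of modality, so all
downstream timing and amplitude code is polarity-blind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "MovieStack", "Trace", "BaselineEstimate",
    "compute_mask", "estimate_baseline", "compute_dff",
    "smooth_trace", "normalize_frames", "polarity_sign",
]


def polarity_sign(polarity: str) -> int:
    if polarity == "positive":
        return 1
    if polarity == "negative":
        return -1
    raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")


@dataclass
class MovieStack:
    """A T x H x W fluorescence recording plus acquisition metadata.

    ``frames`` holds camera counts (``kind='raw'``) or fractional change
    (``kind='dff'``).  ``mask`` marks pixels inside the dish footprint.
    """

    frames: np.ndarray = field(repr=False)
    fps: float
    pixel_pitch_mm: float
    polarity: str = "positive"
    modality: str = "calcium_dye"
    mask: np.ndarray | None = field(default=None, repr=False)
    kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be T x H x W with T >= 2")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        polarity_sign(self.polarity)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:]:
                raise ValueError("mask shape must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.fps

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period_ms

    @property
    def polarity_sign(self) -> int:
        return polarity_sign(self.polarity)


@dataclass
class Trace:
    """A single time series from one pixel or region."""

    values: np.ndarray
    fps: float
    site: object = None
    kind: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.values.size) * 1000.0 / self.fps


@dataclass
class BaselineEstimate:
    """Resting fluorescence F0, per pixel or per site."""

    F0: np.ndarray | float
    method: str
    window: tuple | None = None


def compute_mask(movie: MovieStack, strategy: str = "otsu",
                 quantile: float = 0.5, geometry=None) -> np.ndarray:
    """Isolate the dish region from the temporal-mean image.

    ``strategy='otsu'`` thresholds the temporal mean with Otsu's method;
    ``strategy='quantile'`` keeps pixels above the given quantile of the
    temporal mean.  If a :class:`~cardiomap.geometry.DishGeometry` is given,
    the result is intersected with its mask.
    """
    mean_img = movie.frames.mean(axis=0)
    if strategy == "otsu":
        from skimage.filters import threshold_otsu
        lo, hi = float(mean_img.min()), float(mean_img.max())
        if hi - lo < 1e-12:
            raise ValueError("empty mask: movie has no intensity contrast")
        thr = threshold_otsu(mean_img)
    elif strategy == "quantile":
        thr = np.quantile(mean_img, quantile)
    else:
        raise ValueError(f"unknown threshold strategy {strategy!r}")
    mask = mean_img > thr
    if geometry is not None:
        mask &= geometry.mask
    if not mask.any():
        raise ValueError("empty mask: no pixels above threshold")
    return mask


def _percentile_baseline(arr: np.ndarray, percentile: float, sign: int) -> np.ndarray:
    # negative polarity rests HIGH, so mirror the percentile
    p = percentile if sign > 0 else 100.0 - percentile
    return np.percentile(arr, p, axis=0)


def estimate_baseline(
    source: MovieStack | Trace,
    method: str = "low_percentile",
    percentile: float = 10.0,
    window_ms: tuple[float, float] | None = None,
    polarity: str | None = None,
) -> BaselineEstimate:
    """Estimate resting fluorescence F0.

    ``method='pre_stimulus_mean'`` averages a known quiescent window
    (``window_ms``, at least 3 samples).  ``method='low_percentile'`` takes a
    low percentile of each pixel's time series (mirrored to a high percentile
    for negative-polarity reporters, whose resting level is bright).
    """
    if isinstance(source, MovieStack):
        arr, fps = source.frames.astype(float), source.fps
        sign = source.polarity_sign
    else:
        arr, fps = source.values, source.fps
        sign = polarity_sign(polarity or "positive")

    if method == "pre_stimulus_mean":
        if window_ms is None:
            raise ValueError("pre_stimulus_mean requires window_ms=(start, end)")
        i0 = int(np.ceil(window_ms[0] * fps / 1000.0))
        i1 = int(np.floor(window_ms[1] * fps / 1000.0))
        if i1 - i0 < 3:
            raise ValueError("baseline window must contain at least 3 samples")
        f0 = arr[i0:i1].mean(axis=0)
    elif method == "low_percentile":
        f0 = _percentile_baseline(arr, percentile, sign)
    else:
        raise ValueError(f"unknown baseline method {method!r}")

    return BaselineEstimate(F0=f0, method=method, window=window_ms)


def compute_dff(source: MovieStack | Trace, f0: BaselineEstimate | np.ndarray | float,
                polarity: str | None = None):
    """Convert counts to fractional change dF/F.

    dff(t) = sign(polarity) * (F(t) - F0) / F0, so the upstroke of an
    activation is positive-going in the output for every reporter.
    """
    f0v = f0.F0 if isinstance(f0, BaselineEstimate) else f0
    f0v = np.asarray(f0v, dtype=float)
    if np.any(f0v <= 0):
        raise ValueError("F0 must be positive")
    if isinstance(source, MovieStack):
        sign = source.polarity_sign
        dff = sign * (source.frames.astype(float) - f0v) / f0v
        return MovieStack(
            frames=dff, fps=source.fps, pixel_pitch_mm=source.pixel_pitch_mm,
            polarity="positive", modality=source.modality, mask=source.mask,
            kind="dff", meta=dict(source.meta),
        )
    sign = polarity_sign(polarity or "positive")
    return Trace(values=sign * (source.values - f0v) / f0v,
                 fps=source.fps, site=source.site, kind="dff")


def smooth_trace(source: Trace | np.ndarray, window_ms: float,
                 fps: float | None = None, axis: int = 0):
    """Boxcar (moving-average) smoothing with an odd window.

    ``window_ms=0`` is the identity.  The window is rounded to the nearest
    odd sample count so the filter is symmetric and does not shift timing.
    """
    if window_ms < 0:
        raise ValueError("window_ms must be >= 0")
    if isinstance(source, Trace):
        arr, fps_ = source.values, source.fps
    else:
        arr = np.asarray(source, dtype=float)
        if fps is None:
            raise ValueError("fps required when smoothing a bare array")
        fps_ = fps
    w = int(round(window_ms * fps_ / 1000.0))
    if w % 2 == 0:
        w += 1 if w > 0 else 0
    if w <= 1:
        out = arr.astype(float, copy=True)
    else:
        if w > arr.shape[axis if not isinstance(source, Trace) else 0]:
            raise ValueError("smoothing window longer than trace")
        out = uniform_filter1d(arr.astype(float), size=w,
                               axis=0 if isinstance(source, Trace) else axis,
                               mode="nearest")
    if isinstance(source, Trace):
        return Trace(values=out, fps=fps_, site=source.site, kind=source.kind)
    return out


def normalize_frames(movie: MovieStack, per_pixel: bool = True):
    """Map each masked pixel's time series to [0, 1] (polarity-corrected).

    Returns ``(normalized_movie, n_flat)`` where flat pixels (min == max)
    were set to 0.  Depolarized frames map toward 1 for every reporter.
    Unmasked pixels are 0.  The output is invariant to affine rescaling of
    the input counts.
    """
    mask = movie.mask if movie.mask is not None else np.ones(movie.frames.shape[1:], bool)
    x = movie.polarity_sign * movie.frames.astype(float)
    if per_pixel:
        lo = x.min(axis=0)
        hi = x.max(axis=0)
    else:
        lo = np.full(x.shape[1:], x[:, mask].min())
        hi = np.full(x.shape[1:], x[:, mask].max())
    rng = hi - lo
    flat = (rng <= 0) & mask
    n_flat = int(flat.sum())
    safe = np.where(rng > 0, rng, 1.0)
    out = (x - lo) / safe
    out[:, ~mask] = 0.0
    out[:, flat] = 0.0
    if n_flat:
        warnings.warn(f"{n_flat} flat pixels set to 0 during normalization")
    norm = MovieStack(
        frames=out, fps=movie.fps, pixel_pitch_mm=movie.pixel_pitch_mm,
        polarity="positive", modality=movie.modality, mask=mask,
        kind="normalized", meta=dict(movie.meta),
    )
    return norm, n_flat
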