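"""File formats: TIFF movies with JSON sidecars, CSV metrics, manifests.

A movie on disk is a multi-page grayscale TIFF plus a JSON sidecar of the
same stem carrying the mandatory acquisition metadata (fps, pixel_pitch_mm,
polarity) and anything else the simulator recorded.  Raw uint16 binary with
the same sidecar (plus shape/dtype) is also accepted.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from . import __version__
from .activation import ActivationMap
from .geometry import DishGeometry
from .signals import MovieStack, Trace
from .synth import WaveTruth

__all__ = [
    "write_movie", "read_movie", "write_truth", "read_truth",
    "write_activation_map", "write_trace_csv", "isochrone_figure",
    "RunManifest",
]

MANDATORY_SIDECAR = ("fps", "pixel_pitch_mm", "polarity")


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_movie(movie: MovieStack, path: str | Path,
                geometry: DishGeometry | None = None) -> Path:
    """Write a multi-page 16-bit grayscale TIFF plus its JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(movie.frames),
                     photometric="minisblack")
    sidecar = {
        "fps": movie.fps,
        "pixel_pitch_mm": movie.pixel_pitch_mm,
        "polarity": movie.polarity,
        "modality": movie.modality,
        "kind": movie.kind,
        "meta": _json_safe(movie.meta),
    }
    if geometry is not None:
        sidecar["geometry"] = geometry.to_dict()
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_movie(path: str | Path) -> MovieStack:
    """Read a movie (TIFF or raw binary) with its mandatory JSON sidecar.

    Missing mandatory sidecar fields are an error naming the field, never a
    silent default.  8-bit TIFFs are accepted and promoted to 16 bits, with
    a note left in the movie metadata.
    """
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FileNotFoundError(f"missing sidecar {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    for f in MANDATORY_SIDECAR:
        if f not in sidecar:
            raise ValueError(f"sidecar {sc_path} is missing mandatory field {f!r}")

    meta = dict(sidecar.get("meta", {}))
    if path.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    elif path.suffix.lower() in (".raw", ".bin"):
        if "shape" not in sidecar or "dtype" not in sidecar:
            raise ValueError("raw binary input requires 'shape' and 'dtype' "
                             "in the sidecar")
        frames = np.fromfile(path, dtype=np.dtype(sidecar["dtype"]))
        frames = frames.reshape(sidecar["shape"])
    else:
        raise ValueError(f"unsupported movie format {path.suffix!r}")

    if frames.ndim != 3:
        raise ValueError("movie must decode to T x H x W frames")
    if frames.dtype == np.uint8:
        frames = frames.astype(np.uint16)
        meta["promoted_from"] = "uint8"

    mask = None
    if "geometry" in sidecar:
        mask = DishGeometry.from_dict(sidecar["geometry"]).mask
    return MovieStack(
        frames=frames, fps=float(sidecar["fps"]),
        pixel_pitch_mm=float(sidecar["pixel_pitch_mm"]),
        polarity=sidecar["polarity"],
        modality=sidecar.get("modality", "calcium_dye"),
        mask=mask, kind=sidecar.get("kind", "raw"), meta=meta,
    )


def write_truth(truth: WaveTruth, basepath: str | Path) -> tuple[Path, Path]:
    """Export ground truth: 32-bit float TIFF of activation fields + JSON."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    tif = basepath.with_suffix(".truth.tif")
    js = basepath.with_suffix(".truth.json")
    tifffile.imwrite(tif, truth.activation_field.astype(np.float32),
                     photometric="minisblack")
    js.write_text(json.dumps(_json_safe({
        "speed_cm_s": truth.speed_cm_s,
        "beat_times_ms": truth.beat_times_ms,
        "origin": truth.origin,
        "regime": truth.regime,
        "meta": {k: v for k, v in truth.meta.items()
                 if not isinstance(v, np.ndarray)},
    }), indent=1, sort_keys=True))
    return tif, js


def read_truth(basepath: str | Path) -> WaveTruth:
    basepath = Path(basepath)
    field_ = tifffile.imread(basepath.with_suffix(".truth.tif"))
    if field_.ndim == 2:
        field_ = field_[None]
    d = json.loads(basepath.with_suffix(".truth.json").read_text())
    return WaveTruth(
        activation_field=field_.astype(float),
        beat_times_ms=np.asarray(d["beat_times_ms"], dtype=float),
        origin=tuple(d["origin"]), regime=d["regime"],
        speed_cm_s=d["speed_cm_s"], meta=d.get("meta", {}),
    )


def write_activation_map(amap: ActivationMap, basepath: str | Path) -> tuple[Path, Path]:
    """Export an activation map as float32 TIFF and tidy CSV (row, col, time_ms)."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    tif = basepath.with_suffix(".tif")
    csv = basepath.with_suffix(".csv")
    tifffile.imwrite(tif, amap.times_ms.astype(np.float32),
                     photometric="minisblack")
    rr, cc = np.nonzero(amap.valid)
    with open(csv, "w") as fh:
        fh.write("row,col,time_ms\n")
        for r, c in zip(rr, cc):
            fh.write(f"{r},{c},{amap.times_ms[r, c]:.6g}\n")
    return tif, csv


def write_trace_csv(trace: Trace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("time_ms,value\n")
        for t, v in zip(trace.times_ms, trace.values):
            fh.write(f"{t:.6g},{v:.8g}\n")
    return path


def isochrone_figure(amap: ActivationMap, path: str | Path,
                     spacing_ms: float | None = None) -> Path:
    """Activation map with isochrone contours, saved as PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.ma.masked_invalid(amap.times_ms)
    if spacing_ms is None:
        span = float(t.max() - t.min()) if t.count() else 1.0
        spacing_ms = max(span / 10.0, amap.frame_period_ms)
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(t, cmap="viridis", interpolation="nearest")
    if t.count() and t.max() > t.min():
        levels = np.arange(float(t.min()), float(t.max()), spacing_ms)
        if levels.size >= 2:
            ax.contour(t, levels=levels, colors="white", linewidths=0.6)
    fig.colorbar(im, ax=ax, label="activation time (ms)")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


@dataclass
class RunManifest:
    """Provenance of one analysis run."""

    tool_version: str = __version__
    config_hash: str = ""
    input_checksums: dict = field(default_factory=dict)
    timestamp: str = ""
    warnings: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    @staticmethod
    def checksum(path: str | Path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        return h.hexdigest()

    def finalize(self, config: dict | None = None) -> "RunManifest":
        if config is not None:
            blob = json.dumps(_json_safe(config), sort_keys=True).encode()
            self.config_hash = hashlib.sha256(blob).hexdigest()
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        return self

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(_json_safe(self.__dict__), indent=1,
                                   sort_keys=True))
        return path
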