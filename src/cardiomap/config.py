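"""Run configuration with lossless YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved parameters of one simulate/analyze/compare run.

    Every analysis embeds its resolved config in the output manifest so a
    run can be reproduced exactly.  CLI flags override file values.
    """

    input: str | None = None
    outdir: str = "cardiomap_out"
    seed: int = 0
    # geometry / optics (simulation)
    shape: str = "circle"
    diameter_mm: float = 35.0
    width_mm: float | None = None
    length_mm: float | None = None
    pixel_pitch_mm: float = 0.2
    grid_rows: int = 180
    grid_cols: int = 180
    speed_cm_s: float = 22.9
    pacing_hz: float = 3.0
    duration_s: float = 1.0
    dff_true: float = 0.1143
    f0: float = 1000.0
    fps: float = 300.0
    modality: str = "calcium_dye"
    noise: str = "none"
    noise_gain: float = 1.0
    noise_sigma: float = 0.0
    # analysis thresholds
    n_sites: int = 4
    site_size_mm: float = 3.0
    snr_floor: float = 5.0
    map_smooth_ms: float | None = None
    cv_step_mm: float = 0.5
    trim_outliers: bool = True
    fib_cv_threshold: float = 0.1
    fib_corr_threshold: float = 0.8
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in d.items() if k in known}
        unknown = {k: v for k, v in d.items() if k not in known}
        if unknown:
            kwargs.setdefault("extra", {}).update(unknown)
        return cls(**kwargs)
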