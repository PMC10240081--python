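"""Synthetic paired drug experiments on simulated monolayers.

Reproduces the structure of a pre/post treatment run: each dish is recorded
before treatment (control) and again after, with the drug modeled as a
multiplicative effect — a calcium-channel blocker scales the transient
amplitude, a sodium-channel blocker scales the conduction velocity.  Dishes
vary biologically around typical NRVM monolayer values; the measurement
chain (render with shot noise, then analyze) is the same one applied to any
recorded movie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activation import build_activation_map, segment_beats
from .geometry import DishGeometry, make_geometry
from .metrics import (compare_treatment, conduction_velocity_line,
                      diameter_line, sample_sites, site_trace,
                      transient_amplitude)
from .signals import compute_dff, estimate_baseline
from .synth import (OpticsModel, scale_amplitude, scale_speed,
                    render_movie, simulate_planar_wave)

__all__ = ["ExperimentDesign", "measure_amplitudes", "measure_cv",
           "run_amplitude_arm", "run_cv_arm", "run_demo_experiment"]

# typical NRVM monolayer study conditions: control endpoint levels and their
# between-dish spread, and the drug effect sizes used by the demo experiment
CONTROL_DFF = 0.1143
DFF_DISH_CV = 0.15
CONTROL_CV_CM_S = 22.9
CV_DISH_SD = 1.6
NIFEDIPINE_AMPLITUDE_SCALE = 0.0591 / 0.1143
FLECAINIDE_SPEED_SCALE = 17.9 / 22.9


@dataclass
class ExperimentDesign:
    """Sizes and acquisition settings for one synthetic arm."""

    grid: int = 120
    pixel_pitch_mm: float = 0.3
    fps: float = 300.0
    amp_pacing_hz: float = 2.0
    amp_duration_s: float = 3.0
    cv_pacing_hz: float = 3.0
    cv_duration_s: float = 1.0
    points_per_dish: int = 4
    site_size_mm: float = 3.0
    noise: str = "shot"
    f0: float = 1000.0

    def geometry(self) -> DishGeometry:
        return make_geometry("circle", diameter_mm=35.0,
                             pixel_pitch_mm=self.pixel_pitch_mm,
                             grid_rows=self.grid, grid_cols=self.grid)


def measure_amplitudes(movie, n_sites: int = 4,
                       site_size_mm: float = 3.0) -> list[float]:
    """Site-mean dF/F amplitudes of one movie (one value per site)."""
    dffm = compute_dff(movie, estimate_baseline(movie))
    beats = segment_beats(dffm, stimulus_times_ms=movie.meta.get("beat_times_ms"))
    from .pipeline import geometry_from_movie
    geom = geometry_from_movie(movie)
    origin = movie.meta.get("origin")
    sites = sample_sites(geom, k=n_sites, size_mm=site_size_mm,
                         origin=tuple(origin) if origin else None)
    return [transient_amplitude(site_trace(dffm, s), beats).mean_dff
            for s in sites]


def measure_cv(movie, beat_index: int = 1) -> float:
    """Diameter-line conduction velocity (cm/s) of one movie."""
    dffm = compute_dff(movie, estimate_baseline(movie))
    beats = segment_beats(dffm, stimulus_times_ms=movie.meta.get("beat_times_ms"))
    idx = beat_index if len(beats) > beat_index else 0
    amap = build_activation_map(dffm, beats[idx], beat_index=idx)
    from .pipeline import geometry_from_movie
    geom = geometry_from_movie(movie)
    origin = movie.meta.get("origin")
    line = diameter_line(geom, origin=tuple(origin) if origin else None)
    est = conduction_velocity_line(amap, line, movie.pixel_pitch_mm)
    return est.speed_cm_s


def run_amplitude_arm(
    n_dishes: int,
    amplitude_scale: float,
    seed: int,
    design: ExperimentDesign | None = None,
    label: str = "drug",
) -> pd.DataFrame:
    """Paired pre/post amplitude measurements for one treatment arm.

    Each dish gets its own control amplitude (log-normal spread around the
    typical level); the treatment multiplies the true amplitude by
    ``amplitude_scale``; both recordings are rendered with shot noise and
    measured at ``points_per_dish`` diameter sites.
    """
    design = design or ExperimentDesign()
    geom = design.geometry()
    rng = np.random.default_rng(seed)
    truth = simulate_planar_wave(geom, speed_cm_s=CONTROL_CV_CM_S,
                                 pacing_hz=design.amp_pacing_hz,
                                 duration_s=design.amp_duration_s)
    rows = []
    for dish in range(n_dishes):
        dff_pre = CONTROL_DFF * rng.lognormal(0.0, DFF_DISH_CV)
        optics = OpticsModel(F0=design.f0, dff_true=dff_pre, fps=design.fps,
                             noise=design.noise)
        pre_movie = render_movie(truth, optics, geom, seed=rng)
        post_movie = render_movie(truth, scale_amplitude(optics, amplitude_scale),
                                  geom, seed=rng)
        pre = measure_amplitudes(pre_movie, design.points_per_dish,
                                 design.site_size_mm)
        post = measure_amplitudes(post_movie, design.points_per_dish,
                                  design.site_size_mm)
        for i, (a, b) in enumerate(zip(pre, post)):
            rows.append({"arm": label, "dish_id": dish, "site": f"site{i + 1}",
                         "metric": "dff", "pre": a, "post": b,
                         "true_pre": dff_pre,
                         "true_post": dff_pre * amplitude_scale})
    return pd.DataFrame(rows)


def run_cv_arm(
    n_dishes: int,
    speed_scale: float,
    seed: int,
    design: ExperimentDesign | None = None,
    label: str = "drug",
) -> pd.DataFrame:
    """Paired pre/post conduction-velocity measurements for one arm."""
    design = design or ExperimentDesign()
    geom = design.geometry()
    rng = np.random.default_rng(seed)
    rows = []
    for dish in range(n_dishes):
        speed_pre = max(5.0, rng.normal(CONTROL_CV_CM_S, CV_DISH_SD))
        truth = simulate_planar_wave(geom, speed_cm_s=speed_pre,
                                     pacing_hz=design.cv_pacing_hz,
                                     duration_s=design.cv_duration_s)
        optics = OpticsModel(F0=design.f0, fps=design.fps, noise=design.noise)
        pre_movie = render_movie(truth, optics, geom, seed=rng)
        post_movie = render_movie(scale_speed(truth, speed_scale), optics,
                                  geom, seed=rng)
        rows.append({"arm": label, "dish_id": dish, "site": "diameter",
                     "metric": "cv",
                     "pre": measure_cv(pre_movie),
                     "post": measure_cv(post_movie),
                     "true_pre": speed_pre,
                     "true_post": speed_pre * speed_scale})
    return pd.DataFrame(rows)


def run_demo_experiment(seed: int = 0,
                        design: ExperimentDesign | None = None) -> dict:
    """Full synthetic drug study: amplitude and CV arms with vehicle controls.

    Returns a dict with the tidy per-measurement table and the per-arm
    comparison summaries (group means, SD, paired differences, ratio of
    means).
    """
    design = design or ExperimentDesign()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]

    frames = [
        run_amplitude_arm(3, NIFEDIPINE_AMPLITUDE_SCALE, seeds[0],
                          design, label="nifedipine"),
        run_amplitude_arm(4, 1.0, seeds[1], design, label="vehicle_dff"),
        run_cv_arm(4, FLECAINIDE_SPEED_SCALE, seeds[2], design,
                   label="flecainide"),
        run_cv_arm(4, 1.0, seeds[3], design, label="vehicle_cv"),
    ]
    table = pd.concat(frames, ignore_index=True)

    comparisons = {}
    for arm, grp in table.groupby("arm", sort=True):
        plan = {"dishes": int(grp["dish_id"].nunique()),
                "points_per_dish": int(len(grp) / grp["dish_id"].nunique())}
        cmp_ = compare_treatment(grp["pre"].to_numpy(), grp["post"].to_numpy(),
                                 metric=str(grp["metric"].iloc[0]), plan=plan)
        comparisons[arm] = cmp_.summary
    return {"table": table, "comparisons": comparisons, "seed": seed}
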