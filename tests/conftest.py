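import numpy as np
import pytest

import cardiomap as cm


@pytest.fixture(scope="session")
def small_geom():
    """35 mm dish at coarse 0.5 mm/px calibration (72x72 grid) for speed."""
    return cm.make_geometry(pixel_pitch_mm=0.5, grid_rows=72, grid_cols=72)


@pytest.fixture(scope="session")
def planar_truth_small(small_geom):
    return cm.simulate_planar_wave(small_geom, speed_cm_s=22.9,
                                   pacing_hz=2.0, duration_s=1.5)


@pytest.fixture(scope="session")
def clean_movie_small(small_geom, planar_truth_small):
    optics = cm.OpticsModel(noise="none")
    return cm.render_movie(planar_truth_small, optics, small_geom, seed=0)


@pytest.fixture(scope="session")
def rd_geom():
    return cm.make_geometry(pixel_pitch_mm=0.35, grid_rows=100, grid_cols=100)


@pytest.fixture(scope="session")
def rd_reentry(rd_geom):
    return cm.simulate_reaction_diffusion(rd_geom, init="cross_field",
                                          duration_s=3.0)


@pytest.fixture(scope="session")
def rd_movie(rd_geom, rd_reentry):
    truth, state = rd_reentry
    optics = cm.OpticsModel(noise="shot")
    return cm.render_movie(truth, optics, rd_geom, state_movie=state, seed=3)


def oracle_first_crossing(values, fps, frac=0.5):
    """Independent exhaustive scan for the 50%-rise time of one window.

    Same contract as the production estimator: base is the pre-peak minimum,
    the rising limb starts at the last pre-peak sample below base + 0.25*amp,
    and the first upward crossing of base + frac*amp on that limb wins, with
    linear interpolation.  Returns NaN when no crossing exists.
    """
    v = np.asarray(values, dtype=float)
    pk = int(np.argmax(v))
    base = float(v[:pk + 1].min())
    amp = float(v[pk]) - base
    if amp <= 0:
        return float("nan")
    level = base + frac * amp
    lo = base + 0.25 * amp
    feet = [i for i in range(pk + 1) if v[i] < lo]
    if not feet:
        return float("nan")
    foot = max(feet)
    for i in range(foot + 1, pk + 1):
        if v[i - 1] < level <= v[i]:
            frame = (i - 1) + (level - v[i - 1]) / (v[i] - v[i - 1])
            return frame * 1000.0 / fps
    return float("nan")
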