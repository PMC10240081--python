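import numpy as np
import pytest

import cardiomap as cm
from cardiomap.activation import (BeatWindow, activation_time,
                                  build_activation_map, classify_rhythm,
                                  segment_beats)
from cardiomap.signals import MovieStack, Trace, compute_dff, estimate_baseline

from conftest import oracle_first_crossing


class TestActivationTime:
    def test_linear_ramp_midpoint(self):
        # linear 0 -> 1 over frames 10..20 at 400 fps (2.5 ms/frame)
        v = np.concatenate([np.zeros(10), np.linspace(0, 1, 11)])
        t = activation_time(v, fps=400.0)
        assert t == pytest.approx(15 * 2.5)

    def test_subframe_linear_interpolation(self):
        # f(25 ms) = 0.2, f(30 ms) = 0.8 with base 0 peak 1 -> 27.5 ms
        v = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.2, 0.8, 1.0])
        t = activation_time(v, fps=200.0)  # 5 ms per frame
        assert t == pytest.approx(27.5)

    def test_below_noise_floor_returns_nan(self):
        v = np.full(20, 0.001)
        assert np.isnan(activation_time(v, fps=300.0))

    def test_agrees_with_exhaustive_search_on_randomized_windows(self):
        rng = np.random.default_rng(12345)
        tmpl = cm.calcium_template()
        fps = 300.0
        n_checked = 0
        for _ in range(1000):
            n = int(rng.integers(30, 200))
            tt = np.arange(n) * 1000.0 / fps
            v = rng.normal(0, 0.01, n)
            if rng.random() < 0.8:  # most windows contain a transient
                act = rng.uniform(20.0, tt[-1] - 50.0)
                amp = rng.uniform(0.02, 0.2)
                v += amp * tmpl.evaluate(tt - act)
            if rng.random() < 0.3:  # residual decay entering the window
                v += 0.1 * np.exp(-tt / 150.0)
            ours = activation_time(v, fps=fps, snr_floor=0.0, abs_floor=1e-9)
            ref = oracle_first_crossing(v, fps)
            if np.isnan(ref):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(ref, abs=1e-9)
                n_checked += 1
        assert n_checked > 500


class TestSegmentBeats:
    def test_windows_from_stimulus_times(self):
        tr = Trace(values=np.zeros(600), fps=400.0)
        wins = segment_beats(tr, stimulus_times_ms=[0.0, 500.0, 1000.0])
        assert [(w.start_ms, w.end_ms) for w in wins] == \
            [(0.0, 500.0), (500.0, 1000.0), (1000.0, 1500.0)]

    def test_auto_detection_recovers_paced_cycle_count(self, small_geom):
        truth = cm.simulate_planar_wave(small_geom, speed_cm_s=22.9,
                                        pacing_hz=3.0, duration_s=2.0)
        mv = cm.render_movie(truth, cm.OpticsModel(noise="none"),
                             small_geom, seed=0)
        dffm = compute_dff(mv, estimate_baseline(mv))
        wins = segment_beats(dffm)
        assert len(wins) == 6

    def test_flat_trace_yields_no_windows(self):
        tr = Trace(values=np.zeros(500), fps=300.0)
        with pytest.warns(UserWarning, match="no activity"):
            assert segment_beats(tr) == []


class TestBuildActivationMap:
    def test_noise_free_map_matches_truth_within_one_frame(
            self, small_geom, planar_truth_small, clean_movie_small):
        dffm = compute_dff(clean_movie_small,
                           estimate_baseline(clean_movie_small))
        beats = segment_beats(
            dffm, stimulus_times_ms=clean_movie_small.meta["beat_times_ms"])
        amap = build_activation_map(dffm, beats[1], beat_index=1, smooth_ms=0)
        tru = planar_truth_small.activation_field[1] \
            - planar_truth_small.beat_times_ms[1]
        err = np.abs(amap.times_ms - tru)[amap.valid]
        assert amap.valid.sum() > 0.95 * small_geom.mask.sum()
        assert err.max() <= amap.frame_period_ms

    def test_simultaneous_flash_gives_uniform_times(self, small_geom):
        # near-infinite speed: the whole dish activates in one instant
        truth = cm.simulate_planar_wave(small_geom, speed_cm_s=1e6,
                                        pacing_hz=2.0, duration_s=1.0)
        mv = cm.render_movie(truth, cm.OpticsModel(noise="none"),
                             small_geom, seed=0)
        dffm = compute_dff(mv, estimate_baseline(mv))
        amap = build_activation_map(dffm, BeatWindow(0.0, 500.0),
                                    smooth_ms=0)
        t = amap.times_ms[amap.valid]
        assert t.max() - t.min() <= amap.frame_period_ms

    def test_flat_movie_is_unmappable(self, small_geom):
        frames = np.full((60, 72, 72), 1000.0)
        mv = MovieStack(frames=frames, fps=300.0, pixel_pitch_mm=0.5,
                        mask=small_geom.mask, kind="dff")
        with pytest.raises(ValueError, match="unmappable"):
            build_activation_map(mv, BeatWindow(0.0, 200.0))

    def test_monotone_along_propagation_axis(self, small_geom,
                                             planar_truth_small,
                                             clean_movie_small):
        dffm = compute_dff(clean_movie_small,
                           estimate_baseline(clean_movie_small))
        beats = segment_beats(
            dffm, stimulus_times_ms=clean_movie_small.meta["beat_times_ms"])
        amap = build_activation_map(dffm, beats[1], beat_index=1, smooth_ms=0)
        r, c = planar_truth_small.origin
        row = amap.times_ms[r, :c + 1][::-1]  # origin outward
        row = row[np.isfinite(row)]
        assert np.all(np.diff(row) >= -1e-6)

    def test_doubling_fps_halves_discretization_bound(self, small_geom):
        errs = {}
        for fps in (300.0, 600.0):
            truth = cm.simulate_planar_wave(small_geom, speed_cm_s=22.9,
                                            pacing_hz=2.0, duration_s=1.5)
            mv = cm.render_movie(truth, cm.OpticsModel(noise="none", fps=fps),
                                 small_geom, seed=0)
            dffm = compute_dff(mv, estimate_baseline(mv))
            beats = segment_beats(dffm,
                                  stimulus_times_ms=mv.meta["beat_times_ms"])
            amap = build_activation_map(dffm, beats[1], beat_index=1,
                                        smooth_ms=0)
            tru = truth.activation_field[1] - truth.beat_times_ms[1]
            errs[fps] = np.abs(amap.times_ms - tru)[amap.valid].max()
        assert errs[300.0] <= 1000.0 / 300.0
        assert errs[600.0] <= 0.5 * (1000.0 / 300.0)

    def test_shot_noise_map_error_95th_percentile(self, small_geom,
                                                  planar_truth_small):
        optics = cm.OpticsModel(F0=1000.0, dff_true=0.1, noise="shot")
        mv = cm.render_movie(planar_truth_small, optics, small_geom, seed=8)
        dffm = compute_dff(mv, estimate_baseline(mv))
        beats = segment_beats(dffm, stimulus_times_ms=mv.meta["beat_times_ms"])
        # noisy-data settings: smoothing ~ half the upstroke, 2x2 binning
        amap = build_activation_map(dffm, beats[1], beat_index=1,
                                    smooth_ms=16.7, spatial_bin=2)
        tru = planar_truth_small.activation_field[1] \
            - planar_truth_small.beat_times_ms[1]
        err = np.abs(amap.times_ms - tru)[amap.valid]
        assert np.percentile(err, 95) <= 2 * amap.frame_period_ms


class TestClassifyRhythm:
    def test_paced_planar_movie(self, small_geom):
        truth = cm.simulate_planar_wave(small_geom, speed_cm_s=22.9,
                                        pacing_hz=3.0, duration_s=2.0)
        mv = cm.render_movie(truth, cm.OpticsModel(noise="shot"),
                             small_geom, seed=2)
        label = classify_rhythm(mv, pacing_hz=3.0)
        assert label.label == "paced"
        assert label.dominant_freq_hz == pytest.approx(3.0, rel=0.1)
        assert label.cycle_length_cv < 0.1

    def test_reentry_movie_is_fibrillatory(self, rd_movie):
        label = classify_rhythm(rd_movie, pacing_hz=3.0)
        assert label.label == "fibrillatory"

    def test_silent_movie_is_undetermined(self, small_geom):
        rng = np.random.default_rng(0)
        frames = rng.poisson(1000, size=(300, 72, 72)).astype(np.uint16)
        mv = MovieStack(frames=frames, fps=300.0, pixel_pitch_mm=0.5,
                        mask=small_geom.mask)
        label = classify_rhythm(mv)
        assert label.label == "undetermined"
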