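import numpy as np
import pytest

import cardiomap as cm
from cardiomap.synth import BarkleyKinetics


class TestTransientTemplate:
    def test_waveform_shape_contract(self):
        for tmpl in (cm.calcium_template(), cm.action_potential_template()):
            w = tmpl.waveform(fps=1000.0)
            assert w[0] == pytest.approx(0.0, abs=1e-12)
            assert w.max() == pytest.approx(1.0, abs=1e-6)
            assert w[-1] < 0.05
            upstroke = w[:int(tmpl.rise_ms) + 1]
            assert np.all(np.diff(upstroke) >= -1e-12)

    def test_half_rise_is_at_activation_time(self):
        tmpl = cm.calcium_template()
        assert tmpl.evaluate(np.array(0.0)) == pytest.approx(0.5)


class TestPlanarWave:
    def test_activation_difference_follows_speed(self, small_geom):
        # 100 cm/s = 1 mm/ms, so 10 mm apart means 10 ms apart
        truth = cm.simulate_planar_wave(small_geom, speed_cm_s=100.0,
                                        pacing_hz=1.0, duration_s=1.0,
                                        direction=(0.0, -1.0))
        r, c = truth.origin
        a = truth.activation_field[0]
        # 10 mm along the propagation row = 20 px at 0.5 mm/px
        assert a[r, c - 20] - a[r, c] == pytest.approx(10.0, abs=1e-9)

    def test_control_speed_arithmetic(self, small_geom):
        truth = cm.simulate_planar_wave(small_geom, speed_cm_s=22.9,
                                        pacing_hz=1.0, duration_s=1.0,
                                        direction=(0.0, -1.0))
        r, c = truth.origin
        a = truth.activation_field[0]
        # 17.5 mm apart at 0.229 mm/ms
        dt = a[r, c - 35] - a[r, c]
        assert dt == pytest.approx(17.5 / 0.229, rel=1e-12)

    def test_beat_onsets_are_periodic(self, small_geom):
        truth = cm.simulate_planar_wave(small_geom, speed_cm_s=20.0,
                                        pacing_hz=2.0, duration_s=3.0)
        assert np.allclose(truth.beat_times_ms,
                           [0, 500, 1000, 1500, 2000, 2500])

    def test_kinematic_exactness_on_random_pixel_pairs(self, small_geom):
        truth = cm.simulate_planar_wave(small_geom, speed_cm_s=22.9,
                                        pacing_hz=2.0, duration_s=1.0)
        rng = np.random.default_rng(0)
        yy, xx = np.nonzero(small_geom.mask)
        a = truth.activation_field[0]
        y, x = small_geom.pixel_coords_mm()
        oy = (truth.origin[0] + 0.5) * small_geom.pixel_pitch_mm
        ox = (truth.origin[1] + 0.5) * small_geom.pixel_pitch_mm
        # propagation axis: from origin toward mask centroid
        d = np.array([yy.mean() + 0.5 - truth.origin[0] - 0.5,
                      xx.mean() + 0.5 - truth.origin[1] - 0.5])
        d = d / np.hypot(*d)
        for _ in range(200):
            i, j = rng.integers(0, yy.size, 2)
            p1, p2 = (yy[i], xx[i]), (yy[j], xx[j])
            proj1 = (y[p1] - oy) * d[0] + (x[p1] - ox) * d[1]
            proj2 = (y[p2] - oy) * d[0] + (x[p2] - ox) * d[1]
            if proj1 < 0 or proj2 < 0:
                continue
            dt = a[p2] - a[p1]
            assert dt * 0.229 == pytest.approx(proj2 - proj1, abs=1e-9)

    def test_origin_outside_mask_rejected(self, small_geom):
        with pytest.raises(ValueError, match="outside"):
            cm.simulate_planar_wave(small_geom, speed_cm_s=20.0,
                                    pacing_hz=1.0, duration_s=1.0,
                                    origin=(0, 0))


class TestDrugEffects:
    def test_amplitude_scale_reproduces_post_drug_level(self):
        optics = cm.OpticsModel(dff_true=0.1143)
        scaled = cm.apply_drug_effect(optics, "amplitude_scale",
                                      0.0591 / 0.1143)
        assert scaled.dff_true == pytest.approx(0.0591)

    def test_speed_scale_reproduces_post_drug_level(self, small_geom):
        truth = cm.simulate_planar_wave(small_geom, speed_cm_s=22.9,
                                        pacing_hz=2.0, duration_s=1.0)
        scaled = cm.apply_drug_effect(truth, "speed_scale", 17.9 / 22.9)
        assert scaled.speed_cm_s == pytest.approx(17.9)
        # activation delays rescale by exactly 1/s
        rel0 = truth.activation_field - truth.beat_times_ms[:, None, None]
        rel1 = scaled.activation_field - truth.beat_times_ms[:, None, None]
        m = small_geom.mask
        assert np.allclose(rel1[:, m], rel0[:, m] * (22.9 / 17.9), rtol=1e-12)

    def test_unit_scale_is_identity(self, small_geom, planar_truth_small):
        scaled = cm.scale_speed(planar_truth_small, 1.0)
        m = small_geom.mask
        assert np.allclose(scaled.activation_field[:, m],
                           planar_truth_small.activation_field[:, m])

    def test_speed_scale_refuses_reaction_diffusion(self, rd_reentry):
        truth, _ = rd_reentry
        with pytest.raises(ValueError, match="kinetics"):
            cm.scale_speed(truth, 0.5)

    @pytest.mark.parametrize("factor", [0.0, -1.0])
    def test_nonpositive_factor_rejected(self, factor):
        with pytest.raises(ValueError):
            cm.scale_amplitude(cm.OpticsModel(), factor)


class TestRenderMovie:
    def test_peak_counts_match_amplitude(self, small_geom):
        truth = cm.simulate_planar_wave(small_geom, speed_cm_s=22.9,
                                        pacing_hz=2.0, duration_s=1.0)
        optics = cm.OpticsModel(F0=1000.0, dff_true=0.1143, noise="none")
        mv = cm.render_movie(truth, optics, small_geom, seed=0)
        # 1000 * 1.1143 = 1114.3 -> 1114 after round-half-up quantization
        assert mv.frames[:, small_geom.mask].max() == 1114

    def test_gevi_polarity_dims_on_activation(self, small_geom):
        truth = cm.simulate_planar_wave(small_geom, speed_cm_s=22.9,
                                        pacing_hz=2.0, duration_s=1.0)
        optics = cm.OpticsModel(modality="gevi", F0=1000.0, dff_true=0.05,
                                noise="none", fps=400.0)
        mv = cm.render_movie(truth, optics, small_geom, seed=0)
        assert mv.polarity == "negative"
        assert mv.frames[:, small_geom.mask].min() == 950
        assert mv.frames[0, small_geom.mask].max() <= 1000

    def test_rendering_is_deterministic(self, small_geom, planar_truth_small):
        optics = cm.OpticsModel(noise="shot")
        m1 = cm.render_movie(planar_truth_small, optics, small_geom, seed=9)
        m2 = cm.render_movie(planar_truth_small, optics, small_geom, seed=9)
        assert np.array_equal(m1.frames, m2.frames)

    @pytest.mark.parametrize("gain", [1.0, 4.0])
    def test_shot_noise_variance_tracks_gain_times_mean(self, small_geom, gain):
        truth = cm.simulate_planar_wave(small_geom, speed_cm_s=22.9,
                                        pacing_hz=1.0, duration_s=1.0)
        optics = cm.OpticsModel(F0=1000.0, dff_true=0.0, noise="shot",
                                noise_gain=gain)
        mv = cm.render_movie(truth, optics, small_geom, seed=4,
                             duration_s=0.1)
        samples = mv.frames[:, small_geom.mask].astype(float).ravel()
        assert samples.size >= 1e4
        assert samples.var() == pytest.approx(gain * samples.mean(), rel=0.1)

    def test_unresolved_upstroke_rejected(self, small_geom, planar_truth_small):
        optics = cm.OpticsModel(modality="vsd", fps=300.0)  # 5 ms rise
        with pytest.raises(ValueError, match="upstroke"):
            cm.render_movie(planar_truth_small, optics, small_geom)

    def test_saturation_warns_with_fraction(self, small_geom, planar_truth_small):
        optics = cm.OpticsModel(F0=60000.0, dff_true=0.2, noise="none")
        with pytest.warns(UserWarning, match="saturation"):
            cm.render_movie(planar_truth_small, optics, small_geom, seed=0)


class TestReactionDiffusion:
    def test_point_stimulation_extinguishes(self, rd_geom):
        truth, state = cm.simulate_reaction_diffusion(
            rd_geom, init="point_stim", duration_s=2.0)
        assert truth.regime == "paced"
        # single outward target wave: one upstroke almost everywhere (the
        # forced stimulus disc and wave-back can flicker an extra crossing)
        counts = truth.meta["upstroke_counts"][rd_geom.mask]
        assert np.median(counts) == 1
        assert counts.max() <= 3
        assert state[-1].max() < 1e-3  # activity has died out

    def test_point_stimulation_isochrones_monotone_with_distance(self, rd_geom):
        truth, _ = cm.simulate_reaction_diffusion(
            rd_geom, init="point_stim", duration_s=2.0)
        act = truth.activation_field[0]
        d = rd_geom.distance_mm(truth.origin)
        m = rd_geom.mask & np.isfinite(act)
        # bin distances; mean activation time increases with distance
        bins = np.linspace(0, d[m].max(), 12)
        idx = np.digitize(d[m], bins)
        means = [act[m][idx == k].mean() for k in range(1, 12)
                 if (idx == k).sum() > 10]
        assert np.all(np.diff(means) > 0)

    def test_cross_field_sustains_reentry(self, rd_geom, rd_reentry):
        truth, state = rd_reentry
        assert truth.regime == "fibrillatory"
        counts = truth.meta["upstroke_counts"][rd_geom.mask]
        # re-entry: far more upstrokes than any paced protocol would give
        assert np.median(counts) >= 3
        assert (state[-int(0.1 * len(state)):] > 0.5).any()

    def test_no_diffusion_means_no_propagation(self, rd_geom):
        kin = BarkleyKinetics(D=0.0, dt=0.1)
        truth, _ = cm.simulate_reaction_diffusion(
            rd_geom, kinetics=kin, init="point_stim", duration_s=0.5)
        counts = truth.meta["upstroke_counts"]
        stim = counts > 0
        d = rd_geom.distance_mm(truth.origin)
        # only the directly stimulated disc fires; neighbors never do
        assert d[stim].max() <= 4 * rd_geom.pixel_pitch_mm

    def test_unstable_time_step_rejected_naming_bound(self, rd_geom):
        kin = BarkleyKinetics(dt=0.5)  # bound is dx^2/(4D) = 0.25
        with pytest.raises(ValueError, match="stability bound"):
            cm.simulate_reaction_diffusion(rd_geom, kinetics=kin,
                                           duration_s=0.1)
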