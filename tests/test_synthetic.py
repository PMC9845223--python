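"""Synthetic tracking generator: determinism, FS fidelity, noise, structure."""

import numpy as np
import pandas as pd
import pytest

import fsmotion as fm
from fsmotion.kinematics import compute_velocity, speed_distribution
from fsmotion.motion import KineticParams, coef_A, coef_B
from fsmotion.synthetic import ConfigError, add_noise, generate_sprint_ensemble


class TestGeneratorConfig:
    def test_invalid_config_lists_fields(self):
        cfg = fm.GeneratorConfig(n_outfield=0, noise_sigma=-1.0)
        with pytest.raises(ConfigError) as exc:
            cfg.validate()
        assert "n_outfield" in exc.value.fields
        assert "noise_sigma" in exc.value.fields

    def test_transition_probabilities_checked(self):
        cfg = fm.GeneratorConfig()
        cfg.state_transitions = {"walk": {"jog": 0.5, "sprint": 0.2}}
        with pytest.raises(ConfigError):
            cfg.validate()


class TestGenerateDataset:
    def test_seeded_determinism(self):
        cfg = fm.GeneratorConfig(n_outfield=2, n_segments=1, segment_duration=30.0, seed=42)
        a = fm.generate_dataset(cfg).to_dataframe()
        b = fm.generate_dataset(cfg).to_dataframe()
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        base = dict(n_outfield=2, n_segments=1, segment_duration=30.0)
        a = fm.generate_dataset(fm.GeneratorConfig(seed=1, **base)).to_dataframe()
        b = fm.generate_dataset(fm.GeneratorConfig(seed=2, **base)).to_dataframe()
        assert not np.allclose(a["x_m"], b["x_m"])

    def test_uniform_time_grid_and_roles(self, small_dataset):
        for seg in small_dataset:
            seg.validate()  # raises on non-uniform grids
        df = small_dataset.to_dataframe()
        assert set(df["role"].unique()) == {"OUT", "GK"}

    def test_single_sprint_state_matches_closed_form(self):
        # one state, one direction, no noise: the trajectory IS the closed form
        params = KineticParams(1.3, 8.0)
        cfg = fm.GeneratorConfig(
            n_outfield=1,
            include_goalkeeper=False,
            n_segments=1,
            segment_duration=5.0,
            noise_sigma=0.0,
            state_params={"walk": params, "jog": params, "sprint": params},
            state_mean_dwell={"walk": 1e9, "jog": 1e9, "sprint": 1e9},
            mean_run_duration=1e9,
            pitch_bounds=(10000.0, 10000.0),
            seed=5,
        )
        ds = fm.generate_dataset(cfg)
        xy = ds.segments[0].data[["x_m", "y_m"]].to_numpy()
        # player starts at terminal speed along its initial direction
        t = np.arange(len(xy)) * cfg.sample_interval
        d = np.linalg.norm(xy - xy[0], axis=1)
        a = (1 - np.exp(-params.alpha * t)) / params.alpha
        expected = a * params.vmax + params.vmax * (t - a)  # = vmax * t
        assert np.allclose(d, expected, atol=1e-9)

    def test_outfield_speed_modes_near_walk_and_jog(self, study_dataset):
        vel = pd.concat(
            [compute_velocity(seg) for seg in study_dataset.segments],
            ignore_index=True,
        )
        edges, dens = speed_distribution(vel, role_filter="OUT", bin_width=0.25)
        mids = 0.5 * (edges[1:] + edges[:-1])
        peaks = [
            mids[i]
            for i in range(1, len(dens) - 1)
            if dens[i] >= dens[i - 1] and dens[i] >= dens[i + 1] and dens[i] > 0.05
        ]
        assert any(abs(p - 1.0) <= 0.5 for p in peaks), peaks
        assert any(abs(p - 3.0) <= 0.5 for p in peaks), peaks

    def test_speed_tail_decays(self, study_dataset):
        # log-density slope negative over the 3.5-7 m/s tail
        vel = pd.concat(
            [compute_velocity(seg) for seg in study_dataset.segments],
            ignore_index=True,
        )
        sp = vel.loc[vel["role"] == "OUT", "speed"].to_numpy()
        hist, edges = np.histogram(sp, bins=np.arange(3.5, 7.01, 0.5))
        assert np.all(hist > 0)
        slope = np.polyfit(0.5 * (edges[1:] + edges[:-1]), np.log(hist), 1)[0]
        assert slope < 0

    def test_positions_within_pitch(self):
        cfg = fm.GeneratorConfig(
            n_outfield=3, n_segments=1, segment_duration=60.0, noise_sigma=0.0, seed=9
        )
        df = fm.generate_dataset(cfg).to_dataframe()
        assert df["x_m"].abs().max() <= cfg.pitch_bounds[0] / 2 + 1e-9
        assert df["y_m"].abs().max() <= cfg.pitch_bounds[1] / 2 + 1e-9


class TestAddNoise:
    def test_zero_sigma_is_identity(self, simple_segment):
        out = add_noise(simple_segment, 0.0, seed=1)
        assert out is simple_segment

    def test_white_noise_std(self, simple_segment):
        big = pd.concat([simple_segment.data] * 40, ignore_index=True)
        seg = fm.PlaySegment("S1", big, simple_segment.sample_interval)
        noisy = add_noise(seg, 0.5, seed=3)
        dx = noisy.data["x_m"].to_numpy() - seg.data["x_m"].to_numpy()
        assert dx.std() == pytest.approx(0.5, abs=0.02)
        assert abs(dx.mean()) < 0.02

    def test_seeded_reproducibility(self, simple_segment):
        a = add_noise(simple_segment, 0.5, seed=11).data
        b = add_noise(simple_segment, 0.5, seed=11).data
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_disc_bounded(self, simple_segment):
        noisy = add_noise(simple_segment, 0.5, seed=2, model="uniform_disc")
        dx = noisy.data["x_m"].to_numpy() - simple_segment.data["x_m"].to_numpy()
        dy = noisy.data["y_m"].to_numpy() - simple_segment.data["y_m"].to_numpy()
        assert np.hypot(dx, dy).max() <= 1.0 + 1e-12

    def test_correlated_noise_stationary_std(self, simple_segment):
        big = pd.concat([simple_segment.data] * 40, ignore_index=True)
        seg = fm.PlaySegment("S1", big, simple_segment.sample_interval)
        noisy = add_noise(seg, 0.5, seed=3, correlation_time=2.0)
        dx = noisy.data["x_m"].to_numpy() - seg.data["x_m"].to_numpy()
        assert dx.std() == pytest.approx(0.5, abs=0.05)
        # consecutive-frame jitter is much smaller than the stationary error
        assert np.abs(np.diff(dx[:1000])).std() < 0.1

    def test_negative_sigma_rejected(self, simple_segment):
        with pytest.raises(ValueError):
            add_noise(simple_segment, -0.1)


class TestSprintEnsemble:
    PARAMS = KineticParams(1.23, 14.53)

    def test_standing_start_all_at_distance_B(self):
        ens = generate_sprint_ensemble(self.PARAMS, v0=0.0, delta_t=1.0, n_directions=36, seed=1)
        d = np.linalg.norm(ens.pos1 - ens.pos0, axis=1)
        assert np.allclose(d, coef_B(self.PARAMS, 1.0), atol=1e-12)

    def test_points_on_circle_in_velocity_frame(self):
        from fsmotion.heatmap import velocity_frame_point

        ens = generate_sprint_ensemble(self.PARAMS, v0=6.0, delta_t=1.0, n_directions=720, seed=1)
        a = coef_A(self.PARAMS.alpha, 1.0)
        b = coef_B(self.PARAMS, 1.0)
        for i in range(0, 720, 37):
            p = velocity_frame_point(ens.pos0[i], ens.vel0[i], ens.pos1[i])
            assert np.hypot(p[0] - a * 6.0, p[1]) == pytest.approx(b, abs=1e-9)

    def test_noise_quantile(self):
        ens = generate_sprint_ensemble(
            self.PARAMS, v0=6.0, delta_t=1.0, n_directions=4000, seed=1, noise_sigma=0.5
        )
        clean = generate_sprint_ensemble(
            self.PARAMS, v0=6.0, delta_t=1.0, n_directions=4000, seed=1
        )
        b = coef_B(self.PARAMS, 1.0)
        center = coef_A(self.PARAMS.alpha, 1.0) * clean.vel0
        radial = np.linalg.norm(ens.pos1 - center, axis=1) - b
        assert np.mean(np.abs(radial) <= 1.0) > 0.93  # ~95% within +/- 2 sigma

    def test_seeded_reproducibility(self):
        a = generate_sprint_ensemble(self.PARAMS, 3.0, 1.0, 100, seed=8, noise_sigma=0.3)
        b = generate_sprint_ensemble(self.PARAMS, 3.0, 1.0, 100, seed=8, noise_sigma=0.3)
        assert np.array_equal(a.pos1, b.pos1)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_sprint_ensemble(self.PARAMS, 1.0, 1.0, 0)
        with pytest.raises(ValueError):
            generate_sprint_ensemble(self.PARAMS, -1.0, 1.0, 10)


class TestSprintValidationScenario:
    def test_cruise_mode_generates_valid_bounded_data(self):
        cfg = fm.GeneratorConfig.sprint_validation(
            n_outfield=2, n_segments=1, segment_duration=60.0, seed=6
        )
        ds = fm.generate_dataset(cfg)
        for seg in ds:
            seg.validate()
        df = ds.to_dataframe()
        out = df[df.role == "OUT"]
        assert out.x_m.abs().max() <= cfg.pitch_bounds[0] / 2 + 3.0  # noise margin
        # deterministic given the seed
        df2 = fm.generate_dataset(cfg).to_dataframe()
        pd.testing.assert_frame_equal(df, df2)

    def test_cruise_speeds_cover_fit_range(self):
        cfg = fm.GeneratorConfig.sprint_validation(
            n_outfield=4, n_segments=1, segment_duration=300.0, seed=6, noise_sigma=0.0
        )
        ds = fm.generate_dataset(cfg)
        vel = pd.concat([compute_velocity(s) for s in ds.segments], ignore_index=True)
        sp = vel.loc[vel.role == "OUT", "speed"].to_numpy()
        hist, _ = np.histogram(sp, bins=np.arange(0.0, 6.31, 0.3))
        assert np.all(hist > 0)  # every v0 bin holds steady motion
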