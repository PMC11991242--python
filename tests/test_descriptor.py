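"""Feature-extractor correctness: LPF, differential chirps, energy, windows."""

import logging

import numpy as np
import pytest

from vitalchirp.descriptor import (
    DescriptorWindow,
    FilteredScan,
    analytic_descriptor,
    bandpass,
    descriptor_sequence,
    descriptor_series,
    differential_pair,
    energy,
    lpf_average,
)
from vitalchirp.radar_sim import (
    RadarConfig,
    Trajectory,
    simulate_recording,
    trajectory_displacement,
)

from conftest import make_single_reflector_scene, random_breathing_scene


class TestLpfAverage:
    def test_mean_of_arithmetic_sequence(self):
        train = [([1, 1], [4, 4]), ([2, 2], [5, 5]), ([3, 3], [6, 6])]
        out = lpf_average(train)
        np.testing.assert_array_equal(out.p_bar, [2, 2])
        np.testing.assert_array_equal(out.q_bar, [5, 5])

    def test_idempotent_on_identical_scans(self):
        s = (np.arange(4.0), np.arange(4.0) * 2)
        out = lpf_average([s, s, s])
        np.testing.assert_array_equal(out.p_bar, s[0])

    def test_ragged_lengths_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            lpf_average([([1, 2], [1, 2]), ([1, 2, 3], [1, 2, 3])])

    def test_variance_reduction_is_one_third(self):
        """Averaging 3 i.i.d. Gaussian scans divides the variance by 3."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.0, size=(10_000, 3, 8))
        means = x.mean(axis=1)
        assert means.var() == pytest.approx(1.0 / 3.0, rel=0.05)


class TestDifferentialAndEnergy:
    def test_elementwise_subtraction(self):
        d = differential_pair(
            FilteredScan(np.array([0.5, -1.0]), np.array([2.0, 2.0])),
            FilteredScan(np.array([1.0, 1.0]), np.array([1.0, 1.0])),
        )
        np.testing.assert_array_equal(d[0], [-0.5, -2.0])
        np.testing.assert_array_equal(d[1], [1.0, 1.0])

    def test_no_motion_gives_zero_vectors(self):
        f = FilteredScan(np.ones(4), np.ones(4))
        dp, dq = differential_pair(f, f)
        assert not dp.any() and not dq.any()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            differential_pair(
                FilteredScan(np.ones(3), np.ones(3)),
                FilteredScan(np.ones(4), np.ones(4)),
            )

    def test_energy_examples(self):
        assert energy([1, 1], [1, 1]) == pytest.approx(2.0)
        assert energy([0, 0], [0, 0]) == 0.0
        with pytest.raises(ValueError, match="empty"):
            energy([], [])

    def test_analytic_descriptor_closed_form(self):
        assert analytic_descriptor(1.0, 0.0) == 0.0
        assert analytic_descriptor(1.0, np.pi) == pytest.approx(4.0)
        assert analytic_descriptor(2.0, np.pi / 2) == pytest.approx(8.0)

    def test_energy_matches_closed_form_for_pi_step(self, oracle_config):
        """Single reflector, noise-free, phase step pi: descriptor = 4 A^2."""
        a = make_single_reflector_scene(phase0=0.0)
        b = make_single_reflector_scene(phase0=np.pi)
        pa, qa = (np.asarray(v) for v in _scan(a, oracle_config))
        pb, qb = (np.asarray(v) for v in _scan(b, oracle_config))
        assert energy(pb - pa, qb - qa) == pytest.approx(4.0, rel=1e-12)


def _scan(scene, cfg):
    from vitalchirp.radar_sim import synth_scan

    return synth_scan(scene, cfg, 0.0, cfg.channels[0])


class TestOracleEquivalence:
    def test_descriptor_equals_closed_form_on_random_scenes(self, oracle_config):
        """energy(differential) == 4 A^2 sin^2(2 pi f dd_net / c / ... / 2)
        to 1e-9 relative on randomized single-reflector noise-free scenes."""
        rng = np.random.default_rng(42)
        cfg = oracle_config
        delta_t, delta_steps = 0.25, 5
        for _ in range(20):
            scene = random_breathing_scene(rng)
            refl = scene.reflectors[0]
            rec = simulate_recording(scene, cfg, 2.0, seed=1)
            f = descriptor_series(rec, delta_t)[:, 0]
            t = np.arange(rec.n_trains) * cfg.ts
            d = trajectory_displacement(refl.trajectory, t)
            dphi = 4 * np.pi * cfg.carrier_freq * (d[delta_steps:] - d[:-delta_steps]) / cfg.wave_speed
            oracle = np.array([analytic_descriptor(refl.amplitude, x) for x in dphi])
            np.testing.assert_allclose(f, oracle, rtol=1e-9, atol=1e-9)

    def test_half_wavelength_periodicity(self, oracle_config):
        """Displacements differing by c/(2f) give identical descriptors."""
        cfg = oracle_config
        lam_half = cfg.wave_speed / (2 * cfg.carrier_freq)
        for dd in (0.0003, 0.0011):
            a = _static_step_series(cfg, dd)
            b = _static_step_series(cfg, dd + lam_half)
            np.testing.assert_allclose(a, b, rtol=0, atol=1e-9)


def _static_step_series(cfg, dd):
    """Descriptor for a reflector that jumps by ``dd`` between two scans."""
    from vitalchirp.radar_sim import synth_scan

    base = make_single_reflector_scene(phase0=0.3)
    phi = 4 * np.pi * cfg.carrier_freq * dd / cfg.wave_speed
    moved = make_single_reflector_scene(phase0=0.3 + phi)
    pa, qa = _scan(base, cfg)
    pb, qb = _scan(moved, cfg)
    return energy(pb - pa, qb - qa)


class TestDescriptorSequence:
    def test_static_noise_free_recording_is_all_zero(self, single_channel_config,
                                                     static_scene):
        rec = simulate_recording(static_scene, single_channel_config, 4.0, seed=0)
        wins = descriptor_sequence(rec, 0.25, 2.0)
        assert wins and all(np.allclose(w.values, 0) for w in wins)

    def test_window_accounting(self, single_channel_config, static_scene):
        """Sum of windows = floor((duration - delta_t) / window) per recording."""
        for duration, delta_t, window in ((10.0, 0.25, 2.0), (7.0, 0.5, 3.0)):
            rec = simulate_recording(static_scene, single_channel_config,
                                     duration, seed=0)
            wins = descriptor_sequence(rec, delta_t, window)
            assert len(wins) == int((duration - delta_t) // window)

    def test_non_integer_delta_t_rejected(self, single_channel_config, static_scene):
        rec = simulate_recording(static_scene, single_channel_config, 2.0, seed=0)
        with pytest.raises(ValueError, match="multiple of ts"):
            descriptor_sequence(rec, 0.07, 1.0)

    def test_too_short_recording_returns_empty_with_warning(
        self, single_channel_config, static_scene, caplog
    ):
        rec = simulate_recording(static_scene, single_channel_config, 2.0, seed=0)
        with caplog.at_level(logging.WARNING, logger="vitalchirp.descriptor"):
            wins = descriptor_sequence(rec, 0.25, 12.0)
        assert wins == []
        assert "too short" in caplog.text

    def test_channel_mode_consistency(self):
        """Modes 1/3/12 select leading channels; mode 1 equals the first
        component of mode 12."""
        from vitalchirp.radar_sim import default_channels, scene_preset

        cfg = RadarConfig(channels=default_channels(12), noise_sigma=0.05)
        scene = scene_preset("human_single", seed=2)
        rec = simulate_recording(scene, cfg, 5.0, seed=2)
        f1 = descriptor_series(rec, 0.25, channel_mode=1)
        f3 = descriptor_series(rec, 0.25, channel_mode=3)
        f12 = descriptor_series(rec, 0.25, channel_mode=12)
        assert f1.shape[1] == 1 and f3.shape[1] == 3 and f12.shape[1] == 12
        np.testing.assert_array_equal(f1[:, 0], f12[:, 0])
        np.testing.assert_array_equal(f3, f12[:, :3])

    def test_breathing_descriptor_oscillates_at_twice_the_rate(self, oracle_config):
        """For small displacements sin^2 is quadratic, so the descriptor's
        fundamental sits at 2x the breathing rate (0.5 Hz for 0.25 Hz)."""
        scene = make_single_reflector_scene(
            traj=Trajectory("breathing",
                            {"rate": 0.25, "amplitude": 1e-4, "phase": 0.0})
        )
        rec = simulate_recording(scene, oracle_config, 40.0, seed=0)
        f = descriptor_series(rec, 0.25)[:, 0]
        f = f - f.mean()
        spec = np.abs(np.fft.rfft(f))
        freqs = np.fft.rfftfreq(f.size, d=oracle_config.ts)
        assert freqs[np.argmax(spec)] == pytest.approx(0.5, abs=0.05)

    def test_windows_are_nonnegative_and_shaped(self, single_channel_config):
        rng = np.random.default_rng(1)
        scene = random_breathing_scene(rng)
        rec = simulate_recording(scene, single_channel_config, 5.0, seed=1)
        wins = descriptor_sequence(rec, 0.25, 2.0)
        for w in wins:
            assert w.values.shape == (40, 1)
            assert np.all(w.values >= 0)
            assert w.label == 1


class TestBandpass:
    fs = 20.0

    def test_dc_removed(self):
        x = np.ones((400, 1))
        y = bandpass(x, 0.1, 1.0, fs=self.fs)
        assert np.max(np.abs(y[50:-50])) < 1e-3

    def test_passband_gain_within_1db(self):
        t = np.arange(2000) / self.fs
        x = np.sin(2 * np.pi * 0.5 * t)[:, None]
        y = bandpass(x, 0.1, 1.0, fs=self.fs)[:, 0]
        gain = np.max(np.abs(y[200:-200])) / 1.0
        assert 10 ** (-1 / 20) < gain < 10 ** (1 / 20)

    def test_stopband_attenuation_at_least_20db(self):
        t = np.arange(2000) / self.fs
        x = np.sin(2 * np.pi * 5.0 * t)[:, None]
        y = bandpass(x, 0.1, 1.0, fs=self.fs)[:, 0]
        assert np.max(np.abs(y[200:-200])) < 10 ** (-20 / 20)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            bandpass(np.ones((10, 1)), 1.0, 0.1, fs=self.fs)

    def test_optional_bpf_in_pipeline_keeps_window_contract(
        self, single_channel_config
    ):
        rng = np.random.default_rng(5)
        scene = random_breathing_scene(rng)
        rec = simulate_recording(scene, single_channel_config, 6.0, seed=3)
        wins = descriptor_sequence(rec, 0.25, 2.0, bpf_band=(0.1, 1.0))
        assert wins and all(np.all(w.values >= 0) for w in wins)
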