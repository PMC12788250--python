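"""Range transform, chirp-median phase, displacement scaling, container I/O."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radarvitals.radar_io import (
    ConfigurationError,
    FormatError,
    RadarConfig,
    RadarCube,
    DisplacementSeries,
    chirp_median_phase,
    phase_to_displacement,
    range_transform,
    read_cube,
    write_cube,
)


def _small_config(**kw):
    defaults = dict(chirps_per_frame=4, adc_samples_per_chirp=64, n_range_bins=16)
    defaults.update(kw)
    return RadarConfig(**defaults)


class TestRangeTransform:
    def test_zero_input_gives_zero_cube(self):
        cfg = _small_config()
        cube = range_transform(np.zeros((3, 4, 64)), cfg)
        assert np.all(cube.samples == 0)
        assert cube.samples.shape == (3, 4, 16)

    def test_tone_concentrates_in_its_range_bin(self):
        cfg = _small_config()
        k, n = 5, 64
        chirp = np.exp(2j * np.pi * k * np.arange(n) / n)
        cube = range_transform(chirp[None, None, :].repeat(4, axis=1), cfg)
        mags = np.abs(cube.samples[0, 0])
        assert np.argmax(mags) == k
        assert mags[k] == pytest.approx(n)

    def test_matches_direct_dft_oracle(self, rng):
        cfg = _small_config()
        raw = rng.standard_normal((2, 4, 64)) + 1j * rng.standard_normal((2, 4, 64))
        cube = range_transform(raw, cfg)
        n = 64
        # O(N^2) DFT summation, independently of the FFT path
        dft = np.array(
            [
                [
                    [
                        np.sum(raw[f, c] * np.exp(-2j * np.pi * k * np.arange(n) / n))
                        for k in range(16)
                    ]
                    for c in range(4)
                ]
                for f in range(2)
            ]
        )
        assert np.max(np.abs(cube.samples - dft)) / np.max(np.abs(dft)) < 1e-9

    def test_wrong_sample_count_rejected(self):
        cfg = _small_config()
        with pytest.raises(ConfigurationError):
            range_transform(np.zeros((3, 4, 63)), cfg)
        range_transform(np.zeros((3, 4, 64)), cfg)  # 64 accepted


class TestChirpMedianPhase:
    def test_identical_chirp_phases_pass_through(self):
        cfg = _small_config(n_range_bins=2)
        phi = 0.7
        samples = np.full((5, 4, 2), np.exp(1j * phi))
        series = chirp_median_phase(RadarCube(cfg, samples))
        assert np.allclose(series.values, phi)

    def test_even_count_median_is_mean_of_central_order_statistics(self):
        cfg = RadarConfig(chirps_per_frame=20, n_range_bins=1)
        phases = np.arange(20) * 0.01  # 0.00 .. 0.19
        samples = np.exp(1j * phases)[None, :, None]
        series = chirp_median_phase(RadarCube(cfg, samples))
        assert series.values[0, 0] == pytest.approx(0.095)

    def test_output_sampling_rate_is_frame_rate(self):
        cfg = _small_config(frame_rate_hz=20.0, n_range_bins=3)
        series = chirp_median_phase(RadarCube(cfg, np.ones((8, 4, 3))))
        assert series.sampling_rate_hz == 20.0

    def test_invariant_under_chirp_permutation(self, rng):
        # spread well below pi, the regime the circular median assumes
        cfg = _small_config(n_range_bins=4)
        centers = rng.uniform(-np.pi, np.pi, (6, 1, 4))
        samples = np.exp(1j * (centers + rng.uniform(-0.6, 0.6, (6, 4, 4))))
        base = chirp_median_phase(RadarCube(cfg, samples)).values
        perm = rng.permutation(4)
        shuffled = chirp_median_phase(RadarCube(cfg, samples[:, perm, :])).values
        # equality modulo 2*pi (the wrap branch may differ at the boundary)
        assert np.allclose(np.angle(np.exp(1j * (shuffled - base))), 0.0, atol=1e-9)

    @given(offset=st.floats(-0.5, 0.5))
    @settings(max_examples=20, deadline=None)
    def test_constant_phase_offset_shifts_output(self, offset):
        cfg = RadarConfig(chirps_per_frame=4, n_range_bins=2)
        rng = np.random.default_rng(0)
        phases = rng.uniform(-0.5, 0.5, (5, 4, 2))
        a = chirp_median_phase(RadarCube(cfg, np.exp(1j * phases))).values
        b = chirp_median_phase(RadarCube(cfg, np.exp(1j * (phases + offset)))).values
        assert np.allclose(b - a, offset, atol=1e-9)

    def test_median_is_safe_at_the_wrap_boundary(self):
        # phases straddling +-pi: a naive median would land near 0
        cfg = RadarConfig(chirps_per_frame=4, n_range_bins=1)
        phases = np.array([np.pi - 0.02, -np.pi + 0.02, np.pi - 0.01, -np.pi + 0.01])
        series = chirp_median_phase(RadarCube(cfg, np.exp(1j * phases)[None, :, None]))
        wrapped = np.angle(np.exp(1j * series.values[0, 0]))
        assert min(abs(wrapped - np.pi), abs(wrapped + np.pi)) < 0.05

    def test_temporal_unwrap_crosses_pi(self):
        cfg = RadarConfig(chirps_per_frame=2, n_range_bins=1)
        true_phase = np.linspace(0, 6 * np.pi, 50)  # three full turns
        samples = np.exp(1j * true_phase)[:, None, None].repeat(2, axis=1)
        series = chirp_median_phase(RadarCube(cfg, samples))
        assert np.allclose(series.values[:, 0], true_phase, atol=1e-9)


class TestPhaseToDisplacement:
    def test_zero_phase_is_zero_mm(self):
        cfg = RadarConfig(chirps_per_frame=2, n_range_bins=1)
        s = DisplacementSeries(cfg, np.zeros((4, 1)))
        assert np.all(phase_to_displacement(s).values == 0)

    def test_four_pi_is_one_wavelength(self):
        cfg = RadarConfig(carrier_freq_hz=77e9, chirps_per_frame=2, n_range_bins=1)
        s = DisplacementSeries(cfg, np.full((1, 1), 4 * np.pi))
        out = phase_to_displacement(s)
        assert out.values[0, 0] == pytest.approx(cfg.wavelength_m * 1000.0)

    def test_pi_at_60ghz_is_quarter_wavelength(self):
        cfg = RadarConfig(carrier_freq_hz=60e9, chirps_per_frame=2, n_range_bins=1)
        s = DisplacementSeries(cfg, np.full((1, 1), np.pi))
        assert phase_to_displacement(s).values[0, 0] == pytest.approx(1.2491, abs=1e-4)

    def test_linearity(self, rng):
        cfg = RadarConfig(chirps_per_frame=2, n_range_bins=3)
        phi = rng.standard_normal((10, 3))
        one = phase_to_displacement(DisplacementSeries(cfg, phi)).values
        five = phase_to_displacement(DisplacementSeries(cfg, 5 * phi)).values
        assert np.allclose(five, 5 * one)

    def test_units_are_tracked(self):
        cfg = RadarConfig(chirps_per_frame=2, n_range_bins=1)
        out = phase_to_displacement(DisplacementSeries(cfg, np.ones((2, 1))))
        assert out.units == "mm"
        with pytest.raises(ConfigurationError):
            phase_to_displacement(out)  # already in mm


class TestContainerIO:
    def test_round_trip_is_lossless(self, tmp_path, rng):
        cfg = _small_config(n_range_bins=8)
        samples = (
            rng.standard_normal((10, 4, 8)) + 1j * rng.standard_normal((10, 4, 8))
        ).astype(np.complex64)
        cube = RadarCube(cfg, samples, dt.datetime(2024, 3, 1, 23, 15, 42))
        path = tmp_path / "cube.h5"
        write_cube(cube, path)
        back = read_cube(path)
        assert back.config == cfg
        assert back.start_time == cube.start_time
        assert np.array_equal(back.samples, samples)

    def test_missing_config_is_a_format_error(self, tmp_path):
        import h5py

        path = tmp_path / "broken.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=np.zeros((1, 2, 1), complex))
            f.create_dataset("start_time", data="2024-01-01T00:00:00")
        with pytest.raises(FormatError, match="config"):
            read_cube(path)

    def test_simulated_cube_round_trips_with_timestamps(self, tmp_path):
        from radarvitals.synthetic import noiseless_scene, simulate

        cube, _ = simulate(noiseless_scene(seed=3, duration_s=5.0))
        path = tmp_path / "sim.h5"
        write_cube(cube, path)
        back = read_cube(path)
        assert back.start_time == cube.start_time
        assert np.array_equal(back.samples, cube.samples)
        assert back.frame_times()[-1] == cube.frame_times()[-1]


class TestConfigInvariants:
    def test_max_range_is_bins_times_resolution(self):
        cfg = RadarConfig(n_range_bins=52, range_resolution_m=0.05)
        assert cfg.max_range_m == pytest.approx(2.6)

    def test_bin_distance_convention(self):
        cfg = RadarConfig()
        assert cfg.bin_distance_m(0) == 0.0
        assert cfg.bin_distance_m(10) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "kw", [dict(chirps_per_frame=0), dict(frame_rate_hz=0.0), dict(n_range_bins=0)]
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            RadarConfig(**kw)

    def test_cube_shape_must_match_config(self):
        cfg = _small_config()
        with pytest.raises(ConfigurationError):
            RadarCube(cfg, np.zeros((2, 3, 16)))  # wrong chirp count
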