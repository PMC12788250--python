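"""Radar data model: range transform, phase extraction, displacement, HDF5 I/O.

An FMCW radar chirp sweeps a frequency band; the beat signal of one chirp,
Fourier-transformed along its ADC samples, resolves reflectors into discrete
range bins.  Within a frame the phase of a bin is summarized by the median
over the frame's chirps, giving one phase sample per frame per bin at the
frame rate.  Target displacement follows from the unwrapped phase through the
two-way path relation ``d = phi * lambda / (4 pi)``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

SPEED_OF_LIGHT_M_S = 2.99792458e8


class ConfigurationError(ValueError):
    """Raised when data dimensions or physical parameters are inconsistent."""


class FormatError(ValueError):
    """Raised when a container file lacks a required member."""


@dataclass(frozen=True)
class RadarConfig:
    """Acquisition parameters of an FMCW radar recording.

    Defaults mirror a 60 GHz single-TX/single-RX sensor configured for bed
    monitoring: 20 chirps per frame, 20 Hz frame rate, 64 ADC samples per
    chirp, 0.05 m range resolution.  ``n_range_bins`` is explicit
    configuration rather than being derived from the ADC sample count, so a
    recording may retain fewer bins than the range FFT produces.
    """

    carrier_freq_hz: float = 60.0e9
    bandwidth_hz: float = 3.0e9
    range_resolution_m: float = 0.05
    chirps_per_frame: int = 20
    frame_rate_hz: float = 20.0
    adc_samples_per_chirp: int = 64
    n_range_bins: int = 52

    def __post_init__(self) -> None:
        if self.chirps_per_frame < 1:
            raise ConfigurationError("chirps_per_frame must be >= 1")
        if self.frame_rate_hz <= 0:
            raise ConfigurationError("frame_rate_hz must be > 0")
        if self.n_range_bins < 1:
            raise ConfigurationError("n_range_bins must be >= 1")

    @property
    def max_range_m(self) -> float:
        """Maximum covered range, ``n_range_bins * range_resolution_m``."""
        return self.n_range_bins * self.range_resolution_m

    @property
    def wavelength_m(self) -> float:
        if self.carrier_freq_hz <= 0:
            raise ConfigurationError("carrier_freq_hz must be > 0")
        return SPEED_OF_LIGHT_M_S / self.carrier_freq_hz

    def bin_distance_m(self, bin_index: int | np.ndarray) -> float | np.ndarray:
        """Distance of a range bin (0-based, bin-start convention)."""
        return np.asarray(bin_index) * self.range_resolution_m


@dataclass
class RadarCube:
    """Complex radar samples indexed ``[frame][chirp][range_bin]``.

    Frame ``i`` is timestamped ``start_time + i / frame_rate_hz`` (uniform
    sampling).
    """

    config: RadarConfig
    samples: np.ndarray
    start_time: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2000, 1, 1, 0, 0, 0)
    )

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 3:
            raise ConfigurationError("samples must be [frame][chirp][range_bin]")
        n_frames, n_chirps, n_bins = self.samples.shape
        if n_chirps != self.config.chirps_per_frame:
            raise ConfigurationError(
                f"cube has {n_chirps} chirps per frame, "
                f"config says {self.config.chirps_per_frame}"
            )
        if n_bins != self.config.n_range_bins:
            raise ConfigurationError(
                f"cube has {n_bins} range bins, config says {self.config.n_range_bins}"
            )

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.config.frame_rate_hz

    def frame_times(self) -> np.ndarray:
        """Relative frame timestamps in seconds from ``start_time``."""
        return np.arange(self.n_frames) / self.config.frame_rate_hz

    def slice_frames(self, start: int, stop: int) -> "RadarCube":
        """Sub-cube of frames ``[start, stop)`` with shifted start_time."""
        start = max(0, start)
        new_start = self.start_time + _dt.timedelta(
            seconds=start / self.config.frame_rate_hz
        )
        return RadarCube(self.config, self.samples[start:stop], new_start)


@dataclass
class DisplacementSeries:
    """Per-range-bin phase or displacement at frame rate.

    ``values`` is ``[frame][range_bin]``; ``units`` is ``"rad"`` (unwrapped
    phase) or ``"mm"`` (displacement after the lambda/(4 pi) scaling).
    """

    config: RadarConfig
    values: np.ndarray
    units: str = "rad"
    start_time: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2000, 1, 1, 0, 0, 0)
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("values must be [frame][range_bin]")
        if self.units not in ("rad", "mm"):
            raise ConfigurationError(f"unknown units {self.units!r}")

    @property
    def sampling_rate_hz(self) -> float:
        return self.config.frame_rate_hz

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_range_bins(self) -> int:
        return self.values.shape[1]


def range_transform(raw_adc: np.ndarray, config: RadarConfig) -> RadarCube:
    """Range FFT: per-chirp DFT along the ADC-sample axis.

    The first ``config.n_range_bins`` output bins are retained; bin ``k``
    represents distance ``k * range_resolution_m``.

    Parameters
    ----------
    raw_adc
        Real or complex samples ``[frame][chirp][adc_sample]``.
    """
    raw_adc = np.asarray(raw_adc)
    if raw_adc.ndim != 3:
        raise ConfigurationError("raw_adc must be [frame][chirp][adc_sample]")
    if raw_adc.shape[2] != config.adc_samples_per_chirp:
        raise ConfigurationError(
            f"chirps have {raw_adc.shape[2]} ADC samples, "
            f"config expects {config.adc_samples_per_chirp}"
        )
    if config.n_range_bins > config.adc_samples_per_chirp:
        raise ConfigurationError("n_range_bins exceeds FFT output size")
    spectrum = np.fft.fft(raw_adc, axis=2)[:, :, : config.n_range_bins]
    return RadarCube(config, spectrum)


def _aligned_chirp_phases(samples: np.ndarray) -> np.ndarray:
    """Per-chirp principal phases, wrap-aligned to the first chirp.

    Each chirp phase is shifted by a multiple of 2*pi so it lies within
    +-pi of the frame's first chirp; a plain median across chirps is then
    safe at the +-pi boundary.
    """
    phases = np.angle(samples)  # [frame][chirp][bin]
    ref = phases[:, :1, :]
    return ref + np.angle(np.exp(1j * (phases - ref)))


def chirp_median_phase(cube: RadarCube) -> DisplacementSeries:
    """Summarize each frame by the median chirp phase per range bin.

    The per-frame medians (even chirp counts: mean of the two central order
    statistics) are temporally unwrapped per bin, yielding an unwrapped phase
    series at the frame rate.
    """
    if cube.n_frames == 0:
        raise ConfigurationError("empty cube")
    aligned = _aligned_chirp_phases(cube.samples)
    med = np.median(aligned, axis=1)  # [frame][bin]
    unwrapped = np.unwrap(med, axis=0)
    return DisplacementSeries(cube.config, unwrapped, "rad", cube.start_time)


def phase_to_displacement(
    series: DisplacementSeries, config: RadarConfig | None = None
) -> DisplacementSeries:
    """Convert unwrapped phase (rad) to displacement (mm).

    ``d = phi * lambda / (4 pi)`` — the factor 4 pi accounts for the two-way
    path of the reflected wave.
    """
    config = config or series.config
    if series.units != "rad":
        raise ConfigurationError("input series must be in radians")
    if config.carrier_freq_hz <= 0:
        raise ConfigurationError("carrier_freq_hz must be > 0")
    scale_mm = config.wavelength_m / (4.0 * np.pi) * 1000.0
    return DisplacementSeries(
        series.config, series.values * scale_mm, "mm", series.start_time
    )


def displacement_to_phase_rad(displacement_mm: np.ndarray, config: RadarConfig) -> np.ndarray:
    """Inverse of :func:`phase_to_displacement` on raw arrays."""
    return np.asarray(displacement_mm) / 1000.0 * 4.0 * np.pi / config.wavelength_m


_CONFIG_FIELDS = (
    "carrier_freq_hz",
    "bandwidth_hz",
    "range_resolution_m",
    "chirps_per_frame",
    "frame_rate_hz",
    "adc_samples_per_chirp",
    "n_range_bins",
)


def write_cube(cube: RadarCube, path) -> None:
    """Write a cube to the HDF5 container layout.

    Layout: dataset ``samples`` (complex, frame x chirp x bin), group
    ``config`` carrying one attribute per :class:`RadarConfig` field, dataset
    ``start_time`` (ISO-8601 string).
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=cube.samples)
        grp = f.create_group("config")
        for name in _CONFIG_FIELDS:
            grp.attrs[name] = getattr(cube.config, name)
        f.create_dataset("start_time", data=cube.start_time.isoformat())


def read_cube(path) -> RadarCube:
    """Read a cube written by :func:`write_cube` (lossless round-trip)."""
    with h5py.File(path, "r") as f:
        for member in ("samples", "config", "start_time"):
            if member not in f:
                raise FormatError(f"container is missing {member!r}")
        grp = f["config"]
        kwargs = {}
        for name in _CONFIG_FIELDS:
            if name not in grp.attrs:
                raise FormatError(f"config attribute {name!r} is missing")
            value = grp.attrs[name]
            kwargs[name] = int(value) if name in (
                "chirps_per_frame", "adc_samples_per_chirp", "n_range_bins"
            ) else float(value)
        config = RadarConfig(**kwargs)
        samples = f["samples"][()]
        raw = f["start_time"][()]
        if isinstance(raw, bytes):
            raw = raw.decode()
        start_time = _dt.datetime.fromisoformat(str(raw))
    return RadarCube(config, samples, start_time)


def with_n_range_bins(config: RadarConfig, n: int) -> RadarConfig:
    """Copy of ``config`` with a different retained-bin count."""
    return replace(config, n_range_bins=n)
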