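"""Synthetic bed scene: radar cubes with ground-truth vital-sign tracks.

The simulator emulates a radar at the foot end of a bed, pointed at the
person at an oblique angle: breathing motion (larger, 1-5 mm amplitude)
appears in range bins farther from the radar (upper body), heartbeat motion
(smaller, 0.287-0.568 mm) in bins nearer the radar.  Each vital-sign bin
carries an asymmetric raised-cosine cycle waveform (inhale shorter than
exhale; a narrow systolic spike with a dicrotic bump) rather than a pure
sinusoid, so shape-sensitive selection criteria are meaningfully exercised.
Rates follow piecewise-constant tracks with bounded jumps plus <= 2% cycle
jitter.  Degradations: per-sample phase noise, per-bin random-walk baseline
drift, additive complex receiver noise, and intermittent whole-body motion
bursts fast enough for the Doppler FFT to see.

Synthetic reference channels (respiratory-effort belt, ECG) are generated
from the same ground-truth tracks, so the reference-rate estimators can
recover them end to end.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from radarvitals.motion import EpochGrid
from radarvitals.radar_io import (
    ConfigurationError,
    RadarConfig,
    RadarCube,
    displacement_to_phase_rad,
)


def _default_radar_config() -> RadarConfig:
    # 24 bins x 0.05 m = 1.2 m of bed surface in view
    return RadarConfig(n_range_bins=24)


@dataclass(frozen=True)
class SceneConfig:
    """Bed-scene parameters; defaults are the clean study conditions."""

    seed: int = 0
    duration_s: float = 1800.0
    config: RadarConfig = field(default_factory=_default_radar_config)
    breathing_bins: tuple[int, int] = (13, 17)  # half-open, distal
    heartbeat_bins: tuple[int, int] = (7, 10)  # half-open, proximal
    breathing_amp_mm: tuple[float, float] = (1.0, 5.0)
    heartbeat_amp_mm: tuple[float, float] = (0.287, 0.568)
    breathing_rate_range_bpm: tuple[float, float] = (10.0, 20.0)
    heart_rate_range_bpm: tuple[float, float] = (55.0, 85.0)
    track_block_s: float = 120.0
    rate_jitter_frac: float = 0.02
    breath_shape_jitter: float = 0.08  # breath-to-breath inhale-fraction sd
    breath_amp_mod: float = 0.15  # slow relative amplitude modulation
    phase_noise_sd_rad: float = 0.02
    complex_noise_sd: float = 0.02
    drift_mm_per_min: float = 0.2
    drift_empty_frac: float = 0.1  # empty bins: thermal noise, little body drift
    breathing_leak_mm: float = 0.15
    heart_fade_frac: float = 0.0  # fraction of the night with the pulse faded
    heart_fade_scale: float = 0.12  # amplitude multiplier inside a fade
    fade_timescale_s: float = 180.0
    motion_bursts: tuple[tuple[float, float, float], ...] = ()
    burst_freq_hz: float = 3.0
    chirp_spacing_s: float = 5.0e-4
    start_time: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(2024, 3, 1, 23, 0, 0)
    )

    def __post_init__(self) -> None:
        if not self.heartbeat_bins[1] <= self.breathing_bins[0]:
            raise ConfigurationError(
                "heartbeat bins must lie nearer the radar than breathing bins"
            )
        for lo, hi in (self.breathing_bins, self.heartbeat_bins):
            if not 0 <= lo < hi <= self.config.n_range_bins:
                raise ConfigurationError("bin ranges must fit the radar config")


def noisy_scene(seed: int = 0, duration_s: float = 1800.0) -> SceneConfig:
    """The degraded variant: weak reflections, heavy noise, motion bursts."""
    return SceneConfig(
        seed=seed,
        duration_s=duration_s,
        breathing_amp_mm=(1.0, 2.0),
        heartbeat_amp_mm=(0.287, 0.40),
        phase_noise_sd_rad=0.12,
        complex_noise_sd=0.06,
        drift_mm_per_min=0.6,
        heart_fade_frac=0.45,
        motion_bursts=(
            (duration_s * 0.18, 20.0, 20.0),
            (duration_s * 0.52, 30.0, 25.0),
            (duration_s * 0.86, 15.0, 18.0),
        ),
    )


@dataclass
class GroundTruth:
    """Per-epoch true rates aligned to the pipeline's epoch grid."""

    grid: EpochGrid
    epoch_starts: np.ndarray
    breathing_bpm: np.ndarray
    heart_bpm: np.ndarray
    motion_flag: np.ndarray
    frame_breathing_bpm: np.ndarray = None
    frame_heart_bpm: np.ndarray = None
    frame_rate_hz: float = 20.0


def _piecewise_track(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    block_s: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Piecewise-constant rate track with bounded jumps between blocks."""
    n_blocks = int(np.ceil(n_samples / (block_s * fs)))
    span = hi - lo
    vals = np.empty(n_blocks)
    vals[0] = rng.uniform(lo + 0.2 * span, hi - 0.2 * span)
    for i in range(1, n_blocks):
        vals[i] = np.clip(vals[i - 1] + rng.uniform(-0.25, 0.25) * span, lo, hi)
    track = np.repeat(vals, int(block_s * fs))[:n_samples]
    return track


def _breathing_cycle(u: np.ndarray, inhale_frac: float = 0.4) -> np.ndarray:
    """Asymmetric raised-cosine breathing cycle on phase u in [0, 1): range [0, 1]."""
    u = np.mod(u, 1.0)
    rise = 0.5 * (1.0 - np.cos(np.pi * u / inhale_frac))
    fall = 0.5 * (1.0 + np.cos(np.pi * (u - inhale_frac) / (1.0 - inhale_frac)))
    return np.where(u < inhale_frac, rise, fall)


def _heart_cycle(u: np.ndarray) -> np.ndarray:
    """Heartbeat cycle: narrow systolic spike plus dicrotic bump, range [0, 1]."""
    u = np.mod(u, 1.0)
    s = np.exp(-((u - 0.18) ** 2) / (2 * 0.045**2))
    s = s + 0.35 * np.exp(-((u - 0.42) ** 2) / (2 * 0.07**2))
    return s / s.max() if s.size else s


def _cycle_phase(
    rng: np.random.Generator,
    bpm_track: np.ndarray,
    t: np.ndarray,
    jitter_frac: float,
) -> np.ndarray:
    """Cumulative cycle phase (in cycles) with slow multiplicative jitter."""
    f_hz = bpm_track / 60.0
    if jitter_frac > 0:
        # jitter varies slowly (~ per cycle), bounded by +- jitter_frac
        n_knots = max(2, int(t[-1] * f_hz.mean()) + 2)
        knots = rng.uniform(-jitter_frac, jitter_frac, n_knots)
        jitter = np.interp(t, np.linspace(0, t[-1], n_knots), knots)
        f_hz = f_hz * (1.0 + jitter)
    dt = np.diff(t, prepend=t[0])
    dt[0] = 0.0
    return np.cumsum(f_hz * dt)


def _smooth_noise(
    rng: np.random.Generator, t: np.ndarray, timescale_s: float
) -> np.ndarray:
    """Standardized smooth noise: linear interpolation of unit-normal knots."""
    n_knots = max(3, int(np.ceil(t[-1] / timescale_s)) + 2)
    knots = rng.standard_normal(n_knots)
    return np.interp(t, np.linspace(0.0, t[-1], n_knots), knots)


def _fade_envelope(rng: np.random.Generator, scene: SceneConfig, t: np.ndarray) -> np.ndarray:
    """Slow pulse-visibility envelope in (0, 1].

    Posture and chest orientation modulate how much heartbeat motion the
    radar sees; deep fades bury the pulse under the noise floor.  A smooth
    Gaussian process is thresholded at its ``heart_fade_frac`` quantile so
    the faded fraction of the night is controlled exactly; the transition is
    a soft step, not a hard gate.
    """
    if scene.heart_fade_frac <= 0:
        return np.ones_like(t)
    n_knots = max(4, int(np.ceil(t[-1] / scene.fade_timescale_s)) * 4)
    knots = rng.standard_normal(n_knots)
    g = np.interp(t, np.linspace(0.0, t[-1], n_knots), knots)
    thr = np.quantile(g, scene.heart_fade_frac)
    width = 0.5 * g.std() + 1e-12
    soft = 1.0 / (1.0 + np.exp(-(g - thr) / width))
    return scene.heart_fade_scale + (1.0 - scene.heart_fade_scale) * soft


def _burst_displacement(scene: SceneConfig, t: np.ndarray) -> np.ndarray:
    """Whole-body motion bursts: enveloped fast oscillation, in mm."""
    disp = np.zeros_like(t)
    for start, dur, amp in scene.motion_bursts:
        mask = (t >= start) & (t < start + dur)
        if not mask.any():
            continue
        local = (t[mask] - start) / dur
        env = 0.5 * (1.0 - np.cos(2.0 * np.pi * local))  # Hann envelope
        disp[mask] += amp * env * np.sin(
            2.0 * np.pi * scene.burst_freq_hz * (t[mask] - start)
        )
    return disp


def simulate(scene: SceneConfig, grid: EpochGrid | None = None) -> tuple[RadarCube, GroundTruth]:
    """Generate a radar cube and the aligned ground truth (deterministic in seed)."""
    grid = grid or EpochGrid()
    cfg = scene.config
    rng = np.random.default_rng(scene.seed)
    n_frames = int(round(scene.duration_s * cfg.frame_rate_hz))
    n_chirps = cfg.chirps_per_frame
    n_bins = cfg.n_range_bins

    # chirp-level time axis: frames at the frame rate, chirps packed inside
    t = (
        np.arange(n_frames)[:, None] / cfg.frame_rate_hz
        + np.arange(n_chirps)[None, :] * scene.chirp_spacing_s
    ).ravel()

    frame_t = np.arange(n_frames) / cfg.frame_rate_hz
    br_track_frames = _piecewise_track(
        rng, n_frames, cfg.frame_rate_hz, scene.track_block_s,
        *scene.breathing_rate_range_bpm,
    )
    hr_track_frames = _piecewise_track(
        rng, n_frames, cfg.frame_rate_hz, scene.track_block_s,
        *scene.heart_rate_range_bpm,
    )
    br_track = np.repeat(br_track_frames, n_chirps)
    hr_track = np.repeat(hr_track_frames, n_chirps)

    br_phase = _cycle_phase(rng, br_track, t, scene.rate_jitter_frac)
    hr_phase = _cycle_phase(rng, hr_track, t, scene.rate_jitter_frac)
    burst = _burst_displacement(scene, t)
    fade = _fade_envelope(rng, scene, t)

    cube = np.empty((n_frames * n_chirps, n_bins), dtype=np.complex64)
    drift_step_sd = scene.drift_mm_per_min / np.sqrt(
        60.0 * cfg.frame_rate_hz * n_chirps / (1.0)
    )
    b_lo, b_hi = scene.breathing_bins
    h_lo, h_hi = scene.heartbeat_bins

    for b in range(n_bins):
        disp = np.zeros_like(t)
        if b_lo <= b < b_hi:
            amp = rng.uniform(*scene.breathing_amp_mm)
            offset = rng.uniform(0.0, 1.0)
            inhale = np.clip(
                0.4 + scene.breath_shape_jitter * _smooth_noise(rng, t, 4.0),
                0.25, 0.55,
            )
            amp_mod = 1.0 - scene.breath_amp_mod * 0.5 * (
                1.0 + np.tanh(_smooth_noise(rng, t, 8.0))
            )
            disp = disp + amp * amp_mod * (
                2.0 * _breathing_cycle(br_phase + offset, inhale) - 1.0
            )
        elif h_lo <= b < h_hi:
            amp = rng.uniform(*scene.heartbeat_amp_mm)
            offset = rng.uniform(0.0, 1.0)
            disp = disp + amp * fade * (2.0 * _heart_cycle(hr_phase + offset) - 1.0)
            if scene.breathing_leak_mm > 0:
                disp = disp + scene.breathing_leak_mm * (
                    2.0 * _breathing_cycle(br_phase) - 1.0
                )
        disp = disp + burst
        occupied = (b_lo <= b < b_hi) or (h_lo <= b < h_hi)
        bin_drift_sd = drift_step_sd * (1.0 if occupied else scene.drift_empty_frac)
        if bin_drift_sd > 0:
            disp = disp + np.cumsum(rng.normal(0.0, bin_drift_sd, t.size))
        phase = displacement_to_phase_rad(disp, cfg)
        if scene.phase_noise_sd_rad > 0:
            phase = phase + rng.normal(0.0, scene.phase_noise_sd_rad, t.size)
        static = rng.uniform(0.0, 2.0 * np.pi)
        cube[:, b] = np.exp(1j * (static + phase)).astype(np.complex64)

    if scene.complex_noise_sd > 0:
        noise = rng.normal(0.0, scene.complex_noise_sd, (t.size, n_bins, 2))
        cube += (noise[..., 0] + 1j * noise[..., 1]).astype(np.complex64)

    samples = cube.reshape(n_frames, n_chirps, n_bins)
    radar_cube = RadarCube(cfg, samples, scene.start_time)

    starts = grid.epoch_starts(scene.duration_s)
    win_frames = int(round(grid.window_s * cfg.frame_rate_hz))
    br_epochs = np.empty(starts.size)
    hr_epochs = np.empty(starts.size)
    motion = np.zeros(starts.size, dtype=bool)
    for i, s in enumerate(starts):
        f0 = int(round(s * cfg.frame_rate_hz))
        br_epochs[i] = br_track_frames[f0 : f0 + win_frames].mean()
        hr_epochs[i] = hr_track_frames[f0 : f0 + win_frames].mean()
        for b_start, b_dur, _ in scene.motion_bursts:
            if b_start < s + grid.window_s and b_start + b_dur > s:
                motion[i] = True
    truth = GroundTruth(
        grid, starts, br_epochs, hr_epochs, motion,
        frame_breathing_bpm=br_track_frames,
        frame_heart_bpm=hr_track_frames,
        frame_rate_hz=cfg.frame_rate_hz,
    )
    return radar_cube, truth


@dataclass
class ReferenceData:
    """Synthetic reference channels and their per-epoch rates."""

    breathing_bpm: np.ndarray  # per epoch, jittered truth
    heart_bpm: np.ndarray
    effort: np.ndarray
    effort_fs: float
    ecg: np.ndarray
    ecg_fs: float


def simulate_reference(
    truth: GroundTruth,
    jitter_bpm: float = 0.0,
    seed: int = 12345,
    effort_fs: float = 32.0,
    ecg_fs: float = 200.0,
) -> ReferenceData:
    """Reference rate series plus consistent effort/ECG waveforms.

    Per-epoch reference rates are the ground truth plus N(0, jitter^2).
    The waveforms are rebuilt from the same frame-level rate tracks, so the
    reference estimators recover the tracks end to end.
    """
    if jitter_bpm < 0:
        raise ValueError("jitter_bpm must be >= 0")
    rng = np.random.default_rng(seed)
    n_ep = truth.breathing_bpm.size
    br = truth.breathing_bpm + rng.normal(0.0, jitter_bpm, n_ep) if jitter_bpm else truth.breathing_bpm.copy()
    hr = truth.heart_bpm + rng.normal(0.0, jitter_bpm, n_ep) if jitter_bpm else truth.heart_bpm.copy()

    frame_t = np.arange(truth.frame_breathing_bpm.size) / truth.frame_rate_hz
    duration = frame_t[-1] + 1.0 / truth.frame_rate_hz

    t_eff = np.arange(int(duration * effort_fs)) / effort_fs
    br_hz = np.interp(t_eff, frame_t, truth.frame_breathing_bpm) / 60.0
    eff_phase = np.cumsum(br_hz / effort_fs)
    effort = 2.0 * _breathing_cycle(eff_phase) - 1.0
    effort = effort + rng.normal(0.0, 0.01, effort.size)

    t_ecg = np.arange(int(duration * ecg_fs)) / ecg_fs
    hr_hz = np.interp(t_ecg, frame_t, truth.frame_heart_bpm) / 60.0
    ecg_phase = np.mod(np.cumsum(hr_hz / ecg_fs), 1.0)
    # narrow R spikes with a small T-wave and baseline wander
    ecg = np.exp(-((ecg_phase - 0.1) ** 2) / (2 * 0.008**2))
    ecg = ecg + 0.15 * np.exp(-((ecg_phase - 0.35) ** 2) / (2 * 0.03**2))
    ecg = ecg + 0.1 * np.sin(2.0 * np.pi * 0.2 * t_ecg)
    ecg = ecg + rng.normal(0.0, 0.01, ecg.size)

    return ReferenceData(br, hr, effort, effort_fs, ecg, ecg_fs)


def clean_scene(seed: int = 0, duration_s: float = 1800.0) -> SceneConfig:
    """The default clean scene with an explicit seed/duration."""
    return SceneConfig(seed=seed, duration_s=duration_s)


def noiseless_scene(seed: int = 0, duration_s: float = 300.0) -> SceneConfig:
    """All degradations off; for exact round-trip checks."""
    return SceneConfig(
        seed=seed,
        duration_s=duration_s,
        phase_noise_sd_rad=0.0,
        complex_noise_sd=0.0,
        drift_mm_per_min=0.0,
        rate_jitter_frac=0.0,
        breathing_leak_mm=0.0,
        breath_shape_jitter=0.0,
        breath_amp_mod=0.0,
    )
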