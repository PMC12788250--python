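"""Doppler-FFT motion parameter, smoothing, exclusion mask, window cropping.

High body motion (turning, limb movement) corrupts the phase signal, so
epochs whose motion level exceeds the overnight average are excluded before
rate estimation.  The motion parameter of an epoch is computed in five
steps: (1) Doppler FFT of every frame (FFT along the chirp axis per range
bin); (2) reduction to a per-frame velocity profile by summing cell
magnitudes over range bins; (3) clutter removal by subtracting each velocity
bin's median over the epoch's frames; (4) a Hamming taper across velocity
bins in unshifted FFT order, so the zero-Doppler (static) bin receives the
minimal weight; (5) summation over velocity bins and frames to a scalar.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hamming

from radarvitals.radar_io import FormatError, RadarCube


@dataclass(frozen=True)
class EpochGrid:
    """Sliding analysis windows: 60 s epochs advanced in 5 s steps."""

    window_s: float = 60.0
    step_s: float = 5.0

    def __post_init__(self) -> None:
        if not 0 < self.step_s <= self.window_s:
            raise ValueError("require 0 < step_s <= window_s")

    @property
    def overlap_s(self) -> float:
        return self.window_s - self.step_s

    def epoch_starts(self, duration_s: float) -> np.ndarray:
        """Start times of all epochs fully contained in ``[0, duration_s]``."""
        n = self.n_epochs(duration_s)
        return np.arange(n) * self.step_s

    def n_epochs(self, duration_s: float) -> int:
        if duration_s < self.window_s:
            return 0
        return int(np.floor((duration_s - self.window_s) / self.step_s)) + 1


@dataclass
class MotionSeries:
    """Per-epoch motion parameter with smoothing and exclusion mask.

    ``excluded[n]`` is True exactly when ``smoothed[n]`` strictly exceeds the
    overnight mean ``threshold``.
    """

    grid: EpochGrid
    raw: np.ndarray
    smoothed: np.ndarray
    threshold: float
    excluded: np.ndarray
    epoch_starts: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.smoothed = np.asarray(self.smoothed, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.epoch_starts is None:
            self.epoch_starts = np.arange(self.raw.size) * self.grid.step_s


def doppler_map(frame: np.ndarray) -> np.ndarray:
    """Doppler FFT of one frame: DFT along the chirp axis per range bin.

    Velocity bins are kept in natural (unshifted) FFT order, so zero Doppler
    is bin 0.  Input ``[chirp][range_bin]``, output ``[velocity_bin][range_bin]``.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be [chirp][range_bin]")
    if frame.shape[0] < 2:
        raise ValueError("need at least 2 chirps for a Doppler FFT")
    return np.fft.fft(frame, axis=0)


def _velocity_profiles(samples: np.ndarray) -> np.ndarray:
    """Per-frame velocity profiles: |Doppler cell| summed over range bins.

    ``samples`` is ``[frame][chirp][bin]``; output ``[frame][velocity_bin]``.
    """
    dop = np.fft.fft(samples, axis=1)
    return np.abs(dop).sum(axis=2)


def motion_parameter(cube: RadarCube, frame_slice: slice | None = None) -> float:
    """Scalar motion level of one epoch (the five-step Doppler summary).

    Static epochs give exactly 0: the constant velocity profile is removed by
    the per-bin median subtraction.  Negative post-subtraction cells are kept
    as-is.
    """
    samples = cube.samples if frame_slice is None else cube.samples[frame_slice]
    if samples.shape[0] < 2:
        raise ValueError("epoch must contain at least 2 frames")
    profiles = _velocity_profiles(samples)  # steps 1-2
    cleaned = profiles - np.median(profiles, axis=0, keepdims=True)  # step 3
    taper = hamming(cleaned.shape[1], sym=True)  # step 4, unshifted order
    return float((cleaned * taper).sum())  # step 5


def epoch_slices(duration_s: float, grid: EpochGrid) -> list[tuple[float, float]]:
    """Epoch intervals ``[start, start + window)`` covering a duration.

    Count = ``floor((duration - window)/step) + 1`` when the duration holds at
    least one full window, else 0; epochs never extend past the end.
    """
    if duration_s < 0:
        raise ValueError("duration_s must be >= 0")
    starts = grid.epoch_starts(duration_s)
    return [(float(s), float(s + grid.window_s)) for s in starts]


def smooth_motion(
    raw: np.ndarray, grid: EpochGrid, window_min: float = 5.0
) -> np.ndarray:
    """Centered moving average of the per-epoch motion parameter.

    Averages all epochs whose start lies within +-``window_min``/2 minutes of
    the target epoch's start; the effective window shrinks at the edges
    (mean over available epochs).
    """
    raw = np.asarray(raw, dtype=float)
    half_span = int(np.floor((window_min * 60.0 / 2.0) / grid.step_s))
    n = raw.size
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    for i in range(n):
        lo = max(0, i - half_span)
        hi = min(n, i + half_span + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def exclusion_mask(smoothed: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Boolean mask of epochs whose smoothed motion strictly exceeds the mean.

    At least one value is always <= the mean, so the mask is never all-True.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.size == 0:
        raise ValueError("smoothed series must be non-empty")
    if threshold is None:
        threshold = float(smoothed.mean())
    return smoothed > threshold


def compute_motion_series(cube: RadarCube, grid: EpochGrid | None = None) -> MotionSeries:
    """Raw/smoothed motion parameter per epoch with the exclusion mask."""
    grid = grid or EpochGrid()
    fs = cube.config.frame_rate_hz
    starts = grid.epoch_starts(cube.duration_s)
    win_frames = int(round(grid.window_s * fs))
    profiles = _velocity_profiles(cube.samples)  # shared across epochs
    taper = hamming(profiles.shape[1], sym=True)
    raw = np.empty(starts.size)
    for i, s in enumerate(starts):
        f0 = int(round(s * fs))
        seg = profiles[f0 : f0 + win_frames]
        cleaned = seg - np.median(seg, axis=0, keepdims=True)
        raw[i] = (cleaned * taper).sum()
    smoothed = smooth_motion(raw, grid)
    threshold = float(smoothed.mean()) if smoothed.size else 0.0
    excluded = smoothed > threshold if smoothed.size else np.zeros(0, bool)
    return MotionSeries(grid, raw, smoothed, threshold, excluded,
                        epoch_starts=starts)


def dilate_exclusion(excluded: np.ndarray, grid: EpochGrid) -> np.ndarray:
    """Mark every epoch whose interval overlaps an excluded epoch's interval.

    With overlapping epochs, "removing a segment" removes the whole 60 s
    interval; any epoch sharing time with it is discarded too.
    """
    excluded = np.asarray(excluded, dtype=bool)
    reach = int(np.ceil(grid.window_s / grid.step_s)) - 1
    out = excluded.copy()
    idx = np.flatnonzero(excluded)
    for i in idx:
        out[max(0, i - reach) : i + reach + 1] = True
    return out


def crop_window(
    cube: RadarCube,
    start_clock: _dt.time = _dt.time(22, 0),
    end_clock: _dt.time = _dt.time(6, 0),
) -> RadarCube:
    """Restrict a recording to the nightly clock window (default 22:00-06:00).

    The window may cross midnight; frames with wall-clock time in
    ``[start_clock, end_clock)`` are retained.  An empty result is allowed.
    """
    if cube.start_time is None:
        raise FormatError("recording carries no start_time")
    fs = cube.config.frame_rate_hz
    t0 = cube.start_time

    def seconds_of_day(t: _dt.time) -> float:
        return t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6

    day0 = seconds_of_day(t0.time())
    times = day0 + np.arange(cube.n_frames) / fs  # seconds since local midnight
    tod = np.mod(times, 86400.0)
    a, b = seconds_of_day(start_clock), seconds_of_day(end_clock)
    if a <= b:
        keep = (tod >= a) & (tod < b)
    else:  # crosses midnight
        keep = (tod >= a) | (tod < b)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return RadarCube(cube.config, cube.samples[:0], t0)
    # retain the first contiguous run (one nightly window per recording)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    stop = idx[breaks[0]] + 1 if breaks.size else idx[-1] + 1
    return cube.slice_frames(int(idx[0]), int(stop))
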