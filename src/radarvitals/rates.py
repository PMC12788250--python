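"""Breathing- and heart-rate estimators with physiological bounds.

Breathing rate is estimated from the first prominent peak of the biased,
normalized autocorrelation of a detrended epoch; a consistency check on the
epoch's two halves rejects epochs without a stable respiratory period.
Heart rate comes from peak detection on the band-passed signal with an
adaptive amplitude threshold; the rate is 60 / median inter-beat interval,
rejected when too few beats are found or the intervals are too irregular.

Bounds are 6-30 breaths/min and 40-150 beats/min, widened from typical
adult resting ranges to cover an elderly clinical population and sudden
heart-rate increases.  The same estimators are applied to reference
polysomnography channels (respiratory effort, ECG), so radar and reference
rates share every rejection rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from radarvitals.radar_io import FormatError


@dataclass(frozen=True)
class RateBounds:
    """Admissible rate interval for one vital sign, in events per minute."""

    kind: str  # "breathing" | "heartbeat"
    min_bpm: float
    max_bpm: float

    def __post_init__(self) -> None:
        if not 0 < self.min_bpm < self.max_bpm:
            raise ValueError("require 0 < min_bpm < max_bpm")

    @property
    def min_hz(self) -> float:
        return self.min_bpm / 60.0

    @property
    def max_hz(self) -> float:
        return self.max_bpm / 60.0


BREATHING_BOUNDS = RateBounds("breathing", 6.0, 30.0)
HEARTBEAT_BOUNDS = RateBounds("heartbeat", 40.0, 150.0)


@dataclass
class RateEstimate:
    """One epoch's rate (BPM) or None, with a [0, 1] quality score."""

    epoch_index: int = 0
    value_bpm: float | None = None
    quality: float = 0.0
    source: str = "radar"


def bandpass(x: np.ndarray, fs: float, lo_hz: float, hi_hz: float, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass; clips the upper edge below Nyquist."""
    nyq = fs / 2.0
    hi = min(hi_hz, 0.99 * nyq)
    sos = signal.butter(order, [lo_hz / nyq, hi / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, x)


def _autocorr_biased(x: np.ndarray) -> np.ndarray:
    """Biased, normalized autocorrelation r[k] = sum x_t x_{t+k} / (N r[0])."""
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[:n]
    if ac[0] <= 0:
        return np.zeros(n)
    return ac / ac[0]


def _first_inband_peak(
    x: np.ndarray, fs: float, bounds: RateBounds, min_prominence: float
) -> tuple[float, float] | None:
    """First prominent autocorrelation peak with lag in the bounds' window.

    Returns (lag_s, prominence) or None.  Lags are on the native sample grid
    (no interpolation), a documented quantization floor.
    """
    ac = _autocorr_biased(signal.detrend(np.asarray(x, dtype=float)))
    lo_lag = int(np.ceil(60.0 / bounds.max_bpm * fs))
    hi_lag = int(np.floor(60.0 / bounds.min_bpm * fs))
    if hi_lag >= ac.size or lo_lag < 1:
        return None
    peaks, props = signal.find_peaks(ac, prominence=min_prominence)
    for p, prom in zip(peaks, props["prominences"]):
        if p > hi_lag:
            break
        if lo_lag <= p <= hi_lag:
            return p / fs, float(prom)
    return None


def breathing_rate(
    series: np.ndarray,
    fs: float,
    bounds: RateBounds = BREATHING_BOUNDS,
    epoch_index: int = 0,
    min_prominence: float = 0.15,
    consistency_tol_bpm: float = 2.0,
    source: str = "radar",
) -> RateEstimate:
    """Autocorrelation breathing-rate estimate for one epoch.

    The rate is 60 / lag of the first prominent in-band autocorrelation
    peak.  The estimate is recomputed on the epoch's two halves; if either
    half yields no peak or the half-rates differ by more than
    ``consistency_tol_bpm``, the epoch yields no rate (breathing was not
    consistent across the epoch).  Quality is the peak prominence.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 30 * fs or fs < 10:
        raise ValueError("epoch must span >= 30 s at >= 10 Hz")
    none = RateEstimate(epoch_index, None, 0.0, source)
    if not np.any(x != x[0]):
        return none
    hit = _first_inband_peak(x, fs, bounds, min_prominence)
    if hit is None:
        return none
    lag_s, prom = hit
    half = x.size // 2
    half_rates = []
    for part in (x[:half], x[half:]):
        sub = _first_inband_peak(part, fs, bounds, min_prominence)
        if sub is None:
            return none
        half_rates.append(60.0 / sub[0])
    if abs(half_rates[0] - half_rates[1]) > consistency_tol_bpm:
        return none
    rate = 60.0 / lag_s
    if not bounds.min_bpm <= rate <= bounds.max_bpm:
        return none
    return RateEstimate(epoch_index, float(rate), float(min(prom, 1.0)), source)


def _refine_peaks(x: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Sub-sample peak positions by parabolic interpolation of 3 points."""
    pos = peaks.astype(float)
    ok = (peaks > 0) & (peaks < x.size - 1)
    p = peaks[ok]
    denom = x[p - 1] - 2 * x[p] + x[p + 1]
    shift = np.where(denom != 0, 0.5 * (x[p - 1] - x[p + 1]) / np.where(denom != 0, denom, 1.0), 0.0)
    pos[ok] = p + np.clip(shift, -0.5, 0.5)
    return pos


def _ibi_rate(
    peak_times_s: np.ndarray,
    bounds: RateBounds,
    epoch_s: float,
    min_beats_per_min: int,
    max_cv: float,
    epoch_index: int,
    source: str,
) -> RateEstimate:
    """Median inter-beat-interval rate with count and regularity rejection."""
    none = RateEstimate(epoch_index, None, 0.0, source)
    min_beats = int(np.ceil(min_beats_per_min * epoch_s / 60.0))
    if peak_times_s.size < max(min_beats, 2):
        return none
    ibi = np.diff(peak_times_s)
    mean_ibi = ibi.mean()
    if mean_ibi <= 0:
        return none
    cv = float(ibi.std() / mean_ibi)
    if cv > max_cv:
        return none
    rate = 60.0 / float(np.median(ibi))
    if not bounds.min_bpm <= rate <= bounds.max_bpm:
        return none
    return RateEstimate(epoch_index, float(rate), float(max(0.0, 1.0 - cv)), source)


def heart_rate(
    series: np.ndarray,
    fs: float,
    bounds: RateBounds = HEARTBEAT_BOUNDS,
    epoch_index: int = 0,
    mad_k: float = 0.5,
    min_beats_per_min: int = 20,
    max_cv: float = 0.30,
    source: str = "radar",
) -> RateEstimate:
    """Peak-detection heart-rate estimate for one epoch.

    The signal is band-passed to the bounds' frequency window; beats are
    peaks separated by at least 60/max_bpm s whose height exceeds an
    adaptive threshold (median + ``mad_k`` * MAD of the filtered envelope).
    Rate = 60 / median inter-beat interval; the epoch is rejected when fewer
    than ``min_beats_per_min`` beats per minute are found or the interval
    coefficient of variation exceeds ``max_cv``.  Quality is 1 - CV.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 30 * fs or fs < 10:
        raise ValueError("epoch must span >= 30 s at >= 10 Hz")
    none = RateEstimate(epoch_index, None, 0.0, source)
    if not np.any(x != x[0]):
        return none
    detrended = signal.detrend(x)
    filt = bandpass(detrended, fs, bounds.min_hz, bounds.max_hz)
    # a signal whose oscillation lies outside the heart band leaves only a
    # filter residual; its (subharmonic) peaks are not beats
    total_var = detrended.var()
    if total_var == 0 or filt.var() / total_var < 0.05:
        return none
    # the filtered signal is band-limited, so sinc interpolation recovers
    # beat times well below the native sample spacing
    up = 8
    filt_up = signal.resample_poly(filt, up, 1)
    fs_up = fs * up
    env = np.abs(filt_up)
    mad = np.median(np.abs(env - np.median(env)))
    height = np.median(env) + mad_k * mad
    min_dist = max(1, int(round(60.0 / bounds.max_bpm * fs_up)))
    peaks, _ = signal.find_peaks(filt_up, height=height, distance=min_dist)
    times = _refine_peaks(filt_up, peaks) / fs_up
    return _ibi_rate(times, bounds, x.size / fs, min_beats_per_min, max_cv,
                     epoch_index, source)


def _ecg_r_peaks(x: np.ndarray, fs: float, bounds: RateBounds) -> np.ndarray:
    """Classical derivative-energy R-peak detector (sample indices).

    Differentiate, square, moving-window integrate (150 ms), then pick peaks
    above an adaptive threshold with the bounds-implied refractory distance.
    """
    d = np.diff(x, prepend=x[0])
    energy = d * d
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    thr = np.median(integ) + 2.0 * np.median(np.abs(integ - np.median(integ)))
    min_dist = max(1, int(round(60.0 / bounds.max_bpm * fs)))
    peaks, _ = signal.find_peaks(integ, height=thr, distance=min_dist)
    # snap each integrated-energy peak to the nearest raw-signal maximum
    snapped = []
    half = win
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        snapped.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    return np.unique(snapped)


def reference_rates(
    channel: np.ndarray,
    kind: str,
    fs: float,
    bounds: RateBounds | None = None,
    epoch_index: int = 0,
    **kwargs,
) -> RateEstimate:
    """Reference rate from a PSG channel using the same estimators.

    ``kind="effort"`` (respiratory effort belt) runs the autocorrelation
    breathing estimator; ``kind="ecg"`` runs R-peak detection followed by
    the identical inter-beat-interval logic and rejection rules as the radar
    heart-rate path.  A flatline or inconsistent channel yields no rate.
    """
    x = np.asarray(channel, dtype=float)
    if kind == "effort":
        if fs < 10:
            raise FormatError("effort channel must be sampled at >= 10 Hz")
        b = bounds or BREATHING_BOUNDS
        return breathing_rate(x, fs, b, epoch_index, source="reference", **kwargs)
    if kind == "ecg":
        if fs < 50:
            raise FormatError("ECG channel must be sampled at >= 50 Hz")
        b = bounds or HEARTBEAT_BOUNDS
        if not np.any(x != x[0]):
            return RateEstimate(epoch_index, None, 0.0, "reference")
        peaks = _ecg_r_peaks(signal.detrend(x), fs, b)
        return _ibi_rate(peaks / fs, b, x.size / fs,
                         kwargs.get("min_beats_per_min", 20),
                         kwargs.get("max_cv", 0.30), epoch_index, "reference")
    raise FormatError(f"unsupported reference channel kind {kind!r}")


def load_edf_channel(path, label_substring: str) -> tuple[np.ndarray, float]:
    """Load one channel from an EDF file by label substring.

    Returns (samples, sampling_rate_hz).  Requires the optional ``mne``
    dependency.
    """
    import mne  # deferred: EDF ingest is optional

    raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    matches = [ch for ch in raw.ch_names if label_substring.lower() in ch.lower()]
    if not matches:
        raise FormatError(
            f"no channel matching {label_substring!r}; available: {raw.ch_names}"
        )
    picked = raw.copy().pick([matches[0]]).load_data()
    return picked.get_data()[0], float(picked.info["sfreq"])
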