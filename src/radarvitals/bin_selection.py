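"""Per-epoch range-bin selection for breathing and heart rate estimation.

Two strategies are implemented.  *Single* selection ranks bins by temporal
phase coherence (TPC), estimates a rate for the five best-ranked bins and
keeps the one with the highest signal quality — permissive by design, since
ranking alone cannot reject a window with no physiological signal.
*Multiple* selection accepts every bin whose band-limited signal passes
persistence-homology criteria — the right number of prominent oscillation
cycles in the sublevel-set diagram and, for breathing, a dominant loop in
the Vietoris-Rips diagram of the delay-embedded window — and fuses the
accepted bins' rates by their median.  It is stricter: epochs where no bin
passes yield no rate at all, trading coverage for accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal

from radarvitals.radar_io import DisplacementSeries
from radarvitals.rates import (
    BREATHING_BOUNDS,
    HEARTBEAT_BOUNDS,
    RateBounds,
    RateEstimate,
    bandpass,
    breathing_rate,
    heart_rate,
)
from radarvitals.topology import (
    EmbeddingConfig,
    delay_embed,
    periodicity_scores,
    rips_diagram,
    sublevel_diagram,
)


@dataclass
class BinSelection:
    """Outcome of one epoch's range-bin selection for one vital sign."""

    epoch_index: int
    kind: str  # "breathing" | "heartbeat"
    method: str  # "single" | "multiple"
    bins: tuple[int, ...] = ()
    per_bin_rate: dict[int, float | None] = field(default_factory=dict)
    fused_rate: float | None = None


@dataclass(frozen=True)
class SelectionThresholds:
    """Acceptance thresholds for multiple selection (one vital sign).

    ``tau_abs`` is an absolute persistence floor in the series' units (mm
    for radar displacement); ``tau_rel`` scales the window's maximal 0-dim
    persistence.  A bin is accepted when the count of 0-dim pairs with
    persistence >= max(tau_abs, tau_rel * max_persistence_0) lies within
    the bounds-implied cycle-count range (+- ``count_slack``), the maximal
    persistence reaches ``min_peak_to_peak``, and — for breathing — the
    dominant Rips loop has death/birth >= ``rho_min``.

    Defaults were calibrated once on the synthetic bed scene
    (scripts/calibrate_thresholds.py) and are plain configuration.
    """

    tau_abs: float = 0.6
    tau_rel: float = 0.35
    count_slack: int = 1
    min_peak_to_peak: float = 1.0
    rho_min: float | None = 2.5  # None: skip the Rips criterion
    embedding: EmbeddingConfig = EmbeddingConfig(dimension=2, lag_samples=20)
    rips_max_points: int = 64
    max_offband_ratio: float | None = None  # breathing-band dominance veto


#: Breathing: both filtrations; lag = quarter period at the 15 BPM mid-band.
BREATHING_THRESHOLDS = SelectionThresholds()
#: Heartbeat: sublevel-set criteria only, scaled to the smaller motion.  A bin
#: whose breathing-band oscillation dominates its heart-band oscillation is
#: vetoed: its in-band content is a respiratory harmonic, not a pulse.
HEARTBEAT_THRESHOLDS = SelectionThresholds(
    tau_abs=0.08, tau_rel=0.35, min_peak_to_peak=0.30, rho_min=None,
    max_offband_ratio=2.0,
)


def thresholds_for(kind: str) -> SelectionThresholds:
    return BREATHING_THRESHOLDS if kind == "breathing" else HEARTBEAT_THRESHOLDS


def bounds_for(kind: str) -> RateBounds:
    return BREATHING_BOUNDS if kind == "breathing" else HEARTBEAT_BOUNDS


@lru_cache(maxsize=8)
def _phase_basis(n: int, fs: float, lo_hz: float, hi_hz: float):
    """Complex exponentials e^{-2 pi i f t} on the epoch's Fourier grid."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sel = np.flatnonzero((freqs >= lo_hz) & (freqs <= hi_hz))
    t = np.arange(n) / fs
    basis = np.exp(-2j * np.pi * np.outer(t, freqs[sel]))
    return freqs[sel], basis


def tpc(
    series: np.ndarray,
    fs: float,
    bounds: RateBounds = BREATHING_BOUNDS,
    n_subwindows: int = 6,
) -> float:
    """Temporal phase coherence of one bin's epoch signal, in [0, 1].

    The epoch is split into K equal sub-windows.  The dominant in-band
    frequency is the maximizer of the incoherently averaged sub-window
    periodogram (averaging powers, not complex spectra, keeps the
    sub-window phases unconditioned, so white noise scores the Rayleigh
    mean ~ sqrt(pi)/(2 sqrt(K))).  TPC is the resultant length of the K
    sub-window phases at that frequency, measured on a common time origin:
    ``| mean_k exp(i theta_k) |``.  A phase-locked oscillation scores ~1.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4 * n_subwindows:
        raise ValueError("epoch too short for the sub-window split")
    if not np.any(x != 0):
        return 0.0
    sub_len = x.size // n_subwindows
    n = sub_len * n_subwindows
    freqs, basis = _phase_basis(n, fs, bounds.min_hz, bounds.max_hz)
    if freqs.size == 0:
        return 0.0
    # Z[k, f]: sub-window DFT coefficients with a global time reference
    prods = (x[:n, None] * basis).reshape(n_subwindows, sub_len, -1)
    z = prods.sum(axis=1)
    dominant = int(np.argmax((np.abs(z) ** 2).sum(axis=0)))
    phases = z[:, dominant]
    norms = np.abs(phases)
    if np.any(norms == 0):
        return 0.0
    return float(np.abs((phases / norms).mean()))


def _epoch_signal(
    disp: DisplacementSeries, epoch: slice, bin_index: int, bounds: RateBounds
) -> np.ndarray:
    """Band-limited (zero-phase, 5th order) epoch signal of one range bin."""
    x = disp.values[epoch, bin_index]
    return bandpass(x, disp.sampling_rate_hz, bounds.min_hz, bounds.max_hz)


def _estimate(kind: str, x: np.ndarray, fs: float, bounds: RateBounds,
              epoch_index: int) -> RateEstimate:
    if kind == "breathing":
        return breathing_rate(x, fs, bounds, epoch_index)
    return heart_rate(x, fs, bounds, epoch_index)


def select_single(
    disp: DisplacementSeries,
    epoch: slice,
    kind: str,
    bounds: RateBounds | None = None,
    epoch_index: int = 0,
    n_candidates: int = 5,
) -> BinSelection:
    """TPC-ranked single-bin selection for one epoch.

    Bins are ranked by TPC on the band-limited signal (ties favor the lower
    bin index); rates are computed for the ``n_candidates`` best; the bin
    with the highest quality — autocorrelation peak prominence for
    breathing, inter-beat regularity for heart — provides the epoch's rate.
    Absence of a rate is a valid outcome, not an error.
    """
    bounds = bounds or bounds_for(kind)
    fs = disp.sampling_rate_hz
    n_bins = disp.n_range_bins
    filtered = [_epoch_signal(disp, epoch, b, bounds) for b in range(n_bins)]
    scores = np.array([tpc(xf, fs, bounds) for xf in filtered])
    order = np.lexsort((np.arange(n_bins), -scores))
    candidates = order[: min(n_candidates, n_bins)]

    best_bin, best_est = None, None
    for b in candidates:
        est = _estimate(kind, filtered[b], fs, bounds, epoch_index)
        if est.value_bpm is None:
            continue
        if best_est is None or est.quality > best_est.quality:
            best_bin, best_est = int(b), est
    if best_bin is None:
        return BinSelection(epoch_index, kind, "single")
    return BinSelection(
        epoch_index, kind, "single",
        bins=(best_bin,),
        per_bin_rate={best_bin: best_est.value_bpm},
        fused_rate=best_est.value_bpm,
    )


def _cycle_count_range(bounds: RateBounds, window_s: float, slack: int) -> tuple[int, int]:
    """Admissible number of oscillation cycles within one window."""
    lo = int(np.floor(bounds.min_bpm * window_s / 60.0)) - slack
    hi = int(np.ceil(bounds.max_bpm * window_s / 60.0)) + slack
    return max(1, lo), hi


def accept_bin(
    xf: np.ndarray,
    fs: float,
    kind: str,
    bounds: RateBounds,
    thresholds: SelectionThresholds,
    x_raw: np.ndarray | None = None,
) -> bool:
    """Persistence-homology accept/reject decision for one bin's signal.

    ``xf`` is the band-limited epoch signal.  Sublevel-set criteria apply to
    both vital signs; the Vietoris-Rips loop criterion applies only when
    ``thresholds.rho_min`` is set (breathing).  When
    ``thresholds.max_offband_ratio`` is set (heartbeat) and the raw signal
    ``x_raw`` is available, a bin whose breathing-band peak-to-peak exceeds
    that multiple of its in-band peak-to-peak is vetoed: respiratory
    harmonics fall inside the heart band, but a bin dominated by breathing
    motion is an upper-body bin, not a pulse bin.
    """
    if (
        thresholds.max_offband_ratio is not None
        and x_raw is not None
        and kind == "heartbeat"
    ):
        off = bandpass(x_raw, fs, BREATHING_BOUNDS.min_hz, BREATHING_BOUNDS.max_hz)
        off_p2p = periodicity_scores(sublevel_diagram(off))["max_persistence_0"]
        in_p2p = periodicity_scores(sublevel_diagram(xf))["max_persistence_0"]
        if in_p2p == 0 or off_p2p > thresholds.max_offband_ratio * in_p2p:
            return False
    d0 = sublevel_diagram(xf)
    s0 = periodicity_scores(d0)
    if s0["max_persistence_0"] < thresholds.min_peak_to_peak:
        return False
    tau = max(thresholds.tau_abs, thresholds.tau_rel * s0["max_persistence_0"])
    count = int(periodicity_scores(d0, tau=tau)["persistence_count_0"])
    lo, hi = _cycle_count_range(bounds, xf.size / fs, thresholds.count_slack)
    if not lo <= count <= hi:
        return False
    if thresholds.rho_min is not None:
        cloud = delay_embed(xf, thresholds.embedding)
        d1 = rips_diagram(cloud, max_dim=1, max_points=thresholds.rips_max_points)
        s1 = periodicity_scores(d0, d1)
        if s1["persistence_ratio_1"] < thresholds.rho_min:
            return False
    return True


def select_multiple(
    disp: DisplacementSeries,
    epoch: slice,
    kind: str,
    bounds: RateBounds | None = None,
    thresholds: SelectionThresholds | None = None,
    epoch_index: int = 0,
) -> BinSelection:
    """Persistence-homology multiple-bin selection for one epoch.

    Every accepted bin contributes a rate; the fused rate is the median of
    the per-bin rates (robust to one aberrant bin).  No accepted bin means
    no rate for the epoch — strictness is intended, to keep false positives
    out of the fused estimate.  The decision is deterministic in the epoch
    signal and thresholds.
    """
    bounds = bounds or bounds_for(kind)
    thresholds = thresholds or thresholds_for(kind)
    fs = disp.sampling_rate_hz
    accepted: list[int] = []
    per_bin: dict[int, float | None] = {}
    for b in range(disp.n_range_bins):
        xf = _epoch_signal(disp, epoch, b, bounds)
        raw = disp.values[epoch, b]
        if not accept_bin(xf, fs, kind, bounds, thresholds, x_raw=raw):
            continue
        accepted.append(b)
        est = _estimate(kind, xf, fs, bounds, epoch_index)
        per_bin[b] = est.value_bpm
    rates = [r for r in per_bin.values() if r is not None]
    fused = float(np.median(rates)) if rates else None
    return BinSelection(
        epoch_index, kind, "multiple",
        bins=tuple(accepted), per_bin_rate=per_bin, fused_rate=fused,
    )


def selection_histogram(
    recordings: list[list[BinSelection]], n_range_bins: int
) -> dict[str, np.ndarray]:
    """Per-bin selection counts with across-recording mean and 95% CI.

    ``recordings`` is one list of selections per recording.  The confidence
    interval is the normal approximation mean +- 1.96 * sd / sqrt(R); with a
    single recording it collapses to the point estimate.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    counts = np.zeros((len(recordings), n_range_bins))
    for r, sels in enumerate(recordings):
        for sel in sels:
            for b in sel.bins:
                counts[r, b] += 1
    mean = counts.mean(axis=0)
    if len(recordings) > 1:
        half = 1.96 * counts.std(axis=0, ddof=1) / np.sqrt(len(recordings))
    else:
        half = np.zeros(n_range_bins)
    return {
        "counts": counts,
        "mean": mean,
        "ci_low": mean - half,
        "ci_high": mean + half,
    }


def histogram_peak_bin(hist: dict[str, np.ndarray]) -> int:
    """Range-bin index with the highest mean selection count."""
    return int(np.argmax(hist["mean"]))
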