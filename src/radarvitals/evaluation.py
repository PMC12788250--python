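"""Agreement metrics between reference and radar rate series.

All pairwise metrics (MAE, MAPE, Spearman, <±1 BPM ratio, Bland-Altman) are
computed over the N epochs where both the reference and the radar produced a
rate; recall counts each side independently against the full epoch count.
Undefined metrics (no complete pairs, zero rank variance, a zero reference
rate under MAPE) propagate as ``None`` — never as silent zeros, which would
corrupt aggregate tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from radarvitals.motion import EpochGrid


def _as_nan_array(values) -> np.ndarray:
    """Rate list with None slots -> float array with NaN for missing."""
    return np.array(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )


@dataclass
class RatePairSeries:
    """Per-epoch aligned (reference, radar) rates on a shared grid.

    Missing values are NaN (``None`` accepted on input).
    """

    grid: EpochGrid
    f_psg: np.ndarray
    f_radar: np.ndarray

    def __post_init__(self) -> None:
        self.f_psg = _as_nan_array(self.f_psg)
        self.f_radar = _as_nan_array(self.f_radar)
        if self.f_psg.size != self.f_radar.size:
            raise ValueError("reference and radar series must share the grid")

    @property
    def n_epochs(self) -> int:
        return self.f_psg.size

    def complete(self) -> tuple[np.ndarray, np.ndarray]:
        """The (reference, radar) values of epochs where both are present."""
        ok = ~np.isnan(self.f_psg) & ~np.isnan(self.f_radar)
        return self.f_psg[ok], self.f_radar[ok]


@dataclass
class AgreementReport:
    """Full agreement summary for one vital sign and selection method."""

    n_total_epochs: int
    recall_psg: float | None = None
    recall_psg_count: int = 0
    recall_radar: float | None = None
    recall_radar_count: int = 0
    mae: float | None = None
    mape: float | None = None
    spearman_rho: float | None = None
    within_1bpm: float | None = None
    within_1bpm_count: int = 0
    uncovered_duration_psg_s: float | None = None
    uncovered_duration_radar_s: float | None = None
    bland_altman: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def mae(pairs: RatePairSeries) -> float | None:
    """Mean absolute error over complete pairs, in BPM (symmetric)."""
    ref, rad = pairs.complete()
    if ref.size == 0:
        return None
    return float(np.mean(np.abs(ref - rad)))


def mape(pairs: RatePairSeries) -> float | None:
    """Mean absolute percent error, reference in the denominator."""
    ref, rad = pairs.complete()
    if ref.size == 0:
        return None
    if np.any(ref == 0):
        return None
    return float(100.0 * np.mean(np.abs(ref - rad) / ref))


def spearman(pairs: RatePairSeries) -> float | None:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    ref, rad = pairs.complete()
    if ref.size < 3:
        return None
    if np.all(ref == ref[0]) or np.all(rad == rad[0]):
        return None
    rho = stats.spearmanr(ref, rad).statistic
    return None if np.isnan(rho) else float(rho)


def recall(n_with_rate: int, n_total: int) -> float:
    """Percent of epochs with a computed rate (full precision; round only
    at presentation)."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_with_rate <= n_total:
        raise ValueError("require 0 <= n_with_rate <= n_total")
    return 100.0 * n_with_rate / n_total


def within_tolerance(
    pairs: RatePairSeries, tol_bpm: float = 1.0
) -> tuple[float, int] | None:
    """Percent and count of complete pairs with |difference| strictly < tol."""
    ref, rad = pairs.complete()
    if ref.size == 0:
        return None
    hits = int(np.sum(np.abs(ref - rad) < tol_bpm))
    return 100.0 * hits / ref.size, hits


def uncovered_duration(
    has_rate: np.ndarray,
    grid: EpochGrid,
    total_duration_s: float | None = None,
    epoch_starts: np.ndarray | None = None,
) -> float:
    """Seconds of the analyzed axis not covered by any rate-bearing epoch.

    Each rate-bearing epoch covers ``[start, start + window)``; overlapping
    epochs are merged before measuring, so the result is the measure of the
    complement of the interval union within the analyzed duration.
    """
    has_rate = np.asarray(has_rate, dtype=bool)
    if epoch_starts is None:
        epoch_starts = np.arange(has_rate.size) * grid.step_s
    epoch_starts = np.asarray(epoch_starts, dtype=float)
    if total_duration_s is None:
        total_duration_s = (
            float(epoch_starts[-1] + grid.window_s) if has_rate.size else 0.0
        )
    covered = 0.0
    cur_start = cur_end = None
    for s in epoch_starts[has_rate]:
        e = s + grid.window_s
        if cur_start is None:
            cur_start, cur_end = s, e
        elif s <= cur_end:
            cur_end = max(cur_end, e)
        else:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
    if cur_start is not None:
        covered += cur_end - cur_start
    return float(max(0.0, total_duration_s - covered))


def bland_altman(pairs: RatePairSeries) -> dict | None:
    """Bland-Altman statistics of the reference-minus-radar differences.

    Limits of agreement are mean ± 1.96 sd (sd with denominator N-1);
    ``pct_below``/``pct_above`` count points strictly outside the limits.
    """
    ref, rad = pairs.complete()
    if ref.size < 2:
        return None
    diff = ref - rad
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    return {
        "mean_diff": mean_diff,
        "loa_low": float(lo),
        "loa_high": float(hi),
        "pct_below": float(100.0 * np.mean(diff < lo)),
        "pct_above": float(100.0 * np.mean(diff > hi)),
    }


def agreement_report(
    pairs: RatePairSeries,
    total_duration_s: float | None = None,
    epoch_starts: np.ndarray | None = None,
) -> AgreementReport:
    """Assemble the full agreement summary for one rate-pair series."""
    n_total = pairs.n_epochs
    psg_ok = ~np.isnan(pairs.f_psg)
    radar_ok = ~np.isnan(pairs.f_radar)
    wt = within_tolerance(pairs)
    report = AgreementReport(
        n_total_epochs=n_total,
        recall_psg=recall(int(psg_ok.sum()), n_total) if n_total else None,
        recall_psg_count=int(psg_ok.sum()),
        recall_radar=recall(int(radar_ok.sum()), n_total) if n_total else None,
        recall_radar_count=int(radar_ok.sum()),
        mae=mae(pairs),
        mape=mape(pairs),
        spearman_rho=spearman(pairs),
        within_1bpm=wt[0] if wt else None,
        within_1bpm_count=wt[1] if wt else 0,
        bland_altman=bland_altman(pairs),
    )
    if n_total:
        report.uncovered_duration_psg_s = uncovered_duration(
            psg_ok, pairs.grid, total_duration_s, epoch_starts
        )
        report.uncovered_duration_radar_s = uncovered_duration(
            radar_ok, pairs.grid, total_duration_s, epoch_starts
        )
    return report
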