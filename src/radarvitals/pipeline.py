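"""End-to-end orchestration: crop -> motion exclude -> select -> rate -> evaluate.

The stage order is fixed: the recording is cropped to the nightly clock
window, the Doppler motion parameter is computed per epoch, smoothed, and
thresholded at its overnight mean, epochs overlapping excluded intervals are
dropped, rates are computed on the retained epochs with the requested
selection method(s), and the radar rates are evaluated against the
reference (or the simulator's ground truth).  Every stage logs the epoch
counts entering and leaving it; epoch bookkeeping conserves counts at each
boundary (total = retained + excluded).
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from radarvitals.bin_selection import (
    BinSelection,
    SelectionThresholds,
    select_multiple,
    select_single,
    thresholds_for,
)
from radarvitals.evaluation import AgreementReport, RatePairSeries, agreement_report
from radarvitals.motion import (
    EpochGrid,
    MotionSeries,
    compute_motion_series,
    crop_window,
    dilate_exclusion,
)
from radarvitals.radar_io import RadarCube, chirp_median_phase, phase_to_displacement
from radarvitals.rates import BREATHING_BOUNDS, HEARTBEAT_BOUNDS, RateBounds
from radarvitals.synthetic import GroundTruth, SceneConfig, simulate

logger = logging.getLogger("radarvitals")

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Processing settings; defaults reproduce the study protocol.

    22:00-06:00 sleep window, 60 s epochs advanced in 5 s steps, rate
    bounds 6-30 breaths/min and 40-150 beats/min, both selection methods.
    """

    grid: EpochGrid = field(default_factory=EpochGrid)
    sleep_start: _dt.time = _dt.time(22, 0)
    sleep_end: _dt.time = _dt.time(6, 0)
    crop: bool = True
    motion_exclude: bool = True
    methods: tuple[str, ...] = ("single", "multiple")
    kinds: tuple[str, ...] = ("breathing", "heartbeat")
    breathing_bounds: RateBounds = BREATHING_BOUNDS
    heartbeat_bounds: RateBounds = HEARTBEAT_BOUNDS
    breathing_thresholds: SelectionThresholds | None = None
    heartbeat_thresholds: SelectionThresholds | None = None
    seed: int = 0

    def bounds_for(self, kind: str) -> RateBounds:
        return self.breathing_bounds if kind == "breathing" else self.heartbeat_bounds

    def thresholds(self, kind: str) -> SelectionThresholds:
        override = (
            self.breathing_thresholds
            if kind == "breathing"
            else self.heartbeat_thresholds
        )
        return override or thresholds_for(kind)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        version = raw.pop("schema_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        kwargs = {}
        if "grid" in raw:
            kwargs["grid"] = EpochGrid(**raw.pop("grid"))
        for key in ("sleep_start", "sleep_end"):
            if key in raw:
                kwargs[key] = _dt.time.fromisoformat(raw.pop(key))
        for key in ("breathing_bounds", "heartbeat_bounds"):
            if key in raw:
                kwargs[key] = RateBounds(**raw.pop(key))
        for key in ("methods", "kinds"):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class StageLog:
    stage: str
    epochs_in: int
    epochs_out: int
    wall_s: float


@dataclass
class PipelineResult:
    """Everything the pipeline produces for one recording."""

    config: PipelineConfig
    motion: MotionSeries | None
    retained: np.ndarray  # epoch indices analyzed
    epoch_starts: np.ndarray  # starts of retained epochs, s
    selections: dict[tuple[str, str], list[BinSelection]]
    radar_rates: dict[tuple[str, str], np.ndarray]  # NaN where none
    reference_rates: dict[str, np.ndarray] | None
    reports: dict[tuple[str, str], AgreementReport]
    log: list[StageLog]

    def per_epoch_frame(self) -> pd.DataFrame:
        """Per-retained-epoch table of rates for every kind and method."""
        data = {"epoch_index": self.retained, "epoch_start_s": self.epoch_starts}
        for (kind, method), rates in self.radar_rates.items():
            data[f"{kind}_{method}_bpm"] = rates
        if self.reference_rates is not None:
            for kind, vals in self.reference_rates.items():
                data[f"{kind}_reference_bpm"] = vals
        return pd.DataFrame(data)

    def write(self, out_dir) -> None:
        """Write the per-epoch CSV, agreement JSON, and motion CSV."""
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_epoch_frame().to_csv(out / "rates.csv", index=False)
        if self.motion is not None:
            pd.DataFrame(
                {
                    "epoch_start_s": self.motion.epoch_starts,
                    "raw": self.motion.raw,
                    "smoothed": self.motion.smoothed,
                    "excluded": self.motion.excluded.astype(int),
                }
            ).to_csv(out / "motion.csv", index=False)
        reports = {
            f"{kind}_{method}": rep.to_dict()
            for (kind, method), rep in self.reports.items()
        }
        with open(out / "agreement.json", "w") as f:
            json.dump(reports, f, indent=2)


def _epoch_frame_slice(start_s: float, grid: EpochGrid, fs: float) -> slice:
    f0 = int(round(start_s * fs))
    return slice(f0, f0 + int(round(grid.window_s * fs)))


def run(
    cube: RadarCube,
    config: PipelineConfig | None = None,
    reference: dict[str, np.ndarray] | None = None,
    truth: GroundTruth | None = None,
) -> PipelineResult:
    """Process one recording end to end.

    ``reference`` maps kind -> per-epoch reference rates on the *uncropped*
    epoch grid (NaN allowed); when ``truth`` is given instead, the ground
    truth serves as the reference.  Rates are only computed for epochs that
    survive motion exclusion; excluded epochs appear in no metric.
    """
    config = config or PipelineConfig()
    grid = config.grid
    log: list[StageLog] = []

    def _stage(name: str, n_in: int, n_out: int, t0: float) -> None:
        entry = StageLog(name, n_in, n_out, _time.perf_counter() - t0)
        log.append(entry)
        logger.info("%s: %d -> %d epochs (%.2f s)", name, n_in, n_out, entry.wall_s)

    t0 = _time.perf_counter()
    n_before = grid.n_epochs(cube.duration_s)
    if config.crop:
        cube = crop_window(cube, config.sleep_start, config.sleep_end)
    n_epochs = grid.n_epochs(cube.duration_s)
    _stage("crop", n_before, n_epochs, t0)

    starts_all = grid.epoch_starts(cube.duration_s)
    if n_epochs == 0:
        empty_reports = {
            (kind, method): AgreementReport(n_total_epochs=0)
            for kind in config.kinds
            for method in config.methods
        }
        return PipelineResult(
            config, None, np.array([], int), np.array([]), {}, {}, None,
            empty_reports, log,
        )

    t0 = _time.perf_counter()
    motion = None
    retained_mask = np.ones(n_epochs, dtype=bool)
    if config.motion_exclude:
        motion = compute_motion_series(cube, grid)
        retained_mask = ~dilate_exclusion(motion.excluded, grid)
    retained = np.flatnonzero(retained_mask)
    _stage("motion_exclusion", n_epochs, retained.size, t0)
    assert retained.size + int((~retained_mask).sum()) == n_epochs

    t0 = _time.perf_counter()
    disp = phase_to_displacement(chirp_median_phase(cube))
    _stage("displacement", retained.size, retained.size, t0)

    fs = cube.config.frame_rate_hz
    selections: dict[tuple[str, str], list[BinSelection]] = {}
    radar_rates: dict[tuple[str, str], np.ndarray] = {}
    for kind in config.kinds:
        bounds = config.bounds_for(kind)
        for method in config.methods:
            t0 = _time.perf_counter()
            sels: list[BinSelection] = []
            rates = np.full(retained.size, np.nan)
            for i, ep in enumerate(retained):
                sl = _epoch_frame_slice(starts_all[ep], grid, fs)
                if method == "single":
                    sel = select_single(disp, sl, kind, bounds, epoch_index=int(ep))
                else:
                    sel = select_multiple(
                        disp, sl, kind, bounds, config.thresholds(kind),
                        epoch_index=int(ep),
                    )
                sels.append(sel)
                if sel.fused_rate is not None:
                    rates[i] = sel.fused_rate
            selections[(kind, method)] = sels
            radar_rates[(kind, method)] = rates
            _stage(f"select_{method}_{kind}", retained.size,
                   int(np.isfinite(rates).sum()), t0)

    ref_rates: dict[str, np.ndarray] | None = None
    if truth is not None:
        ref_rates = {
            "breathing": truth.breathing_bpm[retained],
            "heartbeat": truth.heart_bpm[retained],
        }
    elif reference is not None:
        ref_rates = {k: np.asarray(v, float)[retained] for k, v in reference.items()}

    reports: dict[tuple[str, str], AgreementReport] = {}
    analyzed_s = _analyzed_duration(starts_all[retained], grid)
    for kind in config.kinds:
        for method in config.methods:
            rad = radar_rates[(kind, method)]
            ref = (
                ref_rates[kind]
                if ref_rates is not None and kind in ref_rates
                else np.full(rad.size, np.nan)
            )
            pairs = RatePairSeries(grid, ref, rad)
            reports[(kind, method)] = agreement_report(
                pairs, total_duration_s=analyzed_s,
                epoch_starts=starts_all[retained],
            )
    return PipelineResult(
        config, motion, retained, starts_all[retained], selections,
        radar_rates, ref_rates, reports, log,
    )


def _analyzed_duration(starts: np.ndarray, grid: EpochGrid) -> float:
    """Measure of the union of the retained epochs' intervals."""
    if starts.size == 0:
        return 0.0
    total, cur_s, cur_e = 0.0, starts[0], starts[0] + grid.window_s
    for s in starts[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, s + grid.window_s)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, s + grid.window_s
    return float(total + cur_e - cur_s)


def run_simulated(
    scene: SceneConfig, config: PipelineConfig | None = None
) -> tuple[PipelineResult, GroundTruth]:
    """Simulate a scene and run the pipeline against its ground truth."""
    config = config or PipelineConfig()
    cube, truth = simulate(scene, config.grid)
    result = run(cube, config, truth=truth)
    return result, truth
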