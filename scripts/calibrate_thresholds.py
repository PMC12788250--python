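#!/usr/bin/env python
"""Calibration sweep behind the default multiple-selection thresholds.

Scores candidate thresholds on the synthetic bed scene: signal bins (known
from the scene layout) should be accepted and empty bins rejected across
epochs and seeds.  The chosen defaults live in
``radarvitals.bin_selection.BREATHING_THRESHOLDS`` / ``HEARTBEAT_THRESHOLDS``;
re-run this script to inspect how the margins behave if the scene model or
the score definitions change.

Usage:  python scripts/calibrate_thresholds.py [--seeds 3] [--duration 600]
"""

from __future__ import annotations

import argparse
from dataclasses import replace

import numpy as np

from radarvitals.bin_selection import (
    BREATHING_THRESHOLDS,
    HEARTBEAT_THRESHOLDS,
    _epoch_signal,
    accept_bin,
    bounds_for,
)
from radarvitals.motion import EpochGrid
from radarvitals.radar_io import chirp_median_phase, phase_to_displacement
from radarvitals.synthetic import SceneConfig, simulate


def acceptance_rates(scene, thresholds, kind):
    cube, _ = simulate(scene)
    disp = phase_to_displacement(chirp_median_phase(cube))
    grid = EpochGrid()
    bounds = bounds_for(kind)
    fs = disp.sampling_rate_hz
    sig_lo, sig_hi = (
        scene.breathing_bins if kind == "breathing" else scene.heartbeat_bins
    )
    signal_bins = set(range(sig_lo, sig_hi))
    vital = set(range(*scene.breathing_bins)) | set(range(*scene.heartbeat_bins))
    hits = {"signal": [0, 0], "empty": [0, 0]}
    for start in grid.epoch_starts(scene.duration_s)[::4]:
        f0 = int(start * fs)
        sl = slice(f0, f0 + int(grid.window_s * fs))
        for b in range(disp.n_range_bins):
            xf = _epoch_signal(disp, sl, b, bounds)
            ok = accept_bin(xf, fs, kind, bounds, thresholds,
                            x_raw=disp.values[sl, b])
            group = (
                "signal" if b in signal_bins
                else "empty" if b not in vital
                else None
            )
            if group:
                hits[group][0] += ok
                hits[group][1] += 1
    return {g: v[0] / v[1] for g, v in hits.items()}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seeds", type=int, default=3)
    parser.add_argument("--duration", type=float, default=600.0)
    args = parser.parse_args()

    sweeps = {
        "breathing": (
            BREATHING_THRESHOLDS,
            [("rho_min", v) for v in (1.5, 2.0, 2.5, 3.0)]
            + [("min_peak_to_peak", v) for v in (0.5, 1.0, 1.5)],
        ),
        "heartbeat": (
            HEARTBEAT_THRESHOLDS,
            [("min_peak_to_peak", v) for v in (0.15, 0.30, 0.45)]
            + [("tau_abs", v) for v in (0.04, 0.08, 0.16)],
        ),
    }
    for kind, (default, variants) in sweeps.items():
        print(f"== {kind} (default shown first)")
        seen = set()
        for name, value in [(None, None)] + variants:
            th = default if name is None else replace(default, **{name: value})
            key = (name, value)
            if key in seen:
                continue
            seen.add(key)
            sig, emp = [], []
            for seed in range(args.seeds):
                r = acceptance_rates(
                    SceneConfig(seed=seed, duration_s=args.duration), th, kind
                )
                sig.append(r["signal"])
                emp.append(r["empty"])
            label = "default" if name is None else f"{name}={value}"
            print(
                f"  {label:24s} signal acceptance {np.mean(sig):5.2f}   "
                f"empty acceptance {np.mean(emp):5.2f}"
            )


if __name__ == "__main__":
    main()
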