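"""Persistence homology as a periodicity detector.

Compares the diagrams of a breathing-like oscillation and of matched noise.
The sublevel-set diagram of the oscillation shows one prominent 0-dim pair
per cycle (persistence ~ peak-to-peak); the Vietoris-Rips diagram of its
delay embedding shows one dominant loop (large death/birth ratio).  Noise
shows neither.
"""

import numpy as np

from radarvitals import (
    EmbeddingConfig,
    delay_embed,
    periodicity_scores,
    rips_diagram,
    sublevel_diagram,
)

fs = 20.0
t = np.arange(1200) / fs  # one 60 s epoch
rng = np.random.default_rng(0)

breathing = 2.0 * np.sin(2 * np.pi * 0.25 * t) + 0.1 * rng.standard_normal(t.size)
noise = 0.7 * rng.standard_normal(t.size)

for name, x in [("15 BPM oscillation", breathing), ("white noise", noise)]:
    d0 = sublevel_diagram(x)
    cloud = delay_embed(x, EmbeddingConfig(dimension=2, lag_samples=20))
    d1 = rips_diagram(cloud, max_points=64)
    s = periodicity_scores(d0, d1, tau=1.0)
    print(f"{name}:")
    print(f"  0-dim pairs with persistence >= 1.0 : {s['persistence_count_0']}"
          f"   (expect ~15 cycles for the oscillation)")
    print(f"  max 0-dim persistence               : {s['max_persistence_0']:.2f}"
          f"   (~ peak-to-peak)")
    print(f"  dominant loop death/birth ratio     : {s['persistence_ratio_1']:.2f}"
          f"   (large = closed loop = periodic)\n")
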