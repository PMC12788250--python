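# Methods

This note records the models, estimators and numerical choices behind
`radarvitals`, and what the synthetic test bed does and does not establish.

## Signal model

An FMCW radar transmits frequency-swept chirps; the beat signal of one chirp,
Fourier-transformed over its ADC samples, separates reflectors into range
bins (`range_transform`). The default acquisition mirrors a 60 GHz
single-TX/single-RX sensor: 64 ADC samples per chirp, 0.05 m range
resolution, 20 chirps per frame, 20 Hz frame rate. The retained bin count is
explicit configuration (`n_range_bins`, default 52) rather than being derived
from the FFT length: hardware descriptions often quote a maximal detection
range smaller than `adc_samples × resolution`, so the two are deliberately
decoupled. Bin `k` is reported at distance `k × 0.05 m` (bin-start
convention; the data never disambiguate bin centers).

Within a frame, the phase of each bin is summarized by the **chirp median**:
the 20 per-chirp principal phases are wrap-aligned to the frame's first chirp
(shifted by ±2π to lie within ±π of it) and the ordinary median is taken
(even count → mean of the two central order statistics). The alignment
matters only at the ±π boundary; within-frame phase spread from vital motion
is ≪ π, which is the regime the plain median assumes. The per-frame medians
are then unwrapped over time per bin (jumps > π corrected by ±2π) — median
first, unwrap second, because unwrapping 20 independent chirp phases inside
one frame has no time axis to unwrap along. Displacement follows as
`d = φ·λ/(4π)` (two-way path), reported in mm.

## Motion parameter and exclusion

High body motion corrupts the phase, so epochs are vetted with a Doppler
summary computed in five steps per epoch: (1) FFT along the chirp axis per
frame and range bin; (2) cell magnitudes summed over range → one velocity
profile per frame (magnitudes, not complex sums — complex summation across
bins would allow phase cancellation between reflectors); (3) per velocity
bin, subtract that bin's median over the epoch's frames (static-clutter
removal — exactly zero for a static scene); (4) a Hamming taper across
velocity bins in *unshifted* FFT order, so the taper's minima sit on the
zero- and lowest-Doppler bins and slow chest motion is down-weighted;
(5) sum everything. Negative post-subtraction cells are kept: clipping would
bias quiet epochs upward.

Epochs are 60 s advanced in 5 s steps. The per-epoch parameter is smoothed
with a centered 5-minute moving average on the epoch grid (61 epochs,
edge-truncated), and epochs whose smoothed value strictly exceeds the
overnight mean are excluded. "Removing a segment" removes its whole 60 s
interval: any epoch overlapping an excluded interval is discarded too
(a ±11-epoch dilation on the shared grid). Recordings are first cropped to
the 22:00–06:00 wall-clock window, crossing midnight, keeping the first
contiguous run.

## Rate estimators

**Breathing (6–30 breaths/min).** Linear detrend; biased, normalized
autocorrelation (FFT-based); the first peak with prominence ≥ 0.15 whose lag
falls in [2 s, 10 s] gives rate = 60/lag. Lags stay on the native 20 Hz grid
— a quantization floor of `60·f_s⁻¹/lag²` BPM (≈ 0.19 BPM at 15 BPM), small
against the ±1 BPM agreement band. A consistency check re-estimates each
epoch half; disagreement > 2 BPM (or a missing half-peak) yields no rate, so
epochs with pauses or rate shifts abstain rather than average.

**Heart (40–150 beats/min).** Zero-phase 5th-order Butterworth band-pass to
0.667–2.5 Hz; if less than 5% of the detrended signal's variance survives
the filter, the epoch is rejected (what remains of an out-of-band
oscillation is filter residual whose subharmonic peaks are not beats). The
filtered signal is sinc-interpolated ×8 (it is band-limited, so beat times
are recovered well below the native 50 ms spacing; without this, the median
inter-beat interval inherits the sample grid and can bias the rate by
~1 BPM). Beats are peaks above median + 0.5·MAD of the envelope with a
60/150 s refractory distance; rate = 60 / median(IBI). Rejection: fewer
than 20 beats per minute, or IBI coefficient of variation > 0.30. The CV
cutoff admits physiological variability (CV 0.1 passes comfortably) and
rejects missing-beat patterns (deleting every third beat gives CV ≈ 0.47).

**Reference channels.** The same estimators run on polysomnography signals:
respiratory-effort belts through the breathing path; ECG through a classical
derivative–energy R-peak detector (differentiate, square, 150 ms
moving-window integration, median + 2·MAD threshold, refractory distance,
snap to the raw extremum) followed by the identical IBI logic. The reference
may also abstain; no rejection rule differs between radar and reference.

## Range-bin selection

**Single selection.** Bins are ranked by temporal phase coherence: the epoch
is split into K = 6 sub-windows; the dominant in-band frequency is the
maximizer of the *incoherently averaged* sub-window periodogram; TPC is the
resultant length of the six sub-window phases at that frequency on a common
time origin. The incoherent average is deliberate: picking the frequency
from the coherent full-epoch DFT conditions the sub-window phases toward
alignment and inflates the noise floor above the Rayleigh mean
√π/(2√K) ≈ 0.36, which is the natural calibration point of the score.
Rates are estimated for the five best-ranked bins (ties → lower index) and
the epoch reports the bin with the highest quality (autocorrelation peak
prominence for breathing; 1 − IBI CV for heart). Ranking alone cannot
reject an epoch with no physiological signal — this permissiveness is a
property of the method, not a defect of the implementation, and the tests
assert it.

**Multiple selection.** Every bin is tested against persistence-homology
criteria on its band-limited signal; accepted bins each contribute a rate
and the epoch's rate is their median (robust to one aberrant bin; invariant
to bin order). No accepted bin → no rate. Criteria:

- *Sublevel count*: the number of 0-dim pairs with persistence ≥
  max(τ_abs, τ_rel · max-persistence) must fall in the bounds-implied
  cycle-count range (rate·window/60, slack ±1). τ_rel = 0.35 for both signs;
  τ_abs = 0.6 mm (breathing) / 0.08 mm (heart).
- *Amplitude floor*: the maximal 0-dim persistence (≈ in-band peak-to-peak)
  must reach 1.0 mm for breathing and 0.30 mm for heart. The heart floor
  equals the minimum literature heartbeat displacement (0.287 mm): an
  oscillation smaller than the smallest physiological heartbeat motion is
  not accepted as a pulse.
- *Loop criterion (breathing only)*: the band-limited epoch is
  delay-embedded (dimension 2, lag = quarter period at the 15 BPM mid-band
  = 20 samples) and the dominant Vietoris–Rips 1-dim pair must satisfy
  death/birth ≥ 2.5. A clean cycle embeds as a loop (ratio ≫ 1); noise
  embeds as a blob (ratio ≈ 1). Heart epochs skip the Rips stage — the
  sublevel criteria suffice and the Rips cost is the pipeline's dominant
  term.
- *Respiratory-dominance veto (heart only)*: a bin whose breathing-band
  peak-to-peak exceeds twice its heart-band peak-to-peak is rejected;
  breathing harmonics fall inside the heart band, but a bin dominated by
  respiratory motion is an upper-body bin, not a pulse bin.

Thresholds were calibrated once against the synthetic bed scene
(`scripts/calibrate_thresholds.py` reports the acceptance margins) and are
exposed as configuration (`SelectionThresholds`).

## Evaluation

All pairwise metrics are over epochs where both sides report (N complete
pairs): MAE, MAPE (reference in the denominator), Spearman's ρ (Pearson on
mid-ranks), <±1 BPM ratio (strict inequality). Recall counts each side
independently against all analyzed epochs; values are kept at full precision
and rounded to two decimals only at presentation. Uncovered duration is the
measure of the analyzed axis not covered by the union of rate-bearing
60 s intervals — with 55 s overlap this is not `(missing epochs) × 60 s`,
hence the explicit interval union. Bland–Altman uses reference − radar
differences (radar overestimation → negative mean), limits mean ± 1.96·sd
(sd with N−1), and reports the percentages strictly outside each limit.
Undefined metrics (no complete pairs, zero rank variance, zero reference
under MAPE) propagate as absent values, never as zeros.

## Topology primitives

The 0-dim sublevel diagram is computed by union-find with the elder rule
(older birth survives a merge; plateaus and ties broken by index, earlier =
older). The series is first compressed to its sequence of local extrema —
the diagram depends on nothing else — making the cost proportional to the
number of oscillations rather than samples. The Vietoris–Rips diagram uses
the minimum spanning tree for dim 0 and Z2 column reduction of the triangle
boundary matrix for dim 1, with edges indexed by filtration rank and columns
as uint64 bitsets (numba-compiled); zero-persistence pairs are dropped.
Clouds are uniformly decimated to ≤ 200 points by default; the selection
path decimates to 64, which preserves the large-scale loop of a delay-
embedded periodic window (all cycles overlay onto the same closed curve, so
decimation thins the curve rather than breaking it). Both primitives are
verified exactly against brute-force oracles (an independent union-find; a
full boundary-matrix reduction over all simplices) in the test suite.

## Synthetic bed scene

The simulator emulates the measurement geometry, not electromagnetics: each
bin's complex samples are `exp(i·(φ_static + φ_motion(t) + noise))` plus
circular Gaussian receiver noise, with motion evaluated at chirp timestamps
(0.5 ms spacing) so the Doppler FFT sees fast transients. Breathing occupies
distal bins (default 13–16) with amplitude 1–5 mm; the heartbeat occupies
proximal bins (7–9) at 0.287–0.568 mm, with a 0.15 mm respiratory leakage —
the spatial pattern of an oblique foot-end view. Waveforms are asymmetric
raised-cosine cycles (inhale shorter than exhale) and a narrow systolic
spike with a dicrotic bump, with breath-to-breath shape jitter and downward
amplitude modulation; rate tracks are piecewise-constant per 2-minute block
with bounded jumps and ≤ 2% cycle jitter. Degradations: per-sample phase
noise, per-bin random-walk baseline drift (mostly on occupied bins — empty
bins carry chiefly thermal noise), whole-body motion bursts (3 Hz, Hann
envelope), and — in the degraded variant — a slow pulse-visibility fade
(posture and chest orientation modulate how much heartbeat motion the radar
sees). The degraded night's parameters put the pulse between the noise floor
and the multiple-selection amplitude floor for a large fraction of the
night, which is the regime where the two selection strategies separate:
ranking-based selection keeps reporting (sometimes from respiratory-harmonic
bins, i.e. wrongly), persistence-based selection abstains.

What passing tests on this scene do **not** show: performance under real
clutter and multipath, posture changes that relocate the vital-sign bins
mid-night, arrhythmias, apneas, or sensor artifacts. The scene fixes the
bin layout for a whole night and its noise is stationary outside bursts and
fades; clinical recall and error levels will differ. The end-to-end checks
establish correctness of the chain and the *direction* of the
coverage-vs-accuracy trade-off, not clinical effect sizes.

## Problem sizes and runtime

End-to-end checks use 30-minute scenes with 24 range bins (349 raw epochs,
~100–140 after motion exclusion) — large enough for stable agreement
metrics, small enough that a full clean+degraded evaluation completes in a
few minutes on one core. The Rips reduction dominates; gating it behind the
(cheap) sublevel criteria and the 64-point decimation keep it tractable.

## Known limitations

- The chirp-median's wrap alignment references the first chirp; frames whose
  chirp phases straddle ±π can summarize to a value differing by 2π from
  another reference choice — harmless after the λ/(4π) scaling of
  *differences*, but a caveat for absolute-phase uses.
- Single selection's TPC is scale-invariant, so a coherent drift can outrank
  a weak pulse; this is inherent to ranking-only selection.
- The exclusion threshold (overnight mean) assumes the night contains both
  quiet and active periods; on a uniformly quiet recording it discards
  roughly half the epochs by construction.
- Fusion by median assumes accepted bins observe the same rhythm; it is not
  a multi-person model.
- Bin selection is recomputed per epoch with no temporal smoothing of the
  selected set; the per-epoch independence is deliberate (it matches the
  evaluation's epoch-level pairing) but leaves coverage on the table.
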