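# Methods

## Signal model and scope

The pipeline assumes a uniformly sampled 1-D pulse trace whose cardiac
component lies in 0.7–5 Hz (42–300 bpm). Input is either a contact PPG
trace or a camera rPPG candidate; when a per-frame mean-RGB trace is
supplied instead, the POS projection produces the candidate first.
Video decoding, face tracking and skin segmentation are out of scope —
the pipeline starts at the mean-RGB or pulse trace.

Records shorter than 16 s are refused: with fewer than ~15 beats no
interval statistic is meaningful. LF/HF is additionally gated on a
30 s span, below which the low-frequency band (0.04–0.15 Hz) holds
less than about one cycle.

## Front end

**POS.** In every sliding window (default 1.6 s — roughly one cardiac
cycle at the slowest plausible rate, and the shortest window over
which the local-stationarity assumption behind per-window
normalisation holds) the channels are divided by their window means,
projected onto [0, 1, −1] and [−2, 1, 1], combined as
S₁ + (σ(S₁)/σ(S₂))·S₂, mean-removed and overlap-added. The output is
invariant to uniform intensity gain by construction.

**Resampling.** The trace is cubic-spline interpolated onto the
power-of-two rate nearest its own (ties upward, e.g. 24 → 32 Hz, to
avoid discarding bandwidth); 30 fps camera material becomes 32 Hz.
Cubic rather than linear interpolation preserves peak timing, which
the interval statistics inherit directly.

**Pre-cleaning.** A zero-phase (forward–backward) Butterworth
band-pass of design order 7 over 0.7–5 Hz. Zero-phase filtering is
essential: beat *positions* are the signal of interest, and a causal
filter would shift them by its group delay. Before filtering, the
record is odd-extended by up to 3 s per end — narrow-band IIR designs
of this order ring for over a second, and shorter padding leaves
transients that displace the first and last beats by tens of
milliseconds.

## First-order scattering

A bank of 20 complex Morlet wavelets, centres geometric from 0.7 to
5 Hz. Bandwidths follow a constant-Q rule with adjacent filters
crossing near −3 dB (exposed as `bandwidth_scale`); each wavelet is
L2-normalised and truncated at ±4σ_t. Convolution runs over FFT with
reflection padding so record edges do not inject wrap-around
transients into the modulus. Pooling frames are contiguous
non-overlapping 16 s blocks (a trailing partial block is dropped);
16 s trades time resolution for the frequency resolution that
band selection needs. All 20 centres sit inside the heart-rate band:
wavelets above it would mostly resolve harmonics, below it drift.

## Adaptive band selection

For each analysis window (w = 14.5 s, step s = 2 s) the per-wavelet
energies are linearly interpolated between the two pooled frames
bracketing the window's right edge (interpolation weight x/Δ with Δ
the 16 s pooling spacing).

K-means with K = 3 (k-means++ init, 10 restarts, 300 iteration cap,
fixed seed — band selection is fully deterministic) clusters the 20
(frequency, energy) points. Two scaling choices matter and were
settled by the geometry of the problem:

- **Frequency is clustered in the log domain.** The grid is
  geometric; on a linear axis the sub-1 Hz wavelets collapse into a
  near-degenerate clump and the left cluster centroid lands on top of
  the spectral peak rather than below it.
- **The energy feature is min-max scaled to [0, 1/3]** (exposed as
  `energy_weight`). With the frequency axis spanning [0, 1], three
  clusters imply a within-cluster frequency scale of about 1/3. An
  energy span kept below that lets energy shift cluster boundaries
  toward where the power is, but cannot detach a lone spectral peak
  into a singleton cluster — a failure mode that put the band's low
  edge *at* the heart-rate peak, so that the order-7 band edge
  suppressed the fundamental and beat detection locked onto the
  second harmonic (doubled heart rate).

The window's band is the span of the outer cluster centroid
frequencies (geometric means of members), clamped to 0.7–5 Hz. The
alternative `band_rule="peak_cluster"` (frequency extent of the
highest-mean-energy cluster) gives genuinely narrower bands but
tighter margins when the heart rate sits near the grid edge; the
centroid-span rule is the default. Degenerate outcomes (an empty
cluster, a collapsed band) fall back to the full 0.7–5 Hz band with a
logged warning; a band narrower than 0.05 Hz is widened symmetrically
to 0.1 Hz before filtering.

Each window is band-passed (same zero-phase order-7 design) and
mean-removed; windows are summed back in place (overlap-add). The
final window is clipped at the record end; window starts are chosen so
the clipped window is always longer than w − s (≥ 12.5 s at the
defaults), which keeps every segment long enough to filter.

## Edge amplification

Interior samples are covered by ⌊w/s⌋ or ⌈w/s⌉ overlapping windows
(on average w/s = 7.25 at the defaults) but the first step-slice by
one, the second by two, and so on, so the reconstruction's edges come
out attenuated and edge beats would be missed. Samples within w of
either end are therefore multiplied by (w/s)/coverage, capped below
at 1. At the record head this reduces exactly to the per-slice gain
c_j = (w/s)/(j+1), j = 0 … ⌊w/s⌋. At the tail the gain follows the
*actual* per-sample coverage count: whenever (n − w) is not a multiple
of s, the clipped final window shifts the tail coverage profile off
the mirrored pattern, and the mirrored-index gain would over-amplify
by up to 2×. Samples beyond w from both ends are left bit-identical.

## Beat detection and interval refinement

**AMPD.** After linear detrending, a scalogram marks, for every scale
k = 1…L, whether each sample strictly exceeds both its k-step
neighbours (boundary samples count as non-maxima). The scale λ*
minimising the count of non-maxima captures the dominant half-period;
a sample is a beat iff it is a local maximum at *every* scale ≤ λ*.
Two deviations from the original formulation, both determinism-
motivated: the random tie-breaking constants in the scalogram are
replaced by the constant 1 (the randomness only breaks row-sum ties),
and argmin ties resolve to the smallest scale. L is capped at 1.5 s
(the slowest plausible beat); a degenerate input whose detrended
residual is numerical dust (constant, perfect ramp) yields no peaks
rather than noise-artifact peaks.

**Sub-sample refinement** (on by default): each peak time is adjusted
by a three-point parabolic fit. At 32 Hz the 31 ms sampling grid
would otherwise dominate RMSSD; with refinement the timing error on
clean signals is a few milliseconds.

**Refinement rules**, applied in one pass, in order: (1) keep
intervals in [400, 1300] ms (46–150 bpm; bounds for seated adults,
configurable); (2) keep survivors within mean ± 0.4·mean, the mean
computed once on rule-1 survivors; (3) partition survivors into
consecutive blocks of 10 (final partial block included, singleton
blocks trivially kept) and keep intervals within block-mean ±
0.2·block-mean. Every drop is logged with its rule. The single pass
is the defined operation; it is *not* idempotent — re-application
re-evaluates the rule-2/3 means and can trim further (empirically a
fixed point arrives within ~7 passes on plausible series; rule 1
alone is idempotent). The tests pin monotone convergence rather than
a fixed pass count.

## HRV metrics

- **SDNN**: sample SD (N−1) of the intervals, ms.
- **RMSSD**: root mean square of the N−1 successive differences, ms.
- **Baevsky SI** = AMo/(2·Mo·MxDMn): intervals histogrammed into
  50 ms bins *centred* on multiples of the bin width (so 800 ms falls
  in the 775–825 ms bin — the convention of the Baevsky literature,
  and the one that lands resting values in the conventional 50–1500
  range); Mo is the tallest bin's centre in seconds (ties to the
  slower bin), AMo its percentage share, MxDMn the interval range in
  seconds. Undefined (flagged) for constant series or fewer than 10
  intervals.
- **LF/HF**: the tachogram (interval vs beat time) is cubic-spline
  resampled at 4 Hz (standard HRV practice; configurable), linearly
  detrended, and a single periodogram is integrated over 0.04–0.15 Hz
  and 0.15–0.4 Hz. Welch averaging is available behind a flag but the
  plain FFT periodogram is the default.

## Ground-truth cleaning and agreement

Reference (contact) recordings are screened in this order: a
face-covered flag rejects outright; any instantaneous HR outside
45–200 bpm on the *raw* intervals rejects (the criterion detects
device disconnection, which the segment rule below would quietly
repair and thereby mask); intervals outside segment-mean ± 30% are
removed over consecutive 25-interval segments (middle of the 20–30
range; configurable); SDNN > 100 ms or RMSSD > 100 ms *after*
cleaning rejects. An emptied series is rejected with its own reason
label.

Agreement statistics: MAE; the RMS of paired differences (by
definition uncentered — with a pure bias it equals the bias, where a
conventional SD would be zero; a regression test pins this); Pearson
r (undefined for zero-variance vectors); paired t with the sample SD
(N−1) of differences and a two-sided p from t(n−1); Bland-Altman bias
± 1.96·SD of differences.

## Synthetic data

Beat-to-beat intervals follow a truncated AR(1):
RR_n = μ_n + φ(RR_{n−1} − μ_{n−1}) + ε_n, ε ~ N(0, σ²), clipped to
[400, 1300] ms (a warning fires if clipping distorts > 20% of draws),
plus an optional respiratory sine (depth/frequency configurable) and
an optional linear ramp of μ across the record for drifting heart
rate. Defaults: μ = 800 ms (75 bpm), φ = 0.9, σ = 20 ms, giving a
stationary SDNN of ~46 ms and RMSSD of ~21 ms — mid-range for resting
adults; 64 Hz, 120 s, 30 dB SNR, drift amplitude 0.2 at 0.1 Hz.

Each beat renders a fixed template of width 0.4·RR whose maximum sits
exactly at the beat time: the difference of two gamma-like lobes
(v/θ)^k e^{k(1−v/θ)} with k = 2, θ = 0.45 and 0.80, weight 0.30,
cosine-tapered to zero over the last 10% of its support. The shape
crests at 40% of its support (fast systolic rise, slow decay with a
slight undershoot) and gives the rendered train a second-harmonic
amplitude about 0.6 of the fundamental — the upper end of reflective
PPG morphology, deliberately harmonic-rich so band selection is
exercised against harmonics. White noise is scaled to the requested
pulse-power SNR; baseline drift is a sine relative to the unit pulse
amplitude. Injectable artifacts (flatline dropouts, amplitude spikes,
interval outliers) are logged with exact positions for testing the
cleaner.

What the generator does **not** emulate: motion artifacts correlated
with the pulse, lighting changes, compression blocking, skin-tone
variation, ectopic beats and arrhythmias, or the non-stationary noise
of real video. Passing tests demonstrate the pipeline's correctness
and its noise/drift robustness under this model — not performance on
real facial video.

## Problem sizes

Validation runs use 120 s records (about 150 beats) at 256 Hz and at
the camera-like 32 Hz, ten seeds per condition, chosen so the whole
suite and the acceptance script each complete in well under a minute
of compute while keeping ~150-interval series, enough for every
metric including the 10-interval block rule and the LF band.

## Known limitations

- The centroid-span band is wide (typically ~1–3.5 Hz): it reliably
  contains the beat frequency but passes the second harmonic; beat
  detection relies on AMPD's multiscale criterion to reject harmonic
  ripple. The `peak_cluster` rule narrows the band at the cost of
  robustness near the grid edges.
- AMPD cannot detect beats within λ* samples (~half a beat period) of
  the record ends; one edge beat per end may be lost.
- Rule 2's mean is computed on rule-1 survivors (the order the rules
  are stated in); recordings where most intervals are artifacts can
  anchor that mean wrongly — the cleaner's rejection criteria exist
  for exactly that case.
- The Baevsky SI bin convention (centred 50 ms bins) changes the
  index by up to ~20% versus edge-anchored bins; comparisons across
  implementations must match conventions.
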