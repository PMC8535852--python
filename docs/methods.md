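# Methods

This note records the models the package implements, the defaults it ships,
and the choices made where the analysis conventions were genuinely open.

## Experiment clock

A `SpeedProfile` is an ordered list of constant-speed blocks of equal
duration (default 120 s).  The canonical ascending session is
0, 15, 30, 45, 60, 0 mm/s; the descending session is 0, 60, 45, 30, 15, 0.
Transitions are block boundaries where the speed changes; across the two
canonical sessions there are five speed-increasing transitions (0→15, 15→30,
30→45, 45→60 and 0→60).  Frame indices are derived by rounding
`time × frame_rate`; block durations used for rates are the realized frame
spans, so per-block counts always sum to the recording total.  The default
calcium frame rate is 4630/720 ≈ 6.43 Hz, giving exactly 4630 frames per
12-min session.

## Kinematics

Centering maps raw pixel distances to millimetres with
`d_new = α (d_median − d_raw)` (α in mm/px), so the median posture is zero
and forward positions are positive.  Smoothing is an order-2 Butterworth
low-pass applied forward–backward (`filtfilt`); zero-phase filtering is
deliberate, because any group delay applied to one paw and not the other
would corrupt the coordination index.

Stride detection needs two free parameters the convention leaves open; both
defaults are scale-free so they survive recalibration of α:

* `min_prominence` of the vertical spike — half the interquartile range of
  the y trace (falling back to half its range when most frames are flat);
* `min_separation` — 0.1 s of frames.

A stride is emitted when a prominent y peak lies inside the rising phase of
an x spike (preceding trough to peak); its length is `x(peak) − x(trough)`.
Strides are assigned to blocks by the frame of the x peak.  Percent changes
between blocks are `(later − earlier)/earlier × 100`.

The coordination index is computed on the centered **horizontal** traces
(the paw-location traces that show alternation), restricted to a block;
zero-variance traces raise rather than return a silent NaN.

## Event detection

The pipeline's analyses consume binary rasters, not the detector, so any
external deconvolution output can be substituted.  The built-in detector is
a transparent threshold rule: per-neuron baseline is a running median
(default 30-s window); the threshold is baseline + 2.5 × MAD (MAD scaled by
1.4826 to the Gaussian σ); an onset is the first frame of an excursion that
stays above threshold for ≥ 2 frames.  Because the indicator decay can merge
two closely spaced transients into one excursion, an additional onset is
marked where the trace jumps upward by more than `k·MAD·√2` (the same
multiplier applied to a one-frame difference) while already above threshold.
Event rate counts onsets, recorded in the raster's parameter block.

The width of a rate distribution is measured as the full width at half
maximum of its histogram via `scipy.signal.peak_widths` (Freedman–Diaconis
bins by default, light one-bin Gaussian smoothing).  If several peaks exceed
half the maximum the result is flagged multimodal and the highest peak is
measured.  Peri-transition analysis compares the rate 5 s before with 10 s
after each transition; ties count as not transition-associated
(conservative), and transitions whose windows fall off the recording are
skipped with a warning.

## Transition-active neurons

The similarity of a clipped-at-zero trace to the binary transition vector is
`2(s·c)/(|s|² + |c|²)`, which is 1 iff the vectors are identical and 0 iff
their supports are disjoint.  The 15-s windows are taken **after** each
transition, consistent with the post-transition rate analyses; a symmetric
window is available as an option.

"Shuffling the transition vector" is implemented as repositioning each
merged window at a uniformly random onset with circular wrap, preserving
window count and lengths (placements are redrawn when windows would overlap,
so `|s|²` is preserved).  Elementwise permutation is exposed as
`mode="elementwise"` for comparison but destroys the window structure and
makes the null far easier to beat.  A neuron is transition-active when its
observed similarity strictly exceeds the 99.95th percentile of its own null
(5000 shuffles by default).  The vectorized classifier shares one seeded
shuffle ensemble across neurons: each neuron's null still depends on its own
trace, results are independent of neuron order, and the thresholding is
statistically equivalent to per-neuron shuffling.  At percentile 0 the
threshold degenerates to the infimum of the similarity range, so every
neuron with nonzero similarity is flagged.

## Direct correlation

The maximum-entropy distribution for continuous data constrained to match
means and pairwise covariances is Gaussian, so the direct coupling of a pair
given all other recorded neurons is its partial correlation,
`−P_ij/√(P_ii P_jj)` with `P` the inverse of the correlation matrix.
Working on the correlation (not covariance) scale makes the DCC invariant to
per-neuron affine rescaling of the traces.  The sample correlation is shrunk
toward the identity, `(1−λ)R + λI` with λ = 0.05 by default, which
conditions the inversion when frames do not comfortably exceed neurons;
λ = 0 on an underdetermined block raises an error naming the remedy, and
λ = 1 returns the zero matrix (diagonal precision).

Strong pairs exceed the mean + 2 SD of the in-scope coefficients — signed
for Pearson, magnitude for DCC (figures summarize DCC nonnegatively; signed
values are preserved in the pair table).  The same rule defines a "directly
correlated pair" for the persistence analysis, since no separate DCC
threshold convention exists.  Distances are Euclidean centroid separations
times the pixel size; DCC₁₀₀/DCC₂₀₀ is the ratio of mean |DCC| below 100 μm
to the 100–200 μm band, with an informative error when a distance bin is
empty.

## Registration

ROI maps are rendered as sums of isotropic Gaussian peaks (height 1.0,
SD 5 px ≈ a soma radius) on the raw 512×512 frame grid.  The day-1 image is
padded by the search half-width WS on each side (WS = 40, consistent with
the 81×81 score matrix; readings that would imply an 80-px border per side
would give 161×161 and are not used), and the score at each integer offset
is the Pearson correlation of the shifted window with the day-n image,
computed for all offsets at once with FFT cross-correlation plus
integral-image window statistics.  Ties break toward the smallest shift
magnitude, then lexicographically.  Offsets are integer pixels; subpixel
registration is out of scope.

Matching is greedy one-to-one by ascending distance after shift correction,
with a 5-px tolerance (a candidate at exactly 5 px matches; beyond it does
not).  Tracking registers every day to day 1 and reports the identity table
and the fraction of reference neurons found on all days.

## Persistence

Detection-day counts are accumulated over pairs ever detected; pairs never
detected are excluded.  The histogram over counts 1..n_days is normalized to
fractions, and its shape is summarized by excess (Fisher) kurtosis computed
from the histogram as a weighted distribution.  A uniform histogram over n
bins has excess kurtosis `−6(n²+1)/(5(n²−1))` (−1.217 at n = 12,
approaching −6/5); with independent per-day detection at probability p the
counts follow a zero-truncated Binomial(n_days, p), which the tests use as a
calibration oracle.  Group-level comparisons (t tests on kurtosis across
animals) are deliberately left to external statistics packages; the
persistence table provides the per-animal values.

## Synthetic data

The generators define the study conditions for all tests; each is a pure
function of its seed.

**Paw trajectories.**  Each stride is a linear x rise (trough to peak, the
stride length) with a half-sine y spike on the rise, followed by a linear
fall; strides are evenly spaced within blocks.  Default per-block stride
counts follow the reported wild-type means — ≈272 per 2-min block at
15 mm/s and ≈476 at 60 mm/s, linearly interpolated in speed — with default
stride length 4.5 mm (the reported 4.1–5.0 mm range) and 3 mm spike height
at 71.5 Hz.  The right paw mixes the mirrored left trace with an
independent stride train (seed-drawn phase and cadence) so the expected
coordination index equals the requested value; at coordination ±1 the
construction is exact.

**Network traces.**  Per-frame latent activity is multivariate normal with
the correlation structure of the planted graph, convolved with a causal
single-exponential calcium kernel (τ = 0.6 s, a GCaMP6m-like decay) plus
optional white noise.  The same filter applied to every neuron preserves
zero-lag correlations exactly, so the planted structure survives the kernel;
observation noise attenuates but does not reorder it.  Two coupling
semantics are provided: `markov` (forest graphs; coupling = edge marginal
correlation, pairwise correlation = product along the path, precision
supported exactly on the graph — this matches the chain closed form
r(A,C) = r(A,B)·r(B,C)), and `precision` (coupling = requested partial
correlation via P = I − C, requiring spectral radius < 1; `condition=True`
inflates the diagonal minimally and re-standardizes when the requested
couplings are too strong to be jointly realizable, preserving the zero
pattern and edge ranking at the cost of shrinking the realized partial
correlations).

**Transition responders.**  Bernoulli event trains at a 0.1 events/s
baseline; responders fire at baseline × gain (default 4) inside the 15-s
post-transition windows.  The planted raster and labels are stored so both
the event detector and the classifier can be scored.  No claim is made
about the real recordings' noise distribution; `noise_sd` is exposed rather
than asserted.

**ROI sessions.**  Day-1 centroids are uniform over the field away from a
45-px border with ≥ 2-px spacing; later days add a planted integer shift
(|shift| ≤ 40 px by default), per-neuron Gaussian jitter and independent
dropout.

What the generators do **not** emulate: real somatic shapes and overlapping
ROIs, slow drift within a session, neuropil contamination, non-Poisson
firing statistics, and behaviour-locked correlations between kinematics and
neural activity.  Passing tests therefore demonstrate that the analysis
chain recovers planted structure under its own model assumptions, not that
those assumptions hold for any particular recording.

## Problem sizes and tolerances

The test suite validates stochastic claims at sizes chosen to make
Monte-Carlo error small relative to the asserted margins: 4000-frame blocks
for correlation structure (sampling SE ≈ 0.016 per coefficient), 10 seeds
for the 50-node edge-recovery AUC, 2000 neurons at 1000 shuffles for the
permutation-null calibration, 20 seeds for power and stride-robustness
studies, and 20 planted shifts for registration.  Acceptance thresholds are
asserted exactly where the quantity is analytic (matrix side, similarity
endpoints, kurtosis formulas) and with explicit margins where it is
stochastic.
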