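# Methods

## The measurement model

A lifting/thrusting recording is a uniformly sampled displacement series
(mm, 80.3 Hz); larger values mean deeper thrust. The package-wide phase
convention is that a movement cycle starts at the trough (the most-lifted
position): templates start there, segmentation delimits units there, and
the shape comparison anchors both curves there, so no phase-alignment
search is ever needed.

### Templates

A template is `(A, f, r_l:r_t)` — peak-to-trough amplitude (default
4 mm), frequency (default 1 Hz) and the lift:thrust timing ratio. The
waveform is a warped sine

    y(u) = A/2 · (1 − cos(2π·w(u))),   u = cycle fraction in [0, 1),

where the monotone phase map `w` advances fast through the thrust and
slow through the lift, with smooth half-cosine speed ramps of half-width
δ = 0.125 cycle centred on the trough and the peak, solved so that
`w(f_t) = 1/2` exactly (`f_t = r_t/(r_l+r_t)` is the thrust fraction) —
the single peak sits exactly at the stated fraction of the cycle. For
1:1 the map is the identity and the template is the pure sine,
bit-exactly.

Why this realization rather than two half-cycle sinusoids of unequal
duration: both satisfy the stated amplitude/frequency/ratio, but the
half-sine construction has asymmetric curvature at the trough (the
thrust-side wall rises four times faster for 2:1). Band-limiting such a
waveform to the 0.2–5 Hz analysis band shifts its minimum by ~1.5
samples at 80.3 Hz, which systematically misaligns every filtered motion
unit against the template and inflates the shape error of a *perfect*
movement to ~2×10⁻³. With speed ramps locally symmetric about both
extrema, filtering leaves the extrema in place; the noise-free
end-to-end error floor measures 3.4×10⁻⁴ (shape, dimensionless MSE) and
0.03 mm (magnitude). δ is clipped to `min(f_t, 1−f_t)/2` so the ramps
never overlap, and ratios extreme enough to make the map non-monotone
are rejected.

### Preprocessing

4th-order Butterworth band-pass, 0.2–5 Hz, applied forward-backward
(`sosfiltfilt`), so the phase response is identically zero — one-pass
IIR filtering would delay the signal and corrupt the within-cycle timing
that the 2:1 session measures. The effective gain is the squared
magnitude response: 1.000 at 1 Hz, 1.1×10⁻⁵ at 0.05 Hz, 2.2×10⁻³ at
10 Hz. Edges are reflect-padded (*even* reflection — odd reflection
inverts a non-zero-mean oscillation and leaks ~0.3 mm transients several
seconds into the trace) by three periods of the low cut-off, then
trimmed. The order and band edges live in the run configuration.

### Segmentation

Delimiters are local minima with topographic prominence ≥ 0.25 of the
trace's peak-to-trough range and spacing ≥ 0.5 expected periods. Because
cycles start at the trough, a recording that begins at the most-lifted
position begins a cycle at sample 0, which has no left neighborhood; the
first sample is therefore accepted as a delimiter when it lies within
0.1 of the trace range of the first interior delimiter's level and
respects the spacing rule. The trailing partial cycle is discarded.
Units whose trough-to-trough duration falls outside [0.5, 2] periods are
excluded with a reason code (an unbounded unit would corrupt the
fixed-length resampling); exclusions are logged and the counts reconcile
(`detected = analyzed + excluded`). All four constants are configurable.

### Normalization and error metrics

Each unit is linearly interpolated at 50 equally spaced points on
normalized time [0, 1] (endpoints included; cubic interpolation is
available behind a switch). The magnitude error is
`|peak-to-trough − target|` computed on the raw unit *before* any
rescaling; a pointwise alternative (mean |unit − template| in mm) is
implemented behind `magnitude_method="pointwise"` since the defining
phrase admits both readings — peak-to-trough is the default because the
per-unit amplitude comparison is what the processing-figure depicts.
For shape, the unit is min–max rescaled to [0, 1] and compared to the
identically sampled-and-rescaled template cycle by mean squared
difference. Shape error is invariant to affine transforms of the raw
displacement; magnitude error is translation-invariant. Constant units
cannot be rescaled and are excluded as degenerate, with a log entry.
Participant summaries are arithmetic means per (participant, session,
phase).

### Response curves

Per participant and test phase, the rescaled units are pooled and
smoothed with a penalized natural cubic smoothing spline
(second-derivative penalty, λ by generalized cross-validation,
`scipy.interpolate.make_smoothing_spline`); since all units share the
50-point grid, the pooled penalized fit equals a fit to the pointwise
mean with uniform weights. The group curve is the pointwise mean of
participant curves. This two-stage estimator replaces a mixed-model
smooth with participant as a random effect: it targets the same mean
response and serves visualization and the qualitative pre/post contrast,
not inference on smooth terms — no equivalence with any particular
mixed-model formula is claimed. Knots sit at the 50 grid sites rather
than a reduced 20-function basis; at this grid size the GCV-selected
penalty, not the basis dimension, controls the effective degrees of
freedom.

### Paired statistics

For each group × session × metric cell, per-participant pre/post means
are compared two-sided at α = 0.05. Normality of the *differences* (the
quantity the t-test assumes normal) is assessed by Shapiro–Wilk; p < α
routes to the Wilcoxon signed-rank test, otherwise the paired t-test.
The result records the route and the routing p. The Wilcoxon statistic
is W⁺ (sum of positive-difference ranks, zeros dropped, average ranks
for ties); its two-sided p is exact by full 2ⁿ sign enumeration for
n ≤ 12 and a tie-corrected normal approximation with continuity
correction beyond. The approximation's absolute error vs full
enumeration at n = 15 is ≤ 0.01 across representative tied inputs and
can reach ~0.013 in the middle of the distribution (it is much smaller
in the decision-relevant tails). No multiple-testing correction is
applied, matching the uncorrected reporting convention of the design;
`holm_adjust` is provided for reuse.

## The synthetic-data generator

The generator emulates the study's data tree: groups `concurrent_vf`
(n = 10) and `post_trial_vf` (n = 11), sessions `simple` (1:1) and
`complicated` (2:1), phases `pre_test, trial_1..trial_8, post_test`, one
trace per cell. Trial duration is not part of the published design;
the default is 20 s (≈ 19 complete units). A simulated trace is

    distorted template + drift + jitter

with, per cycle k:

* amplitude `A + d_k`, `d_k ~ N(0, s_mag)` clipped to keep the
  excursion positive — the per-unit magnitude error is |d_k| with mean
  `s_mag·√(2/π)`;
* a smooth monotone time-warp `u → u + c_k·sin(2πu)/(2π)`,
  `c_k ~ N(0, 0.8·s_shape)` clipped to ±0.9, plus a second-harmonic
  admixture `A·h_k·sin(4πu)·sin(πu)`, `h_k ~ N(0, 0.12·s_shape)` — shape
  MSE grows continuously from 0 with `s_shape`;
* drift: one sinusoid at 0.05 Hz (amplitude 0.3 mm) — strictly below
  the 0.2 Hz cut; jitter: three sinusoids at random frequencies in
  10–30 Hz (total amplitude 0.1 mm) — strictly above the 5 Hz cut. Both
  are removable by the band-pass *by construction*, which is what makes
  the noise-free round-trip test meaningful.

The error scales follow `E_t = E_∞ + (E_0 − E_∞)·e^(−t/τ)` over trials
t = 1..8; the pre-test uses the naive level (t = 0), the post-test the
trained level (t = 8). Only the qualitative shape of the trial-wise
curves is published (concurrent: low and flat; post-trial: high then
decaying), so the parameter values are this package's own, chosen once
as a plausible motor-learning magnitude and exposed in the
configuration:

| group | magnitude E₀→E∞ (mm) | shape E₀→E∞ | τ (trials) |
|---|---|---|---|
| concurrent_vf | 0.35 → 0.30 | 0.12 → 0.10 | 2.0 |
| post_trial_vf | 1.20 → 0.25 | 0.80 → 0.15 | 2.5 |

Participants differ by a lognormal skill multiplier (σ = 0.25) applied
to both error scales. Session-2 pre-test carry-over from session-1
training (the aftereffect observation) is off by default and available
as `session2_pre_carryover`. Every trace is seeded from (seed, group,
participant, session, phase), so any subset of a dataset regenerates
bitwise on its own.

What the generator does *not* emulate: tissue mechanics and needle-grasp
forces, perceptual details of the feedback itself (only its consequence,
the error trajectory), within-trial fatigue, and non-stationary or
non-sinusoidal sensor noise. Tests passing on this generator therefore
show that the *analysis chain* is correct and calibrated under the
stated error structure, not that real recordings satisfy that structure.

## Problem sizes and numerical choices

Monte-Carlo checks scale the trace length, not the design: the 1000
replicate no-change studies and the 200-replicate power runs use 8 s
traces (7 units each), which only reduces the number of units averaged
into each participant mean; the end-to-end and curve analyses use the
full 20 s default. Under the null the routed test rejects at ≈ 0.04;
under the default post-trial learning it detects the pre→post magnitude
reduction with the correct sign in ≈ 100% of replicates at n = 11.

Degenerate inputs are errors, not silent values: constant traces and
monotone ramps raise "no complete unit"; constant units raise a
degenerate-rescale error and are excluded upstream; zero-variance
differences raise before any test runs. Ties in |differences| share
average ranks; zero differences are dropped. Trace CSV round-trips are
exact (17 significant digits); pipeline outputs are bitwise reproducible
for a fixed configuration and dataset, and the run log records the
configuration hash and every exclusion.

## Known limitations

* The learning-curve parameterization is qualitative; no claim is made
  that the simulated effect sizes match the unpublished recordings, and
  the published test statistics are not reproducible from first
  principles.
* The two-stage response-curve estimator is not a mixed model; standard
  errors and smooth-term inference are out of scope.
* Segmentation assumes a dominant movement frequency near the nominal
  1 Hz (the spacing and duration rules are expressed in its period);
  strongly aperiodic movements would need different constants.
* The boundary-delimiter rule admits a trace whose first sample is up to
  10% of the range above trough level; a recording cut mid-rise within
  that tolerance would contribute one slightly misaligned leading unit.
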