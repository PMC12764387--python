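# Methods

This note documents the models, estimators, defaults, and numerical choices
behind `stimwave`, and what its synthetic benchmarks do and do not show
about real recordings.

## Stimulation regimen twin

A pulse train is specified by shape (biphasic, monophasic, alternating
monophasic), amplitude (V), per-phase duration (ms), and repetition rate
(Hz). "Pulse duration" is interpreted **per phase**, so a biphasic pulse
occupies twice the phase duration; `PulseSpec.from_total_width` supports
protocols that state the total biphasic width instead. The cathodic (+V)
phase leads. Validity requires the whole pulse to fit within one period;
hardware limits (2 ms–1 s phases, ≤ 50 Hz) are enforced only via
`validate_device_limits`, so synthetic studies may exceed them.

Ramped regimens interpolate one field linearly in time between endpoint
specifications. Rates are exact arithmetic: a 1 → 2 Hz ramp over 10 days is
(2−1)/(10·1440) = 6.944×10⁻⁵ Hz/min ≡ 0.1 Hz/day, and 4 → 8 ms over
10 days is 0.4 ms/day. Schedule logs sample `param_at` on a uniform grid
and always include both endpoints, so daily logging of a 10-day ramp yields
11 rows.

Waveform sampling snaps pulse edges to the nearest sample index, computed
per pulse from the nominal period (no cumulative drift). Consequently the
cathodic and anodic phases contain identical sample counts — biphasic charge
balance is exact, not approximate — and any measured duration is within half
a sample of nominal. Pulse measurement uses mid-amplitude (50%) threshold
crossings, the standard timing convention, averaged over all pulses in the
record; percent errors are |measured − expected|/expected × 100. For a
monophasic train the expected anodic duration is zero; a 0 ms measurement
against it is reported as 0% error rather than a division error, while a
nonzero measurement still raises.

## Synthetic data: what it emulates

The calcium transient kernel rises linearly to its peak over `rise_ms`
(default 100 ms) and decays exponentially with `tau_ms` (default 400 ms,
within the range reported for day-10 hiPSC-CM monolayers). This is the
minimal shape whose FWHM has a closed form, rise/2 + τ·ln 2 (327.3 ms at
the defaults), and whose decay constant is exact — precisely the two
quantities the trace metrics estimate, which makes the generator a complete
oracle for them.

Movies default to 120 frames at 20 frames/s with 2 μm pixels. The canonical
beat period is 2000 ms (0.5 Hz), at the slow end of the 0.5–2 Hz band
typical of spontaneously beating monolayers; it is chosen so consecutive
transients (≈1.9 s to 1% decay at the default kernel) do not overlap.
Overlapping tails contaminate both the baseline estimate and the decay
window — at a 1.5 s period they alone bias τ̂ by ≈9% regardless of
estimator — so studies at faster beating should shorten the kernel
accordingly.

Wave movies assign each pixel an activation delay: zero (synchronous),
position projected on the propagation direction divided by speed (plane
wave), or radial distance from the centre divided by speed (source; the
sink reverses the ordering so the wave converges). Pixel intensity is
F0·(1 + kernel((t − delay) mod period)) plus white Gaussian noise specified
in ΔF/F0 units (baseline F0 = 100 intensity units, so normalization is
testable against truth). Trace sets add i.i.d. Gaussian peak-time jitter
per ROI per beat, recorded exactly in the ground truth, which makes the
TPA-MAD oracle exact.

Motion movies warp a static smoothed-noise texture toward the image centre.
Displacement scales linearly with radius (an affine map, inverted exactly
when rendering) and follows a raised-cosine stroke: inward over
`contraction_fraction` of the beat, outward over the remainder, so a short
contraction fraction produces a faster inward stroke of equal excursion.
Ground truth records the per-frame-pair mean material speed.

Not emulated: photobleaching, indicator binding kinetics, cell-scale
texture, out-of-plane motion, illumination drift, and conduction
heterogeneity. Passing recovery tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to every artifact
of live imaging.

## Trace metrics

ΔF/F0 uses F0 = 10th percentile of the trace, computed on a median-filtered
copy (9 samples ≈ 450 ms at 20 frames/s). The filtering matters: a low
percentile of raw noisy samples sits ≈1.3σ below the true baseline, and the
resulting positive offset in every ΔF/F0 trace flattens decay fits (we
measured a 15–20% τ bias at SNR 10 without it).

Peaks are local maxima with a ΔF/F0 prominence threshold (0.5 of the
transient amplitude in the benchmarks) and a minimum separation (250 ms
default); peak times are frame-accurate with no sub-frame refinement,
matching the 50 ms granularity of 20 frames/s data.

FWHM interpolates the half-height crossings linearly between bracketing
samples. A crossing requires two consecutive sub-half samples (or the trace
edge): on monotone flanks this is exact, and on noisy traces it stops
isolated dips near half height from narrowing the width (an 8% downward
bias otherwise). Clipped transients — no crossing on one side — yield NaN
and are omitted.

τ comes from least squares on *A*·exp(−t/τ) + *c* over the window from one
sample after the peak (the sampled maximum can precede the true peak and
lie on the rising limb) to 200 ms before the next peak, or the end of the
trace. The fit is initialized from a log-linear fit of the window's early
samples and flagged NaN when that slope is non-negative or fewer than five
positive samples exist. Two deliberate choices: the offset *c* absorbs the
small residual baseline left by percentile normalization, and extending the
window through the inter-beat interval (rather than stopping at a
fixed fraction of peak height) is what makes *c* identifiable — stopping
rules keyed to the noisy samples themselves censor the tail and bias τ̂
upward by ≈11% at SNR 10. With these choices the estimator is exact on
noiseless exponentials and recovers τ within ≈4% (mean over seeds) at
SNR 10.

TPA-MAD clusters pooled peak times into beats wherever the gap exceeds half
the median inter-beat interval; within a beat each ROI contributes its
nearest peak, beats seen by fewer than two ROIs are dropped, and the
statistic is the median over beats of the raw MAD (no 1.4826 consistency
factor) of arrival times, in ms. It is invariant to global time shifts and
ROI permutations. Note the frame grid quantizes arrival times, so the MAD
of Gaussian jitter σ reads ≈0.67σ rounded to multiples of half a frame.

## Optical flow

Preprocessing follows mesoscale calcium-imaging practice: per-frame 3×3
median filter, then a per-pixel zero-phase (forward–backward) second-order
Butterworth low-pass at 1 Hz. Zero phase preserves peak-arrival times used
by the synchronicity metrics; the cutoff is configurable since it strongly
shapes flow magnitudes.

The Horn–Schunck estimator minimizes the brightness-constancy +
α²-smoothness functional by Jacobi iteration (α = 1, ≤ 200 iterations,
mean-update tolerance 10⁻⁴ by default) with the classical derivative
stencils: averages of first differences over the 2×2×2 spatiotemporal cube.
The stencil choice is load-bearing. Staggered differences have matched
spatial and temporal transfer functions, so the recovered speed of a
traveling wave is unbiased even when its wavelength approaches the pixel
pitch; symmetric central differences underestimate the spatial gradient
there (gain sin(kh)/kh) and inflate speeds — by a measured +33% for a
5 μm/s wave at 2 μm pixels. The cost is that the forward half-pixel
anchoring breaks exact 90°-rotation equivariance; flow summaries commute
with grid rotations to within a few percent, and the tests check exactly
that.

Summaries pool vectors over all frame pairs of a movie. The activity mask
keeps pixels whose ΔF/F0 temporal range is at least 20% of the movie's
median range, restricting statistics to active tissue. Mean magnitude
averages |(u, v)| over all masked vectors and converts px/frame to μm/s;
phase statistics (circular variance 1 − |⟨e^{iθ}⟩|, circular mean, rose
histogram over [−π, π)) use masked vectors above a magnitude floor (10th
percentile of pooled magnitudes by default) and are unweighted by
magnitude. On 128×128, 120-frame plane waves at 5–20 μm/s with 2% noise,
direction is recovered within a degree, circular variance stays below 0.1,
and mean magnitude is within ≈25% of truth (Horn–Schunck smoothing biases
magnitudes near wavefront edges); matched source/sink movies give circular
variance ≈30× higher — the package's separation between unidirectional and
multidirectional propagation.

## Contractility

Velocity traces apply Horn–Schunck to consecutive frame pairs after a 3×3
median filter and a zero-phase 3 Hz temporal low-pass; the per-pair speed
is the whole-frame mean flow magnitude in μm/s. The temporal filter is
required, not cosmetic: camera noise is temporally independent, so unfiltered
2%-of-range noise registers as ≈0.3 px/frame of spurious flow, an order of
magnitude above the beat signal; 3 Hz keeps the stroke content of sub-2 Hz
beating.

Each beat contributes two velocity peaks — inward contraction, outward
relaxation. Peaks (prominence ≥ 20% of the trace maximum by default, low
enough to keep the weaker relaxation stroke of asymmetric beats) are paired
in temporal order; within a pair the first is labelled contraction, since
monolayer recoil follows contraction and movies start at rest. A
divergence-sign cross-check is available (`divergence_trace`): the mean flow
divergence is negative during inward strokes, and supplying it re-labels
pairs independently of order. A trailing unpaired peak is dropped with a
warning. Metrics are the means of the labelled peak speeds; on synthetic
beats they recover the generator's peak mean pixel speed within a few
percent (symmetric strokes balance to <1%).

## Pipeline and reproducibility

`RunConfig` (pydantic) validates every condition before any computation, so
a configuration error produces no partial outputs. One master seed is
expanded into per-condition, per-stage seeds via
`SeedSequence([master, *key])` reduced to 31 bits (`child_seed`), so any
stage can be re-run in isolation. All artifacts are text (CSV/JSON) or
TIFF; the consolidated report carries a SHA-256 config hash, the seed, and
the package version in a comment header, and identical config + seed
produce byte-identical reports.

## Known limitations

* Flow magnitudes inherit Horn–Schunck's smoothing bias; absolute speeds
  are reliable to tens of percent, comparisons across conditions much
  better.
* Trace metrics on ROI grids assume each ROI sees a coherent transient;
  when propagation delay across one ROI approaches the beat period (slow
  waves, coarse grids) the averaged transient flattens and peaks become
  undetectable. Grid resolution must respect the expected wavelength.
* The τ fit assumes a single-exponential decay with a constant local
  baseline; biexponential reuptake kinetics would be reported as an
  effective constant.
* TPA-MAD resolution is limited by the frame interval (50 ms at 20
  frames/s); jitter well below one frame is indistinguishable from zero.
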