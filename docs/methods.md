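# Methods

This note documents the models, conventions and numerical choices behind
the package, in the order data flows through it.

## Arena geometry and calibration

The platform is a disk of radius R = 58.5 mm. Pixel coordinates are
mapped to an arena-centred millimetre frame by a similarity transform
derived from a circle fitted through three user-clicked rim points
(perpendicular-bisector solve; collinear points are rejected as
degenerate). The scale is k = R / r_px; pixel y grows downward, so the
mm frame negates y to stay right-handed. No tilt or lens correction is
applied — with a correctly levelled camera the three-point fit absorbs
the remaining placement error.

Stripe geometry: the two stripe centres project to (0, ±146.5) mm in the
arena frame; the diffuser carrying them has radius 147.5 mm and the
stripes are 313 mm tall. Retinal sizes use the tangent (planar-target)
convention: height = atan(h/d), full width = 2·atan(w/2d), for an eye in
the plane of the stripe base at horizontal distance d. The chord-based
convention differs by under ±0.3° over the platform; the tangent form
was chosen and tests assert angles to ±0.4°.

## Preprocessing

Each burst (maximal uninterrupted tracking segment) is processed
independently — the animal may have been physically replaced between
bursts, so no interpolation, step or pause ever crosses a burst
boundary.

1. **Resampling.** Linear interpolation onto an even grid at 10 Hz,
   anchored at the burst's first timestamp and ending at or before its
   last. Single-point bursts are dropped with a warning. Anchoring at
   the burst start (rather than absolute time zero) keeps the first
   sample of every burst exact.
2. **Minimum-movement filter.** A sequential pass: a displacement
   smaller than 0.8 mm (strict) from the previous *rewritten* position
   is snapped back onto it, and the next displacement is measured from
   the rewritten point. Genuine slow progress therefore accumulates
   until it clears the threshold; isolated jitter vanishes. The filter
   is idempotent and can only shorten the path. The 0.8 mm default
   reflects the ~0.35 mm/px camera scale (two pixels of centroid
   jitter).
3. **Step series.** Per consecutive sample pair: length, speed
   (length/0.1 s), absolute angle α (undefined for zero-length steps),
   turning angle γ between the two nearest *moving* steps (assigned to
   the later one, wrapped to (−180°, 180°]), and a jump flag for speeds
   above 50 mm/s. Pauses between two movements do not break the γ pair:
   a heading exists only while moving.

## Metrics

Medians are used throughout (per-step distributions are heavy-tailed);
group summaries report means ± s.e. of the per-individual values.

- **Median speed** is computed over moving, non-jump steps only.
  Including zero-length steps would pin the median to 0 for any animal
  that rests most of the time.
- **Turning angle** reports the median of |γ|; a signed median would be
  ≈ 0 for any near-symmetric turner.
- **Meander** pairs each |γ| with the speed of the *later* of its two
  moving steps (the step γ is assigned to). The pairing is isolated in
  one function so the other convention can be flipped in if desired.
- **Centrophobism** splits the arena at r = R/√2 into an inner disk and
  outer ring of exactly equal area. Each 10 Hz sample is classified
  moving (nonzero displacement from the previous sample) or sitting;
  the first sample of a burst carries no displacement and counts as
  sitting. Per class, index = (N_out − N_in)/(N_out + N_in).
- **Stripe deviation** measures, per moving step, the angle between the
  velocity vector and the vector from the step's start position to each
  stripe centre, keeping the smaller (the stripe "most in front").
  Stripe-free experiments are evaluated against the nominal stripe
  positions anyway; that is what defines the 45° chance level.
- **Number of walks** uses end zones that are circular segments cut by
  chords perpendicular to the stripe axis at ±0.8 R; a walk is one
  passage from one zone to the other (re-entering the same zone does
  not count).
- **Activity (TT)**: a pause is a maximal still run strictly longer
  than 1 s; everything else is active, so shorter rests count as
  activity and total activity + total pause time equals the record
  duration exactly. Bouts are the maximal active segments; the
  long-bout median keeps bouts whose *cumulative path length* exceeds
  10 mm (path length, not net displacement, is the conservative reading
  of "displacement" here and is the documented choice).
- **Activity (ST)**: per sample, the mean speed is the path length in
  the 1 s window centred on it; walking at ≥ 2.7 mm/s, resting at
  ≤ 1 mm/s, previous state kept in between (hysteresis). The initial
  state is resting unless the first window is already at or above the
  walking threshold. Samples whose window is truncated by the record
  edge inherit the state of the nearest fully-windowed sample; bursts
  shorter than the window yield missing values.

## Random-walk simulators

Both generators share the heading model: first heading uniform, then
wrapped-normal increments with concentration r (s.d. σ = √(−2 ln r),
4.80° at r = 0.9965). The heading diffuses at *every* step, pauses
included — measured turning angles are only defined between moving
steps, which is why a ~4.8° per-step σ yields a ~8.5° median turning
angle once pauses stretch the gaps. Step lengths are a Bernoulli(f)
pause process times a speed draw:

- **Correlated walk** — draw = h·X/E[X] with X ~ Chi(df), so h is the
  mean step length in mm.
- **Lévy-walk** — draw = lo·U^(1/(1−μ)), U ~ Uniform(0, 1], the
  standard inverse-CDF power-law sampler (Pareto tail index μ − 1 =
  1.6); isolated in one function.

Per-walk scales (h or lo) are drawn once per individual, uniformly
within ±h_spread/±lo_spread, giving the cohort the between-individual
variability a correlation analysis needs. Positions build iteratively
from the arena centre; an out-of-bounds candidate is replaced by its
radial projection onto the rim and the heading sequence restarts from a
fresh uniform angle at the next step — so at the rim the next movement
points outward with probability > 0.5 and walks linger at the border,
which is the intended boundary behaviour.

**Calibration of the shipped defaults.** f, r, μ and the session shape
(8999 movements, 900 s at 10 Hz) are fixed study conditions
(f = 0.15, r = 0.9965 correlated; f = 0.12, r = 0.9963, μ = 2.6 Lévy).
The Chi speed convention is genuinely open ("around a mean value h"
names no d.o.f.), so it was calibrated once against the three fitted
summary statistics — median moving speed ≈ 13.4/13.9 mm/s, median
turning angle ≈ 8.3°, TT activity ≈ 33% of 900 s — and then frozen:
df = 1 (half-normal) with h = 0.88 mm. With df = 2 the post-filter
median speed saturates near 12 mm/s for any h because the 0.8 mm filter
dominates the kept-step median, while raising h inflates activity; the
heavier half-normal tail reaches the speed target while keeping
activity in band. The shipped defaults give ≈ 13.7 mm/s, 31.4%, 8.7°
(correlated) and ≈ 14.0 mm/s (Lévy, lo = 0.8) across seeds.

What the simulators emulate — and do not: they reproduce session
length, sampling rate, pause frequency, heading persistence, speed
scale and boundary confinement, and hence the chance levels of the
stripe and centre metrics. They do not emulate centrophobic place
preference, stripe fixation, the fractal structure of real pause
durations, or jump-free locomotion (the Lévy tail produces jumps real
flies do not show). Passing chance-level tests therefore validates the
*metrics*, not any claim about real behaviour.

## Cohort statistics

- **Correlations**: pairwise Pearson r with two-sided p-values; the
  significance mask uses α = 0.05, uncorrected (exposed as a flag).
  Zero-variance or NaN metrics are excluded with a warning.
- **PCA**: metrics are standardized (ddof = 1) and decomposed with a
  covariance PCA, which on z-scores equals an eigendecomposition of the
  Pearson correlation matrix; eigenvalues sum to the number of retained
  metrics. ST activity metrics are discarded beforehand (they duplicate
  speed information). 80% confidence ellipses for group score clouds
  come from the chi-square quantile on the score covariance.
- **Transition maps**: all samples of a group are binned on a 60×60
  square grid over the platform bounding box. Square bins are used rather
  than hexagons (hexagonal tilings complicate the blur for no gain at
  this resolution); the blur kernel carries the ring weights 21/16/4/1
  by Chebyshev ring (self/1st/2nd/3rd), normalized, with
  mass-conserving renormalization at the grid edge. The colour ceiling
  is the 95% quantile of the nonzero blurred counts, computed after the
  blur.

## Tracker

Detection chain per frame: threshold (animal darker than background),
invert, Gaussian blur (σ = 2 px default), connected components
(8-connectivity) of the blurred image above the dot threshold, each
component's brightest pixel as a candidate (ties broken toward the
lowest row, then column, for determinism). Nearest-to-previous wins
among candidates; globally brightest on the first frame or after a
loss. A missing or out-of-platform detection starts a new burst (one
increment per undetectable run). Detection thresholds are interactive settings in live use; the shipped
defaults are calibrated on the synthetic fixtures. Because candidates
are integer pixels, noiseless localization error is bounded by half a
pixel per axis; the synthetic-frame round trip measures ≤ 1 px maximum
error without noise and < 2 px mean error at σ = 5 intensity noise.

## Problem sizes and determinism

Tests and the acceptance script use 20-walk cohorts of 9000 samples
(the standard session), and smaller cohorts (4 × 1500 steps) plus
240×240-px frame sequences (60–400 frames) where the full session adds
nothing to the property under test. All randomness flows through
`numpy.random.Generator` seeded explicitly; identical seeds give
bit-identical cohorts and metrics CSVs.

## Known limitations

- The XML metadata layout is this package's own flat schema; other
  tools' layouts are not parsed, only this dialect.
- Transition maps use square bins with a ring-weighted blur as
  described above; they are density maps, not exact hexagonal tilings.
- MANOVA-style group testing is deliberately out of scope: export the
  metrics CSV to a statistics package.
- The ST segmentation classifies samples, so its durations quantize to
  0.1 s and its totals are not constrained by the TT conservation
  identity.
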