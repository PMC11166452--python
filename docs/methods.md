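# Methods

## Scale-dependent curvature angles

The analysis is purely spatial: a trajectory is parameterised by the
arclength *s* travelled along it, never by time.  On a uniform arclength
grid with step *ds* (default 0.04 m), the Lagrangian increment at scale λ
is δX(s, λ) = X(s + λ) − X(s), and the curvature angle θ(s, λ) is the
angle between δX(s, λ) and δX(s + λ, λ), computed as the arccos of their
normalised dot product with the cosine clamped to [−1, 1] (a pure
floating-point guard near 0° and 180°).  Only the absolute angle is kept;
left/right asymmetries are outside the scope of the statistic.

Angle start positions advance by one grid step *ds* (maximally
overlapping increments), giving `floor((L − 2λ)/ds) + 1` samples on a
track of length L — 319 samples at λ = 0.04 m and exactly 1 at
λ = 6.40 m on a 12.80 m track.  λ is restricted to integer multiples of
*ds* so that no second interpolation enters the increment; the default
scale grid is 0.04–6.40 m in 0.04 m steps (160 scales).  Scales with
2λ > L yield missing curve entries, which propagate as missing (NaN,
n = 0) and are never imputed; short approach segments routinely produce
them.

Per-track curves average |θ| over all samples at one scale; group curves
average the per-track means with equal weight per track, excluding tracks
missing at that scale.  Slope diagnostics are ordinary least-squares line
fits, in log₁₀–log₁₀ space (dimensionless scaling exponent: 0.5 Brownian,
1.0 ballistic; default regime 0.04–1.3 m) or in linear space (turning
rate in deg m⁻¹; default regime 1.2–6.4 m, where spiralling search makes
the mean-angle curve rise linearly).  A line model fitted by
Levenberg–Marquardt would give identical estimates, since the problem is
linear in its parameters.  Non-positive means are dropped from log–log
fits with a warning.

## Smoothing and resampling

Digitised traces are polygonal.  Each trace is divided into blocks of 40
digitisation points, adjacent blocks sharing exactly one boundary point;
each block is the control polygon of a Bézier curve evaluated by
De Casteljau's algorithm at as many uniformly spaced parameter values as
the block has points.  Because Bézier curves interpolate their end control
points, the sub-curves join continuously (C⁰; tangent continuity is not
required) and the output keeps the input's point count and endpoints.
Each sub-curve lies in the convex hull of its block, which preserves
small loops and turns of diameter large compared with the point spacing.
The uniform parameter grid induces slightly non-uniform spacing along the
curve; the subsequent arclength resampling removes it.

Resampling is linear interpolation along the (smoothed) polyline at
arclengths 0, ds, 2ds, …: it adds no smoothing of its own, which is why
the Bézier step is separate and explicit.  Consecutive duplicate points
(stationary animal) are collapsed first, since zero-length increments
leave the angle undefined.  The resampled points sit at exactly uniform
arclength positions along the source polyline; their straight-line
(chord) spacing equals *ds* exactly within straight sections and falls
short of it by O((ds·curvature)²) where a step crosses a corner —
synthetic tracks, which integrate headings in exact *ds* steps, satisfy
the chord criterion to machine precision.  Coordinates are Cartesian
metres (y north); no geographic projection is involved, and time stamps
are ignored throughout.

One numerical wrinkle: the histogram scale of 0.50 m is not an integer
multiple of the 0.04 m grid.  Rather than move the scale to 0.48 or
0.52 m, the pipeline re-grids the segment at 0.50/12 m for the histogram
profile, keeping the 50 cm scale exact; the turning-point rule snaps its
0.5 m heading chord to the nearest grid multiple (0.48 m).  At these
resolutions both choices are far below the scale of interest.

## Approach/search segmentation

A run is split at the first conspicuous turning point: the first place
where the path deviates from its current direction by at least 30° and
does not revert to that direction for at least another 3 m.  Search
segments are evaluated up to 12.80 m from the search onset, making all
searches comparable in length; without a turning point the whole run
counts as approach.

Operationalising the rule on a continuous track needs three choices the
rule itself does not fix:

* *Current direction* is the heading of a 0.5 m chord (snapped to the
  grid), passed through a 1 m running circular mean.  Raw per-grid-point
  headings are dominated by digitisation and gait noise; comparing a
  heading only with the heading one grid point earlier can never
  accumulate a 30° deviation on a smooth track, so the reference heading
  is taken one full persistence window (3 m) earlier.
* The reference must be an *established* direction: the smoothed headings
  in the metre preceding the reference point must all lie within the
  threshold of it.  Without this, a transient excursion (a jink the
  animal immediately abandons) can serve as reference, and the normal
  course afterwards masquerades as a sustained deviation.
* The threshold crossing lags the physical onset of a gradual turn, so
  the reported turning point is back-dated to where the deviation from
  the reference last fell below 10°, and centred for the chord and
  smoothing windows.

"Did not revert" is read strictly: the deviation stays at or above 30° at
every grid point for the full 3 m.  A 45° jink that returns to course
within 1 m is therefore never a turning point, while a sustained turn of
any angle ≥ 30° always is.  On synthetic cohorts with known search
onsets the median split error is well under 0.5 m (the residual scatter
comes from orientation noise making the onset itself fuzzy at the
decimetre scale).  Turning points whose persistence window would extend
beyond the end of the track are not confirmed.

## Angle distributions at the 50 cm scale

Angles are pooled per group (pooling across animals; per-animal
distributions would weight animals equally instead, but the pooled count
is what the histogram sample sizes refer to) into 12 equal-width bins on
[0°, 180°], half-open [lo, hi) with the last bin closed.  The distance of
a sample's shared vertex X(s + λ) to the (fictive) goal assigns it to a
goal-distance band — 0–0.5, 0.5–1, 1–9 m, half-open with the outermost
edge closed; samples beyond all bands are dropped and counted.

Two non-uniformity measures grade each histogram:

* the 1-Wasserstein distance between the empirical angle distribution and
  the uniform distribution on [0, 180]°, reported in degrees.  The
  default mode integrates |ECDF − uniform CDF| exactly (deterministic and
  seed-free); a sampled mode compares against n uniform draws instead,
  for the Monte Carlo variant of the same comparison.  The two agree to
  O(180/√n) on uniform data.
* the mean histogram deviation, Σᵢ |cᵢ − n/12| / n over the 12 bin counts
  — zero for level bins, 11/6 when one bin holds everything.  The
  "mean" of the histogram is the mean bin occupancy n/12 (the only
  reading with consistent units).  The measure is scale-free in the
  counts but sensitive to bin-height scatter at small n.

Histograms are ranked separately by each measure, rank 1 = largest
deviation, ties averaged; empty pools are excluded from the ranking with
a note.  Experience groups are compared with the Epps–Singleton and
Kolmogorov–Smirnov two-sample tests (scipy implementations); no
multiple-testing correction is applied, and Epps–Singleton is reported as
not-applicable below 5 observations per sample.  A chi-squared
goodness-of-fit check is available as a diagnostic only: it is too
sensitive to the histogram representation to serve as the primary
measure.

## Synthetic trajectories

The generator reproduces the statistical structure the analysis assumes,
not the navigation mechanisms (no path integration or landmark guidance
is simulated).  All generators are deterministic given their seed and
integrate headings in exact *ds* steps.

* **Straight line / constant-curvature arc** — degenerate fixtures with
  closed-form statistics.  The arc is the constant-turn polygon with side
  exactly *ds* (heading advances ds/R per step), for which the curvature
  angle obeys θ(λ) = (180/π)·λ/R exactly; points sampled on a true circle
  would violate both the exact-spacing and the closed-form identity at
  the 10⁻⁶ level through the chord/arc distinction.
* **Wormlike chain** — heading increments i.i.d. Gaussian, mean 0,
  variance ds/P rad² for persistence length P.  The heading then diffuses
  linearly in arclength, so mean |θ| grows as λ^0.5 below P (the mean
  absolute value of a centred Gaussian whose s.d. grows as √λ): the
  Brownian signature by construction.
* **Uncorrelated walk** — i.i.d. uniform heading per step.  At scales
  ≥ 25 steps adjacent increments are independent isotropic vectors, the
  angle between them uniform on [0, 180]°, hence mean 90°.
* **Search** — heading turns at `spiral_turn_rate` (default 12 deg m⁻¹ =
  one full turn per 30 m of path) with a sign flipping at Poisson-spaced
  reversals (mean spacing 30 m, roughly one flip per full turn), plus
  Brownian orientation noise (15 deg m^(−1/2)), plus a weak heading bias
  toward the goal proportional to the distance from it
  (0.003 m⁻¹) that keeps the search centred and its occupancy density
  decaying with goal distance.  None of spacing, noise or bias has an
  empirically fixed value; these defaults were chosen once so that, at
  the stated spiral rate, an ensemble of default searches returns that
  rate from the lin–lin fit of its grand-mean curve (a stronger bias
  adds orbit-like curvature and inflates the recovered rate).  An
  optional conspicuous onset turn (80° over 0.8 m in cohort runs, off
  otherwise) models the about-turn at the moment the goal vector runs
  out; it is what makes the search onset sharply localisable.
* **Approach** — wormlike noise on a heading relaxing toward the
  momentary goal bearing (0.5 m⁻¹, stiffening near the goal so the walk
  cannot orbit it), terminating within *ds* of the goal.
* **Cohort** — six groups (nest 30/31, sparse feeder 13/15, plentiful
  feeder 30/22 inexperienced/experienced tracks), each run an approach
  from 10 m out at a random bearing concatenated with a 12.80 m search.
  Experience raises approach persistence and search focus (higher spiral
  rate, lower noise), a qualitative emulation only.  Per-track seeds
  spawn from the cohort seed, so cohorts are byte-identical under a fixed
  seed.  A ground-truth manifest records the true search-onset arclength
  and parameters per track.

What the generator does **not** emulate: the heavy sub-metre-scale
tortuosity of real search paths.  With the noise level that keeps the
spiral rate recoverable, synthetic searches are much smoother below 1 m
than field recordings, so their 50 cm angle histograms are strongly
zero-peaked rather than near-uniform, and the goal-distance bands differ
far more in sample count than in shape.  Pipeline tests on synthetic
cohorts therefore validate bookkeeping, segmentation, ranking mechanics
and the scaling diagnostics — not the field-data histogram shapes, which
require the original recordings.  Digitisation error, human tracing
error and variable point spacing (4–10 cm in the recordings the format
is modelled on; `resolution_hint` is advisory only) are likewise not
simulated.

## Problem sizes and numerical choices

Ensemble checks use 50–100 tracks of 12.8 m (the scaling-law tests) and
the 141-track cohort for segmentation; the benchmark script uses 60
wormlike tracks, one arc and 1000 uncorrelated walks on a coarsened
large-λ grid — at 25° per-track spread, the grand-mean angle then
carries a standard error below 1°.  The log–log ensemble slope for
wormlike chains sits slightly below 0.5 (≈ 0.46): at the single-step
scale the chord average does not yet apply and the curve starts a factor
√(3/2) high, tilting the fit; the effect shrinks with the lower fit
bound and is well inside the ±0.1 band used for the Brownian diagnostic.
Ties in rankings take average ranks; empty histograms, zero-norm
increments and short segments are logged, never silently dropped.
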