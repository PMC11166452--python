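# tortuosity

Geometrical multiscale tortuosity analysis of planar walking trajectories,
built for movement ecologists studying goal approach and goal-centred
search in central-place foragers such as desert ants.

## The statistic

A recorded run is an ordered point sequence in metres.  After Bézier
smoothing of the square-cut digitised trace, the path is resampled to a
uniform arclength grid (step *ds* = 0.04 m), replacing time by distance
travelled.  For a scale λ, the Lagrangian spatial increment is

```
δX(s, λ) = X(s + λ) − X(s)
```

and the scale-dependent curvature angle is the angle between adjacent
increments,

```
θ(s, λ) = arccos [ δX(s, λ) · δX(s + λ, λ) / (|δX(s, λ)| |δX(s + λ, λ)|) ]
```

θ = 0° means the path runs straight at that scale, 90° a left/right turn,
180° a U-turn; only |θ| is analysed.  Averaging |θ| along a track for
each λ of the grid 0.04–6.40 m (0.04 m steps, 160 scales) yields a
mean-angle curve whose log–log slope diagnoses path structure: 0.5 is the
Brownian (random-walk) signature, 1.0 the ballistic one, and the lin–lin
slope of the large-λ regime is a spiral turning rate in deg m⁻¹.

Around that core the package provides:

* approach/search segmentation at the first conspicuous turning point
  (≥ 30° deviation from the current direction, not reverting for ≥ 3 m),
* turning-angle histograms at λ = 0.50 m in goal-distance bands
  (0–0.5, 0.5–1, 1–9 m), graded against the uniform distribution by the
  1-Wasserstein distance and the mean histogram deviation, with 1–18
  rankings,
* Epps–Singleton and Kolmogorov–Smirnov comparisons between experience
  groups,
* a synthetic-trajectory generator (straight lines, constant-curvature
  arcs, wormlike chains, uncorrelated walks, spiral-plus-random-walk
  searches, and a full six-group cohort with known search onsets) so the
  whole pipeline is testable without field data.

## Worked example

```python
import tortuosity as tt

model = tt.TortuosityModel.from_synthetic(tt.CohortConfig(seed=7))
results = model.fit()
print(results.summary())
```

This simulates the default 141-track cohort (nest 30/31, sparse feeder
13/15, plentiful feeder 30/22 inexperienced/experienced animals), splits
each run into approach and search, and prints, among other tables:

```
Slope fits of grand-mean theta(lambda) curves
----------------------------------------------------------------
  feeder_plentiful/experienced/approach        log-log  slope  0.566
  feeder_plentiful/experienced/search          lin-lin  slope 13.347 deg/m
  ...
  nest/experienced/search                      lin-lin  slope 11.607 deg/m
```

The approach log–log slopes near 0.5 are the Brownian signature of the
directional noise on the goal-bound runs; the search lin–lin slopes near
12 deg m⁻¹ recover the generator's spiral turning rate (one full turn per
30 m of path).  The summary continues with the 18 search histograms
(6 groups × 3 goal-distance bands), each annotated with its Wasserstein
distance to uniformity, mean histogram deviation and both ranks, and with
the experience-group comparisons (both tests reject equality of the
inexperienced vs experienced approach-angle distributions in all three
goal types).

The same pipeline runs from the shell:

```sh
tortuosity simulate --seed 7 --outdir cohort/
tortuosity analyze cohort/manifest.csv --outdir results/
tortuosity report results/
```

`analyze` accepts any cohort of plain-text track files (columns
`x_m,y_m`, optional `#`-metadata header) listed in a manifest CSV, so
field recordings can be analysed the same way.

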