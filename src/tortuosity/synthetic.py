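"""Synthetic walking trajectories with known ground truth.

Generators emulate the statistical structure the analysis assumes:
near-straight goal approaches carrying Brownian directional noise
(wormlike chains), goal-centred searches built as an alternating spiral
with a superimposed random walk, uncorrelated random walks, and the
degenerate fixtures (straight line, constant-curvature arc) that have
closed-form angle statistics.  A full cohort mirrors the six
experimental groups of a central-place-foraging study design
(nest / sparse feeder / plentiful feeder x inexperienced / experienced)
with known per-track search-onset arclengths, so segmentation and every
downstream statistic can be validated without any field data.

All generators integrate headings in steps of exactly ``ds``, so their
output satisfies the uniform-spacing invariant of
:class:`~tortuosity.tracks.ArclengthTrack` by construction, and all are
deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import (ArclengthTrack, DEFAULT_DS, GroupLabel, SEARCH_EVAL_LENGTH,
                     TrajectoryRecord)

TWO_PI = 2.0 * math.pi


def _integrate_headings(psi: np.ndarray, ds: float,
                        start: tuple[float, float] = (0.0, 0.0)) -> ArclengthTrack:
    """Turn a per-step heading sequence (radians) into a track with spacing ds."""
    steps = ds * np.column_stack([np.cos(psi), np.sin(psi)])
    pts = np.concatenate([[start], start + np.cumsum(steps, axis=0)])
    return ArclengthTrack(pts, ds=ds)


def gen_line(length: float, ds: float = DEFAULT_DS, heading: float = 0.0,
             start: tuple[float, float] = (0.0, 0.0)) -> ArclengthTrack:
    """Straight track: theta == 0 at every scale."""
    n = int(round(length / ds))
    if n < 1:
        raise ValueError("length must be at least ds")
    psi = np.full(n, math.radians(heading))
    return _integrate_headings(psi, ds, start)


def gen_circle(radius: float, length: float, ds: float = DEFAULT_DS,
               heading0: float = 0.0, ccw: bool = True,
               start: tuple[float, float] = (0.0, 0.0)) -> ArclengthTrack:
    """Constant-curvature arc: the analytic oracle for the curvature angle.

    Built as the constant-turn polygon with side exactly ``ds`` (heading
    advances ds/radius per step).  Sums of k consecutive equal-turn steps
    rotate by exactly k*ds/radius between adjacent increments, so the
    curvature angle obeys the closed form

        theta(lambda) = (180/pi) * lambda / radius   (degrees)

    exactly, and theta is proportional to lambda (log-log slope 1.0, the
    ballistic signature).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = int(round(length / ds))
    if n < 1:
        raise ValueError("length must be at least ds")
    dpsi = (1.0 if ccw else -1.0) * ds / radius
    psi = math.radians(heading0) + dpsi * np.arange(n)
    return _integrate_headings(psi, ds, start)


def circle_theta(radius: float, lam: float | np.ndarray) -> float | np.ndarray:
    """Closed-form curvature angle (deg) of the constant-curvature track."""
    return np.degrees(np.asarray(lam, dtype=float) / radius)


def gen_wormlike(persistence: float, length: float, ds: float = DEFAULT_DS,
                 seed: int | np.random.Generator = 0, heading0: float = 0.0,
                 start: tuple[float, float] = (0.0, 0.0)) -> ArclengthTrack:
    """Wormlike chain: tangent heading performs Brownian orientation diffusion.

    Heading increments are i.i.d. Gaussian with mean 0 and variance
    ``ds / persistence`` (radians squared), so heading variance grows
    linearly in arclength and the mean curvature angle grows like
    lambda^0.5 below the persistence length — the Brownian signature.
    """
    if persistence <= 0:
        raise ValueError("persistence must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(length / ds))
    if n < 1:
        raise ValueError("length must be at least ds")
    dpsi = rng.normal(0.0, math.sqrt(ds / persistence), size=n - 1)
    psi = math.radians(heading0) + np.concatenate([[0.0], np.cumsum(dpsi)])
    return _integrate_headings(psi, ds, start)


def gen_uncorrelated(step: float, length: float, ds: float = DEFAULT_DS,
                     seed: int | np.random.Generator = 0,
                     start: tuple[float, float] = (0.0, 0.0)) -> ArclengthTrack:
    """Uncorrelated random walk: i.i.d. uniform heading per step of given length.

    At scales well above the step length the absolute curvature angle is
    uniformly distributed on [0, 180] deg ("equi-partitioning"), so its
    mean tends to 90 deg.  The walk is laid out on the ds grid (step must
    be an integer multiple of ds).
    """
    k = int(round(step / ds))
    if k < 1 or abs(step - k * ds) > 1e-9:
        raise ValueError("step must be a positive integer multiple of ds")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(length / ds))
    n_steps = int(math.ceil(n / k))
    psi = np.repeat(rng.uniform(-math.pi, math.pi, size=n_steps), k)[:n]
    return _integrate_headings(psi, ds, start)


@dataclass(frozen=True)
class SearchModelParams:
    """Parameters of the spiral-plus-random-walk search generator.

    spiral_turn_rate : deg/m
        Unsigned turning rate of the spiral component; 12 deg/m makes one
        full 360-deg turn per 30 m of path.
    reversal_mean_spacing : m
        Mean arclength between sign flips of the spiralling direction
        (Poisson process along the path); inf disables reversals.
    tangent_noise : deg/sqrt(m)
        Intensity of the superimposed Brownian orientation noise.
    return_to_centre_rate : 1/m
        Strength of the weak heading bias toward the goal that keeps the
        search centred and produces occasional passes near it.
    onset_turn_deg, onset_turn_length : deg, m
        Extra conspicuous turn executed over the first metres of the
        search — the about-turn an animal makes when its goal vector runs
        out and the expected goal is not there.  Zero by default (pure
        spiral-plus-random-walk); the cohort generator switches it on.
    """

    spiral_turn_rate: float = 12.0
    reversal_mean_spacing: float = 30.0
    tangent_noise: float = 15.0
    return_to_centre_rate: float = 0.003
    onset_turn_deg: float = 0.0
    onset_turn_length: float = 0.8

    def __post_init__(self) -> None:
        if min(self.spiral_turn_rate, self.tangent_noise,
               self.return_to_centre_rate, self.onset_turn_deg) < 0 \
                or self.reversal_mean_spacing <= 0 or self.onset_turn_length <= 0:
            raise ValueError("search parameters must be non-negative")


def gen_search(params: SearchModelParams = SearchModelParams(),
               goal: tuple[float, float] = (0.0, 0.0),
               length: float = SEARCH_EVAL_LENGTH, ds: float = DEFAULT_DS,
               seed: int | np.random.Generator = 0,
               heading0: float | None = None) -> ArclengthTrack:
    """Goal-centred search: alternating spiral plus random walk.

    The heading turns at ``spiral_turn_rate`` with a sign that flips at
    Poisson-spaced reversals, plus Brownian orientation noise, plus a weak
    bias toward the goal whose strength grows with distance from it.  The
    track starts at the goal.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(length / ds))
    if n < 1:
        raise ValueError("length must be at least ds")
    psi = rng.uniform(-math.pi, math.pi) if heading0 is None else math.radians(heading0)
    sign = rng.choice([-1.0, 1.0])
    omega = math.radians(params.spiral_turn_rate)
    sigma = math.radians(params.tangent_noise)
    onset_rate = math.radians(params.onset_turn_deg) / params.onset_turn_length
    p_flip = min(1.0, ds / params.reversal_mean_spacing)
    flips = rng.random(n - 1) < p_flip
    noise = rng.normal(0.0, sigma * math.sqrt(ds), size=n - 1)
    g = np.asarray(goal, dtype=float)
    pos = g.copy()
    pts = np.empty((n + 1, 2))
    pts[0] = pos
    for i in range(n):
        pos = pos + ds * np.array([math.cos(psi), math.sin(psi)])
        pts[i + 1] = pos
        if i == n - 1:
            break
        if flips[i]:
            sign = -sign
        dist = float(np.hypot(*(pos - g)))
        if dist > 0:
            bearing = math.atan2(g[1] - pos[1], g[0] - pos[0])
            err = (bearing - psi + math.pi) % TWO_PI - math.pi
            attract = params.return_to_centre_rate * dist * ds * err
        else:
            attract = 0.0
        turn = omega * ds
        if (i + 1) * ds < params.onset_turn_length:
            turn += onset_rate * ds
        psi = psi + sign * turn + noise[i] + attract
    return ArclengthTrack(pts, ds=ds)


def gen_approach(start: tuple[float, float], goal: tuple[float, float],
                 persistence: float = 25.0, ds: float = DEFAULT_DS,
                 seed: int | np.random.Generator = 0,
                 steering_rate: float = 0.5,
                 max_length_factor: float = 10.0) -> ArclengthTrack:
    """Near-straight goal approach: wormlike noise on a goal-seeking heading.

    The heading relaxes toward the momentary goal bearing at
    ``steering_rate`` per metre (stiffening close to the goal so the walk
    cannot orbit it) with Brownian orientation noise of the given
    persistence superimposed.  The walk stops within ``ds`` of the goal.
    """
    if np.allclose(start, goal):
        raise ValueError("start must differ from goal")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pos = np.asarray(start, dtype=float).copy()
    g = np.asarray(goal, dtype=float)
    psi = math.atan2(g[1] - pos[1], g[0] - pos[0])
    beeline = float(np.linalg.norm(g - pos))
    max_steps = int(max_length_factor * beeline / ds) + 10
    sd = math.sqrt(ds / persistence) if math.isfinite(persistence) else 0.0
    pts = [pos.copy()]
    for _ in range(max_steps):
        pos = pos + ds * np.array([math.cos(psi), math.sin(psi)])
        pts.append(pos.copy())
        dist = float(np.linalg.norm(g - pos))
        if dist <= ds:
            break
        bearing = math.atan2(g[1] - pos[1], g[0] - pos[0])
        err = (bearing - psi + math.pi) % TWO_PI - math.pi
        gain = steering_rate + 2.0 / max(dist, 0.2)  # stiffen near the goal
        psi = psi + min(1.0, gain * ds) * err + (rng.normal(0.0, sd) if sd else 0.0)
    else:
        raise RuntimeError("approach failed to reach the goal")
    return ArclengthTrack(np.asarray(pts), ds=ds)


# ---------------------------------------------------------------------------
# Six-group cohort
# ---------------------------------------------------------------------------

#: Per-group trajectory counts: the study design's sample sizes.
DEFAULT_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("nest", "inexperienced"): 30,
    ("nest", "experienced"): 31,
    ("feeder_sparse", "inexperienced"): 13,
    ("feeder_sparse", "experienced"): 15,
    ("feeder_plentiful", "inexperienced"): 30,
    ("feeder_plentiful", "experienced"): 22,
}

#: Qualitative group structure: experience straightens approaches (longer
#: persistence) and focuses searches (higher spiral rate, less noise);
#: inexperienced feeder searches spiral less.  Values are free model
#: choices, not estimates from any field data.
DEFAULT_GROUP_PARAMS: dict[tuple[str, str], dict] = {
    ("nest", "inexperienced"): dict(persistence=15.0, spiral=12.0, noise=20.0),
    ("nest", "experienced"): dict(persistence=25.0, spiral=12.0, noise=19.0),
    ("feeder_sparse", "inexperienced"): dict(persistence=12.0, spiral=7.0, noise=22.0),
    ("feeder_sparse", "experienced"): dict(persistence=30.0, spiral=11.0, noise=17.0),
    ("feeder_plentiful", "inexperienced"): dict(persistence=15.0, spiral=8.0, noise=22.0),
    ("feeder_plentiful", "experienced"): dict(persistence=40.0, spiral=12.0, noise=15.0),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition configuration of the synthetic cohort."""

    group_sizes: tuple[tuple[tuple[str, str], int], ...] = tuple(DEFAULT_GROUP_SIZES.items())
    ds: float = DEFAULT_DS
    seed: int = 0
    approach_beeline: float = 10.0   # nest-feeder distance (m)
    search_length: float = SEARCH_EVAL_LENGTH

    def sizes(self) -> dict[tuple[str, str], int]:
        return dict(self.group_sizes)


def gen_cohort(cfg: CohortConfig = CohortConfig(),
               ) -> tuple[list[TrajectoryRecord], pd.DataFrame]:
    """Generate the full six-group cohort of approach + search runs.

    Each record concatenates a goal approach from 10 m out (random bearing)
    with a goal-centred search starting at the approach's final heading.
    Returns the records plus a ground-truth manifest (one row per record:
    animal id, group, true search-onset arclength, generator parameters,
    per-track seed).  Deterministic given ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    records: list[TrajectoryRecord] = []
    truth_rows = []
    sizes = cfg.sizes()
    children = root.spawn(len(sizes))
    for (key, n_tracks), group_seed in zip(sizes.items(), children):
        goal_type, experience = key
        pars = DEFAULT_GROUP_PARAMS[key]
        track_seeds = group_seed.spawn(n_tracks)
        for j, ss in enumerate(track_seeds):
            rng = np.random.default_rng(ss)
            goal = (0.0, 0.0)
            bearing = rng.uniform(-math.pi, math.pi)
            start = (cfg.approach_beeline * math.cos(bearing),
                     cfg.approach_beeline * math.sin(bearing))
            approach = gen_approach(start, goal, persistence=pars["persistence"],
                                    ds=cfg.ds, seed=rng)
            d = approach.points[-1] - approach.points[-2]
            final_heading = math.degrees(math.atan2(d[1], d[0]))
            search = gen_search(
                SearchModelParams(spiral_turn_rate=pars["spiral"],
                                  tangent_noise=pars["noise"],
                                  onset_turn_deg=80.0),
                goal=tuple(approach.points[-1]), length=cfg.search_length,
                ds=cfg.ds, seed=rng, heading0=final_heading,
            )
            pts = np.vstack([approach.points, search.points[1:]])
            animal_id = f"{goal_type[:4]}_{experience[:5]}_{j:03d}"
            rec = TrajectoryRecord(points=pts, animal_id=animal_id,
                                   group=GroupLabel(goal_type, experience),
                                   goal=goal, resolution_hint=cfg.ds)
            records.append(rec)
            truth_rows.append({
                "animal_id": animal_id,
                "goal_type": goal_type,
                "experience": experience,
                "split_s": approach.total_arclength,
                "persistence": pars["persistence"],
                "spiral_turn_rate": pars["spiral"],
                "tangent_noise": pars["noise"],
                "spawn_key": "/".join(str(k) for k in ss.spawn_key),
            })
    return records, pd.DataFrame(truth_rows)
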