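"""Trajectory data model, track-file I/O and arclength geometry.

A recorded run is an ordered sequence of planar points in metres
(:class:`TrajectoryRecord`).  All angular statistics are computed on a
track resampled to a uniform arclength grid (:class:`ArclengthTrack`),
which replaces time by distance travelled along the path: the analysis
is purely spatial.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GOAL_TYPES = ("nest", "feeder_sparse", "feeder_plentiful")
EXPERIENCE_LEVELS = ("inexperienced", "experienced")
PHASES = ("approach", "search")

#: Evaluation length shared by all search trajectories (metres): the length
#: of the shortest recorded search, applied to every record for comparability.
SEARCH_EVAL_LENGTH = 12.80

#: Default arclength grid step in metres; every analysis scale lambda is an
#: integer multiple of this step, so no second interpolation is ever needed.
DEFAULT_DS = 0.04


class TrackParseError(ValueError):
    """Raised when a track file contains a malformed row."""


@dataclass(frozen=True)
class GroupLabel:
    """Experimental group: goal type x experience level (x optional phase)."""

    goal_type: str
    experience: str
    phase: str | None = None

    def __post_init__(self) -> None:
        if self.goal_type not in GOAL_TYPES:
            raise ValueError(f"unknown goal_type {self.goal_type!r}")
        if self.experience not in EXPERIENCE_LEVELS:
            raise ValueError(f"unknown experience {self.experience!r}")
        if self.phase is not None and self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")

    def with_phase(self, phase: str) -> "GroupLabel":
        return replace(self, phase=phase)

    def __str__(self) -> str:
        parts = [self.goal_type, self.experience]
        if self.phase:
            parts.append(self.phase)
        return "/".join(parts)


def _as_points(points: Iterable) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of x, y in metres")
    return pts


@dataclass
class TrajectoryRecord:
    """Raw ordered planar points (metres) with goal and group metadata."""

    points: np.ndarray
    animal_id: str = "unknown"
    group: GroupLabel | None = None
    goal: tuple[float, float] | None = None
    resolution_hint: float | None = None  # digitisation spacing, advisory only

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if len(self.points) < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("trajectory coordinates must be finite")
        if self.goal is not None:
            self.goal = (float(self.goal[0]), float(self.goal[1]))
            if not np.all(np.isfinite(self.goal)):
                raise ValueError("goal coordinates must be finite")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def has_duplicate_points(self) -> bool:
        """True if consecutive duplicate points (stationary animal) occur."""
        return bool(np.any(np.all(np.diff(self.points, axis=0) == 0.0, axis=1)))

    @property
    def path_length(self) -> float:
        return float(cumulative_arclength(self.points)[-1])


@dataclass
class ArclengthTrack:
    """Track on a uniform arclength grid with step ``ds`` (metres).

    Consecutive points are exactly ``ds`` apart along the polyline, so grid
    index ``i`` corresponds to arclength ``i * ds``.
    """

    points: np.ndarray
    ds: float

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)
        if len(self.points) < 2:
            raise ValueError("an arclength track needs at least 2 points")
        if self.ds <= 0:
            raise ValueError("ds must be positive")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def total_arclength(self) -> float:
        return (self.n_points - 1) * self.ds

    @property
    def arclengths(self) -> np.ndarray:
        return np.arange(self.n_points) * self.ds

    def validate_spacing(self, rtol: float = 1e-6) -> None:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if not np.allclose(seg, self.ds, rtol=rtol, atol=rtol * self.ds):
            raise ValueError("grid spacing deviates from ds beyond tolerance")


def cumulative_arclength(points: Iterable) -> np.ndarray:
    """Arclength of each vertex along the polyline; starts at 0."""
    pts = _as_points(points) if not isinstance(points, np.ndarray) else points
    if pts.ndim != 2:
        pts = _as_points(points)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def collapse_duplicates(points: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate points (zero-length increments)."""
    pts = _as_points(points)
    keep = np.concatenate([[True], np.any(np.diff(pts, axis=0) != 0.0, axis=1)])
    return pts[keep]


def resample_uniform(record: TrajectoryRecord | np.ndarray, ds: float = DEFAULT_DS) -> ArclengthTrack:
    """Resample a trajectory to a uniform arclength grid by linear interpolation.

    Interpolation follows the raw polyline; it adds no smoothing of its own
    (smoothing is a separate, explicit step).  The resampled track covers
    arclengths ``0, ds, 2 ds, ...`` up to the largest multiple of ``ds`` not
    exceeding the polyline length.
    """
    pts = record.points if isinstance(record, TrajectoryRecord) else _as_points(record)
    pts = collapse_duplicates(pts)
    if ds <= 0:
        raise ValueError("ds must be positive")
    s = cumulative_arclength(pts)
    length = s[-1]
    # tiny tolerance so a track of nominal length k*ds survives float rounding
    n_steps = int(np.floor(length / ds + 1e-9))
    if n_steps < 1:
        raise ValueError(f"polyline length {length:.4g} m is shorter than ds={ds:g} m")
    grid = np.arange(n_steps + 1) * ds
    x = np.interp(grid, s, pts[:, 0])
    y = np.interp(grid, s, pts[:, 1])
    return ArclengthTrack(np.column_stack([x, y]), ds=ds)


def distance_to_goal(track: ArclengthTrack, goal: Sequence[float]) -> np.ndarray:
    """Euclidean distance of every grid point to the (fictive) goal."""
    g = np.asarray(goal, dtype=float)
    if g.shape != (2,) or not np.all(np.isfinite(g)):
        raise ValueError("goal must be a finite (x, y) pair")
    return np.linalg.norm(track.points - g, axis=1)


def truncate_to_length(track: ArclengthTrack, max_len: float) -> ArclengthTrack:
    """Keep grid points with arclength <= max_len; no-op on shorter tracks."""
    if max_len < track.ds:
        raise ValueError("max_len must be at least one grid step")
    n_keep = int(np.floor(max_len / track.ds + 1e-9)) + 1
    if n_keep >= track.n_points:
        return track
    return ArclengthTrack(track.points[:n_keep].copy(), ds=track.ds)


# ---------------------------------------------------------------------------
# Track-file format: plain-text delimited, two numeric columns x_m, y_m and
# optional '#'-prefixed 'key: value' metadata header lines.
# ---------------------------------------------------------------------------

_META_KEYS = ("goal_x", "goal_y", "animal_id", "goal_type", "experience",
              "resolution_hint")


def read_track(path: str | Path) -> TrajectoryRecord:
    """Read a track file into a :class:`TrajectoryRecord`.

    Raises :class:`TrackParseError` naming the offending line for malformed
    rows, and ``ValueError`` for files with fewer than two points.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    meta[key.strip()] = val.strip()
                continue
            if line.lower().replace(" ", "").replace("\t", ",").replace(",", "") == "x_my_m":
                continue  # optional column-name row
            cells = [c for c in line.replace(",", " ").replace(";", " ").split() if c]
            if len(cells) < 2:
                raise TrackParseError(f"{path.name}, line {lineno}: expected two columns")
            try:
                xs.append(float(cells[0]))
                ys.append(float(cells[1]))
            except ValueError as exc:
                raise TrackParseError(
                    f"{path.name}, line {lineno}: non-numeric cell ({exc})"
                ) from None
    if len(xs) < 2:
        raise ValueError(f"{path.name}: a track needs at least 2 points")
    goal = None
    if "goal_x" in meta and "goal_y" in meta:
        goal = (float(meta["goal_x"]), float(meta["goal_y"]))
    group = None
    if "goal_type" in meta and "experience" in meta:
        group = GroupLabel(meta["goal_type"], meta["experience"])
    res = float(meta["resolution_hint"]) if "resolution_hint" in meta else None
    return TrajectoryRecord(
        points=np.column_stack([xs, ys]),
        animal_id=meta.get("animal_id", path.stem),
        group=group,
        goal=goal,
        resolution_hint=res,
    )


def write_track(record: TrajectoryRecord, path: str | Path) -> None:
    """Write a record in the plain-text track format (round-trips read_track)."""
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# animal_id: {record.animal_id}\n")
    if record.group is not None:
        buf.write(f"# goal_type: {record.group.goal_type}\n")
        buf.write(f"# experience: {record.group.experience}\n")
    if record.goal is not None:
        buf.write(f"# goal_x: {record.goal[0]:.6f}\n")
        buf.write(f"# goal_y: {record.goal[1]:.6f}\n")
    if record.resolution_hint is not None:
        buf.write(f"# resolution_hint: {record.resolution_hint:g}\n")
    buf.write("x_m,y_m\n")
    for x, y in record.points:
        buf.write(f"{x:.6f},{y:.6f}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_manifest(path: str | Path) -> list[TrajectoryRecord]:
    """Read a cohort manifest (CSV: path, goal_type, experience) into records.

    Track paths are resolved relative to the manifest's directory.  Group
    labels in the manifest override any stored in the track files.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"path", "goal_type", "experience"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    records = []
    missing = []
    for _, row in df.iterrows():
        track_path = path.parent / str(row["path"])
        if not track_path.exists():
            missing.append(str(track_path))
            continue
        rec = read_track(track_path)
        rec.group = GroupLabel(str(row["goal_type"]), str(row["experience"]))
        records.append(rec)
    if missing:
        raise FileNotFoundError("missing track files: " + ", ".join(missing))
    return records


def write_manifest(records: Sequence[TrajectoryRecord], directory: str | Path,
                   manifest_name: str = "manifest.csv") -> Path:
    """Write each record as a track file plus a cohort manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        fname = f"track_{i:04d}_{rec.animal_id}.csv"
        write_track(rec, directory / fname)
        if rec.group is None:
            raise ValueError("manifest records need group labels")
        rows.append({"path": fname, "goal_type": rec.group.goal_type,
                     "experience": rec.group.experience})
    manifest = directory / manifest_name
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
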