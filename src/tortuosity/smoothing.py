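"""Bezier sub-curve smoothing of square-cut digitised traces.

Hand-digitised trajectories are polygonal ("square-cut").  Before angular
analysis each trace is divided into blocks of digitisation points; each
block's points act as the control polygon of a Bezier curve evaluated with
De Casteljau's algorithm at as many parameter values as the block has
points.  Because a Bezier curve interpolates its end control points,
adjacent blocks sharing one boundary point join end-to-end without a gap,
and the smoothed trace keeps the original point count.  Small loops and
turns survive: each sub-curve stays inside the convex hull of its block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import TrajectoryRecord


@dataclass(frozen=True)
class SmoothingConfig:
    """Block size = digitisation points per sub-trajectory (default 40)."""

    block_size: int = 40
    eval_count: int | None = None  # points per sub-curve; None -> block size

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.eval_count is not None and self.eval_count < 2:
            raise ValueError("eval_count must be >= 2")


def split_blocks(points: np.ndarray, block_size: int) -> list[np.ndarray]:
    """Split points into consecutive blocks sharing one boundary point.

    Block k covers indices ``[k*(B-1), k*(B-1) + B - 1]``; the final block
    may be shorter but always has at least 2 points.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    stride = block_size - 1
    blocks = []
    start = 0
    while start < len(pts) - 1:
        stop = min(start + block_size, len(pts))
        blocks.append(pts[start:stop])
        start += stride
    return blocks


def decasteljau_eval(control: np.ndarray, t: float) -> np.ndarray:
    """Evaluate the Bezier curve of a control polygon at parameter t.

    Repeated pairwise linear interpolation until a single point remains;
    t=0 gives the first control point, t=1 the last.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    pts = np.asarray(control, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if len(pts) == 0:
        raise ValueError("need at least one control point")
    while len(pts) > 1:
        pts = (1.0 - t) * pts[:-1] + t * pts[1:]
    return pts[0]


def _bezier_curve(control: np.ndarray, n_eval: int) -> np.ndarray:
    """Vectorised De Casteljau over a uniform t grid."""
    t = np.linspace(0.0, 1.0, n_eval)[:, None, None]  # (T, 1, 1)
    pts = np.broadcast_to(np.asarray(control, float)[None], (n_eval, len(control), 2)).copy()
    while pts.shape[1] > 1:
        pts = (1.0 - t) * pts[:, :-1] + t * pts[:, 1:]
    return pts[:, 0]


def bezier_smooth(record: TrajectoryRecord | np.ndarray,
                  cfg: SmoothingConfig = SmoothingConfig()) -> TrajectoryRecord | np.ndarray:
    """Smooth a trajectory blockwise into Bezier sub-curves.

    Each block's points form the control polygon of one sub-curve, evaluated
    at uniformly spaced parameter values (one per control point, unless
    ``cfg.eval_count`` overrides it for full blocks).  Shared block-boundary
    points are emitted once, so the output has exactly the input's point
    count and fixed endpoints.  Returns the same type it was given.
    """
    is_record = isinstance(record, TrajectoryRecord)
    pts = record.points if is_record else np.asarray(record, dtype=float)
    blocks = split_blocks(pts, cfg.block_size)
    pieces = []
    for i, block in enumerate(blocks):
        n_eval = cfg.eval_count if (cfg.eval_count and len(block) == cfg.block_size) else len(block)
        curve = _bezier_curve(block, n_eval)
        pieces.append(curve if i == 0 else curve[1:])  # dedupe shared endpoint
    smoothed = np.vstack(pieces)
    if not is_record:
        return smoothed
    return TrajectoryRecord(
        points=smoothed,
        animal_id=record.animal_id,
        group=record.group,
        goal=record.goal,
        resolution_hint=record.resolution_hint,
    )
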