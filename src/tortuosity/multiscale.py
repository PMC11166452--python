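"""Scale-dependent curvature angles theta(lambda) and scaling diagnostics.

The central statistic: along a track X(s) parameterised by arclength s, the
Lagrangian spatial increment at scale lambda is

    dX(s, lambda) = X(s + lambda) - X(s),

and the curvature angle theta(s, lambda) is the angle between the adjacent
increments dX(s, lambda) and dX(s + lambda, lambda), obtained from the
arccos of their normalised dot product.  theta = 0 deg means the path runs
straight at that scale, 90 deg a left/right turn, 180 deg a U-turn; only
the absolute angle |theta| is analysed.  Averaging |theta| along a track
for each lambda of a scale grid yields the mean-angle curve whose log-log
slope diagnoses path structure: 0.5 is the Brownian (random-walk)
signature, 1.0 the ballistic (smooth/constant-curvature) one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tracks import ArclengthTrack, DEFAULT_DS

logger = logging.getLogger(__name__)

#: Default scale grid: 0.04 m to 6.40 m in 0.04 m increments (160 scales).
DEFAULT_LAMBDA_MIN = 0.04
DEFAULT_LAMBDA_MAX = 6.40


def lambda_grid(lam_min: float = DEFAULT_LAMBDA_MIN,
                lam_max: float = DEFAULT_LAMBDA_MAX,
                step: float = DEFAULT_DS) -> np.ndarray:
    """Scale grid lam_min, lam_min+step, ..., lam_max (inclusive)."""
    n = int(round((lam_max - lam_min) / step)) + 1
    grid = lam_min + step * np.arange(n)
    if np.any(grid <= 0):
        raise ValueError("all scales must be positive")
    return grid


def _lam_steps(lam: float, ds: float) -> int:
    k = lam / ds
    k_int = int(round(k))
    if k_int < 1 or abs(k - k_int) > 1e-6 * max(1.0, k):
        raise ValueError(f"lambda={lam:g} m is not a positive integer multiple of ds={ds:g} m")
    return k_int


def increment(track: ArclengthTrack, s_index: int, lam_steps: int) -> np.ndarray:
    """Lagrangian spatial increment X(s + lambda) - X(s) as a vector (m)."""
    if s_index < 0 or s_index + lam_steps >= track.n_points:
        raise IndexError("increment extends beyond the track")
    return track.points[s_index + lam_steps] - track.points[s_index]


def curvature_angle(track: ArclengthTrack, s_index: int, lam_steps: int) -> float:
    """Angle (deg, in [0, 180]) between adjacent increments at one position."""
    if s_index < 0 or s_index + 2 * lam_steps >= track.n_points:
        raise IndexError("angle needs two increments inside the track")
    v1 = increment(track, s_index, lam_steps)
    v2 = increment(track, s_index + lam_steps, lam_steps)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ZeroDivisionError("zero-norm increment: angle undefined")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def angle_profile(track: ArclengthTrack, lam: float,
                  goal: Sequence[float] | None = None) -> pd.DataFrame:
    """All curvature angles of one track at one scale.

    One sample per grid start index s = 0, ds, 2 ds, ... with
    s + 2*lambda <= total arclength (maximally overlapping increments),
    i.e. ``floor((L - 2 lambda)/ds) + 1`` samples.  Returns a DataFrame with
    columns ``s`` (m), ``lam`` (m), ``theta`` (deg) and ``dist_goal`` (m,
    NaN when no goal is given); ``dist_goal`` is measured at the shared
    vertex X(s + lambda), where the turn happens.  Samples with a zero-norm
    increment are skipped with a warning.
    """
    k = _lam_steps(lam, track.ds)
    m = track.n_points - 2 * k
    cols = ["s", "lam", "theta", "dist_goal"]
    if m < 1:
        logger.info("track of length %.2f m too short for lambda=%.2f m",
                    track.total_arclength, lam)
        return pd.DataFrame(columns=cols, dtype=float)
    P = track.points
    a, b, c = P[:m], P[k:k + m], P[2 * k:2 * k + m]
    v1 = b - a
    v2 = c - b
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 > 0) & (n2 > 0)
    if not np.all(ok):
        warnings.warn(f"skipped {int((~ok).sum())} zero-norm increments at lambda={lam:g} m",
                      RuntimeWarning, stacklevel=2)
    cosang = np.full(m, np.nan)
    cosang[ok] = np.einsum("ij,ij->i", v1[ok], v2[ok]) / (n1[ok] * n2[ok])
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if goal is not None:
        g = np.asarray(goal, dtype=float)
        dist = np.linalg.norm(b - g, axis=1)
    else:
        dist = np.full(m, np.nan)
    df = pd.DataFrame({
        "s": np.arange(m) * track.ds,
        "lam": lam,
        "theta": theta,
        "dist_goal": dist,
    })
    return df[ok].reset_index(drop=True)[cols]


@dataclass
class ScaleCurve:
    """Mean |theta| as a function of scale for one track or a group mean."""

    lam: np.ndarray           # scales (m)
    mean_theta: np.ndarray    # mean |theta| per scale (deg); NaN = missing
    n_samples: np.ndarray     # angle samples (or tracks) behind each entry
    provenance: str = ""

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.mean_theta = np.asarray(self.mean_theta, dtype=float)
        self.n_samples = np.asarray(self.n_samples, dtype=int)
        if not (len(self.lam) == len(self.mean_theta) == len(self.n_samples)):
            raise ValueError("curve arrays must share one length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "lambda_m": self.lam,
            "mean_theta_deg": self.mean_theta,
            "n_samples": self.n_samples,
            "provenance": self.provenance,
        })


def mean_angle_curve(track: ArclengthTrack, grid: np.ndarray | None = None,
                     goal: Sequence[float] | None = None,
                     provenance: str = "") -> ScaleCurve:
    """Mean |theta| over the angle profile at every scale of the grid.

    Scales too long for the track (2*lambda > L) yield missing entries
    (NaN mean, zero count); they are never imputed.
    """
    grid = lambda_grid() if grid is None else np.asarray(grid, dtype=float)
    means = np.full(len(grid), np.nan)
    counts = np.zeros(len(grid), dtype=int)
    for i, lam in enumerate(grid):
        prof = angle_profile(track, lam, goal=goal)
        if len(prof):
            means[i] = prof["theta"].mean()
            counts[i] = len(prof)
    return ScaleCurve(grid, means, counts, provenance=provenance)


def grand_mean_curve(curves: Sequence[ScaleCurve], provenance: str = "grand mean") -> ScaleCurve:
    """Unweighted per-scale mean over tracks' mean-angle curves.

    Each track contributes equally at each scale; tracks missing an entry
    are excluded at that scale, and the count records how many contributed.
    """
    if not curves:
        raise ValueError("need at least one curve")
    lam0 = curves[0].lam
    for c in curves[1:]:
        if len(c.lam) != len(lam0) or not np.allclose(c.lam, lam0):
            raise ValueError("curves must share one lambda grid")
    stack = np.vstack([c.mean_theta for c in curves])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        means = np.nanmean(stack, axis=0)
    counts = np.sum(np.isfinite(stack), axis=0)
    means[counts == 0] = np.nan
    return ScaleCurve(lam0, means, counts, provenance=provenance)


@dataclass(frozen=True)
class SlopeFit:
    """Straight-line fit to a mean-angle curve over a scale regime.

    ``space='log-log'`` fits log10(theta) against log10(lambda): the slope
    is the dimensionless scaling exponent (0.5 Brownian, 1.0 ballistic).
    ``space='lin-lin'`` fits theta against lambda: the slope is a turning
    rate in deg/m (the mean bend of a search spiral).
    """

    regime: tuple[float, float]
    space: str
    slope: float
    intercept: float
    residual_norm: float
    n_points: int


def fit_slope(curve: ScaleCurve, regime: tuple[float, float],
              space: str = "log-log") -> SlopeFit:
    """Ordinary-least-squares line fit to a curve within a scale regime."""
    if space not in ("log-log", "lin-lin"):
        raise ValueError("space must be 'log-log' or 'lin-lin'")
    lo, hi = regime
    if not lo < hi:
        raise ValueError("regime must satisfy lo < hi")
    eps = 1e-9
    mask = (curve.lam >= lo - eps) & (curve.lam <= hi + eps) \
        & np.isfinite(curve.mean_theta) & (curve.n_samples > 0)
    if space == "log-log":
        pos = curve.mean_theta > 0
        dropped = int(np.sum(mask & ~pos))
        if dropped:
            warnings.warn(f"dropped {dropped} non-positive theta values from log-log fit",
                          RuntimeWarning, stacklevel=2)
        mask &= pos
    x = curve.lam[mask]
    y = curve.mean_theta[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 curve points inside the regime")
    if space == "log-log":
        x = np.log10(x)
        y = np.log10(y)
    coeffs, residuals, *_ = np.polyfit(x, y, 1, full=True)
    rnorm = float(np.sqrt(residuals[0])) if len(residuals) else 0.0
    return SlopeFit(regime=(lo, hi), space=space, slope=float(coeffs[0]),
                    intercept=float(coeffs[1]), residual_norm=rnorm,
                    n_points=int(len(x)))
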