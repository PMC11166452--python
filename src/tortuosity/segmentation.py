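"""Approach/search segmentation and goal-distance banding.

A recorded run consists of a rather straight goal approach followed by
spiralling search around the (fictive) goal.  The two phases are split at
the first conspicuous turning point: the first place where the path
deviates from its current direction by at least 30 deg and does not
revert to the previous direction for at least another 3 m.  Search
trajectories are evaluated up to 12.80 m from the search onset.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .tracks import ArclengthTrack, SEARCH_EVAL_LENGTH


def wrap_angle(deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle difference to (-180, 180] degrees."""
    return -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)


@dataclass(frozen=True)
class TurnRuleConfig:
    """Parameters of the first-conspicuous-turning-point rule.

    ``heading_chord`` is the chord over which the local path direction is
    measured and ``heading_smooth`` the running circular-mean window that
    suppresses digitisation and gait noise before the rule is applied.
    ``angle_threshold``/``persistence_window`` encode the rule "deviates by
    >= 30 deg and does not revert for at least 3 m".  The reference
    direction is the smoothed heading one ``reference_lag`` before the
    candidate (default: the persistence window), and the reported turning
    point is back-dated from the threshold crossing to where the deviation
    last fell below ``onset_tol_deg`` — on gradually bending tracks the
    crossing itself lags the physical onset of the turn.
    """

    angle_threshold: float = 30.0
    persistence_window: float = 3.0
    heading_chord: float = 0.5
    heading_smooth: float = 1.0
    reference_lag: float | None = None   # None -> persistence_window
    onset_tol_deg: float = 10.0

    def __post_init__(self) -> None:
        if min(self.angle_threshold, self.persistence_window, self.heading_chord) <= 0:
            raise ValueError("all turn-rule parameters must be positive")
        if self.heading_smooth < 0:
            raise ValueError("heading_smooth must be non-negative")

    @property
    def lag(self) -> float:
        return self.persistence_window if self.reference_lag is None else self.reference_lag


def _circular_running_mean(h_deg: np.ndarray, win_steps: int) -> np.ndarray:
    """Running circular mean of headings (forward window of win_steps)."""
    if win_steps <= 1:
        return h_deg
    z = np.exp(1j * np.radians(h_deg))
    zs = np.convolve(z, np.ones(win_steps) / win_steps, mode="valid")
    return np.degrees(np.angle(zs))


def headings(track: ArclengthTrack, chord: float) -> np.ndarray:
    """Local path direction at each grid point, in degrees on (-180, 180].

    The heading at grid point i is the direction of the chord from X(s_i)
    to X(s_i + chord); the returned array therefore has ``n_points - c``
    entries where c = chord/ds.
    """
    c = int(round(chord / track.ds))
    if abs(chord - c * track.ds) > 1e-6 * chord or c < 1:
        raise ValueError("chord must be a positive integer multiple of ds")
    if track.total_arclength < chord:
        raise ValueError("track shorter than the heading chord")
    d = track.points[c:] - track.points[:-c]
    return np.degrees(np.arctan2(d[:, 1], d[:, 0]))


def find_turning_point(track: ArclengthTrack,
                       cfg: TurnRuleConfig = TurnRuleConfig()) -> float | None:
    """Arclength of the first conspicuous turning point, or None.

    Scans the smoothed heading series for the first value that deviates
    from the reference heading (one reference lag earlier) by at least the
    threshold and keeps deviating from that reference over the whole
    persistence window; the returned arclength is back-dated from the
    threshold crossing to the onset of the deviation and centred for the
    chord/smoothing windows.  Returns None when no crossing can be
    confirmed over a full persistence window inside the track.
    """
    ds = track.ds
    min_len = cfg.heading_chord + cfg.persistence_window
    if track.total_arclength < min_len:
        return None
    # snap the chord to the nearest grid multiple (0.5 m on a 0.04 m grid
    # becomes 12 steps = 0.48 m); the rule is insensitive at this resolution
    c = max(1, int(round(cfg.heading_chord / ds)))
    m = max(1, int(round(cfg.heading_smooth / ds)))
    h = _circular_running_mean(headings(track, c * ds), m)
    lag = max(1, int(round(cfg.lag / ds)))
    win = int(round(cfg.persistence_window / ds))
    n = len(h)
    offset = ((m - 1) / 2 + c / 2) * ds  # centre of the chord+smoothing window
    for j in range(lag, n):
        ref = h[j - lag]
        if abs(wrap_angle(h[j] - ref)) < cfg.angle_threshold:
            continue
        stop = j + win
        if stop >= n:
            return None  # cannot confirm persistence inside the track
        # the reference must itself be an established direction, not a
        # transient excursion: the headings just before it stay within the
        # threshold of it
        pre = h[max(0, j - lag - m):j - lag + 1]
        if np.any(np.abs(wrap_angle(pre - ref)) > cfg.angle_threshold):
            continue
        dev = np.abs(wrap_angle(h[j:stop + 1] - ref))
        if np.all(dev >= cfg.angle_threshold):
            # back-date to where deviation from ref last fell below tolerance
            back = np.abs(wrap_angle(h[j - lag:j + 1] - ref))
            below = np.nonzero(back <= cfg.onset_tol_deg)[0]
            onset = (j - lag + below[-1]) if len(below) else (j - lag + int(np.argmin(back)))
            s_star = onset * ds + offset
            return min(s_star, track.total_arclength - ds)
    return None


def split_run(track: ArclengthTrack, cfg: TurnRuleConfig = TurnRuleConfig(),
              search_eval_length: float = SEARCH_EVAL_LENGTH,
              ) -> tuple[ArclengthTrack, ArclengthTrack | None]:
    """Split a run into (approach, search) at the first turning point.

    The split point is shared by both segments; the search segment is
    truncated to ``search_eval_length`` from its own start.  Without a
    turning point the whole track is approach and search is None; a
    turning point in the last grid step likewise leaves no search segment.
    """
    from .tracks import truncate_to_length

    s_star = find_turning_point(track, cfg)
    if s_star is None:
        return track, None
    i = int(round(s_star / track.ds))
    i = min(max(i, 1), track.n_points - 1)  # approach keeps >= 2 points
    approach = ArclengthTrack(track.points[:i + 1].copy(), ds=track.ds)
    if i >= track.n_points - 1:
        return approach, None
    search = ArclengthTrack(track.points[i:].copy(), ds=track.ds)
    return approach, truncate_to_length(search, search_eval_length)


DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((0.0, 0.5), (0.5, 1.0), (1.0, 9.0))


@dataclass(frozen=True)
class GoalBands:
    """Goal-distance bands (m); half-open [lo, hi), last band closed."""

    edges: tuple[tuple[float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        for (lo, hi) in self.edges:
            if not lo < hi:
                raise ValueError("each band needs lo < hi")
        for (_, hi), (lo2, _) in zip(self.edges, self.edges[1:]):
            if lo2 < hi:
                raise ValueError("bands must be non-overlapping and increasing")

    def label(self, i: int) -> str:
        lo, hi = self.edges[i]
        return f"{lo:g}-{hi:g}m"


def band_samples(samples: pd.DataFrame, bands: GoalBands = GoalBands(),
                 ) -> tuple[dict[str, pd.DataFrame], int]:
    """Assign angle samples to goal-distance bands by their ``dist_goal``.

    Returns (band label -> samples, count of samples outside all bands).
    Band intervals are half-open [lo, hi); the last band includes its upper
    edge so the partition has no gap at the outer boundary.
    """
    if "dist_goal" not in samples.columns:
        raise ValueError("samples need a dist_goal column")
    d = samples["dist_goal"].to_numpy()
    out: dict[str, pd.DataFrame] = {}
    assigned = np.zeros(len(samples), dtype=bool)
    last = len(bands.edges) - 1
    for i, (lo, hi) in enumerate(bands.edges):
        mask = (d >= lo) & ((d <= hi) if i == last else (d < hi))
        mask &= ~assigned
        out[bands.label(i)] = samples[mask].reset_index(drop=True)
        assigned |= mask
    return out, int((~assigned).sum())
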