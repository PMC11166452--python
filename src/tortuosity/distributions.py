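"""Turning-angle distribution statistics at a fixed scale.

At the histogram scale (default lambda = 0.50 m) the absolute turning
angles of a group of tracks are pooled into a 12-bin histogram on
[0, 180] deg.  Uncorrelated random motion predicts a uniform angle
distribution; departure from uniformity is graded by two measures —
the 1-Wasserstein distance of the angle sample to the uniform
distribution on [0, 180], and the mean histogram deviation (mhd), the
summed absolute deviation of the 12 bin counts from their mean divided
by the total sample count.  Histograms are ranked by each measure
(rank 1 = largest deviation).  Experience groups are compared with
Epps-Singleton and Kolmogorov-Smirnov two-sample tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ANGLE_RANGE = (0.0, 180.0)
DEFAULT_BINS = 12


@dataclass
class AngleHistogram:
    """Equal-width angle histogram on [0, 180] deg."""

    bin_edges: np.ndarray   # 13 edges for 12 bins
    counts: np.ndarray      # 12 non-negative integers
    n_total: int
    label: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need one more edge than bins")
        if self.counts.sum() != self.n_total:
            raise ValueError("counts must sum to n_total")

    @property
    def is_empty(self) -> bool:
        return self.n_total == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo_deg": self.bin_edges[:-1],
            "bin_hi_deg": self.bin_edges[1:],
            "count": self.counts,
        })


def make_histogram(angles: Sequence[float], bins: int = DEFAULT_BINS,
                   label: str = "") -> AngleHistogram:
    """Bin absolute angles into equal-width bins on [0, 180] deg.

    Bins are half-open [lo, hi); the last bin includes 180.  An empty input
    yields an all-zero histogram (flagged via ``is_empty``).
    """
    a = np.asarray(angles, dtype=float)
    if a.size and (np.any(a < ANGLE_RANGE[0]) or np.any(a > ANGLE_RANGE[1])):
        raise ValueError("angles must lie in [0, 180] deg")
    counts, edges = np.histogram(a, bins=bins, range=ANGLE_RANGE)
    return AngleHistogram(edges, counts, int(a.size), label=label)


def wasserstein_to_uniform(angles: Sequence[float], mode: str = "analytic",
                           n_ref: int | None = None,
                           seed: int | None = None) -> float:
    """1-Wasserstein distance (deg) of an angle sample to uniform [0, 180].

    ``analytic`` integrates |ECDF - uniform CDF| exactly (deterministic,
    seed-free).  ``sampled`` compares against n_ref uniform draws from the
    given seed — the Monte Carlo variant of the same comparison.
    """
    a = np.sort(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("need at least one angle")
    lo, hi = ANGLE_RANGE
    if mode == "sampled":
        if n_ref is None:
            n_ref = a.size
        rng = np.random.default_rng(seed)
        ref = rng.uniform(lo, hi, n_ref)
        return float(stats.wasserstein_distance(a, ref))
    if mode != "analytic":
        raise ValueError("mode must be 'analytic' or 'sampled'")
    # Exact integral of |F_n(x) - x/(hi-lo)| over [lo, hi]: on each interval
    # between consecutive order statistics the ECDF is constant, so the
    # integrand is a piecewise-linear |c - u(x)| with at most one sign change.
    width = hi - lo
    xs = np.concatenate([[lo], a, [hi]])
    total = 0.0
    n = a.size
    for i in range(len(xs) - 1):
        x0, x1 = xs[i], xs[i + 1]
        if x1 <= x0:
            continue
        c = i / n if i <= n else 1.0  # ECDF level on (x0, x1)
        xc = lo + c * width           # where uniform CDF equals c
        def seg(u0, u1):              # integral of |c - (x-lo)/width| on [u0, u1]
            m0 = c - (u0 - lo) / width
            m1 = c - (u1 - lo) / width
            return abs(m0 + m1) / 2 * (u1 - u0)
        if x0 < xc < x1:
            total += seg(x0, xc) + seg(xc, x1)
        else:
            total += seg(x0, x1)
    return float(total)


def mean_histogram_deviation(hist: AngleHistogram) -> float:
    """Summed |bin count - mean bin count| normalised by the sample count.

    Zero for perfectly level bins; maximal (2*(B-1)/B, i.e. 11/6 for 12
    bins) when all samples fall in one bin.
    """
    if hist.n_total == 0:
        raise ValueError("mean histogram deviation undefined for empty histogram")
    mean = hist.n_total / len(hist.counts)
    return float(np.abs(hist.counts - mean).sum() / hist.n_total)


def rank_histograms(values: Sequence[float]) -> np.ndarray:
    """Ranks with 1 = largest value; ties get the average rank."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    return stats.rankdata(-v, method="average")


@dataclass
class UniformityStats:
    """Deviation-from-uniformity measures for one angle histogram."""

    label: str
    n_total: int
    wasserstein: float
    mhd: float
    w_rank: float | None = None
    mhd_rank: float | None = None


def uniformity_table(angle_sets: dict[str, Sequence[float]],
                     bins: int = DEFAULT_BINS) -> pd.DataFrame:
    """Wasserstein/mhd statistics and both rankings for a set of angle pools.

    Empty pools are reported with n=0 and excluded from the ranking.
    Returns a DataFrame with one row per label, ranks 1..K (ties averaged,
    rank 1 = largest deviation).
    """
    rows = []
    for label, angles in angle_sets.items():
        a = np.asarray(angles, dtype=float)
        if a.size == 0:
            rows.append({"label": label, "n": 0, "wasserstein_deg": np.nan,
                         "mhd": np.nan})
            continue
        hist = make_histogram(a, bins=bins, label=label)
        rows.append({
            "label": label,
            "n": int(a.size),
            "wasserstein_deg": wasserstein_to_uniform(a, mode="analytic"),
            "mhd": mean_histogram_deviation(hist),
        })
    df = pd.DataFrame(rows)
    valid = df["n"] > 0
    df["w_rank"] = np.nan
    df["mhd_rank"] = np.nan
    if valid.any():
        df.loc[valid, "w_rank"] = rank_histograms(df.loc[valid, "wasserstein_deg"])
        df.loc[valid, "mhd_rank"] = rank_histograms(df.loc[valid, "mhd"])
    return df


def compare_two_samples(a: Sequence[float], b: Sequence[float],
                        min_es_n: int = 5) -> pd.DataFrame:
    """Epps-Singleton and Kolmogorov-Smirnov two-sample comparisons.

    Both tests challenge the null hypothesis that the two angle samples
    follow the same underlying distribution.  Epps-Singleton needs at
    least ``min_es_n`` observations per sample and is reported as
    not-applicable below that; no multiple-testing correction is applied.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    rows = []
    ks = stats.ks_2samp(a, b)
    rows.append({"test": "kolmogorov_smirnov", "statistic": float(ks.statistic),
                 "p_value": float(ks.pvalue), "applicable": True})
    if min(a.size, b.size) >= min_es_n:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                es = stats.epps_singleton_2samp(a, b)
            rows.append({"test": "epps_singleton", "statistic": float(es.statistic),
                         "p_value": float(es.pvalue), "applicable": True})
        except np.linalg.LinAlgError:
            rows.append({"test": "epps_singleton", "statistic": np.nan,
                         "p_value": np.nan, "applicable": False})
    else:
        rows.append({"test": "epps_singleton", "statistic": np.nan,
                     "p_value": np.nan, "applicable": False})
    return pd.DataFrame(rows)


def chi2_uniformity(hist: AngleHistogram) -> tuple[float, float]:
    """Chi-squared goodness of fit against level bins (diagnostic only).

    Retained as an optional cross-check; it is sensitive to the histogram
    representation (bin number and width) and is not part of the main
    pipeline.
    """
    if hist.n_total == 0:
        raise ValueError("empty histogram")
    res = stats.chisquare(hist.counts)
    return float(res.statistic), float(res.pvalue)
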