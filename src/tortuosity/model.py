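"""End-to-end tortuosity analysis as a model / results pair.

:class:`TortuosityModel` holds a cohort of trajectory records plus an
:class:`AnalysisConfig`; :meth:`TortuosityModel.fit` runs the full
pipeline — Bezier smoothing, uniform-arclength resampling, approach /
search segmentation, multiscale mean-angle curves with slope fits,
fixed-scale turning-angle histograms in goal-distance bands, uniformity
statistics with rankings, and experience-group comparisons — and returns
a :class:`TortuosityResults` carrying the tables, a text ``summary()``
and export/plot helpers.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import multiscale, segmentation, distributions
from .multiscale import ScaleCurve, fit_slope, grand_mean_curve, mean_angle_curve
from .segmentation import GoalBands, TurnRuleConfig, band_samples, split_run
from .smoothing import SmoothingConfig, bezier_smooth
from .tracks import (ArclengthTrack, DEFAULT_DS, GOAL_TYPES, EXPERIENCE_LEVELS,
                     GroupLabel, SEARCH_EVAL_LENGTH, TrajectoryRecord,
                     read_manifest, resample_uniform)
from .synthetic import CohortConfig, gen_cohort


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline, in metres and degrees."""

    ds: float = DEFAULT_DS
    lam_min: float = multiscale.DEFAULT_LAMBDA_MIN
    lam_max: float = multiscale.DEFAULT_LAMBDA_MAX
    lam_step: float = DEFAULT_DS
    hist_lambda: float = 0.50          # scale of the histogram analysis
    n_bins: int = 12
    bands: tuple[tuple[float, float], ...] = segmentation.DEFAULT_BANDS
    search_eval_length: float = SEARCH_EVAL_LENGTH
    loglog_regime: tuple[float, float] = (0.04, 1.3)
    linlin_regime: tuple[float, float] = (1.2, 6.4)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    turn_rule: TurnRuleConfig = field(default_factory=TurnRuleConfig)
    apply_smoothing: bool = True

    def grid(self) -> np.ndarray:
        return multiscale.lambda_grid(self.lam_min, self.lam_max, self.lam_step)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bands"] = [list(b) for b in self.bands]
        d["loglog_regime"] = list(self.loglog_regime)
        d["linlin_regime"] = list(self.linlin_regime)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()), encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "smoothing" in d and isinstance(d["smoothing"], dict):
            d["smoothing"] = SmoothingConfig(**d["smoothing"])
        if "turn_rule" in d and isinstance(d["turn_rule"], dict):
            d["turn_rule"] = TurnRuleConfig(**d["turn_rule"])
        if "bands" in d:
            d["bands"] = tuple(tuple(b) for b in d["bands"])
        for key in ("loglog_regime", "linlin_regime"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


class TortuosityModel:
    """Multiscale tortuosity analysis of a cohort of walking trajectories."""

    def __init__(self, records: Sequence[TrajectoryRecord],
                 config: AnalysisConfig | None = None):
        if not records:
            raise ValueError("need at least one trajectory record")
        for rec in records:
            if rec.group is None:
                raise ValueError(f"record {rec.animal_id!r} lacks a group label")
            if rec.goal is None:
                raise ValueError(f"record {rec.animal_id!r} lacks a goal position")
        self.records = list(records)
        self.config = config or AnalysisConfig()

    @classmethod
    def from_manifest(cls, manifest_path: str | Path,
                      config: AnalysisConfig | None = None) -> "TortuosityModel":
        return cls(read_manifest(manifest_path), config=config)

    @classmethod
    def from_synthetic(cls, cohort: CohortConfig | None = None,
                       config: AnalysisConfig | None = None) -> "TortuosityModel":
        records, truth = gen_cohort(cohort or CohortConfig())
        model = cls(records, config=config)
        model.ground_truth = truth
        return model

    # -- pipeline ----------------------------------------------------------

    def _prepare(self, rec: TrajectoryRecord) -> ArclengthTrack:
        cfg = self.config
        smoothed = bezier_smooth(rec, cfg.smoothing) if cfg.apply_smoothing else rec
        return resample_uniform(smoothed, cfg.ds)

    def _profile_at_scale(self, seg: ArclengthTrack, lam: float, goal):
        """Angle profile at an arbitrary scale.

        When ``lam`` is not an integer multiple of the grid step (0.50 m on
        a 0.04 m grid), the segment is re-gridded at the nearest step that
        divides ``lam`` exactly, keeping the scale itself exact.
        """
        k = lam / seg.ds
        if abs(k - round(k)) <= 1e-6 * max(1.0, k):
            return multiscale.angle_profile(seg, lam, goal=goal)
        ds2 = lam / max(1, round(k))
        seg2 = resample_uniform(seg.points, ds2)
        return multiscale.angle_profile(seg2, lam, goal=goal)

    def fit(self) -> "TortuosityResults":
        cfg = self.config
        grid = cfg.grid()
        bands = GoalBands(cfg.bands)
        curves: dict[str, list[ScaleCurve]] = {}
        approach_angles: dict[tuple[str, str], list[np.ndarray]] = {}
        band_angles: dict[tuple[str, str, str], list[np.ndarray]] = {}
        log_rows = []
        per_track_curves = []
        for rec in self.records:
            track = self._prepare(rec)
            approach, search = split_run(track, cfg.turn_rule, cfg.search_eval_length)
            key = (rec.group.goal_type, rec.group.experience)
            row = {"animal_id": rec.animal_id, "goal_type": key[0],
                   "experience": key[1], "track_length_m": track.total_arclength,
                   "approach_length_m": approach.total_arclength,
                   "search_length_m": search.total_arclength if search else 0.0,
                   "dropped_outside_bands": 0}
            for phase, seg in (("approach", approach), ("search", search)):
                if seg is None:
                    continue
                label = f"{key[0]}/{key[1]}/{phase}"
                curve = mean_angle_curve(seg, grid, goal=rec.goal,
                                         provenance=f"{rec.animal_id}/{phase}")
                curves.setdefault(label, []).append(curve)
                per_track_curves.append(curve)
                prof = self._profile_at_scale(seg, cfg.hist_lambda, rec.goal)
                if phase == "approach" and len(prof):
                    approach_angles.setdefault(key, []).append(prof["theta"].to_numpy())
                if phase == "search" and len(prof):
                    by_band, dropped = band_samples(prof, bands)
                    row["dropped_outside_bands"] = dropped
                    for band_label, sub in by_band.items():
                        band_angles.setdefault(key + (band_label,), []).append(
                            sub["theta"].to_numpy())
            log_rows.append(row)

        # group grand-mean curves + slope fits
        grand: dict[str, ScaleCurve] = {}
        slope_rows = []
        for label, curve_list in sorted(curves.items()):
            gm = grand_mean_curve(curve_list, provenance=label)
            grand[label] = gm
            phase = label.rsplit("/", 1)[1]
            for space, regime in (("log-log", cfg.loglog_regime),
                                  ("lin-lin", cfg.linlin_regime)):
                if phase == "approach" and space == "lin-lin":
                    continue  # the linear turning-rate regime is a search feature
                try:
                    f = fit_slope(gm, regime, space=space)
                except ValueError:
                    continue
                slope_rows.append({
                    "group": label, "space": space,
                    "regime_lo_m": f.regime[0], "regime_hi_m": f.regime[1],
                    "slope": f.slope, "intercept": f.intercept,
                    "residual_norm": f.residual_norm, "n_points": f.n_points,
                })

        # 6 x 3 search histograms with uniformity statistics and ranks
        pools: dict[str, np.ndarray] = {}
        for gt in GOAL_TYPES:
            for exp in EXPERIENCE_LEVELS:
                for i in range(len(bands.edges)):
                    bl = bands.label(i)
                    chunks = band_angles.get((gt, exp, bl), [])
                    pools[f"{gt}/{exp}/{bl}"] = (
                        np.concatenate(chunks) if chunks else np.array([]))
        search_stats = distributions.uniformity_table(pools, bins=cfg.n_bins)

        # approach histograms + inexperienced-vs-experienced comparisons
        approach_pools = {
            f"{gt}/{exp}": (np.concatenate(approach_angles[(gt, exp)])
                            if (gt, exp) in approach_angles else np.array([]))
            for gt in GOAL_TYPES for exp in EXPERIENCE_LEVELS
        }
        test_rows = []
        for gt in GOAL_TYPES:
            a = approach_pools[f"{gt}/inexperienced"]
            b = approach_pools[f"{gt}/experienced"]
            if a.size == 0 or b.size == 0:
                continue
            rep = distributions.compare_two_samples(a, b)
            for _, r in rep.iterrows():
                test_rows.append({"goal_type": gt, **r.to_dict()})

        return TortuosityResults(
            model=self,
            per_track_curves=per_track_curves,
            grand_curves=grand,
            slopes=pd.DataFrame(slope_rows),
            search_stats=search_stats,
            approach_pools=approach_pools,
            search_pools=pools,
            approach_tests=pd.DataFrame(test_rows),
            run_log=pd.DataFrame(log_rows),
        )


@dataclass
class TortuosityResults:
    """Fitted tables of the tortuosity pipeline, with export and summary."""

    model: TortuosityModel
    per_track_curves: list[ScaleCurve]
    grand_curves: dict[str, ScaleCurve]
    slopes: pd.DataFrame
    search_stats: pd.DataFrame
    approach_pools: dict[str, np.ndarray]
    search_pools: dict[str, np.ndarray]
    approach_tests: pd.DataFrame
    run_log: pd.DataFrame

    # -- views -------------------------------------------------------------

    def curves_frame(self) -> pd.DataFrame:
        frames = [c.to_frame() for c in self.grand_curves.values()]
        return pd.concat(frames, ignore_index=True)

    def histograms_frame(self) -> pd.DataFrame:
        cfg = self.model.config
        frames = []
        for label, angles in {**self.approach_pools, **self.search_pools}.items():
            hist = distributions.make_histogram(angles, bins=cfg.n_bins, label=label)
            df = hist.to_frame()
            df.insert(0, "label", label)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        cfg = self.model.config
        lines = []
        lines.append("Multiscale tortuosity analysis")
        lines.append("=" * 64)
        lines.append(f"tracks analysed: {len(self.model.records)}  "
                     f"(ds={cfg.ds:g} m, lambda {cfg.lam_min:g}-{cfg.lam_max:g} m, "
                     f"histogram lambda {cfg.hist_lambda:g} m)")
        lines.append("")
        lines.append("Slope fits of grand-mean theta(lambda) curves")
        lines.append("-" * 64)
        if len(self.slopes):
            for _, r in self.slopes.iterrows():
                unit = "" if r["space"] == "log-log" else " deg/m"
                lines.append(f"  {r['group']:<44s} {r['space']:>7s}  "
                             f"slope {r['slope']:6.3f}{unit}")
        lines.append("")
        lines.append("Search-angle uniformity (Wasserstein deg / mhd; rank 1 = "
                     "largest deviation)")
        lines.append("-" * 64)
        df = self.search_stats.sort_values("w_rank", na_position="last")
        for _, r in df.iterrows():
            if r["n"] == 0:
                lines.append(f"  {r['label']:<40s} n=0 (excluded from ranking)")
            else:
                lines.append(f"  {r['label']:<40s} n={int(r['n']):6d}  "
                             f"W={r['wasserstein_deg']:6.2f}  mhd={r['mhd']:5.3f}  "
                             f"ranks {r['w_rank']:4.1f}/{r['mhd_rank']:4.1f}")
        lines.append("")
        lines.append("Approach comparisons (inexperienced vs experienced)")
        lines.append("-" * 64)
        for _, r in self.approach_tests.iterrows():
            if r["applicable"]:
                lines.append(f"  {r['goal_type']:<18s} {r['test']:<20s} "
                             f"stat={r['statistic']:8.4f}  p={r['p_value']:.3g}")
            else:
                lines.append(f"  {r['goal_type']:<18s} {r['test']:<20s} not applicable")
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, outdir: str | Path) -> Path:
        """Write all result tables, the config echo and the run log."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.curves_frame().to_csv(outdir / "grand_mean_curves.csv", index=False)
        pd.concat([c.to_frame() for c in self.per_track_curves],
                  ignore_index=True).to_csv(outdir / "per_track_curves.csv", index=False)
        self.slopes.to_csv(outdir / "slope_fits.csv", index=False)
        self.search_stats.to_csv(outdir / "search_uniformity.csv", index=False)
        self.histograms_frame().to_csv(outdir / "histograms.csv", index=False)
        self.approach_tests.to_csv(outdir / "approach_tests.csv", index=False)
        self.run_log.to_csv(outdir / "run_log.csv", index=False)
        self.model.config.to_yaml(outdir / "config.yaml")
        (outdir / "summary.txt").write_text(self.summary() + "\n", encoding="utf-8")
        return outdir

    def digest(self) -> str:
        """Deterministic content hash of the result tables (rerun check)."""
        h = hashlib.sha256()
        for df in (self.curves_frame(), self.slopes, self.search_stats,
                   self.approach_tests, self.run_log):
            h.update(df.round(10).to_csv(index=False).encode())
        return h.hexdigest()

    def plot_curves(self, path: str | Path | None = None):
        """Mean theta(lambda) per group in lin-lin and log-log panels."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
        for label, curve in self.grand_curves.items():
            ok = np.isfinite(curve.mean_theta)
            axes[0].plot(curve.lam[ok], curve.mean_theta[ok], label=label, lw=1.2)
            pos = ok & (curve.mean_theta > 0)
            axes[1].loglog(curve.lam[pos], curve.mean_theta[pos], lw=1.2)
        ref_x = np.array([0.05, 1.0])
        axes[1].loglog(ref_x, 30 * ref_x ** 0.5, "k--", lw=0.8, label="slope 0.5")
        axes[0].set_xlabel("scale $\\lambda$ (m)")
        axes[0].set_ylabel("mean $|\\theta|$ (deg)")
        axes[1].set_xlabel("scale $\\lambda$ (m)")
        axes[0].legend(fontsize=6)
        axes[1].legend(fontsize=7)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return fig
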