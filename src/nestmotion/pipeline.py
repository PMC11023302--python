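"""End-to-end orchestration: frames -> profiles -> spectra -> statistics.

A :class:`RunConfig` fully describes one analysis run (input source,
surveillance zones, session schedule, thresholds, options); it serializes
to YAML and its hash is stamped into every output so that result tables are
traceable to the exact configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import ripple as ripple_mod
from .inhibition import ModelComparison, SkewnessProfile, fit_models
from .motion import (
    DEFAULT_LUM_TH,
    MotionProfile,
    SurveillanceZone,
    episode_maximum,
    motion_profiles,
    normalize_profile,
)
from .sessions import PD, SessionSchedule, slice_profile
from .spectra import (
    N_BINS,
    TAIL_OFFSET,
    histogram_spectrum,
    peak_position,
    quantile_spectrum,
    scale_episode,
    skewness_qs,
)
from .synthetic import (
    GroundTruth,
    NestScenario,
    scenario_from_dict,
    scenario_to_dict,
    simulate_profiles,
)
from .tradeoff import SOURCES, extract_tradeoff_points, fit_tradeoff, points_to_frame

__all__ = ["RunConfig", "RunResult", "run_pipeline", "read_frame_dir"]

log = logging.getLogger("nestmotion")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    scenario: NestScenario | None = None  # synthetic input ...
    frames_dir: str | None = None  # ... or a directory of numbered images
    video: str | None = None  # ... or a video container readable by imageio
    zones: list[SurveillanceZone] | None = None  # required for file input
    schedule: SessionSchedule | None = None  # required for file input
    frame_rate_hz: float = 50.0
    px_per_cm: float = 8.8
    lum_th: float = DEFAULT_LUM_TH
    morphology: bool = True
    n_bins: int = N_BINS
    tail_offset: int = TAIL_OFFSET
    intervals: tuple[int, ...] = ripple_mod.DEFAULT_INTERVALS
    quantile_step: float = 0.01
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        sources = [self.scenario is not None, self.frames_dir is not None, self.video is not None]
        if sum(sources) != 1:
            raise ValueError("exactly one of scenario / frames_dir / video must be set")
        if self.scenario is None and (self.zones is None or self.schedule is None):
            raise ValueError("file input needs explicit zones and schedule")
        if self.lum_th < 0:
            raise ValueError("lum_th must be >= 0")

    # -- resolved views ---------------------------------------------------
    @property
    def effective_zones(self) -> list[SurveillanceZone]:
        return self.scenario.zones if self.scenario is not None else list(self.zones or [])

    @property
    def effective_schedule(self) -> SessionSchedule:
        return self.scenario.schedule if self.scenario is not None else self.schedule  # type: ignore[return-value]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.scenario is not None:
            d["scenario"] = scenario_to_dict(self.scenario)
        if self.zones is not None:
            d["zones"] = [
                {"label": z.label, "rect": list(z.rect), "functional_role": z.functional_role}
                for z in self.zones
            ]
        if self.schedule is not None:
            sched = self.schedule
            d["schedule"] = {
                "episode_id": sched.episode_id,
                "frame_rate_hz": sched.frame_rate_hz,
                "mfa_bounds": list(sched.mfa_bounds) if sched.mfa_bounds else None,
                "sessions": [
                    {
                        "index": s.index,
                        "stimulus": s.stimulus,
                        "frame_range": list(s.frame_range),
                        "phase": s.phase,
                    }
                    for s in sched.sessions
                ],
            }
        d["intervals"] = list(self.intervals)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .sessions import Session

        d = dict(d)
        if d.get("scenario") is not None:
            d["scenario"] = scenario_from_dict(d["scenario"])
        if d.get("zones") is not None:
            d["zones"] = [
                SurveillanceZone(z["label"], tuple(z["rect"]), z.get("functional_role", "periphery"))
                for z in d["zones"]
            ]
        if d.get("schedule") is not None:
            sd = d["schedule"]
            d["schedule"] = SessionSchedule(
                episode_id=sd["episode_id"],
                sessions=[
                    Session(s["index"], s["stimulus"], tuple(s["frame_range"]), s.get("phase", "nMFA"))
                    for s in sd["sessions"]
                ],
                frame_rate_hz=sd.get("frame_rate_hz", 50.0),
                mfa_bounds=tuple(sd["mfa_bounds"]) if sd.get("mfa_bounds") else None,
            )
        if d.get("intervals") is not None:
            d["intervals"] = tuple(d["intervals"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    """Tabular result bundle of one pipeline run."""

    config: RunConfig
    profiles: pd.DataFrame  # per frame x zone: counts and normalized activity
    sessions: pd.DataFrame  # per session x zone: spectral statistics
    spectra: pd.DataFrame  # long-format histogram spectra
    frequency: pd.DataFrame  # frequency weights of the pre-MFA window
    model_fits: pd.DataFrame  # inhibition-model comparison per zone
    tradeoff_points: pd.DataFrame
    tradeoff_fits: pd.DataFrame
    episode_max: int
    ground_truth: GroundTruth | None = None

    def manifest(self) -> dict:
        sched = self.config.effective_schedule
        return {
            "config_hash": self.config.config_hash(),
            "episode_id": sched.episode_id,
            "episode_max": int(self.episode_max),
            "n_sessions": len(sched.sessions),
            "n_zones": len(self.config.effective_zones),
            "mfa_bounds": list(sched.mfa_bounds) if sched.mfa_bounds else None,
            "tables": [
                "profiles.csv",
                "sessions.csv",
                "spectra.csv",
                "frequency.csv",
                "model_fits.csv",
                "tradeoff_points.csv",
                "tradeoff_fits.csv",
            ],
        }

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = self.config.config_hash()
        for name in self.manifest()["tables"]:
            df = getattr(self, name.split(".")[0])
            df = df.copy()
            df.insert(0, "config_hash", stamp)
            df.to_csv(outdir / name, index=False)
        (outdir / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))
        self.config.to_yaml(outdir / "config.yaml")
        return outdir


def read_frame_dir(path: str | Path) -> "np.ndarray":
    """Load a directory of numbered PNG/TIFF frames as a frame stack."""
    import imageio.v3 as iio

    files = sorted(
        p for p in Path(path).iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if len(files) < 2:
        raise ValueError(f"no usable frame images in {path}")
    return np.stack([iio.imread(f) for f in files])


def _load_profiles(config: RunConfig) -> tuple[list[MotionProfile], GroundTruth | None]:
    if config.scenario is not None:
        log.info("simulating scenario (%d frames)", config.scenario.n_frames)
        return simulate_profiles(
            config.scenario, lum_th=config.lum_th, morphology=config.morphology
        )
    if config.frames_dir is not None:
        frames = read_frame_dir(config.frames_dir)
    else:
        import imageio.v3 as iio

        frames = iio.imread(config.video)
    log.info("loaded %d frames", len(frames))
    profiles = motion_profiles(
        frames,
        config.effective_zones,
        lum_th=config.lum_th,
        morphology=config.morphology,
        frame_rate_hz=config.frame_rate_hz,
    )
    return profiles, None


def _pre_mfa_window(schedule: SessionSchedule):
    """The nPd session containing or immediately preceding the MFA onset."""
    if schedule.mfa_bounds is None:
        return None
    onset = schedule.mfa_bounds[0]
    candidates = [s for s in schedule.npd_sessions() if s.frame_range[0] < onset]
    return candidates[-1] if candidates else None


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis chain and return the result bundle."""
    profiles, truth = _load_profiles(config)
    schedule = config.effective_schedule
    episode_max = episode_maximum(profiles)
    log.info("episode maximum count: %d", episode_max)
    if episode_max > 0:
        profiles = [normalize_profile(p, episode_max) for p in profiles]

    prof_rows = []
    for p in profiles:
        prof_rows.append(
            pd.DataFrame(
                {
                    "zone": p.zone.label,
                    "frame": p.frame_indices,
                    "time_min": p.frame_indices / p.frame_rate_hz / 60.0,
                    "count": p.counts,
                    "normalized": p.normalized if p.normalized is not None else np.nan,
                }
            )
        )
    profiles_df = pd.concat(prof_rows, ignore_index=True)

    # per session x zone spectra and statistics
    sess_rows = []
    spec_rows = []
    all_spectra = []
    for p in profiles:
        for sess, sub in slice_profile(p, schedule):
            if len(sub) == 0:
                continue
            spec = histogram_spectrum(
                sub.counts,
                n_bins=config.n_bins,
                episode_max=episode_max,
                session_index=sess.index,
                zone_label=p.zone.label,
            )
            all_spectra.append(spec)
            sk = skewness_qs(spec, tail_offset=config.tail_offset)
            row = {
                "zone": p.zone.label,
                "session_index": sess.index,
                "stimulus": sess.stimulus,
                "phase": sess.phase,
                "start_frame": sess.frame_range[0],
                "end_frame": sess.frame_range[1],
                "midpoint_min": sess.midpoint_frame() / schedule.frame_rate_hz / 60.0,
                "n_frames": len(sub),
                "q_s": sk.q_s,
                "q_s_degenerate": sk.degenerate,
                "lower_tail_area": sk.lower_tail_area,
                "upper_tail_area": sk.upper_tail_area,
                "peak_bin": spec.peak_bin,
                "peak_position": peak_position(spec),
                "spectrum_degenerate": spec.degenerate,
            }
            try:
                qs = quantile_spectrum(
                    sub.counts,
                    grid_step=config.quantile_step,
                    episode_max=episode_max if episode_max > 0 else None,
                )
                row["low_base"] = qs.low_base
                row["slope_030_090"] = qs.slope_030_090
            except ValueError:
                row["low_base"] = np.nan
                row["slope_030_090"] = np.nan
            sess_rows.append(row)
    sessions_df = pd.DataFrame(sess_rows)
    scale_episode(all_spectra) if episode_max > 0 else None
    for spec in all_spectra:
        spec_rows.append(
            pd.DataFrame(
                {
                    "zone": spec.zone_label,
                    "session_index": spec.session_index,
                    "bin": np.arange(spec.n_bins),
                    "bin_center_log10": spec.bin_centers,
                    "rel_count": spec.rel_counts,
                    "episode_scaled": spec.episode_scaled
                    if spec.episode_scaled is not None
                    else np.nan,
                }
            )
        )
    spectra_df = pd.concat(spec_rows, ignore_index=True)

    # frequency-weight analysis of the pre-MFA nPd window (ripple check)
    window = _pre_mfa_window(schedule)
    freq_profiles = []
    for p in profiles:
        if window is not None:
            subs = dict(
                (s.index, sub) for s, sub in slice_profile(p, schedule)
            )
            sub = subs.get(window.index, p)
        else:
            sub = p
        freq_profiles.append(sub)
    usable = [
        p for p in freq_profiles if len(p) > max(config.intervals)
    ]
    frequency_df = (
        ripple_mod.frequency_weight_table(usable, intervals=config.intervals)
        if usable
        else pd.DataFrame()
    )
    if window is not None and not frequency_df.empty:
        frequency_df.insert(1, "session_index", window.index)

    # inhibition-model comparison on the Pd skewness series
    model_rows = []
    bounds_min = schedule.mfa_bounds_min()
    if bounds_min is not None:
        pd_rows = sessions_df[sessions_df["stimulus"] == PD]
        groups: list[tuple[str, pd.DataFrame]] = list(pd_rows.groupby("zone", sort=False))
        if len(groups) > 1:
            pooled = (
                pd_rows.groupby("session_index")
                .agg(midpoint_min=("midpoint_min", "first"), q_s=("q_s", lambda v: float(np.exp(np.mean(np.log(v))))))
                .reset_index()
            )
            groups.append(("all", pooled))
        for zone, sub in groups:
            sub = sub.sort_values("session_index")
            if len(sub) < 3 or not np.all(sub["q_s"] > 0):
                continue
            prof = SkewnessProfile(
                times_min=sub["midpoint_min"].to_numpy(),
                q_s=sub["q_s"].to_numpy(),
                mfa_bounds_min=bounds_min,
                zone_label=str(zone),
            )
            cmp_: ModelComparison = fit_models(prof)
            model_rows.append(
                {
                    "zone": zone,
                    "pcc_linear_ramp": cmp_.linear.pcc,
                    "pcc_semicircular": cmp_.semicircular.pcc,
                    "preferred": cmp_.preferred,
                    "degenerate": cmp_.degenerate,
                    "n_pd_sessions": len(sub),
                }
            )
    model_fits_df = pd.DataFrame(model_rows)

    # trade-off nomogram statistics
    point_frames = []
    fit_rows = []
    if not sessions_df.empty and sessions_df["low_base"].notna().any():
        for source in SOURCES:
            pts = extract_tradeoff_points(sessions_df.dropna(subset=["low_base"]), source=source)
            if not pts:
                continue
            point_frames.append(points_to_frame(pts))
            for zone in sorted({p.zone_label for p in pts}):
                zpts = [p for p in pts if p.zone_label == zone]
                if len(zpts) >= 3:
                    fit_rows.append(_fit_row(zone, source, zpts))
            if len(pts) >= 3:
                fit_rows.append(_fit_row("all", source, pts))
    tradeoff_points_df = (
        pd.concat(point_frames, ignore_index=True) if point_frames else pd.DataFrame()
    )
    tradeoff_fits_df = pd.DataFrame(fit_rows)

    return RunResult(
        config=config,
        profiles=profiles_df,
        sessions=sessions_df,
        spectra=spectra_df,
        frequency=frequency_df,
        model_fits=model_fits_df,
        tradeoff_points=tradeoff_points_df,
        tradeoff_fits=tradeoff_fits_df,
        episode_max=episode_max,
        ground_truth=truth,
    )


def _fit_row(zone: str, source: str, pts) -> dict:
    try:
        fit = fit_tradeoff(pts)
        return {
            "zone": zone,
            "source": source,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "pcc": fit.pcc,
            "coefficient_a": fit.coefficient_a,
            "n_points": fit.n_points,
            "degenerate": fit.degenerate,
        }
    except ValueError as exc:
        return {
            "zone": zone,
            "source": source,
            "slope": np.nan,
            "intercept": np.nan,
            "r_squared": np.nan,
            "pcc": np.nan,
            "coefficient_a": np.nan,
            "n_points": len(pts),
            "degenerate": True,
        }
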