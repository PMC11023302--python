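"""Synthetic nest-surface video generator.

Emulates the statistical structure of giant-honeybee nest recordings that
the analysis chain assumes, without rendering bees: per-pixel luminance
*changes* are simulated directly as Bernoulli "flips" of the pixel value by
more than the motion threshold, because the downstream analysis consumes
only luminance differences.

Four excitation regimes are emulated:

* **quiescent** — sparse baseline flicker everywhere, with a busier mouth
  zone at all times;
* **shimmering** — during dummy-presentation (Pd) windows, annular wave
  fronts of super-threshold change expand from an origin zone across the
  nest at a configured speed, each front trailing a band of active pixels
  corresponding to the individual pulse duration;
* **mfa** — mass flight: all-zone flip rates ramp from onset to peak and
  back down to the end, the mouth zone recruiting first and the periphery
  last; per-frame multiplicative "lull" excursions below the recruitment
  ceiling give the activity plateau its characteristic downward spread;
* **ripple** — a slow sinusoidal modulation of the rates in the 1-2 minutes
  before MFA onset, strongest at the mouth and weakest at the periphery.

Shimmer-wave strength during MFA is scaled by a configurable inhibition
time course (linear_ramp or semicircular), which is what makes the
defensiveness suppression recoverable downstream.

Flip seeds are optionally dilated into small square blobs (``flicker_blob``)
so that simulated motion survives the morphological noise filtering of the
analysis chain, as the multi-pixel body parts of real bees do.

All randomness is threaded through one seeded generator: identical
scenario + seed gives bit-identical frames.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy import ndimage

from .motion import FrameSequence, MotionProfile, SurveillanceZone, motion_profiles
from .sessions import PD, SessionSchedule, generate_schedule
from .inhibition import evaluate_model

__all__ = [
    "ShimmerWaveParams",
    "MfaParams",
    "RippleParams",
    "NestScenario",
    "GroundTruth",
    "REGIMES",
    "default_zones",
    "default_scenario",
    "small_scenario",
    "generate_frames",
    "iter_frames",
    "simulate_profiles",
    "write_frames",
    "scenario_to_dict",
    "scenario_from_dict",
]

#: Regime codes used in the ground-truth maps.
REGIMES = ("quiescent", "shimmering", "ripple", "mfa")

_BASE_LEVEL = 100  # resting gray value
_FLIP_DELTA = 30  # toggled gray offset, > lum_th under either luminance rule

#: Zone recruitment order during MFA (mouth first) and ripple strength.
_ROLE_RANK = {"mouth": 0, "near-mouth": 1, "center": 2, "periphery": 3}
_DEFAULT_RIPPLE_AMPLITUDE = {
    "mouth": 0.8,
    "near-mouth": 0.6,
    "center": 0.4,
    "periphery": 0.2,
}


@dataclass
class ShimmerWaveParams:
    origin_role: str = "center"  # zone the waves start from
    speed_cm_s: float = 50.0  # propagation speed of the front
    pulse_ms: float = 300.0  # individual shimmer pulse duration
    period_s: float = 3.0  # time between successive wave launches
    density: float = 0.08  # flip-seed probability inside the active band


@dataclass
class MfaParams:
    onset_frame: int
    peak_frame: int
    end_frame: int
    recruitment_rate: float = 0.02  # flip-seed probability at the MFA peak
    spread_delay_s: float = 5.0  # envelope delay per recruitment rank
    lull_scale: float = 0.5  # scale of exponential downward excursions


@dataclass
class RippleParams:
    frequency_hz: float = 0.5
    duration_s: float = 90.0  # window immediately before MFA onset
    amplitude_by_role: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RIPPLE_AMPLITUDE)
    )


@dataclass
class NestScenario:
    width_px: int = 1280
    height_px: int = 720
    frame_rate_hz: float = 50.0
    px_per_cm: float = 8.8
    zones: list[SurveillanceZone] = field(default_factory=lambda: default_zones())
    schedule: SessionSchedule | None = None
    quiescent_flicker_rate: float = 0.005
    mouth_activity_rate: float = 0.02
    baseline_wander: float = 0.3  # sd of the mean-one lognormal slow modulation
    flicker_blob: int = 3  # flip seeds dilated to blob x blob squares
    shimmer: ShimmerWaveParams = field(default_factory=ShimmerWaveParams)
    mfa: MfaParams | None = None
    ripple: RippleParams | None = None
    inhibition_model: str | None = "semicircular"
    rgb: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schedule is None:
            self.schedule = generate_schedule(
                17, 1.018, 2.166, self.frame_rate_hz, episode_id="synthetic"
            )
        for z in self.zones:
            if not z.within(self.height_px, self.width_px):
                raise ValueError(
                    f"zone {z.label!r} rect {z.rect} lies outside the "
                    f"{self.height_px}x{self.width_px} frame"
                )
        for name in ("quiescent_flicker_rate", "mouth_activity_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mfa is not None:
            m = self.mfa
            if not m.onset_frame < m.peak_frame < m.end_frame:
                raise ValueError("mfa requires onset < peak < end")
            if not 0.0 <= m.recruitment_rate <= 1.0:
                raise ValueError("mfa.recruitment_rate must be in [0, 1]")
            if self.schedule.mfa_bounds is None:
                # propagate the true MFA window into the session phase labels
                self.schedule = SessionSchedule(
                    episode_id=self.schedule.episode_id,
                    sessions=list(self.schedule.sessions),
                    frame_rate_hz=self.schedule.frame_rate_hz,
                    mfa_bounds=(m.onset_frame, m.end_frame),
                )

    @property
    def n_frames(self) -> int:
        return self.schedule.n_frames

    def zone_by_role(self, role: str) -> SurveillanceZone:
        for z in self.zones:
            if z.functional_role == role:
                return z
        return self.zones[0]


def default_zones(
    width_px: int = 1280, height_px: int = 720, side_px: int = 100
) -> list[SurveillanceZone]:
    """Five square surveillance zones in the canonical nest layout.

    sz4 = mouth (bottom left), sz1 = above the mouth (near-mouth),
    sz5 = nest center, sz2/sz3 = right-side periphery.
    """
    m = side_px // 2  # margin
    left, right = m, width_px - side_px - m
    top, bottom = m, height_px - side_px - m
    center_r = (height_px - side_px) // 2
    center_c = (width_px - side_px) // 2
    return [
        SurveillanceZone("sz1", (top, left, side_px, side_px), "near-mouth"),
        SurveillanceZone("sz2", (top, right, side_px, side_px), "periphery"),
        SurveillanceZone("sz3", (bottom, right, side_px, side_px), "periphery"),
        SurveillanceZone("sz4", (bottom, left, side_px, side_px), "mouth"),
        SurveillanceZone("sz5", (center_r, center_c, side_px, side_px), "center"),
    ]


def default_scenario(seed: int = 0, inhibition_model: str | None = "semicircular") -> NestScenario:
    """Full-scale scenario mirroring the original recordings.

    1280x720 px at 50 Hz, 8.8 px/cm, five 100x100 px zones, 17 alternating
    sessions (nPd about 2 min, Pd about 1 min), a mass-flight episode
    ramping up from minute 2.6 and ending near minute 13.6, and a 0.5 Hz
    ripple in the 90 s before MFA onset.
    """
    rate = 50.0
    schedule = generate_schedule(17, 1.018, 2.166, rate, episode_id="synthetic")
    mfa = MfaParams(
        onset_frame=int(2.63 * 60 * rate),
        peak_frame=int(8.0 * 60 * rate),
        end_frame=int(13.6 * 60 * rate),
    )
    return NestScenario(
        schedule=schedule,
        mfa=mfa,
        ripple=RippleParams(),
        inhibition_model=inhibition_model,
        seed=seed,
    )


def small_scenario(
    seed: int = 0,
    inhibition_model: str | None = "semicircular",
    with_mfa: bool = True,
    with_ripple: bool = True,
    n_sessions: int = 17,
    npd_s: float = 24.0,
    pd_s: float = 12.0,
) -> NestScenario:
    """Scaled-down scenario for fast end-to-end analysis.

    200x160 px at 25 Hz with 36x36 px zones; sessions of 24 s (nPd) and
    12 s (Pd) by default, keeping the 2:1 duration ratio of the original
    protocol; the MFA window covers the middle ~60% of the episode with
    its peak at mid-episode, and the ripple occupies the 30 s before
    onset.  Preserves the structure of :func:`default_scenario` at a
    fraction of the pixel and frame budget.
    """
    rate = 25.0
    schedule = generate_schedule(
        n_sessions, pd_s / 60.0, npd_s / 60.0, rate, episode_id="synthetic-small"
    )
    total_s = schedule.n_frames / rate
    mfa = (
        MfaParams(
            onset_frame=int(0.16 * total_s * rate),
            peak_frame=int(0.45 * total_s * rate),
            end_frame=int(0.74 * total_s * rate),
            spread_delay_s=2.0,
        )
        if with_mfa
        else None
    )
    ripple = RippleParams(duration_s=30.0) if with_ripple else None
    return NestScenario(
        width_px=200,
        height_px=160,
        frame_rate_hz=rate,
        px_per_cm=2.2,
        zones=default_zones(200, 160, side_px=36),
        schedule=schedule,
        shimmer=ShimmerWaveParams(),
        mfa=mfa,
        ripple=ripple,
        inhibition_model=inhibition_model,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Per-frame, per-zone expected activity regime plus true annotations."""

    regimes: dict[str, np.ndarray]  # zone label -> int codes into REGIMES
    mfa_bounds: tuple[int, int] | None
    schedule: SessionSchedule

    def regime_names(self, zone_label: str) -> np.ndarray:
        return np.asarray(REGIMES)[self.regimes[zone_label]]


def _ground_truth(scenario: NestScenario) -> GroundTruth:
    n = scenario.n_frames
    sched = scenario.schedule
    pd_mask = np.zeros(n, dtype=bool)
    start0 = sched.frame_range[0]
    for s in sched.sessions:
        if s.stimulus == PD:
            pd_mask[s.frame_range[0] - start0 : s.frame_range[1] - start0] = True
    frames = np.arange(start0, start0 + n)
    regimes: dict[str, np.ndarray] = {}
    for z in scenario.zones:
        code = np.where(pd_mask, REGIMES.index("shimmering"), REGIMES.index("quiescent"))
        if scenario.mfa is not None:
            m = scenario.mfa
            if scenario.ripple is not None:
                rip0 = m.onset_frame - int(
                    scenario.ripple.duration_s * scenario.frame_rate_hz
                )
                code = np.where(
                    (frames >= rip0) & (frames < m.onset_frame),
                    REGIMES.index("ripple"),
                    code,
                )
            code = np.where(
                (frames >= m.onset_frame) & (frames <= m.end_frame),
                REGIMES.index("mfa"),
                code,
            )
        regimes[z.label] = code.astype(np.int8)
    bounds = (
        (scenario.mfa.onset_frame, scenario.mfa.end_frame)
        if scenario.mfa is not None
        else None
    )
    return GroundTruth(regimes=regimes, mfa_bounds=bounds, schedule=sched)


def _zone_rates(scenario: NestScenario, rng: np.random.Generator) -> np.ndarray:
    """Per-zone, per-frame flip-seed rates (waves handled separately)."""
    n = scenario.n_frames
    rate = scenario.frame_rate_hz
    nz = len(scenario.zones)
    out = np.empty((nz, n))
    # slow mean-one lognormal wander, AR(1) with a ~5 s time constant
    phi = float(np.exp(-1.0 / (5.0 * rate)))
    innov_sd = np.sqrt(1.0 - phi**2)
    sigma = scenario.baseline_wander
    t = np.arange(n)
    for j, z in enumerate(scenario.zones):
        base = (
            scenario.mouth_activity_rate
            if z.functional_role == "mouth"
            else scenario.quiescent_flicker_rate
        )
        if sigma > 0:
            g = np.empty(n)
            e = rng.standard_normal(n)
            g[0] = e[0]
            for i in range(1, n):
                g[i] = phi * g[i - 1] + innov_sd * e[i]
            wander = np.exp(sigma * g - 0.5 * sigma**2)
        else:
            rng.standard_normal(n)  # keep the stream layout fixed
            wander = np.ones(n)
        series = base * wander
        if scenario.ripple is not None and scenario.mfa is not None:
            rp = scenario.ripple
            rip0 = scenario.mfa.onset_frame - int(rp.duration_s * rate)
            window = (t >= rip0) & (t < scenario.mfa.onset_frame)
            amp = rp.amplitude_by_role.get(z.functional_role, 0.0)
            mod = 1.0 + amp * np.sin(2.0 * np.pi * rp.frequency_hz * t / rate)
            series = np.where(window, series * mod, series)
        if scenario.mfa is not None:
            m = scenario.mfa
            delay = int(_ROLE_RANK.get(z.functional_role, 3) * m.spread_delay_s * rate)
            env = np.interp(
                t,
                [m.onset_frame + delay, m.peak_frame + delay, m.end_frame + delay],
                [0.0, 1.0, 0.0],
                left=0.0,
                right=0.0,
            )
            lull = np.exp(-rng.exponential(m.lull_scale, size=n))
            series = series + m.recruitment_rate * env * lull
        else:
            rng.exponential(1.0, size=n)  # keep the stream layout fixed
        out[j] = np.clip(series, 0.0, 1.0)
    return out


@dataclass
class _Wave:
    origin: tuple[float, float]
    t0: int
    strength: float
    dist: np.ndarray | None = None


def _wave_launches(
    scenario: NestScenario, rng: np.random.Generator
) -> list[_Wave]:
    """Wave launch times/origins for all Pd sessions, inhibition applied."""
    waves: list[_Wave] = []
    rate = scenario.frame_rate_hz
    period = max(1, int(round(scenario.shimmer.period_s * rate)))
    origin_zone = scenario.zone_by_role(scenario.shimmer.origin_role)
    r0, c0, h, w = origin_zone.rect
    start0 = scenario.schedule.frame_range[0]
    for s in scenario.schedule.sessions:
        if s.stimulus != PD:
            continue
        for t0 in range(s.frame_range[0], s.frame_range[1], period):
            oy = r0 + rng.random() * h
            ox = c0 + rng.random() * w
            strength = 1.0
            if scenario.mfa is not None and scenario.inhibition_model is not None:
                m = scenario.mfa
                if scenario.inhibition_model == "proportional":
                    # suppression proportional to the recruitment envelope
                    env = float(
                        np.interp(
                            t0,
                            [m.onset_frame, m.peak_frame, m.end_frame],
                            [0.0, 1.0, 0.0],
                        )
                    )
                    strength = 1.0 - env
                else:
                    strength = float(
                        evaluate_model(
                            scenario.inhibition_model,
                            float(t0),
                            (float(m.onset_frame), float(m.end_frame)),
                        )
                    )
            waves.append(_Wave(origin=(oy, ox), t0=t0 - start0, strength=strength))
    return waves


def iter_frames(scenario: NestScenario) -> Iterator[np.ndarray]:
    """Yield the scenario's frames one by one (bit-deterministic in the seed)."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_frames
    h, w = scenario.height_px, scenario.width_px
    zone_rates = _zone_rates(scenario, rng)
    waves = _wave_launches(scenario, rng)
    rate = scenario.frame_rate_hz
    speed_px_frame = scenario.shimmer.speed_cm_s * scenario.px_per_cm / rate
    band_px = max(
        3.0, scenario.shimmer.speed_cm_s * scenario.shimmer.pulse_ms / 1000.0 * scenario.px_per_cm
    )
    max_dist = float(np.hypot(h, w))
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    blob = scenario.flicker_blob
    structure = np.ones((blob, blob), dtype=bool) if blob > 1 else None

    toggle = np.zeros((h, w), dtype=bool)

    def emit() -> np.ndarray:
        frame = np.full((h, w), _BASE_LEVEL, dtype=np.uint8)
        frame[toggle] += _FLIP_DELTA
        if scenario.rgb:
            return np.repeat(frame[:, :, None], 3, axis=2)
        return frame

    yield emit()
    for t in range(1, n):
        rate_map = np.full((h, w), scenario.quiescent_flicker_rate)
        for j, z in enumerate(scenario.zones):
            rs, cs = z.slices
            rate_map[rs, cs] = zone_rates[j, t]
        for wv in waves:
            if wv.strength <= 0.0 or t < wv.t0:
                continue
            radius = speed_px_frame * (t - wv.t0)
            if radius - band_px > max_dist:
                continue
            if wv.dist is None:
                wv.dist = np.hypot(rows - wv.origin[0], cols - wv.origin[1])
            band = (wv.dist <= radius) & (wv.dist >= radius - band_px)
            if band.any():
                p = scenario.shimmer.density * wv.strength
                rate_map[band] = np.maximum(rate_map[band], p)
        flips = rng.random((h, w)) < rate_map
        if structure is not None:
            flips = ndimage.binary_dilation(flips, structure=structure)
        toggle ^= flips
        yield emit()


def generate_frames(scenario: NestScenario) -> tuple[FrameSequence, GroundTruth]:
    """Materialize the full frame stack of a scenario, with its ground truth."""
    frames = np.stack(list(iter_frames(scenario)))
    seq = FrameSequence(
        frames=frames,
        frame_rate_hz=scenario.frame_rate_hz,
        px_per_cm=scenario.px_per_cm,
    )
    return seq, _ground_truth(scenario)


def simulate_profiles(
    scenario: NestScenario,
    lum_th: float = 10,
    morphology: bool = True,
) -> tuple[list[MotionProfile], GroundTruth]:
    """Stream the scenario straight into per-zone motion profiles.

    Equivalent to ``motion_profiles(generate_frames(...))`` but never holds
    more than one frame in memory.
    """
    profiles = motion_profiles(
        iter_frames(scenario),
        scenario.zones,
        lum_th=lum_th,
        morphology=morphology,
        frame_rate_hz=scenario.frame_rate_hz,
    )
    start0 = scenario.schedule.frame_range[0]
    for p in profiles:
        p.frame_indices = p.frame_indices + start0
    return profiles, _ground_truth(scenario)


# ---------------------------------------------------------------------------
# serialization


def scenario_to_dict(scenario: NestScenario) -> dict:
    d = dataclasses.asdict(scenario)
    d["zones"] = [
        {"label": z.label, "rect": list(z.rect), "functional_role": z.functional_role}
        for z in scenario.zones
    ]
    sched = scenario.schedule
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
    return d


def scenario_from_dict(d: dict) -> NestScenario:
    from .sessions import Session

    d = dict(d)
    d["zones"] = [
        SurveillanceZone(z["label"], tuple(z["rect"]), z.get("functional_role", "periphery"))
        for z in d["zones"]
    ]
    sd = d["schedule"]
    d["schedule"] = SessionSchedule(
        episode_id=sd["episode_id"],
        sessions=[
            Session(
                index=s["index"],
                stimulus=s["stimulus"],
                frame_range=tuple(s["frame_range"]),
                phase=s.get("phase", "nMFA"),
            )
            for s in sd["sessions"]
        ],
        frame_rate_hz=sd.get("frame_rate_hz", 50.0),
        mfa_bounds=tuple(sd["mfa_bounds"]) if sd.get("mfa_bounds") else None,
    )
    if d.get("shimmer") is not None and isinstance(d["shimmer"], dict):
        d["shimmer"] = ShimmerWaveParams(**d["shimmer"])
    if d.get("mfa") is not None and isinstance(d["mfa"], dict):
        d["mfa"] = MfaParams(**d["mfa"])
    if d.get("ripple") is not None and isinstance(d["ripple"], dict):
        d["ripple"] = RippleParams(**d["ripple"])
    return NestScenario(**d)


def _rle(codes: np.ndarray) -> list[list[int]]:
    out: list[list[int]] = []
    for c in codes:
        if out and out[-1][0] == int(c):
            out[-1][1] += 1
        else:
            out.append([int(c), 1])
    return out


def write_frames(
    scenario: NestScenario, outdir: str | Path, ground_truth: GroundTruth | None = None
) -> Path:
    """Write numbered PNG frames plus a JSON sidecar with scenario and truth."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(iter_frames(scenario)):
        iio.imwrite(outdir / f"frame_{i:06d}.png", frame)
    if ground_truth is None:
        ground_truth = _ground_truth(scenario)
    sidecar = {
        "scenario": scenario_to_dict(scenario),
        "regime_codes": list(REGIMES),
        "regimes_rle": {z: _rle(c) for z, c in ground_truth.regimes.items()},
        "mfa_bounds": list(ground_truth.mfa_bounds) if ground_truth.mfa_bounds else None,
    }
    (outdir / "scenario.json").write_text(json.dumps(sidecar, indent=2))
    return outdir
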