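"""Episode / session structure of dummy-presentation experiments.

An *episode* is one continuous recording covering a mass-flight event (MFA)
and the semi-quiescent phases around it.  It is divided into alternating
sessions without (nPd) and with (Pd) the dummy-wasp presentation.  Each
session additionally carries an excitation phase label, nMFA or MFA,
derived from the episode's MFA boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .motion import MotionProfile

__all__ = [
    "Session",
    "SessionSchedule",
    "generate_schedule",
    "slice_profile",
    "partition_long_session",
    "record_count",
    "detect_mfa_bounds",
]

NPD = "nPd"
PD = "Pd"
NMFA = "nMFA"
MFA = "MFA"


@dataclass(frozen=True)
class Session:
    index: int
    stimulus: str  # "nPd" | "Pd"
    frame_range: tuple[int, int]  # half-open [start, end)
    phase: str = NMFA  # "nMFA" | "MFA"

    def __post_init__(self) -> None:
        start, end = self.frame_range
        if end <= start:
            raise ValueError(f"session {self.index}: empty frame range {self.frame_range}")
        if self.stimulus not in (NPD, PD):
            raise ValueError(f"unknown stimulus {self.stimulus!r}")
        if self.phase not in (NMFA, MFA):
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def n_frames(self) -> int:
        return self.frame_range[1] - self.frame_range[0]

    def midpoint_frame(self) -> float:
        return 0.5 * (self.frame_range[0] + self.frame_range[1])


@dataclass
class SessionSchedule:
    episode_id: str
    sessions: list[Session]
    frame_rate_hz: float = 50.0
    mfa_bounds: tuple[int, int] | None = None  # (onset frame, end frame)

    def __post_init__(self) -> None:
        for a, b in zip(self.sessions, self.sessions[1:]):
            if a.frame_range[1] != b.frame_range[0]:
                raise ValueError(
                    f"sessions {a.index} and {b.index} are not contiguous: "
                    f"{a.frame_range} then {b.frame_range}"
                )
        if self.mfa_bounds is not None:
            onset, end = self.mfa_bounds
            if end <= onset:
                raise ValueError("mfa_bounds must satisfy onset < end")
            self.sessions = [
                replace(s, phase=self._phase_of(s)) for s in self.sessions
            ]

    def _phase_of(self, session: Session) -> str:
        # Majority rule for straddling sessions; the boundary frames
        # themselves count as MFA.
        onset, end = self.mfa_bounds  # type: ignore[misc]
        s, e = session.frame_range
        inside = max(0, min(e - 1, end) - max(s, onset) + 1)
        return MFA if inside * 2 > session.n_frames else NMFA

    @property
    def frame_range(self) -> tuple[int, int]:
        if not self.sessions:
            return (0, 0)
        return self.sessions[0].frame_range[0], self.sessions[-1].frame_range[1]

    @property
    def n_frames(self) -> int:
        s, e = self.frame_range
        return e - s

    def pd_sessions(self) -> list[Session]:
        return [s for s in self.sessions if s.stimulus == PD]

    def npd_sessions(self) -> list[Session]:
        return [s for s in self.sessions if s.stimulus == NPD]

    def mfa_bounds_min(self) -> tuple[float, float] | None:
        if self.mfa_bounds is None:
            return None
        onset, end = self.mfa_bounds
        return onset / self.frame_rate_hz / 60.0, end / self.frame_rate_hz / 60.0


def generate_schedule(
    n_sessions: int,
    pd_duration_min: float,
    npd_duration_min: float,
    frame_rate_hz: float = 50.0,
    episode_id: str = "episode",
    start_stimulus: str = NPD,
    start_frame: int = 0,
    mfa_bounds: tuple[int, int] | None = None,
) -> SessionSchedule:
    """Alternating nPd/Pd schedule with contiguous frame ranges.

    Durations follow the experimental protocol (Pd around 1 min, nPd around
    2 min at 50 Hz in the original recordings).
    """
    if pd_duration_min <= 0 or npd_duration_min <= 0:
        raise ValueError("durations must be positive")
    if n_sessions < 0:
        raise ValueError("n_sessions must be >= 0")
    n_pd_frames = int(round(pd_duration_min * 60.0 * frame_rate_hz))
    n_npd_frames = int(round(npd_duration_min * 60.0 * frame_rate_hz))
    sessions: list[Session] = []
    stim = start_stimulus
    cursor = start_frame
    for i in range(n_sessions):
        n = n_pd_frames if stim == PD else n_npd_frames
        sessions.append(Session(index=i, stimulus=stim, frame_range=(cursor, cursor + n)))
        cursor += n
        stim = PD if stim == NPD else NPD
    return SessionSchedule(
        episode_id=episode_id,
        sessions=sessions,
        frame_rate_hz=frame_rate_hz,
        mfa_bounds=mfa_bounds,
    )


def slice_profile(
    profile: MotionProfile, schedule: SessionSchedule
) -> list[tuple[Session, MotionProfile]]:
    """Split a motion profile into per-session sub-profiles.

    The concatenation of the slices reproduces the profile entries that fall
    inside the schedule; the schedule must lie within the profile's range.
    """
    if not schedule.sessions:
        return []
    lo, hi = schedule.frame_range
    fmin, fmax = int(profile.frame_indices.min()), int(profile.frame_indices.max())
    if lo < fmin - 1 or hi > fmax + 1:
        raise ValueError(
            f"schedule frames [{lo}, {hi}) outside profile frames [{fmin}, {fmax}]"
        )
    out: list[tuple[Session, MotionProfile]] = []
    for sess in schedule.sessions:
        s, e = sess.frame_range
        sel = (profile.frame_indices >= s) & (profile.frame_indices < e)
        sub = MotionProfile(
            zone=profile.zone,
            counts=profile.counts[sel],
            frame_indices=profile.frame_indices[sel],
            frame_rate_hz=profile.frame_rate_hz,
            normalized=None if profile.normalized is None else profile.normalized[sel],
        )
        out.append((sess, sub))
    return out


def partition_long_session(session: Session, step_frames: int) -> list[Session]:
    """Chop a long session into consecutive pseudo-sessions of step_frames.

    Used for uninterrupted nPd stretches (original analysis: steps of
    5 000 frames); the last chunk may be shorter; labels are inherited.
    """
    if step_frames <= 0:
        raise ValueError("step_frames must be > 0")
    s, e = session.frame_range
    chunks: list[Session] = []
    k = 0
    while s < e:
        chunk_end = min(s + step_frames, e)
        chunks.append(
            Session(
                index=session.index * 1000 + k,
                stimulus=session.stimulus,
                frame_range=(s, chunk_end),
                phase=session.phase,
            )
        )
        s = chunk_end
        k += 1
    return chunks


def record_count(session: Session, n_zones: int) -> int:
    """Number of analysis records a session contributes over n zones."""
    return session.n_frames * n_zones


def detect_mfa_bounds(
    profile: MotionProfile, k: float = 3.0, baseline_fraction: float = 0.1
) -> tuple[int, int] | None:
    """Optional helper: baseline + k*sigma crossing of an all-zone profile.

    The first ``baseline_fraction`` of the series estimates the quiescent
    baseline; the MFA window is the first/last crossing of baseline + k*sd.
    Meant as a convenience only — configured (manually annotated or
    ground-truth) bounds always take precedence.
    """
    counts = profile.counts.astype(float)
    n0 = max(10, int(len(counts) * baseline_fraction))
    base, sd = counts[:n0].mean(), counts[:n0].std()
    over = np.flatnonzero(counts > base + k * max(sd, 1e-9))
    if over.size == 0:
        return None
    onset = int(profile.frame_indices[over[0]])
    end = int(profile.frame_indices[over[-1]])
    if end <= onset:
        return None
    return onset, end
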