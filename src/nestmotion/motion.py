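"""Frame-differencing motion quantification.

The motion measure is the number of *motion-active* pixels per difference
image inside a surveillance zone: a pixel is motion-active when the absolute
change of its luminance between two consecutive frames exceeds the threshold
``lum_th`` (default 10).  Luminance of an RGB pixel is the channel sum
(R+G+B); for grayscale input the pixel value itself is used.  An optional
morphological opening (erosion then dilation, 3x3 square) removes isolated
noise pixels from the binary motion mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "FrameSequence",
    "SurveillanceZone",
    "MotionProfile",
    "luminance",
    "difference_image",
    "segment_motion",
    "zone_counts",
    "motion_profiles",
    "episode_maximum",
    "normalize_profile",
    "frame_to_time",
    "px_cm_calibration",
    "zone_real_size",
    "DEFAULT_LUM_TH",
]

DEFAULT_LUM_TH = 10

#: 3x3 square structuring element used for the opening pass.  A square
#: (8-connected) element removes isolated noise pixels while leaving filled
#: rectangular regions exactly intact; a 3x3 cross would clip their corners.
_OPENING_STRUCTURE = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SurveillanceZone:
    """Rectangular surveillance zone on the nest image.

    ``rect`` is (row0, col0, height, width), 0-based, half-open.
    ``functional_role`` is one of mouth / near-mouth / center / periphery.
    """

    label: str
    rect: tuple[int, int, int, int]
    functional_role: str = "periphery"

    def __post_init__(self) -> None:
        r0, c0, h, w = self.rect
        if h <= 0 or w <= 0:
            raise ValueError(f"zone {self.label!r} has non-positive area: {self.rect}")
        if r0 < 0 or c0 < 0:
            raise ValueError(f"zone {self.label!r} has negative origin: {self.rect}")

    @property
    def area(self) -> int:
        return self.rect[2] * self.rect[3]

    @property
    def slices(self) -> tuple[slice, slice]:
        r0, c0, h, w = self.rect
        return slice(r0, r0 + h), slice(c0, c0 + w)

    def within(self, height: int, width: int) -> bool:
        r0, c0, h, w = self.rect
        return r0 + h <= height and c0 + w <= width


@dataclass
class FrameSequence:
    """Calibrated stack of video frames.

    frames : (n, h, w) or (n, h, w, 3) uint8 array
    frame_rate_hz : acquisition rate (recordings here: 50 Hz)
    px_per_cm : spatial calibration (recordings here: 8.8 px/cm)
    """

    frames: np.ndarray
    frame_rate_hz: float = 50.0
    px_per_cm: float = 8.8
    origin_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (n, h, w) or (n, h, w, channels)")
        if len(self.frames) < 2:
            raise ValueError("a frame sequence needs at least 2 frames")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class MotionProfile:
    """Per-difference-frame motion-active pixel counts for one zone.

    ``frame_indices[i]`` is the index of the *later* frame of difference i,
    so a sequence of n frames yields n-1 entries starting at index 1.
    """

    zone: SurveillanceZone
    counts: np.ndarray
    frame_indices: np.ndarray
    frame_rate_hz: float = 50.0
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.frame_indices = np.asarray(self.frame_indices, dtype=np.int64)
        if self.counts.shape != self.frame_indices.shape:
            raise ValueError("counts and frame_indices must align")
        if np.any(self.counts < 0) or np.any(self.counts > self.zone.area):
            raise ValueError("counts must lie in [0, zone area]")

    @property
    def times_s(self) -> np.ndarray:
        return self.frame_indices / self.frame_rate_hz

    def __len__(self) -> int:
        return len(self.counts)


def luminance(frame: np.ndarray) -> np.ndarray:
    """Total luminance per pixel: channel sum for RGB, the value itself for gray."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(np.int32)
    if frame.ndim == 3:
        return frame.astype(np.int32).sum(axis=-1)
    raise ValueError(f"expected 2-D or 3-D frame, got shape {frame.shape}")


def difference_image(frame_a: np.ndarray, frame_b: np.ndarray) -> np.ndarray:
    """Absolute per-pixel luminance difference between two consecutive frames."""
    frame_a = np.asarray(frame_a)
    frame_b = np.asarray(frame_b)
    if frame_a.shape != frame_b.shape:
        raise ValueError(
            f"frame shapes differ: {frame_a.shape} vs {frame_b.shape}"
        )
    return np.abs(luminance(frame_b) - luminance(frame_a))


def segment_motion(
    diff: np.ndarray, lum_th: float = DEFAULT_LUM_TH, morphology: bool = True
) -> np.ndarray:
    """Binary motion mask: pixel motion-active iff diff > lum_th (strict).

    With ``morphology`` on, a single opening (erosion then dilation with a
    3x3 square) removes isolated super-threshold pixels while leaving filled
    regions intact.
    """
    if lum_th < 0:
        raise ValueError("lum_th must be >= 0")
    mask = np.asarray(diff) > lum_th
    if morphology:
        mask = ndimage.binary_opening(mask, structure=_OPENING_STRUCTURE)
    return mask


def zone_counts(
    masks: Iterable[np.ndarray],
    zones: Sequence[SurveillanceZone],
    frame_rate_hz: float = 50.0,
    start_index: int = 1,
) -> list[MotionProfile]:
    """Count motion-active pixels per zone for each binary mask in sequence."""
    per_zone: list[list[int]] = [[] for _ in zones]
    indices: list[int] = []
    checked = False
    for i, mask in enumerate(masks):
        mask = np.asarray(mask)
        if not checked:
            h, w = mask.shape
            for z in zones:
                if not z.within(h, w):
                    raise ValueError(
                        f"zone {z.label!r} rect {z.rect} outside {h}x{w} frame"
                    )
            checked = True
        indices.append(start_index + i)
        for j, z in enumerate(zones):
            rs, cs = z.slices
            per_zone[j].append(int(np.count_nonzero(mask[rs, cs])))
    return [
        MotionProfile(
            zone=z,
            counts=np.array(per_zone[j], dtype=np.int64),
            frame_indices=np.array(indices, dtype=np.int64),
            frame_rate_hz=frame_rate_hz,
        )
        for j, z in enumerate(zones)
    ]


def _iter_masks(
    frames: Iterable[np.ndarray], lum_th: float, morphology: bool
) -> Iterator[np.ndarray]:
    prev_lum: np.ndarray | None = None
    for frame in frames:
        lum = luminance(frame)
        if prev_lum is not None:
            diff = np.abs(lum - prev_lum)
            yield segment_motion(diff, lum_th=lum_th, morphology=morphology)
        prev_lum = lum


def motion_profiles(
    frames: FrameSequence | Iterable[np.ndarray],
    zones: Sequence[SurveillanceZone],
    lum_th: float = DEFAULT_LUM_TH,
    morphology: bool = True,
    frame_rate_hz: float | None = None,
) -> list[MotionProfile]:
    """Full chain frames -> difference -> threshold -> opening -> zone counts.

    Accepts a FrameSequence or any iterable of frames (streamed, so long
    sequences never need to be materialized at once).
    """
    if isinstance(frames, FrameSequence):
        rate = frames.frame_rate_hz
        it: Iterable[np.ndarray] = frames.frames
    else:
        rate = frame_rate_hz if frame_rate_hz is not None else 50.0
        it = frames
    masks = _iter_masks(it, lum_th=lum_th, morphology=morphology)
    return zone_counts(masks, zones, frame_rate_hz=rate)


def episode_maximum(profiles: Sequence[MotionProfile]) -> int:
    """Episode-wide maximum count over all zones and all frames."""
    if not profiles:
        raise ValueError("no profiles given")
    return int(max(int(p.counts.max()) for p in profiles))


def normalize_profile(profile: MotionProfile, episode_max: int) -> MotionProfile:
    """Scale counts by the episode-wide maximum into [0, 1]."""
    if episode_max <= 0:
        raise ValueError("degenerate episode: episode_max must be > 0")
    return replace(profile, normalized=profile.counts / float(episode_max))


def frame_to_time(f: int | np.ndarray, frame_rate_hz: float, unit: str = "s"):
    """Elapsed time of frame index f at the given frame rate.

    unit: "s", "min" or "ms".
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    t = np.asarray(f) / frame_rate_hz
    if unit == "s":
        out = t
    elif unit == "min":
        out = t / 60.0
    elif unit == "ms":
        out = t * 1000.0
    else:
        raise ValueError(f"unknown unit {unit!r}")
    return float(out) if np.isscalar(f) or np.ndim(f) == 0 else out


def px_cm_calibration(width_px: float, width_cm: float, precision: int = 1) -> float:
    """Pixels-per-cm conversion factor from a known real-world width."""
    if width_cm <= 0 or width_px <= 0:
        raise ValueError("widths must be positive")
    return round(width_px / width_cm, precision)


def zone_real_size(
    side_px: float, px_per_cm: float, precision: int = 2
) -> tuple[float, float]:
    """Real-world side length [cm] and area [cm^2] of a square zone.

    The area is the square of the side length rounded to ``precision``, so
    printed side/area pairs stay mutually consistent.
    """
    if px_per_cm <= 0 or side_px <= 0:
        raise ValueError("inputs must be positive")
    side_cm = round(side_px / px_per_cm, precision)
    area_cm2 = round(side_cm**2, precision)
    return side_cm, area_cm2
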