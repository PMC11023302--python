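"""Frame-interval frequency-weight analysis of motion profiles.

A lightweight substitute for a Fourier transform: for a set of frame
intervals k the mean absolute lagged difference of the motion-activity
series is computed,

    weight(k) = mean_t | activity(t + k) - activity(t) |,

and plotted against the equivalent frequency frame_rate / k.  Slow ripples
(the 0.5 Hz-and-below unrest that precedes a mass-flight episode) show up
as elevated weights at the long intervals.  The default set of eight
intervals spans 1..100 frames, i.e. 50 Hz down to 0.5 Hz at 50 fps.

The statistic is pluggable: any callable (series, lag) -> float can replace
the mean-absolute-difference reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .motion import MotionProfile

__all__ = ["FrequencyWeights", "frequency_weights", "frequency_weight_table", "DEFAULT_INTERVALS"]

#: Eight geometrically spaced intervals from 1 to 100 frames.
DEFAULT_INTERVALS: tuple[int, ...] = (1, 2, 4, 7, 14, 27, 52, 100)


def _mean_abs_lagged_diff(series: np.ndarray, lag: int) -> float:
    return float(np.mean(np.abs(series[lag:] - series[:-lag])))


@dataclass
class FrequencyWeights:
    zone_label: str
    interval_frames: np.ndarray
    frequency_hz: np.ndarray  # frame_rate / interval, strictly decreasing
    raw_weights: np.ndarray
    weights: np.ndarray  # normalized to unit maximum

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zone": self.zone_label,
                "interval_frames": self.interval_frames,
                "frequency_hz": self.frequency_hz,
                "raw_weight": self.raw_weights,
                "weight": self.weights,
            }
        )


def frequency_weights(
    profile: MotionProfile | np.ndarray,
    intervals: Sequence[int] = DEFAULT_INTERVALS,
    frame_rate_hz: float | None = None,
    statistic: Callable[[np.ndarray, int], float] = _mean_abs_lagged_diff,
    zone_label: str | None = None,
) -> FrequencyWeights:
    """Frequency weights of one motion-activity series.

    Weights are normalized to unit maximum (all-zero series keep zero
    weights).  Raw weights are kept for cross-zone comparison.
    """
    if isinstance(profile, MotionProfile):
        series = profile.counts.astype(float)
        rate = profile.frame_rate_hz if frame_rate_hz is None else frame_rate_hz
        label = profile.zone.label if zone_label is None else zone_label
    else:
        series = np.asarray(profile, dtype=float)
        rate = 50.0 if frame_rate_hz is None else frame_rate_hz
        label = zone_label or "series"
    intervals = np.asarray(sorted(intervals), dtype=int)
    if intervals.min(initial=1) < 1:
        raise ValueError("intervals must be >= 1 frame")
    if intervals.max(initial=0) >= len(series):
        raise ValueError(
            f"largest interval {intervals.max()} >= series length {len(series)}"
        )
    raw = np.array([statistic(series, int(k)) for k in intervals])
    top = raw.max()
    weights = raw / top if top > 0 else raw.copy()
    return FrequencyWeights(
        zone_label=label,
        interval_frames=intervals,
        frequency_hz=rate / intervals,
        raw_weights=raw,
        weights=weights,
    )


def frequency_weight_table(
    profiles: Sequence[MotionProfile],
    intervals: Sequence[int] = DEFAULT_INTERVALS,
    frame_rate_hz: float | None = None,
) -> pd.DataFrame:
    """Jointly normalized frequency weights for several zones.

    Normalization uses the global maximum raw weight over the whole zone
    set, so zones remain comparable within one analysis window.
    """
    parts = [
        frequency_weights(p, intervals=intervals, frame_rate_hz=frame_rate_hz)
        for p in profiles
    ]
    df = pd.concat([p.as_frame() for p in parts], ignore_index=True)
    top = df["raw_weight"].max()
    df["weight"] = df["raw_weight"] / top if top > 0 else df["raw_weight"]
    return df
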