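"""Histogram- and quantile-based motion spectra and derived statistics.

A *motion spectrum* is the distribution of per-frame motion-active pixel
counts of one session x zone, binned into 50 logarithmically scaled size
classes.  The log coordinate is log10(count + 1) so that zero-count frames
are representable; the bin range is anchored to the episode-wide maximum
count, so all spectra of one episode share an abscissa and their left/right
shifts are comparable.

Derived statistics:

* ``q_s`` — the tail-area quotient, the ratio of the spectral mass beyond
  5 bins to the right vs to the left of the spectral peak.  q_s > 1 means a
  right-dominant spectrum (shimmering bursts on top of the quiescent mode);
  q_s < 1 a left-dominant one (mass-flight plateau with downward lulls).
* ``peak_position`` — the relative abscissa position of the spectral peak,
  a monotone proxy for the mass-flight state.
* ``Q_mf`` — ratio of de-logarithmised spectral sums between two episodes'
  mass-flight sessions (base-motion comparison).
* quantile spectra — empirical quantile functions of normalized counts,
  with the 0.30-0.90 mean slope (defensiveness proxy) and the lowest-decile
  mean ("low base", mass-flight proxy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "MotionSpectrum",
    "SkewnessResult",
    "QuantileSpectrum",
    "BaseMotionResult",
    "histogram_spectrum",
    "scale_episode",
    "skewness_qs",
    "peak_position",
    "count_modes",
    "base_motion_ratio",
    "quantile_spectrum",
    "N_BINS",
    "TAIL_OFFSET",
]

N_BINS = 50
TAIL_OFFSET = 5

_SMOOTH_KERNEL = np.ones(3) / 3.0


def _log_transform(counts: np.ndarray) -> np.ndarray:
    return np.log10(np.asarray(counts, dtype=float) + 1.0)


def _smoothed(rel_counts: np.ndarray) -> np.ndarray:
    # 3-bin moving average; edge bins average over the available window.
    padded = np.convolve(rel_counts, _SMOOTH_KERNEL, mode="same")
    norm = np.convolve(np.ones_like(rel_counts), _SMOOTH_KERNEL, mode="same")
    return padded / norm


@dataclass
class MotionSpectrum:
    bin_edges: np.ndarray  # n_bins + 1 edges in the log10(count+1) coordinate
    rel_counts: np.ndarray  # sums to 1 (per-session normalization)
    peak_bin: int
    n_frames: int
    episode_max: int
    degenerate: bool = False
    episode_scaled: np.ndarray | None = None  # rel / episode-wide max rel
    session_index: int | None = None
    zone_label: str | None = None

    @property
    def n_bins(self) -> int:
        return len(self.rel_counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def histogram_spectrum(
    counts: Sequence[int] | np.ndarray,
    n_bins: int = N_BINS,
    episode_max: int | None = None,
    session_index: int | None = None,
    zone_label: str | None = None,
) -> MotionSpectrum:
    """Log-binned, per-session-normalized motion spectrum.

    ``episode_max`` anchors the abscissa (episode-wide maximum count); it
    defaults to the session's own maximum and must not be smaller than it.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("need at least one frame of counts")
    cmax = int(counts.max(initial=0))
    if episode_max is None:
        episode_max = cmax
    if episode_max < cmax:
        raise ValueError("episode_max must be >= max(counts)")
    degenerate = episode_max == 0
    top = _log_transform([max(episode_max, 1)])[0]
    edges = np.linspace(0.0, top, n_bins + 1)
    hist, _ = np.histogram(_log_transform(counts), bins=edges)
    rel = hist / counts.size
    if degenerate:
        rel = np.zeros(n_bins)
        rel[0] = 1.0
    peak = int(np.argmax(_smoothed(rel)))  # ties break toward the lower bin
    return MotionSpectrum(
        bin_edges=edges,
        rel_counts=rel,
        peak_bin=peak,
        n_frames=int(counts.size),
        episode_max=int(episode_max),
        degenerate=degenerate,
        session_index=session_index,
        zone_label=zone_label,
    )


def scale_episode(spectra: Sequence[MotionSpectrum]) -> list[MotionSpectrum]:
    """Second normalization: divide by the episode-wide maximum rel_count.

    After scaling, the maximum of ``episode_scaled`` over all sessions and
    zones of the episode equals 1.
    """
    if not spectra:
        return []
    peak = max(float(s.rel_counts.max()) for s in spectra)
    if peak <= 0:
        raise ValueError("episode has no occupied spectral bins")
    for s in spectra:
        s.episode_scaled = s.rel_counts / peak
    return list(spectra)


@dataclass
class SkewnessResult:
    q_s: float
    lower_tail_area: float  # lT_a, mass in bins <= peak - tail_offset
    upper_tail_area: float  # uT_a, mass in bins >= peak + tail_offset
    peak_bin: int
    tail_offset: int = TAIL_OFFSET
    degenerate: bool = False


def skewness_qs(
    spectrum: MotionSpectrum, tail_offset: int = TAIL_OFFSET, eps: float = 1e-6
) -> SkewnessResult:
    """Tail-area quotient q_s = uT_a / lT_a of a motion spectrum.

    If the left tail is empty the plain quotient is undefined; the result is
    flagged degenerate and the epsilon-regularized quotient is reported.
    """
    rel = spectrum.rel_counts
    peak = spectrum.peak_bin
    upper = float(rel[min(peak + tail_offset, len(rel)) :].sum())
    lo = peak - tail_offset
    lower = float(rel[: lo + 1].sum()) if lo >= 0 else 0.0
    if lower > 0.0 and upper > 0.0:
        return SkewnessResult(upper / lower, lower, upper, peak, tail_offset)
    # an empty tail makes the plain quotient 0 or undefined
    return SkewnessResult(
        (upper + eps) / (lower + eps), lower, upper, peak, tail_offset, degenerate=True
    )


def peak_position(spectrum: MotionSpectrum) -> float:
    """Relative abscissa position of the (3-bin smoothed) spectral peak in [0, 1]."""
    return spectrum.peak_bin / (spectrum.n_bins - 1)


def count_modes(
    spectrum: MotionSpectrum, prominence_fraction: float = 0.05
) -> int:
    """Number of modes of the smoothed spectrum (bimodality check).

    A mode is a local maximum with prominence at least ``prominence_fraction``
    of the spectral maximum.
    """
    sm = _smoothed(spectrum.rel_counts)
    prom = prominence_fraction * float(sm.max())
    padded = np.concatenate([[0.0], sm, [0.0]])  # count boundary maxima too
    peaks, _ = signal.find_peaks(padded, prominence=prom)
    return int(len(peaks))


@dataclass
class BaseMotionResult:
    per_zone: dict[str, float]  # Q_mf per zone
    mean: float
    se: float


def _delogged_sum(spectrum: MotionSpectrum) -> float:
    # De-logarithmise the class measures (bin centers) and sum the products
    # with the relative class occupancies.
    magnitudes = 10.0 ** spectrum.bin_centers - 1.0
    return float(np.sum(magnitudes * spectrum.rel_counts))


def base_motion_ratio(
    episode_a: Mapping[str, MotionSpectrum],
    episode_b: Mapping[str, MotionSpectrum],
) -> BaseMotionResult:
    """Base-motion ratio Q_mf = S(b) / S(a) per zone, with mean +/- se.

    ``episode_a``/``episode_b`` map zone labels to the (mass-flight nPd)
    spectra of two episodes, each normalized within its own episode.
    """
    zones = [z for z in episode_a if z in episode_b]
    if not zones:
        raise ValueError("episodes share no zones")
    per_zone: dict[str, float] = {}
    for z in zones:
        s_a = _delogged_sum(episode_a[z])
        if s_a == 0.0:
            raise ValueError(f"zone {z!r}: zero base motion in the reference episode")
        per_zone[z] = _delogged_sum(episode_b[z]) / s_a
    vals = np.array(list(per_zone.values()))
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return BaseMotionResult(per_zone=per_zone, mean=float(vals.mean()), se=se)


@dataclass
class QuantileSpectrum:
    grid: np.ndarray  # quantile levels in [0, 1]
    values: np.ndarray  # empirical quantiles of normalized counts
    slope_030_090: float  # defensiveness proxy
    low_base: float  # mass-flight proxy: mean quantile value on [0, 0.10]
    session_index: int | None = None
    zone_label: str | None = None


def quantile_spectrum(
    counts: Sequence[int] | np.ndarray,
    grid_step: float = 0.01,
    episode_max: int | None = None,
    low_base_window: float = 0.10,
    session_index: int | None = None,
    zone_label: str | None = None,
) -> QuantileSpectrum:
    """Quantile-based motion spectrum of normalized counts.

    Counts are normalized by ``episode_max`` (default: their own maximum);
    the quantile function is evaluated on a regular grid.  The mean slope
    between the 0.30 and 0.90 quantiles measures the spread of the upper
    distribution (shimmering bursts steepen it); the mean of the lowest
    decile of quantile values measures the motion floor.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 100:
        raise ValueError("quantile spectra need >= 100 frames")
    norm = float(episode_max) if episode_max is not None else float(counts.max())
    if norm <= 0:
        norm = 1.0
    x = counts / norm
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    values = np.quantile(x, grid)
    q30, q90 = np.quantile(x, [0.30, 0.90])
    slope = (q90 - q30) / 0.60
    low_base = float(values[grid <= low_base_window + 1e-12].mean())
    return QuantileSpectrum(
        grid=grid,
        values=values,
        slope_030_090=float(slope),
        low_base=low_base,
        session_index=session_index,
        zone_label=zone_label,
    )
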