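"""Mass-flight vs defensiveness trade-off analysis.

Each consecutive (nPd, Pd) session pair of an episode yields one point:
the abscissa measures the mass-flight state from the nPd session (spectral
peak position for histogram-based spectra, or the quantile "low base"), the
ordinate measures defensiveness from the immediately following Pd session
(the tail-area quotient q_s, or the 0.30-0.90 quantile slope).  Points are
scaled per zone and episode by their maxima into (0, 1].

The reference model is the normalized hyperbola y = A / x, which double
logarithmic scaling turns into a -45-degree diagonal from [0, 1] to [1, 0]
when A = 1.  A least-squares line on (log10 x, log10 y) summarizes each
point cloud; its r is reported as the PCC against the reference diagonal
(r = -1 for a perfect trade-off) and r^2 as the coefficient of
determination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TradeoffPoint",
    "TradeoffFit",
    "extract_tradeoff_points",
    "fit_tradeoff",
    "hyperbola",
    "points_to_frame",
    "LOG_EPS",
]

#: Zero clamp applied before the log-log transform.
LOG_EPS = 1e-3

SOURCES = ("histogram", "quantile")
_X_COL = {"histogram": "peak_position", "quantile": "low_base"}
_Y_COL = {"histogram": "q_s", "quantile": "slope_030_090"}


def hyperbola(x, coefficient_a: float = 1.0):
    """The reference trade-off curve y = A / x."""
    return coefficient_a / np.asarray(x, dtype=float)


@dataclass(frozen=True)
class TradeoffPoint:
    zone_label: str
    x: float  # mass-flight state of the nPd session, scaled to (0, 1]
    y: float  # defensiveness of the following Pd session, scaled to (0, 1]
    source: str  # "histogram" | "quantile"
    npd_session: int
    pd_session: int


def extract_tradeoff_points(
    session_table: pd.DataFrame, source: str = "histogram"
) -> list[TradeoffPoint]:
    """Pair consecutive (nPd, Pd) sessions into trade-off points.

    ``session_table`` needs one row per session x zone with columns
    ``zone``, ``session_index``, ``stimulus`` and the four spectral
    statistics (``peak_position``, ``q_s``, ``low_base``,
    ``slope_030_090``).  Scaling to (0, 1] is by the per-zone maximum over
    the episode's points, which preserves hyperbolic structure.
    """
    if source not in SOURCES:
        raise ValueError(f"source must be one of {SOURCES}")
    xcol, ycol = _X_COL[source], _Y_COL[source]
    points: list[TradeoffPoint] = []
    for zone, sub in session_table.groupby("zone", sort=False):
        sub = sub.sort_values("session_index")
        raw: list[tuple[float, float, int, int]] = []
        rows = sub.to_dict("records")
        for a, b in zip(rows, rows[1:]):
            if a["stimulus"] == "nPd" and b["stimulus"] == "Pd":
                raw.append(
                    (float(a[xcol]), float(b[ycol]), int(a["session_index"]), int(b["session_index"]))
                )
        if not raw:
            continue
        xmax = max(x for x, *_ in raw)
        ymax = max(y for _, y, *_ in raw)
        for x, y, ia, ib in raw:
            points.append(
                TradeoffPoint(
                    zone_label=str(zone),
                    x=x / xmax if xmax > 0 else 0.0,
                    y=y / ymax if ymax > 0 else 0.0,
                    source=source,
                    npd_session=ia,
                    pd_session=ib,
                )
            )
    return points


def points_to_frame(points: Sequence[TradeoffPoint]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in points])


@dataclass
class TradeoffFit:
    slope: float  # log-log regression slope (-1 on the reference diagonal)
    intercept: float  # log-log intercept, log10 of coefficient A
    r_squared: float
    pcc: float  # Pearson r of (log10 x, log10 y); -1 = perfect trade-off
    coefficient_a: float
    n_points: int
    degenerate: bool = False


def fit_tradeoff(
    points: Sequence[TradeoffPoint] | tuple[np.ndarray, np.ndarray],
    eps: float = LOG_EPS,
) -> TradeoffFit:
    """Least-squares line through the points in log-log space.

    Accepts a point list or a raw ``(x, y)`` array pair.  Values are clamped
    to ``eps`` before taking logs.  A constant-y cloud is reported with
    slope and correlation 0 and flagged degenerate; a degenerate x-range is
    an error.
    """
    if isinstance(points, tuple):
        x, y = (np.asarray(v, dtype=float) for v in points)
    else:
        x = np.array([p.x for p in points], dtype=float)
        y = np.array([p.y for p in points], dtype=float)
    if x.size < 3:
        raise ValueError("trade-off fitting needs at least 3 points")
    lx = np.log10(np.clip(x, eps, None))
    ly = np.log10(np.clip(y, eps, None))
    if np.ptp(lx) == 0:
        raise ValueError("degenerate x-range: all abscissa values equal")
    if np.ptp(ly) == 0:
        return TradeoffFit(
            slope=0.0,
            intercept=float(ly[0]),
            r_squared=0.0,
            pcc=0.0,
            coefficient_a=float(10.0 ** ly[0]),
            n_points=int(x.size),
            degenerate=True,
        )
    res = stats.linregress(lx, ly)
    return TradeoffFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pcc=float(res.rvalue),
        coefficient_a=float(10.0**res.intercept),
        n_points=int(x.size),
    )
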