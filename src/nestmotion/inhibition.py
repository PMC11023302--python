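"""Candidate time-course models of defensiveness inhibition during mass flight.

The skewness quotient q_s of the Pd-session motion spectra tracks how far
shimmering can still be triggered.  Two bounded model time courses describe
its suppression during a mass-flight episode:

* ``linear_ramp`` — defensiveness decreases linearly from 1 at MFA onset to
  0 at MFA end and switches back to 1 immediately afterwards (progressive
  inhibition with abrupt release).
* ``semicircular`` — a semicircular depression: gradual non-linear decrease
  after onset, minimum 0 at mid-MFA, gradual re-increase toward the end
  (inhibition proportional to the mass-flight turbulence).

Empirical series are log10(q_s) values of the Pd sessions, min-max
normalized to [0, 1], placed at the sessions' temporal midpoints; each model
is scored by the Pearson correlation coefficient against the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SkewnessProfile",
    "ModelFit",
    "ModelComparison",
    "model_linear_ramp",
    "model_semicircular",
    "evaluate_model",
    "fit_models",
    "MODELS",
]

MODELS = ("linear_ramp", "semicircular")


def model_linear_ramp(t, mfa_bounds: tuple[float, float]):
    """Linear decline 1 -> 0 across the MFA window, 1 outside.

    The value is exactly 0 at the MFA end and jumps back to 1 after it.
    """
    onset, end = _check_bounds(mfa_bounds)
    t = np.asarray(t, dtype=float)
    inside = (t >= onset) & (t <= end)
    out = np.ones_like(t)
    out[inside] = 1.0 - (t[inside] - onset) / (end - onset)
    return float(out) if out.ndim == 0 else out


def model_semicircular(t, mfa_bounds: tuple[float, float]):
    """Semicircular depression across the MFA window, 1 outside.

    With u = 2(t - onset)/(end - onset) - 1 in [-1, 1], the in-MFA value is
    1 - sqrt(1 - u^2): 1 at both boundaries, 0 at mid-MFA.
    """
    onset, end = _check_bounds(mfa_bounds)
    t = np.asarray(t, dtype=float)
    inside = (t >= onset) & (t <= end)
    out = np.ones_like(t)
    u = 2.0 * (t[inside] - onset) / (end - onset) - 1.0
    out[inside] = 1.0 - np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    return float(out) if out.ndim == 0 else out


def _check_bounds(mfa_bounds: tuple[float, float]) -> tuple[float, float]:
    onset, end = mfa_bounds
    if end <= onset:
        raise ValueError(f"invalid MFA bounds: {mfa_bounds}")
    return float(onset), float(end)


def evaluate_model(name: str, t, mfa_bounds: tuple[float, float]):
    if name == "linear_ramp":
        return model_linear_ramp(t, mfa_bounds)
    if name == "semicircular":
        return model_semicircular(t, mfa_bounds)
    raise ValueError(f"unknown model {name!r}; choose from {MODELS}")


@dataclass
class SkewnessProfile:
    """Per-session q_s series of the Pd sessions of one episode x zone."""

    times_min: np.ndarray  # session temporal midpoints [min]
    q_s: np.ndarray
    mfa_bounds_min: tuple[float, float]
    zone_label: str | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.q_s = np.asarray(self.q_s, dtype=float)
        if self.times_min.shape != self.q_s.shape:
            raise ValueError("times and q_s must align")
        if np.any(self.q_s <= 0):
            raise ValueError("q_s values must be positive")

    def normalized(self) -> np.ndarray:
        """log10(q_s), min-max normalized to [0, 1]."""
        log_q = np.log10(self.q_s)
        lo, hi = log_q.min(), log_q.max()
        if hi == lo:
            return np.full_like(log_q, np.nan)
        return (log_q - lo) / (hi - lo)


@dataclass
class ModelFit:
    model: str
    predicted: np.ndarray  # model values at the session midpoints
    pcc: float


@dataclass
class ModelComparison:
    linear: ModelFit
    semicircular: ModelFit
    preferred: str  # "linear_ramp" | "semicircular" | "tie" | "undefined"
    degenerate: bool = False


def fit_models(profile: SkewnessProfile) -> ModelComparison:
    """Score both inhibition models against an empirical skewness series.

    The preferred model is the one with the larger PCC; a constant empirical
    series (or constant model predictions) yields an undefined, flagged
    comparison.
    """
    if len(profile.q_s) < 3:
        raise ValueError("model fitting needs at least 3 Pd sessions")
    empirical = profile.normalized()
    fits: dict[str, ModelFit] = {}
    degenerate = bool(np.any(np.isnan(empirical)))
    for name in MODELS:
        pred = evaluate_model(name, profile.times_min, profile.mfa_bounds_min)
        if degenerate or np.std(pred) == 0:
            pcc = float("nan")
            degenerate = True
        else:
            pcc = float(stats.pearsonr(empirical, pred).statistic)
        fits[name] = ModelFit(model=name, predicted=np.asarray(pred), pcc=pcc)
    lin, semi = fits["linear_ramp"], fits["semicircular"]
    if degenerate or np.isnan(lin.pcc) or np.isnan(semi.pcc):
        preferred = "undefined"
        degenerate = True
    elif lin.pcc > semi.pcc:
        preferred = "linear_ramp"
    elif semi.pcc > lin.pcc:
        preferred = "semicircular"
    else:
        preferred = "tie"
    return ModelComparison(linear=lin, semicircular=semi, preferred=preferred, degenerate=degenerate)
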