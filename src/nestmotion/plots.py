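"""Optional plotting helpers (matplotlib is imported lazily).

These mirror the figures practitioners draw from the result bundle: motion
profiles, per-session motion spectra, skewness time courses, and the
trade-off nomogram with its hyperbolic reference diagonal.  Nothing in the
analysis chain depends on this module.
"""

from __future__ import annotations

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_motion_profiles(profiles_df, ax=None, log_scale=True):
    """Per-zone motion-activity dot plots against experimental time [min]."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    for zone, sub in profiles_df.groupby("zone"):
        ax.plot(sub["time_min"], sub["count"] + 1, ".", ms=1, label=zone, alpha=0.5)
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("experimental time [min]")
    ax.set_ylabel("motion-active pixels + 1")
    ax.legend(markerscale=10, fontsize=8)
    return ax


def plot_spectra(spectra_df, zone, ax=None):
    """Stacked per-session histogram spectra of one surveillance zone."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    sub = spectra_df[spectra_df.zone == zone]
    for k, (sess, spec) in enumerate(sub.groupby("session_index")):
        ax.plot(spec["bin"], spec["rel_count"] + 0.02 * k, lw=0.8)
    ax.set_xlabel("log-scaled size class")
    ax.set_ylabel("relative frequency (sessions offset)")
    ax.set_title(f"motion spectra, {zone}")
    return ax


def plot_skewness_profiles(sessions_df, mfa_bounds_min=None, ax=None):
    """q_s time courses of the Pd sessions, one line per zone."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    pd_rows = sessions_df[sessions_df.stimulus == "Pd"]
    for zone, sub in pd_rows.groupby("zone"):
        sub = sub.sort_values("midpoint_min")
        ax.plot(sub["midpoint_min"], sub["q_s"], "o-", label=zone, ms=3)
    ax.axhline(1.0, color="k", lw=0.5)
    if mfa_bounds_min is not None:
        ax.axvspan(*mfa_bounds_min, color="orange", alpha=0.15)
    ax.set_yscale("log")
    ax.set_xlabel("experimental time [min]")
    ax.set_ylabel("tail-area quotient q$_s$")
    ax.legend(fontsize=8)
    return ax


def plot_tradeoff_nomogram(points_df, ax=None, eps=1e-3):
    """Log-log trade-off points against the -45 degree reference diagonal."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for zone, sub in points_df.groupby("zone_label"):
        ax.plot(
            np.log10(np.clip(sub["x"], eps, None)),
            np.log10(np.clip(sub["y"], eps, None)),
            "o",
            ms=4,
            label=zone,
        )
    lo = np.log10(eps)
    ax.plot([lo, 0], [0, lo], "k-", lw=1, label="hyperbola A=1")
    ax.set_xlabel("log$_{10}$ mass-flight state")
    ax.set_ylabel("log$_{10}$ defensiveness")
    ax.legend(fontsize=8)
    return ax
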