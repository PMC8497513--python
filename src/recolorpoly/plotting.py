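"""Matplotlib convenience plots for ensemble traces and phase diagrams."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_density_trace(summary, termination_time: float | None = None, ax=None):
    """Ensemble-mean squared local density vs time with an SD band.

    A vertical line marks the binding-termination time.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = summary.times
    m = summary.mean["density_sq"]
    s = summary.sd["density_sq"]
    ax.plot(t, m, color="tab:purple", lw=1.5, label="mean")
    ax.fill_between(t, m - s, m + s, color="tab:purple", alpha=0.25, label="+/- SD")
    if termination_time is not None:
        ax.axvline(termination_time, color="k", ls="--", lw=1)
    ax.set_xlabel(r"time ($\tau$)")
    ax.set_ylabel(r"local density$^2$ ($\sigma^{-6}$)")
    ax.legend(frameon=False)
    return ax


def plot_phase_diagram(table, ax=None):
    """Scatter of core concentration vs valence, split by the phase label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sep = table[table["phase_separated"]]
    mixed = table[~table["phase_separated"]]
    ax.scatter(sep["core_conc"], sep["valence"], marker="o", color="tab:red",
               label="phase separated")
    ax.scatter(mixed["core_conc"], mixed["valence"], marker="+", color="tab:red",
               label="not separated")
    if len(table):
        ax.set_xscale("log")
        ax.set_yscale("log")
    ax.set_xlabel("core concentration (uM)")
    ax.set_ylabel("valence (sspB / core)")
    ax.legend(frameon=False)
    return ax


def plot_variance_traces(traces, ax=None):
    """Overlay normalized variance traces (one line per channel)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for trace in np.atleast_1d(traces):
        ax.plot(trace.times, trace.values, label=trace.label or None)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalized variance")
    if any(t.label for t in np.atleast_1d(traces)):
        ax.legend(frameon=False)
    return ax
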