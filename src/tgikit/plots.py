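"""Plotting helpers: per-patient trajectory panels with dose bars, VPC
overlays and observed-vs-predicted scatter.  All functions return the
matplotlib figure and never call show()."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .estimate import FitResult
from .model import PatientRecord, individual_from_population, solve_trajectory
from .simulate import VpcResult

__all__ = ["plot_patient", "plot_vpc", "plot_obs_vs_pred"]


def plot_patient(
    patient: PatientRecord,
    fits: Sequence[FitResult] = (),
    ebes: Optional[Sequence[np.ndarray]] = None,
    ax=None,
):
    """SLD observations with a dose barplot and optional fitted curves."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
    else:
        fig = ax.figure
    times = [o.time for o in patient.observations]
    slds = [o.sld for o in patient.observations]
    ax.plot(times, slds, "ko", label="observed")
    t_end = max(times) if times else patient.dosing.end
    grid = np.linspace(0, t_end, 120)
    styles = ["r--", "b-"]
    for i, fr in enumerate(fits):
        eta = ebes[i] if ebes is not None else np.zeros(3)
        indiv = individual_from_population(
            fr.params, patient.baseline_sld, patient.covariates, eta
        )
        pred = solve_trajectory(
            indiv, fr.variant, patient.dosing.extended(t_end), patient.baseline_sld, grid
        )
        ax.plot(grid, pred, styles[i % 2], label=fr.variant.value)
    ax2 = ax.twinx()
    for iv in patient.dosing.intervals:
        if iv.dose > 0:
            ax2.bar(
                iv.start,
                iv.dose,
                width=min(iv.end, t_end) - iv.start,
                align="edge",
                alpha=0.15,
                color="tab:green",
            )
    ax2.set_ylim(0, 40)
    ax2.set_ylabel("dose (mg/day)")
    ax.set_xlabel("day")
    ax.set_ylabel("SLD (cm)")
    ax.legend(loc="best", fontsize=8)
    ax.set_title(patient.id)
    return fig


def plot_vpc(result: VpcResult):
    """Observed percentiles over simulated envelopes, one panel per stratum."""
    n = len(result.strata)
    fig, axes = plt.subplots(1, max(n, 1), figsize=(5 * max(n, 1), 3.5), squeeze=False)
    for ax, (label, df) in zip(axes[0], result.strata.items()):
        for p, color in ((5, "tab:blue"), (50, "tab:orange"), (95, "tab:red")):
            ax.fill_between(
                df.day, df[f"sim_p{p}_lo"], df[f"sim_p{p}_hi"], alpha=0.2, color=color
            )
            ax.plot(df.day, df[f"sim_p{p}_md"], color=color, lw=1)
            ax.plot(df.day, df[f"obs_p{p}"], "o-", color=color, ms=3, lw=1)
        ax.set_title(label)
        ax.set_xlabel("day")
        ax.set_ylabel("SLD (cm)")
    fig.tight_layout()
    return fig


def plot_obs_vs_pred(pairs, ax=None):
    """Observed vs individual-predicted SLD with the identity line."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(4, 4))
    else:
        fig = ax.figure
    ax.plot(pairs.predicted, pairs.observed, "k.", alpha=0.4, ms=3)
    lim = [0, max(pairs.observed.max(), pairs.predicted.max()) * 1.05]
    ax.plot(lim, lim, "r-", lw=1)
    ax.set_xlabel("individual prediction (cm)")
    ax.set_ylabel("observed SLD (cm)")
    return fig
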