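"""Diagnostic figures for a processed trial and for the study summary."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .energetics import TrialEnergetics
from .forceplate import GRFSeries
from .kinematics import HeelTrack, LocalCOP

__all__ = ["plot_grf", "plot_deformation", "plot_local_cop", "plot_energy_methods"]


def _event_lines(ax, res: TrialEnergetics) -> None:
    for t, label, style in ((res.t0, "$t_0$", ":"), (res.t_p, "$t_p$", "--"),
                            (res.t_e, "$t_e$", "-.")):
        ax.axvline(t, color="k", linestyle=style, linewidth=0.8)
        ax.text(t, ax.get_ylim()[1], label, ha="left", va="top", fontsize=9)


def plot_grf(grf: GRFSeries, res: TrialEnergetics, path: str | Path) -> None:
    """Ground reaction force components with the detected events."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(grf.time, grf.F_Z, label="$F_Z$")
    ax.plot(grf.time, grf.F_X, label="$F_X$", linewidth=0.8)
    ax.plot(grf.time, grf.F_Y, label="$F_Y$", linewidth=0.8)
    ax.set_xlim(res.t0 - 0.02, res.t_e + 0.04)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("force on foot (N)")
    _event_lines(ax, res)
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_deformation(grf: GRFSeries, track: HeelTrack, res: TrialEnergetics,
                     path: str | Path) -> None:
    """Vertical force and foot-ankle deformation on a shared time axis."""
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(grf.time, grf.F_Z, color="C0")
    ax1.set_ylabel("$F_Z$ (N)", color="C0")
    ax1.set_xlabel("time (s)")
    ax2 = ax1.twinx()
    ax2.plot(track.time, track.S[:, 2] * 1e3, color="C1")
    ax2.set_ylabel("$S_Z$ (mm)", color="C1")
    ax1.set_xlim(res.t0 - 0.01, res.t_e + 0.03)
    _event_lines(ax1, res)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_local_cop(local_cop: LocalCOP, r_H: np.ndarray, res: TrialEnergetics,
                   path: str | Path,
                   q_offset: tuple[float, float, float] = (0.01, -0.01, -0.01)) -> None:
    """Local-frame COP cloud during heel strike with points H and Q."""
    sel = (local_cop.time >= res.t0) & (local_cop.time <= res.t_e) & local_cop.valid
    pts = local_cop.xyz[sel] * 1e3
    q = (np.asarray(r_H) + np.asarray(q_offset)) * 1e3
    h = np.asarray(r_H) * 1e3
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, (i, j), labels in zip(axes, [(0, 1), (1, 2)],
                                  [("x (mm)", "y (mm)"), ("y (mm)", "z (mm)")]):
        ax.scatter(pts[:, i], pts[:, j], s=6, alpha=0.5, label="local COP")
        ax.plot(h[i], h[j], "k^", markersize=8, label="H")
        ax.plot(q[i], q[j], "rs", markersize=8, label="Q")
        ax.set_xlabel(labels[0])
        ax.set_ylabel(labels[1])
        ax.set_aspect("equal")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_energy_methods(table, path: str | Path) -> None:
    """Bar chart of the energy measures (overall mean +/- inter-subject SD)."""
    keys = ["W", "W_Z", "dE_e", "dE_p", "dE_p_CS"]
    labels = ["$W$", "$W_Z$", r"$\Delta E_e$", r"$\Delta E_p$", r"$\Delta E_{p,CS}$"]
    means = [table.loc[k, "overall_mean"] for k in keys]
    errs = [table.loc[k, "inter_subject"] for k in keys]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(labels, means, yerr=errs, capsize=4, color="C0", alpha=0.8)
    ax.set_ylabel("energy absorbed per heel strike (J)")
    ax.axhline(0, color="k", linewidth=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
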