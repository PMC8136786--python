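"""Matplotlib conveniences mirroring the paper-style panels.

Plots are side products; the CSV tables written by the CLI are the contract
surface.  All functions accept a tidy frame and write a PNG.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_cycle_msd", "plot_distribution_snapshots", "plot_linker_scan", "plot_rho_scan"]


def plot_cycle_msd(df: pd.DataFrame, path: str | Path, l_eq_sq: float) -> None:
    """Mean-square promoter height over the cycle, normalized by N0 b^2."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(df["t_over_period"], df["msd"] / (3.0 * l_eq_sq), lw=1.5)
    ax.set_xlabel("t / period")
    ax.set_ylabel(r"$\langle z^2\rangle / (N_0 b^2)$")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_distribution_snapshots(snap: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, sub in snap.groupby("t"):
        ax.plot(sub["z"], sub["psi"], lw=1.2, label=f"t={label:.3g}")
    ax.set_xlabel("z")
    ax.set_ylabel(r"$\psi(z,t)$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_linker_scan(df: pd.DataFrame, path: str | Path) -> None:
    """sigma vs tau_N0/tau_ex, extrusion active and inhibited."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.semilogx(df["ratio"], df["sigma_active"], "m-", label="extrusion active")
    ax.semilogx(df["ratio"], df["sigma_equilibrium"], "c-", label="inhibited")
    ax.set_xlabel(r"$\tau_{N_0}/\tau_{ex}$")
    ax.set_ylabel(r"contact probability $\sigma$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rho_scan(df: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for ratio, sub in df.groupby("ratio"):
        ax.plot(sub["rho_over_K_elo"], sub["sigma"], label=rf"$\tau_{{N_0}}/\tau_{{ex}}={ratio:g}$")
    ax.set_xlabel(r"$\rho / K_{elo}$")
    ax.set_ylabel(r"contact probability $\sigma$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
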