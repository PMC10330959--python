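"""Diagnostic and simulation plots (vector-graphics output)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["gof_scatter", "cwres_panels", "vpc_plot", "bridging_plot"]


def _save(fig, path):
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def gof_scatter(gof_table, path: str | Path) -> None:
    """Observed vs population and individual predictions with the unit line."""
    t = gof_table.table
    fig, axes = plt.subplots(1, 2, figsize=(9, 4.2))
    for ax, col, label in ((axes[0], "PRED", "Population prediction"),
                           (axes[1], "IPRED", "Individual prediction")):
        ax.scatter(t[col], t["DV"], s=10, alpha=0.5)
        lim = max(t[col].max(), t["DV"].max()) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel(f"{label} (ng/mL)")
        ax.set_ylabel("Observed (ng/mL)")
    _save(fig, path)


def cwres_panels(gof_table, path: str | Path) -> None:
    """CWRES vs PRED, vs time, histogram and normal QQ panel."""
    from scipy import stats

    t = gof_table.table
    cw = t["CWRES"].to_numpy()
    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    axes[0, 0].scatter(t["PRED"], cw, s=10, alpha=0.5)
    axes[0, 0].set_xlabel("PRED (ng/mL)")
    axes[0, 1].scatter(t["TIME"], cw, s=10, alpha=0.5)
    axes[0, 1].set_xlabel("Time (h)")
    for ax in axes[0]:
        ax.axhline(0, color="k", lw=1)
        for y in (-4, 4):
            ax.axhline(y, color="r", ls=":", lw=1)
        ax.set_ylabel("CWRES")
    axes[1, 0].hist(cw, bins=30, density=True)
    xs = np.linspace(-4, 4, 200)
    axes[1, 0].plot(xs, stats.norm.pdf(xs), "r-", lw=1)
    axes[1, 0].set_xlabel("CWRES")
    stats.probplot(cw, plot=axes[1, 1])
    _save(fig, path)


def vpc_plot(vpc_result, path: str | Path) -> None:
    """Simulated 5/50/95 percentile band with observed percentile overlay."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    v = vpc_result
    ax.fill_between(v.times, v.sim_p5, v.sim_p95, alpha=0.25, label="simulated 5th-95th")
    ax.plot(v.times, v.sim_p50, "r-", label="simulated median")
    ax.plot(v.times, v.obs_p50, "bo-", ms=4, label="observed median")
    ax.plot(v.times, v.obs_p5, "b:", lw=1)
    ax.plot(v.times, v.obs_p95, "b:", lw=1)
    ax.set_xlabel("Time (h)")
    ax.set_ylabel("Concentration (ng/mL)")
    ax.legend()
    _save(fig, path)


def bridging_plot(report, observed=None, path: str | Path = "bridge.svg") -> None:
    """Simulated concentration band with external observed points overlaid."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    b = report.bands
    ax.fill_between(b["time"], b["p5"], b["p95"], alpha=0.25, label="simulated 5th-95th")
    ax.plot(b["time"], b["p50"], "r-", label="simulated median")
    if observed is not None:
        ax.scatter(observed["time"], observed["conc"], s=12, color="tab:blue",
                   alpha=0.6, label="observed")
    ax.set_xlabel("Time (h)")
    ax.set_ylabel("Concentration (ng/mL)")
    ax.legend()
    _save(fig, path)
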