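"""Optional plot artifacts: percentile bands and distribution violins.

The JSON reports are the authoritative output; these figures are quick-look
diagnostics.  Matplotlib is imported lazily with the Agg backend so headless
runs work.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .bootstrap import BootstrapEnsemble, percentile_band


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_band(
    ensemble: BootstrapEnsemble,
    state: str,
    path: str | Path,
    lo: float = 5.0,
    hi: float = 95.0,
) -> None:
    """Shaded percentile envelope of the fitted one-period trajectories."""
    plt = _pyplot()
    period = float(np.median(ensemble.periods))
    grid = np.linspace(0.0, period, 200)
    lower, upper = percentile_band(ensemble, state, grid, lo, hi)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.fill_between(grid, lower, upper, alpha=0.4, label=f"{lo:g}-{hi:g}%")
    ax.set_xlabel("time (one period)")
    ax.set_ylabel(state)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_distributions(ensemble: BootstrapEnsemble, path: str | Path) -> None:
    """Violin plots of parameter and sensitivity bootstrap distributions."""
    plt = _pyplot()
    names = list(ensemble.param_names)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.violinplot(ensemble.parameters, showmedians=True)
    ax1.set_xticks(range(1, len(names) + 1), names)
    ax1.set_ylabel("parameter value")
    sens = ensemble.sensitivities
    keep = ~np.any(np.isnan(sens), axis=0)
    ax2.violinplot(sens[:, keep], showmedians=True)
    ax2.set_xticks(range(1, int(keep.sum()) + 1), [n for n, k in zip(names, keep) if k])
    ax2.axhline(0.0, color="k", lw=0.6)
    ax2.set_ylabel("relative period sensitivity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
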