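"""Summary figure for a synthetic (or measured) dataset and its fits."""
from __future__ import annotations

import numpy as np

from .meanfield import MeanFieldModel
from .synth import SyntheticDataset


def summary_figure(dataset: SyntheticDataset, report: dict | None = None):
    """Four-panel overview of a dataset.

    Panels: growth-rate vs width scatter with the fitted feedback line;
    branch-count mean ± sd vs time with the exponential fit; branch width vs
    time split by terminal / non-terminal class; cell number vs time with the
    mean-field prediction overlaid.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report is None:
        report = dataset.fit()

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))

    # growth rate vs width
    ax = axes[0, 0]
    ax.scatter(
        dataset.pairs["width [um]"],
        dataset.pairs["growth_rate [1/day]"],
        s=6, alpha=0.3, label="branches",
    )
    kd0 = report["feedback"]["kd0 [1/day]"]
    w0 = report["feedback"]["w0 [um]"]
    if w0 is not None:
        wg = np.linspace(0, max(w0, dataset.pairs["width [um]"].max()), 50)
        ax.plot(wg, kd0 * (1 - wg / w0), "g--", label=f"kd0={kd0:.2f}/d, w0={w0:.0f} um")
    ax.set_xlabel("branch width [um]")
    ax.set_ylabel("normalized volumetric growth rate [1/day]")
    ax.legend(fontsize=8)

    # branch counts vs time
    ax = axes[0, 1]
    g = dataset.branch_counts.groupby("time [day]")["n_terminal [count]"]
    t = np.array(sorted(g.groups))
    mean, sd = g.mean().to_numpy(), g.std().fillna(0.0).to_numpy()
    ax.errorbar(t, mean, yerr=sd, fmt="o", ms=4, label="mean +/- sd")
    kb = report["branching"]["kb [1/day]"]
    b0 = np.exp(report["branching"]["log_intercept"])
    ax.plot(t, b0 * np.exp(kb * t), "r--", label=f"exp fit, kb={kb:.2f}/d")
    ax.set_yscale("log")
    ax.set_xlabel("time [day]")
    ax.set_ylabel("terminal branches per organoid")
    ax.legend(fontsize=8)

    # widths by branch class
    ax = axes[1, 0]
    for terminal, label in ((True, "terminal"), (False, "non-terminal")):
        sub = dataset.widths[dataset.widths["terminal"] == terminal]
        if len(sub):
            gg = sub.groupby("time [day]")["width [um]"]
            ax.errorbar(
                np.array(sorted(gg.groups)), gg.mean().to_numpy(),
                yerr=gg.sem().fillna(0.0).to_numpy(), fmt="o-", ms=3, label=label,
            )
    ax.set_xlabel("time [day]")
    ax.set_ylabel("branch width [um]")
    ax.legend(fontsize=8)

    # cell counts vs time with mean-field overlay
    ax = axes[1, 1]
    cc = dataset.cell_count_summary()
    ax.errorbar(
        cc["time [day]"], cc["mean_nc [cells]"], yerr=cc["sd_nc [cells]"],
        fmt="o", ms=4, label="observed",
    )
    t_end = float(cc["time [day]"].max())
    traj = MeanFieldModel(dataset.truth).simulate(t_end=t_end, dt=0.01)
    ax.plot(traj.t, traj.Nc, "r--", label="mean-field model")
    ax.set_yscale("log")
    ax.set_xlabel("time [day]")
    ax.set_ylabel("cells per organoid")
    ax.legend(fontsize=8)

    fig.tight_layout()
    return fig
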