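"""Optional figure rendering: forest plot of the per-scenario odds ratios
and the power sweep curve."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def forest_plot(fig5: pd.DataFrame, path=None):
    """Forest plot of adjusted ORs with 95% CIs, one panel per unit,
    scenarios on the y-axis (mirrors the tiered scenario report)."""
    units = list(dict.fromkeys(fig5["unit"]))
    fig, axes = plt.subplots(1, len(units), figsize=(2.2 * len(units), 4),
                             sharey=True, squeeze=False)
    for ax, unit in zip(axes[0], units):
        sub = fig5[fig5["unit"] == unit]
        ypos = np.arange(len(sub))
        ors = sub["adjusted_oddsratio"].to_numpy(float)
        lo = sub["ci_low"].to_numpy(float)
        hi = sub["ci_high"].to_numpy(float)
        ok = np.isfinite(ors)
        ax.errorbar(ors[ok], ypos[ok],
                    xerr=[ors[ok] - lo[ok], hi[ok] - ors[ok]],
                    fmt="s", color="tab:blue", ecolor="grey", capsize=2)
        ax.axvline(1.0, color="k", lw=0.8, ls=":")
        ax.set_xscale("log")
        ax.set_title(unit, fontsize=8)
        ax.set_yticks(ypos)
        ax.set_yticklabels(sub["scenario"], fontsize=6)
    fig.suptitle("Adjusted OR (95% CI) by filtering scenario")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def power_curve(sweep: pd.DataFrame, path=None):
    """Power vs causal fraction, one line per causal-MAF threshold.

    ``sweep`` columns: causal_fraction, causal_maf_threshold, power,
    mc_standard_error.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    for thr, sub in sweep.groupby("causal_maf_threshold"):
        sub = sub.sort_values("causal_fraction")
        ax.errorbar(sub["causal_fraction"], sub["power"],
                    yerr=sub["mc_standard_error"], marker="o",
                    label=f"causal MAF < {thr:g}")
    ax.set_xlabel("fraction of eligible sites causal")
    ax.set_ylabel("burden-test power")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
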