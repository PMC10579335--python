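"""Plot helpers: down-core Gibbs-energy envelopes per reaction."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_energetics"]


def plot_energetics(result: pd.DataFrame, site: str | None = None, ax=None):
    """Down-core ΔG lines with substrate-range envelopes.

    ``result`` is the tidy output of
    :func:`methanesource.energetics.downcore_energetics`; one line + shaded
    envelope per reaction, dashed where the methane activity was imputed,
    depth increasing downward, a vertical line at ΔG = 0.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 7))
    df = result if site is None else result[result["site"] == site]
    df = df[df["error"] == ""]
    cmap = plt.get_cmap("tab10")
    for i, (rid, grp) in enumerate(df.groupby("reaction_id")):
        grp = grp.sort_values("depth_mbsf")
        color = cmap(i % 10)
        ax.fill_betweenx(grp["depth_mbsf"], grp["dG_min"], grp["dG_max"],
                         color=color, alpha=0.15, linewidth=0)
        solid = grp[~grp["imputed"]]
        dashed = grp[grp["imputed"]]
        label = f"R{rid} {grp['reaction'].iloc[0]}"
        if len(solid):
            ax.plot(solid["dG_mean"], solid["depth_mbsf"], color=color,
                    label=label)
            label = None
        if len(dashed):
            ax.plot(dashed["dG_mean"], dashed["depth_mbsf"], color=color,
                    linestyle="--", label=label)
    ax.axvline(0.0, color="k", linestyle=":", linewidth=1)
    ax.set_xlabel(r"$\Delta G_r$ (kJ / mol C)")
    ax.set_ylabel("depth (mbsf)")
    if not ax.yaxis_inverted():
        ax.invert_yaxis()
    ax.legend(fontsize=7, loc="lower left")
    return ax
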