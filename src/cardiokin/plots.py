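"""Optional figure exports: field profiles and group means with LSD CIs.

Plotting is a presentation concern only; nothing in the analysis depends on
this module. Both functions return the Matplotlib figure and optionally
save it.
"""

from __future__ import annotations

import numpy as np

from .fieldmodel import FieldMap
from .stats import AnovaResult, LsdComparison


def plot_field_profiles(fmap: FieldMap, path=None):
    """B_Z along the X and Y axes of the culture plane, one panel each."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, coords, bz, label in ((axes[0], fmap.x, fmap.bz_x, "X"),
                                  (axes[1], fmap.y, fmap.bz_y, "Y")):
        ax.plot(coords * 100, bz, lw=1.5)
        ax.set_xlabel(f"{label} [cm]")
        ax.axhline(fmap.center_bz, color="0.7", lw=0.8, ls="--")
    axes[0].set_ylabel(r"$B_Z$ [mT]")
    fig.suptitle(f"Vertical field at the culture plane "
                 f"(I = {fmap.current * 1e3:.0f} mA)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


def plot_group_means(res: AnovaResult, comparisons: list[LsdComparison],
                     metric_label: str = "", path=None):
    """Bar chart of group means with half-LSD whiskers.

    Whiskers are half of each group's largest pairwise LSD half-width, so
    two groups differ significantly when their whiskers do not overlap —
    the standard way these comparisons are displayed.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    half = {}
    for c in comparisons:
        for lab in c.pair:
            half[lab] = max(half.get(lab, 0.0), c.half_width / 2)
    errs = [half.get(lab, 0.0) for lab in res.labels]

    fig, ax = plt.subplots(figsize=(5, 3.5))
    xs = np.arange(len(res.labels))
    ax.bar(xs, res.means, yerr=errs, capsize=4, color="0.75",
           edgecolor="black")
    ax.set_xticks(xs, res.labels)
    ax.set_ylabel(metric_label)
    ax.set_title("Group means with half-LSD intervals\n"
                 "(non-overlapping whiskers: p < 0.05, unadjusted)",
                 fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
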