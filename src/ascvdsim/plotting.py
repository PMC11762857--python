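"""Optional plots: acceptability curves and the DSA tornado.

Plots are conveniences over the CSV outputs; nothing in the analysis
pipeline depends on them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .economics import WTP_1GDP, WTP_3GDP

__all__ = ["plot_ceac", "plot_tornado"]


def plot_ceac(curves: pd.DataFrame, ax=None, mark_gdp: bool = True):
    """Plot CEAC curves from the tidy (wtp, strategy, probability) frame."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for name, grp in curves.groupby("strategy"):
        grp = grp.sort_values("wtp")
        ax.plot(grp["wtp"], grp["probability"], label=name)
    if mark_gdp:
        for wtp, label in ((WTP_1GDP, "1x GDP"), (WTP_3GDP, "3x GDP")):
            ax.axvline(wtp, color="grey", ls="--", lw=0.8)
            ax.annotate(label, (wtp, 1.02), ha="center", fontsize=8,
                        annotation_clip=False)
    ax.set_xlabel("willingness to pay (CN¥ per QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_tornado(rows, base_icer: float | None = None, ax=None):
    """Horizontal tornado bars from one-way DSA rows (widest on top)."""
    rows = list(rows)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.5 * max(len(rows), 2) + 1))
    ys = np.arange(len(rows))[::-1]
    for y, row in zip(ys, rows):
        lo, hi = sorted((row.icer_low, row.icer_high))
        ax.barh(y, hi - lo, left=lo, height=0.6, color="#4477aa")
    if base_icer is not None:
        ax.axvline(base_icer, color="black", lw=1)
    ax.set_yticks(ys)
    ax.set_yticklabels([r.parameter for r in rows], fontsize=8)
    ax.set_xlabel("ICER (CN¥ per QALY)")
    return ax
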