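"""Small plotting helpers for the tidy aggregate tables.

One panel per herd type with free y-scales, biomass in '000 tonnes (or
'000 kg at herd level) and value in EUR million — the reporting-boundary
unit conversions live here and nowhere else.
"""

from __future__ import annotations

import math

import pandas as pd


def panel_by_herd_type(df: pd.DataFrame, x: str, y: str, unit_scale: float = 1.0,
                       ylabel: str = "", title: str = ""):
    """Line panels of ``y`` against ``x``, one subplot per herd type.

    ``unit_scale`` converts the internal kg / EUR values to the reporting
    unit (e.g. ``1e-6`` for '000 tonnes from kg, or EUR million from EUR).
    Returns the matplotlib figure.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    types = sorted(df["herd_type"].unique())
    ncol = 3
    nrow = math.ceil(len(types) / ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False)
    for ax in axes.ravel():
        ax.set_visible(False)
    for i, ht in enumerate(types):
        ax = axes[i // ncol][i % ncol]
        ax.set_visible(True)
        sub = df[df["herd_type"] == ht].sort_values(x)
        ax.plot(sub[x], sub[y] * unit_scale, marker="o", ms=3)
        ax.set_title(ht)
        ax.set_xlabel(x)
        ax.set_ylabel(ylabel or y)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig
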