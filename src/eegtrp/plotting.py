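"""Basic box plots of TRP distributions, in the style the results tables use."""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd


def trp_boxplot(table: pd.DataFrame, band: str, segment: str,
                by: str = "projection", ax=None):
    """Box plot of TRP values for one band and task segment, split by a factor.

    Returns the matplotlib Axes; import of matplotlib is deferred so the
    numerical pipeline has no hard plotting dependency at import time.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = table[(table["band"] == band) & (table["segment"] == segment)]
    if sub.empty:
        raise ValueError(f"no rows for band={band}, segment={segment}")
    levels = sorted(sub[by].unique())
    data = [sub.loc[sub[by] == lv, "trp"].to_numpy() for lv in levels]
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.boxplot(data, tick_labels=levels)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel(f"{band} TRP (log10)")
    ax.set_title(f"{band} TRP, {segment}")
    return ax
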