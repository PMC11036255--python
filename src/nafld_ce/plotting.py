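"""Convenience plots: tornado diagram, CEAC, cost-effectiveness plane.

All figures are drawn from the corresponding data exports; nothing here is
needed for the analyses themselves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def tornado_plot(entries, metric: str = "icer", top: int = 12, ax=None):
    """Horizontal tornado bars sorted by range width."""
    import matplotlib.pyplot as plt

    from .sensitivity import tornado_frame

    df = tornado_frame(entries, metric).dropna(subset=["width"]).head(top)[::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(df) + 1))
    for i, row in enumerate(df.itertuples(index=False)):
        lo, hi = sorted((row.at_low, row.at_high))
        ax.barh(i, hi - lo, left=lo, color="#4878a8")
    ax.set_yticks(range(len(df)), df["path"])
    if len(df):
        ax.axvline(df["base"].iloc[0], color="k", lw=1)
    ax.set_xlabel(metric)
    return ax


def ceac_plot(ceac_df: pd.DataFrame, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for strategy, grp in ceac_df.groupby("strategy"):
        ax.plot(grp["wtp"], grp["probability"], marker="o", label=strategy)
    ax.set_xlabel("willingness to pay ($/QALY)")
    ax.set_ylabel("P(highest net monetary benefit)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def ce_plane_plot(plane_df: pd.DataFrame, wtp: float = 150_000.0, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(plane_df["delta_qaly"], plane_df["delta_cost"], s=6, alpha=0.4)
    q = np.linspace(*ax.get_xlim(), 10)
    ax.plot(q, wtp * q, "k--", lw=1, label=f"WTP ${wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost ($)")
    ax.legend()
    return ax
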