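"""Predicted-vs-observed concordance plot."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_concordance"]


def plot_concordance(observed, predicted, ax=None, **scatter_kwargs):
    """Scatter of predicted against observed NE with the identity line.

    Returns the matplotlib axes.  Perfect concordance puts every point
    on the dashed y = x line.
    """
    import matplotlib.pyplot as plt

    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(o, p, **({"color": "tab:blue", "zorder": 3} | scatter_kwargs))
    lo = min(o.min(), p.min())
    hi = max(o.max(), p.max())
    pad = 0.05 * (hi - lo) if hi > lo else 1.0
    lims = (lo - pad, hi + pad)
    ax.plot(lims, lims, "k--", lw=1, label="identity")
    ax.set_xlim(lims)
    ax.set_ylim(lims)
    ax.set_xlabel("observed NE, kcal/day")
    ax.set_ylabel("predicted NE, kcal/day")
    ax.legend(frameon=False)
    return ax
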