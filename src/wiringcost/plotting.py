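"""Static plots: filtration difference curves and the metric-battery dots."""

from __future__ import annotations

import numpy as np

from .filtration import FILTRATION_METRICS


def plot_filtration_difference(diff: dict, ax=None, title: str = ""):
    """Plot EC - EO metric curves from :func:`filtration_difference`."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig, axes = plt.subplots(2, 2, figsize=(9, 6), constrained_layout=True)
        axes = axes.ravel()
    else:
        axes = np.atleast_1d(ax)
    for a, name in zip(axes, FILTRATION_METRICS):
        a.step(diff["thresholds"], diff[name], where="post")
        a.axhline(0.0, color="0.6", lw=0.8)
        a.set_xlabel("threshold")
        a.set_ylabel(f"EC - EO {name.replace('_', ' ')}")
    if title:
        axes[0].figure.suptitle(title)
    return axes[0].figure


def plot_metric_battery(differences, metric_names=None, ax=None):
    """Dot plot of per-subject EC - EO metric differences.

    ``differences`` is a list of per-subject dicts (one dot per subject per
    metric); positive differences (larger with eyes closed) are blue,
    negative red.
    """
    import matplotlib.pyplot as plt

    if metric_names is None:
        metric_names = sorted({k for d in differences for k in d})
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(metric_names), 4))
    for x, name in enumerate(metric_names):
        for d in differences:
            v = d.get(name, np.nan)
            ax.plot(x, v, "o", color="tab:blue" if v >= 0 else "tab:red",
                    alpha=0.7)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.set_xticks(range(len(metric_names)))
    ax.set_xticklabels(metric_names, rotation=60, ha="right")
    ax.set_ylabel("EC - EO")
    return ax.figure
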