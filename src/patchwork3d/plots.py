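"""Plotting helpers: ROC curves of putaminal volume and Bland-Altman plots.

Matplotlib is imported lazily so headless library use never touches a
plotting backend.
"""

from __future__ import annotations

import numpy as np

from .diagnostics import roc_auc
from .metrics import bland_altman

__all__ = ["plot_roc", "plot_bland_altman"]


def plot_roc(volume_sets: dict[str, tuple], ax=None):
    """ROC curves for MSA detection by volume, one curve per method.

    ``volume_sets`` maps a label to ``(volumes_mL, is_msa)``; the AUC is
    appended to each legend entry.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for label, (volumes, is_msa) in volume_sets.items():
        auc, fpr, tpr = roc_auc(volumes, is_msa)
        ax.plot(fpr, tpr, label=f"{label} (AUC {auc:.2f})")
    ax.plot([0, 1], [0, 1], ls=":", color="gray", lw=1)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", frameon=False)
    return ax


def plot_bland_altman(method, reference, ax=None, label_method="method", label_ref="reference"):
    """Agreement plot: per-subject mean vs difference with limits of agreement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    stats = bland_altman(method, reference)
    ax.scatter(stats["means"], stats["diffs"], s=14)
    for y, ls in [(stats["mean_diff"], "-"), (stats["loa_lower"], "--"), (stats["loa_upper"], "--")]:
        ax.axhline(y, ls=ls, color="gray", lw=1)
    ax.set_xlabel(f"mean of {label_method} and {label_ref} (mL)")
    ax.set_ylabel(f"{label_method} - {label_ref} (mL)")
    return ax
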