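"""Optional diagnostic plots (requires matplotlib, not a core dependency)."""

from __future__ import annotations

import numpy as np

from .evaluate import BootDist, _check_scores_labels, _oriented

__all__ = ["plot_roc", "plot_boot_dist"]


def _roc_points(scores, labels, orientation="lower"):
    scores, pos = _check_scores_labels(scores, labels)
    s = _oriented(scores, orientation)
    order = np.argsort(-s, kind="stable")
    tp = np.concatenate([[0], np.cumsum(pos[order])])
    fp = np.concatenate([[0], np.cumsum(~pos[order])])
    return fp / (~pos).sum(), tp / pos.sum()


def plot_roc(scores_by_name: dict, labels, orientation: str = "lower", ax=None,
             path=None):
    """ROC curves for one or more measures on the same subjects."""
    import matplotlib.pyplot as plt

    from .evaluate import roc_auc

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for name, scores in scores_by_name.items():
        fpr, tpr = _roc_points(scores, labels, orientation)
        auc = roc_auc(scores, labels, orientation)
        ax.plot(fpr, tpr, label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax


def plot_boot_dist(dists_by_name: dict[str, BootDist], ax=None, path=None):
    """Histograms of bootstrap AUC-difference distributions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name, dist in dists_by_name.items():
        ax.hist(dist.samples, bins=80, histtype="step", density=True, label=name)
    ax.axvline(0.0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("AUC difference")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    return ax
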