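"""Plots: ROC curves, per-patient NRS histograms, Kaplan-Meier curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_roc_curves(results, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    curves = [("cells (train)", results.roc_cell_train), ("ROI median", results.roc_roi)]
    if results.roc_cell_test is not None:
        curves.insert(1, ("cells (test)", results.roc_cell_test))
    for name, roc in curves:
        ax.plot(1 - roc.specificity, roc.sensitivity, label=f"{name}: AUC {100 * roc.auc:.1f}%")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    return ax


def plot_nrs_histograms(results, patient_ids=None, ax=None):
    scores = results.scores
    if patient_ids is None:
        patient_ids = scores["patient_id"].unique()[:2]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for pid in patient_ids:
        vals = scores.loc[scores["patient_id"] == pid, "nrs"]
        ax.hist(vals, bins=20, range=(0, 1), alpha=0.5, label=str(pid), density=True)
    ax.axvline(0.5, color="k", ls="--", lw=0.8)
    ax.set_xlabel("NRS")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    return ax


def plot_km(curves: dict, ax=None, title=""):
    """Step plot of Kaplan-Meier curve tables keyed by group label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, table in curves.items():
        ax.step(table["time"], table["survival"], where="post", label=str(label))
    ax.set_ylim(0, 1.05)
    ax.set_xlabel("years")
    ax.set_ylabel("survival")
    ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
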