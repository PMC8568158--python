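"""Aggregation of cell scores to ROI- and patient-level risk calls.

Cell NRS values are rolled up two ways: the median NRS per region of
interest (robust to a minority of aberrant cells within an ROI), and the
percent of "positive" cells (NRS ≥ 0.5) per patient.  ROC analysis on the
per-patient percent-positive values selects an operating cutoff by Youden's
J (sensitivity + specificity − 1, ties broken toward higher specificity);
patients above the cutoff form the high-risk group.  Poorly differentiated
(G3) tumors bypass the trained model's cutoff and use an independent, lower
cutoff on the same percent-positive statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .nrs import CELL_CUTOFF

PATIENT_CUTOFF_DEFAULT = 61.0  # percent positive cells, G1/G2 pathway
G3_CUTOFF_DEFAULT = 25.0


# ---------------------------------------------------------------------------
# roll-ups


def roi_median_nrs(scores: pd.DataFrame) -> pd.DataFrame:
    """Median NRS per ROI (even-count median = mean of the middle two)."""
    if scores["roi_id"].isna().any():
        raise ValueError("every score needs an ROI id")
    grouped = scores.groupby(["roi_id", "patient_id"], sort=True)["nrs"]
    out = grouped.agg(n_cells="size", median_nrs="median").reset_index()
    empty = out["n_cells"] == 0
    if empty.any():
        warnings.warn(f"omitting {int(empty.sum())} empty ROIs")
        out = out[~empty]
    return out


def percent_positive(
    scores: pd.DataFrame, cutoff: float = CELL_CUTOFF, patients: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per patient: percent of cells with NRS ≥ cutoff, plus median NRS.

    A patient with zero epithelial cells cannot be summarized and is an
    error.  ``patients`` (patient_id, ln_status, grade, ...) is merged in
    when given."""
    counts = scores.groupby("patient_id")["nrs"].agg(
        n_cells="size",
        median_nrs="median",
        percent_positive=lambda s: 100.0 * (s >= cutoff).mean(),
    ).reset_index()
    if (counts["n_cells"] == 0).any():
        raise ValueError("patient with 0 epithelial cells cannot be summarized")
    if patients is not None:
        known = set(counts["patient_id"])
        missing = [p for p in patients["patient_id"] if p not in known]
        if missing:
            raise ValueError(f"patients with 0 epithelial cells: {missing}")
        counts = patients.merge(counts, on="patient_id", how="inner")
    return counts


# ---------------------------------------------------------------------------
# ROC machinery


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


def roc_analysis(values: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC over the observed values; AUC equals the Mann–Whitney statistic
    (ties at ½ credit).  Positive prediction convention: value ≥ threshold."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, thr = roc_curve(labels, values)
    return ROCCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=float(roc_auc_score(labels, values)),
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
    )


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV, accuracy (fractions in [0, 1])."""

    def _ratio(a, b):
        return a / b if b > 0 else float("nan")

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "accuracy": _ratio(tp + tn, tp + fn + tn + fp),
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


@dataclass
class CutoffResult:
    cutoff: float
    youden_j: float
    auc: float
    metrics: dict[str, float]


def _confusion_at(values: np.ndarray, labels: np.ndarray, cutoff: float, strict: bool) -> dict:
    pred = values > cutoff if strict else values >= cutoff
    labels = np.asarray(labels).astype(bool)
    return confusion_metrics(
        tp=int((pred & labels).sum()),
        fn=int((~pred & labels).sum()),
        tn=int((~pred & ~labels).sum()),
        fp=int((pred & ~labels).sum()),
    )


def best_cutoff(roc: ROCCurve) -> CutoffResult:
    """Cutoff maximizing Youden's J; ties broken toward higher specificity
    (i.e. the larger threshold)."""
    j = roc.sensitivity + roc.specificity - 1.0
    order = np.lexsort((roc.specificity, j))  # last entry = max J, then max spec
    k = order[-1]
    cutoff = float(roc.thresholds[k])
    if not math.isfinite(cutoff):  # sklearn's sentinel top threshold
        cutoff = float(np.nanmax(roc.thresholds[np.isfinite(roc.thresholds)]) + 1.0)
    sens, spec = float(roc.sensitivity[k]), float(roc.specificity[k])
    metrics = {
        "sensitivity": sens,
        "specificity": spec,
        "tp": round(sens * roc.n_pos), "fn": round((1 - sens) * roc.n_pos),
        "tn": round(spec * roc.n_neg), "fp": round((1 - spec) * roc.n_neg),
    }
    m = confusion_metrics(metrics["tp"], metrics["fn"], metrics["tn"], metrics["fp"])
    return CutoffResult(cutoff=cutoff, youden_j=float(j[k]), auc=roc.auc, metrics=m)


# ---------------------------------------------------------------------------
# patient classification


def classify_patients(
    summaries: pd.DataFrame, cutoff: float = PATIENT_CUTOFF_DEFAULT, comparator: str = ">"
) -> pd.DataFrame:
    """High/low risk from percent positive cells.

    Default comparator is strict ``>`` (a patient exactly at the cutoff is
    low risk); ``>=`` is available."""
    if comparator not in (">", ">="):
        raise ValueError("comparator must be '>' or '>='")
    out = summaries.copy()
    pp = out["percent_positive"].to_numpy()
    high = pp > cutoff if comparator == ">" else pp >= cutoff
    out["risk_group"] = np.where(high, "high", "low")
    out["risk_cutoff"] = cutoff
    return out


def split_patients(
    patients: pd.DataFrame, fraction: float = 0.8, seed: int = 0, stratify: str = "ln_status"
) -> tuple[list, list]:
    """Patient-level split stratified by LN status; no patient appears in
    both partitions.  Per-stratum train size is floor(fraction·n), but never
    0 — a stratum always contributes at least one training patient."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for _, grp in patients.groupby(stratify, sort=True):
        ids = grp["patient_id"].to_numpy()
        perm = rng.permutation(len(ids))
        n_train = max(1, int(math.floor(fraction * len(ids))))
        train.extend(ids[perm[:n_train]].tolist())
        test.extend(ids[perm[n_train:]].tolist())
    return sorted(train), sorted(test)


def select_patient_cutoff(
    train_summaries: pd.DataFrame,
    test_summaries: pd.DataFrame | None = None,
    comparator: str = ">",
) -> dict:
    """ROC + Youden cutoff on the training patients' percent-positive values;
    test-set confusion is computed only at the frozen training cutoff."""
    y_train = (train_summaries["ln_status"] == "LN+").to_numpy()
    if y_train.all() or not y_train.any():
        raise ValueError(
            "patient training partition contains a single LN class; "
            "cutoff selection needs both (cohort too small for a stratified split)"
        )
    roc = roc_analysis(train_summaries["percent_positive"].to_numpy(), y_train)
    chosen = best_cutoff(roc)
    out = {"roc": roc, "cutoff": chosen, "train_metrics": chosen.metrics}
    if test_summaries is not None and len(test_summaries):
        out["test_metrics"] = _confusion_at(
            test_summaries["percent_positive"].to_numpy(),
            (test_summaries["ln_status"] == "LN+").to_numpy(),
            chosen.cutoff,
            strict=(comparator == ">"),
        )
    return out


def g3_pathway(
    g3_summaries: pd.DataFrame, cutoff: float = G3_CUTOFF_DEFAULT, comparator: str = ">"
) -> tuple[CutoffResult, pd.DataFrame]:
    """Percent-positive risk call for poorly differentiated tumors with an
    independent cutoff; reports sensitivity/specificity/accuracy."""
    if len(g3_summaries) == 0:
        raise ValueError("empty G3 patient set")
    if (g3_summaries.get("grade") is not None) and (g3_summaries["grade"] != "G3").any():
        raise ValueError("g3_pathway expects grade G3 patients only")
    groups = classify_patients(g3_summaries, cutoff=cutoff, comparator=comparator)
    labels = (g3_summaries["ln_status"] == "LN+").to_numpy()
    m = _confusion_at(
        g3_summaries["percent_positive"].to_numpy(), labels, cutoff, strict=(comparator == ">")
    )
    result = CutoffResult(cutoff=cutoff, youden_j=m["sensitivity"] + m["specificity"] - 1.0,
                          auc=float("nan"), metrics=m)
    return result, groups
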