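"""Model/Results interface over the nodal-risk pipeline.

:class:`NodalRiskModel` is built from a per-cell feature table plus patient
metadata; :meth:`NodalRiskModel.fit` runs the full modelling stage — cell
split, forest tuning, cell scoring, ROI/patient aggregation, cutoff
selection, G3 pathway — and returns a :class:`NodalRiskResults` carrying the
estimates, operating points and diagnostics, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nrs as _nrs
from . import riskagg as _agg
from .registry import FeatureRegistry, default_registry


@dataclass
class NodalRiskModel:
    """Nodal-risk model specification bound to data.

    Parameters
    ----------
    cells : per-cell table with patient_id, roi_id, grade, ln_status and the
        registered feature columns (normalized upstream when they come from
        images).
    patients : per-patient table with patient_id, ln_status, grade.
    feature_names : subset of columns used as predictors; defaults to every
        registry feature present in ``cells``.
    """

    cells: pd.DataFrame
    patients: pd.DataFrame
    feature_names: list[str] | None = None
    registry: FeatureRegistry | None = None
    rf_config: _nrs.RFConfig | None = None
    cell_split_fraction: float = 0.8
    cell_split_mode: str = "cell"
    patient_split_fraction: float = 0.8
    patient_comparator: str = ">"
    g3_cutoff: float = _agg.G3_CUTOFF_DEFAULT

    def __post_init__(self) -> None:
        self.registry = self.registry or default_registry()
        if self.feature_names is None:
            self.feature_names = [n for n in self.registry.names if n in self.cells.columns]
        if not self.feature_names:
            raise ValueError("no registered feature columns found in cells")
        for col in ("patient_id", "roi_id", "grade", "ln_status"):
            if col not in self.cells.columns:
                raise ValueError(f"cells table lacks required column '{col}'")

    @classmethod
    def from_feature_table(cls, cells: pd.DataFrame, patients: pd.DataFrame, **kw) -> "NodalRiskModel":
        return cls(cells=cells, patients=patients, **kw)

    @classmethod
    def from_synthetic(cls, spec=None, **kw) -> "NodalRiskModel":
        from .synthetic import CohortSpec, generate_feature_cohort

        spec = spec or CohortSpec()
        cells, truth = generate_feature_cohort(spec)
        return cls(cells=cells, patients=truth.patients, **kw)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0) -> "NodalRiskResults":
        """Train the NRS forest on G1/G2 cells and assemble all risk calls."""
        cfg = self.rf_config or _nrs.RFConfig(seed=seed)
        g12 = self.cells[self.cells["grade"].isin(["G1", "G2"])].reset_index(drop=True)
        g3 = self.cells[self.cells["grade"] == "G3"].reset_index(drop=True)
        if g12.empty:
            raise ValueError("no G1/G2 cells to train on")

        split = _nrs.split_cells(g12, self.cell_split_fraction, seed=seed, mode=self.cell_split_mode)
        train_cells = g12[split.train.to_numpy()]
        test_cells = g12[~split.train.to_numpy()]
        model = _nrs.tune_and_train(
            train_cells, self.feature_names, cfg, registry_hash=self.registry.hash()
        )

        scores_train = _nrs.score_cells(model, train_cells)
        scores_test = _nrs.score_cells(model, test_cells)
        y_tr = (train_cells["ln_status"] == "LN+").to_numpy()
        y_te = (test_cells["ln_status"] == "LN+").to_numpy()
        roc_cell_train = _agg.roc_analysis(scores_train["nrs"].to_numpy(), y_tr)
        roc_cell_test = (
            _agg.roc_analysis(scores_test["nrs"].to_numpy(), y_te)
            if 0 < y_te.sum() < len(y_te)
            else None
        )

        scores_all = pd.concat([scores_train, scores_test], ignore_index=True)
        roi = _agg.roi_median_nrs(scores_all)
        roi = roi.merge(self.patients[["patient_id", "ln_status"]], on="patient_id")
        roc_roi = _agg.roc_analysis(
            roi["median_nrs"].to_numpy(), (roi["ln_status"] == "LN+").to_numpy()
        )

        pats_g12 = self.patients[self.patients["grade"].isin(["G1", "G2"])]
        summaries = _agg.percent_positive(scores_all, patients=pats_g12)
        train_ids, test_ids = _agg.split_patients(
            pats_g12, self.patient_split_fraction, seed=seed
        )
        s_train = summaries[summaries["patient_id"].isin(train_ids)]
        s_test = summaries[summaries["patient_id"].isin(test_ids)]
        cutoff_sel = _agg.select_patient_cutoff(s_train, s_test, comparator=self.patient_comparator)
        risk = _agg.classify_patients(
            summaries, cutoff=cutoff_sel["cutoff"].cutoff, comparator=self.patient_comparator
        )
        risk["partition"] = np.where(risk["patient_id"].isin(train_ids), "train", "test")

        g3_result = g3_groups = None
        if not g3.empty:
            g3_scores = _nrs.score_cells(model, g3)
            pats_g3 = self.patients[self.patients["grade"] == "G3"]
            g3_summaries = _agg.percent_positive(g3_scores, patients=pats_g3)
            if g3_summaries["ln_status"].nunique() > 0:
                g3_result, g3_groups = _agg.g3_pathway(
                    g3_summaries, cutoff=self.g3_cutoff, comparator=self.patient_comparator
                )

        return NodalRiskResults(
            model=self,
            nrs_model=model,
            cell_split=split,
            scores=scores_all,
            roc_cell_train=roc_cell_train,
            roc_cell_test=roc_cell_test,
            roi_summaries=roi,
            roc_roi=roc_roi,
            patient_summaries=risk,
            patient_cutoff=cutoff_sel["cutoff"],
            patient_train_ids=train_ids,
            patient_test_ids=test_ids,
            patient_test_metrics=cutoff_sel.get("test_metrics"),
            g3_result=g3_result,
            g3_groups=g3_groups,
            seed=seed,
        )


@dataclass
class NodalRiskResults:
    """Fitted nodal-risk pipeline: scores, ROC curves, cutoffs, risk calls."""

    model: NodalRiskModel
    nrs_model: _nrs.NRSModel
    cell_split: _nrs.CellSplit
    scores: pd.DataFrame
    roc_cell_train: _agg.ROCCurve
    roc_cell_test: _agg.ROCCurve | None
    roi_summaries: pd.DataFrame
    roc_roi: _agg.ROCCurve
    patient_summaries: pd.DataFrame
    patient_cutoff: _agg.CutoffResult
    patient_train_ids: list
    patient_test_ids: list
    patient_test_metrics: dict | None
    g3_result: _agg.CutoffResult | None
    g3_groups: pd.DataFrame | None
    seed: int

    # -- headline numbers -------------------------------------------------
    @property
    def cell_auc_train(self) -> float:
        return self.roc_cell_train.auc

    @property
    def cell_auc_test(self) -> float | None:
        return self.roc_cell_test.auc if self.roc_cell_test else None

    @property
    def roi_auc(self) -> float:
        return self.roc_roi.auc

    @property
    def patient_auc_train(self) -> float:
        return self.patient_cutoff.auc

    def as_dict(self) -> dict:
        d = {
            "n_cells": len(self.scores),
            "n_trees": self.nrs_model.n_trees,
            "mtry": self.nrs_model.mtry,
            "oob_error": self.nrs_model.oob_error,
            "cell_auc_train": self.cell_auc_train,
            "cell_auc_test": self.cell_auc_test,
            "roi_auc": self.roi_auc,
            "patient_auc_train": self.patient_auc_train,
            "patient_cutoff_pct": self.patient_cutoff.cutoff,
            "patient_train_sensitivity": self.patient_cutoff.metrics["sensitivity"],
            "patient_train_specificity": self.patient_cutoff.metrics["specificity"],
        }
        if self.patient_test_metrics:
            d["patient_test_accuracy"] = self.patient_test_metrics["accuracy"]
        if self.g3_result:
            d["g3_accuracy"] = self.g3_result.metrics["accuracy"]
        return d

    def summary(self) -> str:
        d = self.as_dict()
        lines = [
            "Nodal Risk Score results",
            "=" * 40,
            f"cells scored:            {d['n_cells']}",
            f"forest: {d['n_trees']} trees, mtry={d['mtry']}, OOB error {d['oob_error']:.3f}",
            f"cell AUC (train):        {100 * d['cell_auc_train']:.1f}%",
        ]
        if d["cell_auc_test"] is not None:
            lines.append(f"cell AUC (test):         {100 * d['cell_auc_test']:.1f}%")
        lines += [
            f"ROI median-NRS AUC:      {100 * d['roi_auc']:.1f}%",
            f"patient %positive AUC:   {100 * d['patient_auc_train']:.1f}% (train)",
            f"chosen patient cutoff:   {d['patient_cutoff_pct']:.1f}% positive cells",
            f"  train sens/spec:       {100 * d['patient_train_sensitivity']:.1f}% / "
            f"{100 * d['patient_train_specificity']:.1f}%",
        ]
        if "patient_test_accuracy" in d:
            lines.append(f"  test accuracy:         {100 * d['patient_test_accuracy']:.1f}%")
        if "g3_accuracy" in d:
            lines.append(
                f"G3 pathway (cutoff {self.g3_result.cutoff:.0f}%): accuracy "
                f"{100 * d['g3_accuracy']:.1f}%"
            )
        return "\n".join(lines)

    # -- survival hooks ---------------------------------------------------
    def rr_free_analysis(self, records: pd.DataFrame) -> dict:
        """RR-free KM + log-rank by predicted risk group, per partition."""
        from . import outcomes

        groups = self.patient_summaries[["patient_id", "risk_group", "partition"]]
        return outcomes.rr_free_analysis(records, groups)

    # -- plots ------------------------------------------------------------
    def plot_roc(self, ax=None):
        from . import plotting

        return plotting.plot_roc_curves(self, ax=ax)

    def plot_nrs_histograms(self, patient_ids=None, ax=None):
        from . import plotting

        return plotting.plot_nrs_histograms(self, patient_ids=patient_ids, ax=ax)
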