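"""End-to-end pipeline stages with file artifacts.

Each stage reads the artifacts of its upstream stage from one output
directory and writes its own, so any prefix of the pipeline can be re-run.
A missing upstream artifact raises an error naming the command that produces
it.  All randomness flows from the seeds in the config; fixed seeds give
byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imaging, nrs, outcomes, riskagg, triage
from .model import NodalRiskModel
from .registry import default_registry
from .synthetic import CohortSpec, GroundTruth, generate_feature_cohort, generate_image_cohort, generate_survival

logger = logging.getLogger(__name__)

_COHORT_KEYS = {f.name for f in dataclasses.fields(CohortSpec)}


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration; written next to every run's outputs."""

    mode: str = "table"  # "table" (per-cell feature route) | "image"
    cohort: dict = field(default_factory=dict)
    seed: int = 0
    rf: dict = field(default_factory=lambda: {
        "n_trees_grid": [100, 250], "mtry_grid": ["sqrt", "third"], "cv_folds": 5,
    })
    cell_split_fraction: float = 0.8
    cell_split_mode: str = "cell"
    patient_split_fraction: float = 0.8
    patient_comparator: str = ">"
    g3_cutoff: float = 25.0
    landmark_years: float = 2.0
    survival: dict = field(default_factory=lambda: {
        "rr_hazard_ln_pos": 0.35, "rr_hazard_ln_neg": 0.02,
        "dss_hazard_ln_pos": 0.15, "dss_hazard_ln_neg": 0.0,
        "censor_time": 5.0,
    })
    segmentation: dict = field(default_factory=dict)
    normalize_all_od: bool = True
    min_reference: int = 50

    def __post_init__(self) -> None:
        if self.mode not in ("table", "image"):
            raise ValueError(f"mode must be 'table' or 'image', got {self.mode!r}")
        unknown = set(self.cohort) - _COHORT_KEYS
        if unknown:
            raise ValueError(f"unknown cohort keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def cohort_spec(self) -> CohortSpec:
        kw = dict(self.cohort)
        for k in ("rois_per_patient", "cells_per_roi", "tile_shape", "nucleus_radius_um"):
            if k in kw:
                kw[k] = tuple(kw[k])
        kw.setdefault("seed", self.seed)
        return CohortSpec(**kw)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.resolved(), sort_keys=True).encode()).hexdigest()[:16]


def _write_metadata(cfg: PipelineConfig, outdir: Path) -> None:
    (outdir / "resolved_config.yaml").write_text(yaml.safe_dump(cfg.resolved(), sort_keys=True))
    (outdir / "run_metadata.json").write_text(json.dumps(
        {"config_hash": cfg.hash(), "registry_hash": default_registry().hash()}, indent=1
    ))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing {path.name}: run the '{producer}' command first")
    return path


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_metadata(cfg, outdir)
    spec = cfg.cohort_spec()
    if cfg.mode == "table":
        cells, truth = generate_feature_cohort(spec)
        cells.to_csv(outdir / "cells.csv", index=False)
        truth.objects.to_csv(outdir / "truth_objects.csv", index=False)
        truth.patients.to_csv(outdir / "patients.csv", index=False)
    else:
        _, truth = generate_image_cohort(spec, outdir / "tiles")
        truth.patients.to_csv(outdir / "patients.csv", index=False)
    sv = cfg.survival
    rr = generate_survival(truth, sv["rr_hazard_ln_pos"], sv["rr_hazard_ln_neg"],
                           sv["censor_time"], endpoint="RR", seed=spec.seed)
    dss = generate_survival(truth, sv["dss_hazard_ln_pos"], sv["dss_hazard_ln_neg"],
                            sv["censor_time"], endpoint="DSS", seed=spec.seed + 1)
    rr.to_csv(outdir / "survival_rr.csv", index=False)
    dss.to_csv(outdir / "survival_dss.csv", index=False)


def _image_only(cfg: PipelineConfig, stage: str) -> None:
    if cfg.mode != "image":
        raise RuntimeError(
            f"'{stage}' applies to the image route only; config mode is 'table' "
            "(cells.csv comes straight from 'simulate')"
        )


def stage_segment(cfg: PipelineConfig, outdir: Path) -> None:
    _image_only(cfg, "segment")
    tiles = _require(outdir / "tiles" / "manifest.json", "simulate").parent
    import tifffile

    rois, _meta = imaging.load_manifest(tiles / "manifest.json")
    params = imaging.SegmentationParams(**cfg.segmentation)
    seg_dir = outdir / "segmentation"
    seg_dir.mkdir(exist_ok=True)
    for roi in rois:
        image = tifffile.imread(tiles / roi.tile)
        bg = imaging.estimate_background(image)
        od = imaging.to_optical_density(image, bg, pixel_size=cfg.cohort_spec().pixel_size)
        labels = imaging.segment_nuclei(od, params)
        tifffile.imwrite(seg_dir / f"{roi.roi_id}_labels.tif", labels.astype(np.uint16))
    logger.info("segmented %d ROIs", len(rois))


def stage_features(cfg: PipelineConfig, outdir: Path) -> None:
    _image_only(cfg, "features")
    import tifffile

    from .qnp import compute_qnp
    from .triage import focus_sharpness

    tiles = _require(outdir / "tiles" / "manifest.json", "simulate").parent
    seg_dir = _require(outdir / "segmentation", "segment")
    registry = default_registry()
    rois, _ = imaging.load_manifest(tiles / "manifest.json")
    truth = pd.read_csv(tiles / "truth_objects.csv")
    rows, rejects = [], []
    for roi in rois:
        image = tifffile.imread(tiles / roi.tile)
        bg = imaging.estimate_background(image)
        od = imaging.to_optical_density(image, bg, pixel_size=cfg.cohort_spec().pixel_size)
        labels = tifffile.imread(seg_dir / f"{roi.roi_id}_labels.tif").astype(np.int32)
        truth_labels = tifffile.imread(tiles / f"{roi.roi_id}_truth_labels.tif").astype(np.int32)
        roi_truth = truth[truth["roi_id"] == roi.roi_id].reset_index(drop=True)
        objs, log = imaging.extract_objects(od, labels, patient_id=roi.patient_id, roi_id=roi.roi_id)
        rejects.append(log)
        for obj in objs:
            r, c = int(round(obj.centroid[0])), int(round(obj.centroid[1]))
            tl = truth_labels[min(r, truth_labels.shape[0] - 1), min(c, truth_labels.shape[1] - 1)]
            true_class = roi_truth.iloc[tl - 1]["true_class"] if tl > 0 else "junk"
            vec = compute_qnp(obj, registry)
            rows.append({
                "object_id": obj.object_id, "patient_id": obj.patient_id, "roi_id": obj.roi_id,
                "true_class": true_class, "sharpness": focus_sharpness(obj),
                "flags": ";".join(sorted(obj.flags)), **vec,
            })
    feats = pd.DataFrame(rows)
    feats.to_csv(outdir / "features_raw.csv", index=False)
    pd.concat(rejects, ignore_index=True).to_csv(outdir / "rejection_log.csv", index=False)


def stage_triage(cfg: PipelineConfig, outdir: Path) -> None:
    _image_only(cfg, "triage")
    feats = pd.read_csv(_require(outdir / "features_raw.csv", "features"))
    registry = default_registry()
    names = [n for n in registry.names if n in feats.columns]
    # impute flagged-missing features from the per-slide epithelial-candidate median
    for pid, idx in feats.groupby("patient_id").groups.items():
        block = feats.loc[idx, names]
        feats.loc[idx, names] = block.fillna(block.median())
    feats[names] = feats[names].fillna(feats[names].median())
    cascade = triage.train_cascade(
        feats, feats["true_class"], registry, sharpness=feats["sharpness"], seed=cfg.seed
    )
    classes = triage.classify_objects(feats, cascade, sharpness=feats["sharpness"])
    feats["class"] = classes
    report = feats.groupby(["roi_id", "class"]).size().rename("n").reset_index()
    report.to_csv(outdir / "triage_report.csv", index=False)
    triage.save_cascade(cascade, outdir / "triage_cascade")

    pats = pd.read_csv(outdir / "patients.csv")
    cells_out = []
    factors = {}
    for pid, grp in feats.groupby("patient_id"):
        epi = grp[grp["class"] == "epithelial"]
        ref = triage.reference_stats(grp, grp["class"], min_count=cfg.min_reference)
        normed, factor = triage.normalize_features(epi, ref, cfg.normalize_all_od)
        factors[pid] = factor
        cells_out.append(normed)
    cells = pd.concat(cells_out, ignore_index=True)
    cells = cells.merge(pats[["patient_id", "ln_status", "grade"]], on="patient_id")
    cells.to_csv(outdir / "cells.csv", index=False)
    (outdir / "normalization_factors.json").write_text(json.dumps(factors, indent=1))


def _load_cells(cfg: PipelineConfig, outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    producer = "simulate" if cfg.mode == "table" else "triage"
    cells = pd.read_csv(_require(outdir / "cells.csv", producer))
    patients = pd.read_csv(_require(outdir / "patients.csv", "simulate"))
    return cells, patients


def _build_model(cfg: PipelineConfig, cells: pd.DataFrame, patients: pd.DataFrame) -> NodalRiskModel:
    rf = nrs.RFConfig(
        n_trees_grid=tuple(cfg.rf.get("n_trees_grid", (100, 250))),
        mtry_grid=tuple(cfg.rf.get("mtry_grid", ("sqrt", "third"))),
        cv_folds=int(cfg.rf.get("cv_folds", 5)),
        seed=cfg.seed,
    )
    return NodalRiskModel(
        cells=cells, patients=patients, rf_config=rf,
        cell_split_fraction=cfg.cell_split_fraction, cell_split_mode=cfg.cell_split_mode,
        patient_split_fraction=cfg.patient_split_fraction,
        patient_comparator=cfg.patient_comparator, g3_cutoff=cfg.g3_cutoff,
    )


def stage_model(cfg: PipelineConfig, outdir: Path):
    """train-nrs + score + aggregate + cutoffs in one fitted Results object."""
    cells, patients = _load_cells(cfg, outdir)
    results = _build_model(cfg, cells, patients).fit(seed=cfg.seed)
    nrs.save_model(results.nrs_model, outdir / "nrs_model")
    results.scores.to_csv(outdir / "scores.csv", index=False)
    results.roi_summaries.to_csv(outdir / "roi_summary.csv", index=False)
    risk = results.patient_summaries.copy()
    if results.g3_groups is not None:
        risk = pd.concat([risk, results.g3_groups.assign(partition="g3")], ignore_index=True)
    risk.to_csv(outdir / "patient_risk.csv", index=False)
    (outdir / "cutoffs.json").write_text(json.dumps({
        "cell_cutoff": nrs.CELL_CUTOFF,
        "patient_cutoff_pct": results.patient_cutoff.cutoff,
        "patient_comparator": cfg.patient_comparator,
        "g3_cutoff_pct": cfg.g3_cutoff,
        "train_metrics": results.patient_cutoff.metrics,
        "test_metrics": results.patient_test_metrics,
        "g3_metrics": results.g3_result.metrics if results.g3_result else None,
    }, indent=1, default=float))
    (outdir / "model_summary.txt").write_text(results.summary() + "\n")
    for name, roc in (("cell_train", results.roc_cell_train),
                      ("cell_test", results.roc_cell_test),
                      ("roi", results.roc_roi)):
        if roc is not None:
            pd.DataFrame({"threshold": roc.thresholds, "sensitivity": roc.sensitivity,
                          "specificity": roc.specificity}).to_csv(
                outdir / f"roc_{name}.csv", index=False)
    return results


def stage_survival(cfg: PipelineConfig, outdir: Path) -> dict:
    rr = pd.read_csv(_require(outdir / "survival_rr.csv", "simulate"))
    dss = pd.read_csv(_require(outdir / "survival_dss.csv", "simulate"))
    risk = pd.read_csv(_require(outdir / "patient_risk.csv", "score"))
    out: dict = {}
    try:
        dss_lm = outcomes.landmark_dss_analysis(dss, cfg.landmark_years)
        out["dss_landmark"] = {k: dss_lm[k] for k in ("statistic", "p", "n", "n_events")}
    except ValueError as e:
        out["dss_landmark"] = {"error": str(e)}
    g12 = risk[risk["partition"].isin(["train", "test"])]
    try:
        rrfree = outcomes.rr_free_analysis(rr, g12[["patient_id", "risk_group", "partition"]])
        out["rr_free"] = {
            name: {k: v for k, v in res.items() if k != "curves"} for name, res in rrfree.items()
        }
    except ValueError as e:
        out["rr_free"] = {"error": str(e)}
    (outdir / "survival_results.json").write_text(json.dumps(out, indent=1, default=float))
    # KM curve tables
    for endpoint, rec in (("rr", rr), ("dss", dss)):
        outcomes.km_estimate(rec).to_csv(outdir / f"km_{endpoint}_all.csv", index=False)
    # descriptive cohort table by nodal group
    pats = pd.read_csv(outdir / "patients.csv")
    outcomes.cohort_table(
        pats, {"grade": "categorical", "doi_mm": "continuous"}
    ).to_csv(outdir / "cohort_table.csv", index=False)
    return out


def stage_report(cfg: PipelineConfig, outdir: Path) -> dict:
    _require(outdir / "scores.csv", "score")
    cutoffs = json.loads(_require(outdir / "cutoffs.json", "cutoffs").read_text())
    summary = _require(outdir / "model_summary.txt", "train-nrs").read_text()
    survival = (
        json.loads((outdir / "survival_results.json").read_text())
        if (outdir / "survival_results.json").exists()
        else None
    )
    report = {
        "config_hash": cfg.hash(),
        "registry_hash": default_registry().hash(),
        "cutoffs": cutoffs,
        "survival": survival,
        "summary": summary,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=float))
    # plots
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from . import plotting

    scores = pd.read_csv(outdir / "scores.csv")
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(scores["nrs"], bins=40, range=(0, 1))
    ax.set_xlabel("NRS")
    ax.set_ylabel("cells")
    fig.savefig(outdir / "nrs_histogram.png", dpi=110)
    plt.close(fig)
    for endpoint in ("rr", "dss"):
        path = outdir / f"km_{endpoint}_all.csv"
        if path.exists():
            fig, ax = plt.subplots(figsize=(5, 4))
            plotting.plot_km({endpoint.upper(): pd.read_csv(path)}, ax=ax)
            fig.savefig(outdir / f"km_{endpoint}.png", dpi=110)
            plt.close(fig)
    return report


STAGES = {
    "simulate": stage_simulate,
    "segment": stage_segment,
    "features": stage_features,
    "triage": stage_triage,
    "train-nrs": stage_model,
    "score": stage_model,
    "aggregate": stage_model,
    "cutoffs": stage_model,
    "survival": stage_survival,
    "report": stage_report,
}


def run(command: str, cfg: PipelineConfig, outdir: str | Path) -> None:
    """Run one subcommand, or 'all' for the full chain."""
    outdir = Path(outdir)
    if command == "all":
        chain = ["simulate"] + (["segment", "features", "triage"] if cfg.mode == "image" else [])
        chain += ["train-nrs", "survival", "report"]
        done = set()
        for c in chain:
            fn = STAGES[c]
            if fn in done:
                continue
            logger.info("stage: %s", c)
            fn(cfg, outdir)
            done.add(fn)
        return
    if command not in STAGES:
        raise ValueError(f"unknown command {command!r}")
    STAGES[command](cfg, outdir)
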