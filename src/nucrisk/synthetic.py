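"""Synthetic Feulgen-like cohorts with known ground truth.

Every downstream stage of the pipeline (segmentation, feature extraction,
triage, nodal-risk modelling, survival analysis) is testable against this
module: it emulates a cohort of oral squamous cell carcinoma patients whose
tumors were sampled as multiple regions of interest (ROIs), each imaged as a
Feulgen-thionin-stained grayscale tile.  Two routes are provided:

* :func:`generate_roi_image` draws an actual 8-bit tile containing elliptical
  nuclei with exact photometric ground truth (per-nucleus integrated optical
  density is specified in OD units and converted to intensity through the
  inverse OD transform), plus junk and lymphocyte-like non-squamous objects.
* :func:`generate_feature_cohort` skips imaging and draws per-cell feature
  vectors directly from class-conditional multivariate normals, for fast
  statistical tests of the modelling stages.

Node-positive (LN+) tumors differ from node-negative (LN0) tumors by a
configurable mean shift (in pooled-SD units) on a subset of features, applied
to a configurable fraction of their cells (intratumor heterogeneity: LN+
tumors are mixtures of shifted "high-risk-like" and baseline cells).
Survival times are exponential per nodal arm with administrative censoring.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .registry import default_registry

logger = logging.getLogger(__name__)

#: Features receiving the class-conditional shift by default: DNA amount and
#: chromatin-texture readouts are where node-positive tumors differ.
DEFAULT_EFFECT_FEATURES = (
    "iod",
    "od_mean",
    "od_var",
    "glcm_entropy",
    "dt_high_area_frac",
)


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic cohort.

    Defaults mirror the shape of a 35-patient / 561-ROI / ~468k-cell clinical
    cohort at desk scale: 30 patients, 3 ROIs each, 300 cells per ROI
    (~27k cells).  ``effect`` is the per-feature LN+ vs LN0 mean shift in
    pooled-SD units; the default is a 2-SD shift on five DNA-amount/texture
    features, applied to a ``heterogeneity`` fraction of LN+ cells.
    """

    n_patients: int = 30
    ln_prevalence: float = 19 / 35
    rois_per_patient: tuple[int, int] = (3, 3)
    cells_per_roi: tuple[int, int] = (300, 300)
    effect: dict[str, float] | None = None
    # a cell-level classifier's AUC ceiling is h + (1-h)/2 for mixture weight
    # h; 0.9 keeps the LN+ arm heterogeneous while matching the ~0.9+ cell
    # AUC scale reported for tumor-wide nuclear-phenotype shifts
    heterogeneity: float = 0.9
    patient_sigma: float = 0.25
    junk_rate: float = 0.10
    nonsquamous_rate: float = 0.10
    pixel_size: float = 0.25
    seed: int = 0
    # imaging-route parameters (OD units unless noted)
    tile_shape: tuple[int, int] = (1024, 1024)
    background_level: int = 235
    noise_sd: float = 1.0
    diploid_mean_od: float = 0.55
    nucleus_radius_um: tuple[float, float] = (3.0, 4.5)
    texture_od_sd: float = 0.15
    texture_corr_px: float = 2.0
    iod_cv: float = 0.08
    iod_shift: float = 0.5
    texture_shift: float = 0.5

    def __post_init__(self) -> None:
        for name in ("ln_prevalence", "heterogeneity", "junk_rate", "nonsquamous_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("rois_per_patient", "cells_per_roi"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name}={(lo, hi)} is not a valid range")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def effect_vector(self, feature_names: list[str]) -> np.ndarray:
        eff = dict.fromkeys(DEFAULT_EFFECT_FEATURES, 2.0) if self.effect is None else self.effect
        unknown = set(eff) - set(feature_names)
        if unknown:
            raise ValueError(f"effect refers to unknown features: {sorted(unknown)}")
        return np.array([eff.get(f, 0.0) for f in feature_names])


@dataclass
class PatientState:
    """Per-patient latent state shared across that patient's ROIs."""

    patient_id: str
    ln_status: str  # "LN0" | "LN+"
    grade: str  # "G1" | "G2" | "G3"
    doi_mm: float
    heterogeneity: float
    feature_offset: np.ndarray | None = None  # patient random effect, SD units


@dataclass
class GroundTruth:
    """Object- and patient-level truth for a generated cohort."""

    objects: pd.DataFrame  # one row per drawn object
    patients: pd.DataFrame  # one row per patient

    def __post_init__(self) -> None:
        if self.objects["object_id"].duplicated().any():
            raise ValueError("duplicate object ids in ground truth")


# ---------------------------------------------------------------------------
# patient-level sampling

_GRADES = ("G1", "G2", "G3")
# grade given nodal status, shaped on the 35-patient cohort (LN+: 7/7/5 of 19,
# LN0: 8/7/1 of 16)
_GRADE_P = {"LN+": (7 / 19, 7 / 19, 5 / 19), "LN0": (8 / 16, 7 / 16, 1 / 16)}
_DOI = {"LN+": (9.8, 6.9), "LN0": (4.9, 2.8)}  # mm, mean/SD


def sample_patients(spec: CohortSpec, rng: np.random.Generator) -> list[PatientState]:
    states = []
    for i in range(spec.n_patients):
        ln = "LN+" if rng.random() < spec.ln_prevalence else "LN0"
        grade = rng.choice(_GRADES, p=_GRADE_P[ln])
        mu, sd = _DOI[ln]
        doi = max(0.5, rng.normal(mu, sd))
        states.append(
            PatientState(
                patient_id=f"P{i:03d}",
                ln_status=ln,
                grade=str(grade),
                doi_mm=round(float(doi), 1),
                heterogeneity=spec.heterogeneity,
            )
        )
    return states


def _patient_table(states: list[PatientState]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in states],
            "ln_status": [s.ln_status for s in states],
            "grade": [s.grade for s in states],
            "doi_mm": [s.doi_mm for s in states],
        }
    )


# ---------------------------------------------------------------------------
# feature-table route


def generate_feature_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a per-cell feature table directly (no images).

    Cells are class-conditional multivariate normals over the default feature
    registry's names: baseline N(0, 1) per feature plus a patient-level random
    intercept (SD ``spec.patient_sigma``); within LN+ tumors a
    ``spec.heterogeneity`` fraction of cells receives the mean shift
    ``spec.effect`` (pooled-SD units).
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    names = [f.name for f in default_registry().features]
    effect = spec.effect_vector(names)
    states = sample_patients(spec, rng)

    rows = []
    feats = []
    for s in states:
        s.feature_offset = rng.normal(0.0, spec.patient_sigma, len(names))
        n_rois = rng.integers(spec.rois_per_patient[0], spec.rois_per_patient[1] + 1)
        for r in range(n_rois):
            n_cells = rng.integers(spec.cells_per_roi[0], spec.cells_per_roi[1] + 1)
            shifted = (
                rng.random(n_cells) < s.heterogeneity
                if s.ln_status == "LN+"
                else np.zeros(n_cells, bool)
            )
            x = rng.standard_normal((n_cells, len(names))) + s.feature_offset
            x[shifted] += effect
            feats.append(x)
            for c in range(n_cells):
                rows.append(
                    (
                        f"{s.patient_id}_R{r}_C{c:04d}",
                        s.patient_id,
                        f"{s.patient_id}_R{r}",
                        s.ln_status,
                        s.grade,
                        bool(shifted[c]),
                    )
                )
    meta = pd.DataFrame(
        rows, columns=["cell_id", "patient_id", "roi_id", "ln_status", "grade", "is_shifted"]
    )
    table = pd.concat(
        [meta, pd.DataFrame(np.vstack(feats), columns=names, index=meta.index)], axis=1
    )
    objects = meta.rename(columns={"cell_id": "object_id"}).assign(true_class="epithelial")
    truth = GroundTruth(objects=objects, patients=_patient_table(states))
    return table, truth


def bayes_optimal_auc(spec: CohortSpec, n_mc: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo cell-level AUC of the optimal (likelihood-ratio) classifier.

    For the two-Gaussian mixture the generator uses, the optimal per-cell
    score is the log-likelihood ratio of the LN+ mixture vs the LN0 baseline;
    the AUC is estimated by the probability a random LN+ cell outscores a
    random LN0 cell.
    """
    rng = np.random.default_rng(seed)
    names = [f.name for f in default_registry().features]
    d = spec.effect_vector(names)
    active = d != 0
    d = d[active]
    if not active.any():
        return 0.5

    def llr(x: np.ndarray) -> np.ndarray:
        # log[(1-h) + h * exp(x.d - |d|^2/2)] for the mixture vs baseline
        h = spec.heterogeneity
        z = x @ d - d @ d / 2.0
        return np.logaddexp(math.log1p(-h) if h < 1 else -np.inf, math.log(h) + z)

    x0 = rng.standard_normal((n_mc, active.sum()))
    is_shift = rng.random(n_mc) < spec.heterogeneity
    x1 = rng.standard_normal((n_mc, active.sum()))
    x1[is_shift] += d
    s0, s1 = llr(x0), llr(x1)
    return float((s1[:, None] > s0[None, :]).mean()) if n_mc <= 2000 else _fast_auc(s0, s1)


def _fast_auc(s0: np.ndarray, s1: np.ndarray) -> float:
    from scipy.stats import rankdata

    all_s = np.concatenate([s0, s1])
    ranks = rankdata(all_s)
    r1 = ranks[len(s0):].sum()
    n0, n1 = len(s0), len(s1)
    return float((r1 - n1 * (n1 + 1) / 2) / (n0 * n1))


# ---------------------------------------------------------------------------
# survival


def generate_survival(
    truth: GroundTruth,
    hazard_ln_pos: float,
    hazard_ln_neg: float,
    censor_time: float,
    endpoint: str = "RR",
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times per nodal arm with administrative censoring.

    Returns a table with columns patient_id, endpoint, time (years), event,
    group.  A zero hazard (e.g. no disease-specific deaths among LN0) yields
    an arm censored in full.
    """
    if hazard_ln_pos < 0 or hazard_ln_neg < 0:
        raise ValueError("hazards must be >= 0")
    if censor_time < 0:
        raise ValueError("censor_time must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    pats = truth.patients
    hazards = np.where(pats["ln_status"] == "LN+", hazard_ln_pos, hazard_ln_neg)
    with np.errstate(divide="ignore"):
        t_event = np.where(hazards > 0, rng.exponential(1.0, len(pats)) / np.maximum(hazards, 1e-300), np.inf)
    time = np.minimum(t_event, censor_time)
    event = (t_event <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "patient_id": pats["patient_id"].to_numpy(),
            "endpoint": endpoint,
            "time": time,
            "event": event,
            "group": pats["ln_status"].to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# image route


def _harmonic_radius(theta: np.ndarray, r0: float, rng: np.random.Generator) -> np.ndarray:
    """Ellipse-like radius function perturbed by low-order harmonics."""
    ecc = rng.uniform(0.0, 0.6)
    phi = rng.uniform(0, 2 * np.pi)
    b = r0 * math.sqrt(1 - ecc**2)
    # ellipse radius in polar form about its centre
    r = (r0 * b) / np.sqrt((b * np.cos(theta - phi)) ** 2 + (r0 * np.sin(theta - phi)) ** 2)
    for k in (2, 3, 4):
        amp = rng.uniform(0, 0.04) * r0
        r += amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return np.maximum(r, 1.5)


def _place_centres(
    n: int, shape: tuple[int, int], radii: np.ndarray, rng: np.random.Generator, max_tries: int = 60
) -> np.ndarray:
    """Non-overlapping circle packing by bounded rejection sampling.

    Returns the centres actually placed (may be fewer than requested)."""
    placed: list[tuple[float, float, float]] = []
    margin = 4
    for r in radii:
        ok = False
        for _ in range(max_tries):
            cy = rng.uniform(r + margin, shape[0] - r - margin)
            cx = rng.uniform(r + margin, shape[1] - r - margin)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 2) ** 2 for py, px, pr in placed):
                placed.append((cy, cx, r))
                ok = True
                break
        if not ok:
            continue
    return np.array(placed).reshape(-1, 3)


def _rasterize(centre: tuple[float, float], r0: float, rng: np.random.Generator, shape) -> np.ndarray:
    cy, cx = centre
    rr = int(math.ceil(r0 * 1.4)) + 2
    y, x = np.mgrid[-rr : rr + 1, -rr : rr + 1]
    theta = np.arctan2(y, x)
    rad = np.hypot(y, x)
    r_of_theta = _harmonic_radius(theta.ravel(), r0, rng).reshape(theta.shape)
    local = rad <= r_of_theta
    mask = np.zeros(shape, bool)
    y0, x0 = int(round(cy)) - rr, int(round(cx)) - rr
    ys = slice(max(y0, 0), min(y0 + local.shape[0], shape[0]))
    xs = slice(max(x0, 0), min(x0 + local.shape[1], shape[1]))
    mask[ys, xs] = local[ys.start - y0 : ys.stop - y0, xs.start - x0 : xs.stop - x0]
    return mask


def _textured_od(
    mask: np.ndarray, target_iod: float, texture_sd: float, corr_px: float, rng: np.random.Generator
) -> np.ndarray:
    """OD patch over ``mask`` with correlated-noise chromatin texture.

    The patch is rescaled so its sum equals ``target_iod`` exactly: photometric
    ground truth holds by construction."""
    noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape), corr_px)
    nsd = noise[mask].std()
    noise = noise / nsd if nsd > 0 else noise
    base = target_iod / mask.sum()
    od = np.clip(base * (1.0 + texture_sd / max(base, 1e-9) * noise * base), 0.05 * base, None)
    od = np.where(mask, od, 0.0)
    s = od.sum()
    return od * (target_iod / s) if s > 0 else od


def generate_roi_image(
    spec: CohortSpec, patient_state: PatientState, roi_index: int
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """One Feulgen-like 8-bit grayscale tile plus its ground-truth slice.

    Returns ``(image, truth_objects, truth_labels)`` where ``truth_labels`` is
    an integer label image over the drawn objects (0 = background).  Epithelial
    nuclei are harmonic-perturbed ellipses with exact target IOD; LN+-like
    cells draw IOD and texture contrast from shifted distributions; junk
    objects are defocused Gaussian blobs; non-squamous objects are small round
    high-OD (lymphocyte-like) nuclei.  Determinism: the RNG stream is derived
    from (seed, patient_id, roi_index) only.
    """
    pidx = int(patient_state.patient_id.lstrip("P"))
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 3, pidx, roi_index)))
    shape = spec.tile_shape
    lo, hi = spec.cells_per_roi
    n_epi = int(rng.integers(lo, hi + 1))
    n_junk = rng.binomial(max(n_epi, 1), spec.junk_rate)
    n_ns = rng.binomial(max(n_epi, 1), spec.nonsquamous_rate)

    r_lo, r_hi = (r / spec.pixel_size for r in spec.nucleus_radius_um)
    radii = np.concatenate(
        [
            rng.uniform(r_lo, r_hi, n_epi),
            rng.uniform(1.2 * r_hi, 2.0 * r_hi, n_junk),
            rng.uniform(0.45 * r_lo, 0.7 * r_lo, n_ns),
        ]
    )
    kinds = ["epithelial"] * n_epi + ["junk"] * n_junk + ["non_squamous"] * n_ns
    order = rng.permutation(len(radii))
    centres = _place_centres(len(radii), shape, radii[order], rng)
    n_requested = len(radii)

    od_img = np.zeros(shape)
    labels = np.zeros(shape, np.int32)
    rows = []
    shifted_flags = rng.random(n_requested) < (
        patient_state.heterogeneity if patient_state.ln_status == "LN+" else 0.0
    )

    label = 0
    for j, (cy, cx, r) in enumerate(centres):
        kind = kinds[order[j]]
        shifted = bool(shifted_flags[order[j]]) and kind == "epithelial"
        if kind == "junk":
            # defocused debris: broad blob, soft edge -> fails the sharpness rule
            y, x = np.mgrid[0 : shape[0], 0 : shape[1]]
            blob = np.exp(-(((y - cy) ** 2 + (x - cx) ** 2) / (2 * (r / 1.6) ** 2)))
            peak = rng.uniform(0.15, 0.4)
            od_img += peak * blob
            mask = blob > 0.25
            iod = float((peak * blob)[mask].sum())
        else:
            mask = _rasterize((cy, cx), r, rng, shape)
            if not mask.any():
                continue
            if kind == "non_squamous":
                mean_od = spec.diploid_mean_od * rng.uniform(1.6, 2.2)
                tex_sd = spec.texture_od_sd * 0.5
            else:
                ploidy = 1.0 + (spec.iod_shift if shifted else 0.0)
                mean_od = spec.diploid_mean_od * ploidy * (1 + rng.normal(0, spec.iod_cv))
                tex_sd = spec.texture_od_sd * (1.0 + (spec.texture_shift if shifted else 0.0))
            iod = float(mean_od * mask.sum())
            od_img += _textured_od(mask, iod, tex_sd, spec.texture_corr_px, rng)
        label += 1
        labels[mask] = label
        rows.append(
            (
                f"{patient_state.patient_id}_R{roi_index}_O{label:04d}",
                patient_state.patient_id,
                f"{patient_state.patient_id}_R{roi_index}",
                kind,
                shifted,
                float(cy),
                float(cx),
                float(r),
                iod,
            )
        )

    if label < n_requested:
        logger.warning(
            "ROI %s_R%d: placed %d of %d requested objects (crowded tile)",
            patient_state.patient_id,
            roi_index,
            label,
            n_requested,
        )

    intensity = spec.background_level * np.power(10.0, -od_img)
    intensity += rng.normal(0, spec.noise_sd, shape)
    image = np.clip(np.round(intensity), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(
        rows,
        columns=[
            "object_id",
            "patient_id",
            "roi_id",
            "true_class",
            "is_shifted",
            "center_row",
            "center_col",
            "radius_px",
            "target_iod",
        ],
    )
    truth["n_requested"] = n_requested
    return image, truth, labels


def generate_image_cohort(spec: CohortSpec, outdir: str | Path) -> tuple[Path, GroundTruth]:
    """Write a full image cohort: TIFF tiles, truth CSVs, manifest JSON.

    Returns the output directory and the cohort ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    states = sample_patients(spec, rng)
    manifest = {"pixel_size": spec.pixel_size, "seed": spec.seed, "rois": []}
    all_truth = []
    for s in states:
        n_rois = int(rng.integers(spec.rois_per_patient[0], spec.rois_per_patient[1] + 1))
        for r in range(n_rois):
            image, truth, labels = generate_roi_image(spec, s, r)
            tile = f"{s.patient_id}_R{r}.tif"
            tifffile.imwrite(outdir / tile, image)
            tifffile.imwrite(outdir / f"{s.patient_id}_R{r}_truth_labels.tif", labels.astype(np.uint16))
            all_truth.append(truth)
            h, w = spec.tile_shape
            manifest["rois"].append(
                {
                    "roi_id": f"{s.patient_id}_R{r}",
                    "patient_id": s.patient_id,
                    "tile": tile,
                    "polygon": [[0, 0], [0, w], [h, w], [h, 0]],
                    "depth_stratum": ["surface", "mid", "invasion_front"][r % 3],
                }
            )
    objects = pd.concat(all_truth, ignore_index=True)
    objects.to_csv(outdir / "truth_objects.csv", index=False)
    patients = _patient_table(states)
    patients.to_csv(outdir / "truth_patients.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "cohort_spec.json").write_text(
        json.dumps({k: v if not isinstance(v, tuple) else list(v) for k, v in dataclasses.asdict(spec).items()}, indent=1)
    )
    return outdir, GroundTruth(objects=objects, patients=patients)
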