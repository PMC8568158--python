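"""Object triage: good epithelial squamous / good non-squamous / junk.

Segmentation yields a mixed bag — in-focus epithelial nuclei (the scoring
substrate), small dense non-squamous nuclei (lymphocytes and the like), and
junk (debris, out-of-focus blobs, fused objects).  A cascade of hard rules
(area bounds, solidity, focus sharpness) followed by a random-forest stage
separates them; only epithelial objects flow to nodal-risk scoring.  The
photometric features of each slide are then normalized by its epithelial
population: dividing IOD by the slide's epithelial median IOD yields a DNA
index in which the (roughly diploid) reference population centres at 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .qnp import NuclearObject
from .registry import FeatureRegistry, default_registry

CLASSES = ("epithelial", "non_squamous", "junk")


@dataclass
class TriageRules:
    """Hard rules applied before any learned stage; failures are junk."""

    # area floor sits below small dense non-squamous nuclei (~8-15 um^2) so
    # they reach the learned stage; the sharpness threshold sits between the
    # defocused-junk (~0.08) and in-focus (>0.13) boundary-gradient modes
    min_area_um2: float = 6.0
    max_area_um2: float = 400.0
    min_solidity: float = 0.85
    min_sharpness: float = 0.10  # mean |grad OD| on the boundary band


@dataclass
class ReferenceStats:
    """Per-slide epithelial reference population for normalization."""

    median_iod: float
    mad_iod: float
    n_epithelial: int
    min_count: int = 50

    def __post_init__(self) -> None:
        if self.n_epithelial < self.min_count:
            raise ValueError(
                f"insufficient reference population: {self.n_epithelial} epithelial "
                f"cells < required {self.min_count}"
            )


def focus_sharpness(obj: NuclearObject) -> float:
    """Mean OD gradient magnitude over a 2-px band around the object boundary.

    Defocused (junk) objects have soft edges and score low."""
    gy, gx = np.gradient(obj.od_patch)
    grad = np.hypot(gy, gx)
    band = ndimage.binary_dilation(obj.mask, iterations=2) & ~ndimage.binary_erosion(
        obj.mask, iterations=2
    )
    return float(grad[band].mean()) if band.any() else 0.0


def apply_rules(
    features: pd.DataFrame, rules: TriageRules | None = None, sharpness: pd.Series | None = None
) -> pd.Series:
    """Provisional classes from hard rules; survivors are 'epithelial' pending
    the learned stage.  Requires registered feature columns."""
    rules = rules or TriageRules()
    for col in ("area_um2", "solidity"):
        if col not in features.columns:
            raise ValueError(f"rule references unknown feature '{col}'")
    junk = (
        (features["area_um2"] < rules.min_area_um2)
        | (features["area_um2"] > rules.max_area_um2)
        | (features["solidity"] < rules.min_solidity)
    )
    if sharpness is not None:
        junk |= sharpness.reindex(features.index) < rules.min_sharpness
    return pd.Series(np.where(junk, "junk", "epithelial"), index=features.index, name="rule_class")


@dataclass
class TriageCascade:
    """Hard rules, then a forest separating epithelial from non-squamous
    among rule survivors."""

    rules: TriageRules
    forest: RandomForestClassifier | None
    feature_names: list[str]
    registry_hash: str
    seed: int = 0

    def metadata(self) -> dict:
        return {
            "rules": vars(self.rules),
            "feature_names": self.feature_names,
            "registry_hash": self.registry_hash,
            "seed": self.seed,
            "n_trees": getattr(self.forest, "n_estimators", None),
        }


def train_cascade(
    features: pd.DataFrame,
    labels: pd.Series,
    registry: FeatureRegistry | None = None,
    rules: TriageRules | None = None,
    sharpness: pd.Series | None = None,
    n_trees: int = 100,
    seed: int = 0,
) -> TriageCascade:
    """Fit the forest stage (epithelial vs non-squamous) on rule survivors.

    ``labels`` are true classes from annotation or synthetic truth."""
    registry = registry or default_registry()
    rules = rules or TriageRules()
    if labels.nunique() < 2:
        raise ValueError("need at least 2 classes to train the cascade")
    rule_class = apply_rules(features, rules, sharpness)
    survivors = rule_class == "epithelial"
    train_mask = survivors & labels.isin(["epithelial", "non_squamous"])
    names = [n for n in registry.names if n in features.columns]
    x = features.loc[train_mask, names].to_numpy()
    y = labels[train_mask].to_numpy()
    if len(np.unique(y)) < 2:
        forest = None  # rules-only cascade: nothing for the forest to separate
    else:
        forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
        forest.fit(x, y)
    return TriageCascade(
        rules=rules, forest=forest, feature_names=names, registry_hash=registry.hash(), seed=seed
    )


def classify_objects(
    features: pd.DataFrame, cascade: TriageCascade, sharpness: pd.Series | None = None
) -> pd.Series:
    """Final class per object; class counts always sum to the input count."""
    if features.empty:
        return pd.Series(dtype=object, name="class")
    out = apply_rules(features, cascade.rules, sharpness)
    survivors = out == "epithelial"
    if cascade.forest is not None and survivors.any():
        x = features.loc[survivors, cascade.feature_names].to_numpy()
        out.loc[survivors] = cascade.forest.predict(x)
    out.name = "class"
    return out


def reference_stats(features: pd.DataFrame, classes: pd.Series, min_count: int = 50) -> ReferenceStats:
    """Median / MAD of epithelial IOD for one slide."""
    iod = features.loc[classes == "epithelial", "iod"]
    med = float(iod.median()) if len(iod) else float("nan")
    mad = float((iod - med).abs().median()) if len(iod) else float("nan")
    return ReferenceStats(median_iod=med, mad_iod=mad, n_epithelial=len(iod), min_count=min_count)


#: Photometric features linear in OD (divide by the DNA-index factor) and
#: quadratic in OD (divide by its square).  Shape features are untouched.
OD_LINEAR = ("iod", "od_mean", "od_max")
OD_QUADRATIC = ("od_var",)


def normalize_features(
    cells: pd.DataFrame, ref: ReferenceStats, normalize_all_od: bool = True
) -> tuple[pd.DataFrame, float]:
    """Scale DNA-amount features by the slide's epithelial median IOD.

    ``iod`` becomes the DNA index (reference population centred at 1).  With
    ``normalize_all_od`` the other OD-linear intensity features are scaled by
    the same factor (squared for variance); morphology is never touched.
    Returns the normalized table and the factor used."""
    factor = ref.median_iod
    if not np.isfinite(factor) or factor <= 0:
        raise ValueError("invalid reference median IOD")
    out = cells.copy()
    out["iod"] = out["iod"] / factor
    if normalize_all_od:
        for col in OD_LINEAR[1:]:
            if col in out.columns:
                out[col] = out[col] / factor
        for col in OD_QUADRATIC:
            if col in out.columns:
                out[col] = out[col] / factor**2
    return out, factor


def save_cascade(cascade: TriageCascade, path: str | Path) -> None:
    import joblib

    path = Path(path)
    joblib.dump(cascade.forest, path.with_suffix(".joblib"))
    path.with_suffix(".json").write_text(json.dumps(cascade.metadata(), indent=1))
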