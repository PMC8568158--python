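"""Registry of quantitative nuclear phenotype (QNP) features.

The registry fixes the identity, order and parameterization of every feature
the pipeline computes, in the three families of Feulgen image cytometry:
nuclear morphology, photometric (DNA amount), and chromatin organization /
texture.  A hash of the registry travels with every feature table so that a
trained model can refuse feature sets it was not trained on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

REGISTRY_VERSION = "1"

MORPHOLOGY = "morphology"
PHOTOMETRIC = "photometric"
TEXTURE = "texture"


@dataclass(frozen=True)
class FeatureDef:
    name: str
    family: str
    group: str  # which extractor computes it
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class FeatureRegistry:
    features: tuple[FeatureDef, ...]
    version: str = REGISTRY_VERSION

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("duplicate feature names in registry")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def feature_count(self) -> int:
        return len(self.features)

    def family(self, name: str) -> str:
        for f in self.features:
            if f.name == name:
                return f.family
        raise KeyError(name)

    def names_in(self, family: str) -> list[str]:
        return [f.name for f in self.features if f.family == family]

    def hash(self) -> str:
        payload = json.dumps(
            [[f.name, f.family, f.group, f.params] for f in self.features] + [self.version],
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_DT_STATS = ("area_frac", "iod_frac", "n_blobs", "compactness", "dist")
_GLCM_STATS = ("entropy", "energy", "contrast", "homogeneity", "correlation")
_RL_STATS = ("sre", "lre", "gln", "rln", "rp")

#: Default parameters for the texture operators (all config-exposed).
DEFAULT_DT_THRESHOLDS = (0.75, 1.25)  # multiples of the object's mean OD
DEFAULT_QUANTIZATION = 16


def default_registry(
    dt_thresholds: tuple[float, float] = DEFAULT_DT_THRESHOLDS,
    quantization: int = DEFAULT_QUANTIZATION,
) -> FeatureRegistry:
    """The default QNP registry (46 features across the three families)."""
    feats: list[FeatureDef] = []

    for n in (
        "area_um2",
        "perimeter_um",
        "compactness",
        "eccentricity",
        "elongation",
        "solidity",
        "radius_mean_um",
        "radius_var_um2",
    ):
        feats.append(FeatureDef(n, MORPHOLOGY, "morphology"))
    for k in (2, 3, 4, 5):
        feats.append(FeatureDef(f"harmonic_{k}", MORPHOLOGY, "morphology", {"order": k}))

    for n in ("iod", "od_mean", "od_var", "od_skew", "od_kurt", "od_max"):
        feats.append(FeatureDef(n, PHOTOMETRIC, "photometric"))

    dt_params = {"thresholds": list(dt_thresholds)}
    for state in ("low", "med", "high"):
        for stat in _DT_STATS:
            feats.append(FeatureDef(f"dt_{state}_{stat}", TEXTURE, "discrete_texture", dt_params))
    q = {"Q": quantization}
    for stat in _GLCM_STATS:
        feats.append(FeatureDef(f"glcm_{stat}", TEXTURE, "cooccurrence", q))
    for stat in _RL_STATS:
        feats.append(FeatureDef(f"rl_{stat}", TEXTURE, "runlength", q))
    for n in ("fractal_dim", "com_displacement", "inner_iod_frac"):
        feats.append(FeatureDef(n, TEXTURE, "fractal_radial"))

    return FeatureRegistry(tuple(feats))
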