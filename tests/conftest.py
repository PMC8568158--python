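import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from nucrisk import CohortSpec, NodalRiskModel, generate_feature_cohort
from nucrisk.nrs import RFConfig


@pytest.fixture(scope="session")
def small_cohort():
    """Small strong-effect feature cohort shared across modelling tests."""
    spec = CohortSpec(seed=42, n_patients=16, rois_per_patient=(2, 2), cells_per_roi=(60, 60))
    cells, truth = generate_feature_cohort(spec)
    return spec, cells, truth


@pytest.fixture(scope="session")
def fitted_results(small_cohort):
    """One fitted nodal-risk model reused by modelling/aggregation tests."""
    _, cells, truth = small_cohort
    model = NodalRiskModel(
        cells=cells,
        patients=truth.patients,
        rf_config=RFConfig(n_trees_grid=(40,), mtry_grid=("sqrt",), seed=42),
    )
    return model.fit(seed=42)


@pytest.fixture(scope="session")
def roi_image_fixture():
    """One small synthetic Feulgen tile with truth, segmented and extracted."""
    from nucrisk import imaging
    from nucrisk.synthetic import PatientState, generate_roi_image

    spec = CohortSpec(
        seed=7, tile_shape=(512, 512), cells_per_roi=(45, 45),
        junk_rate=0.15, nonsquamous_rate=0.15,
    )
    state = PatientState("P000", "LN+", "G2", 7.0, heterogeneity=0.8)
    image, truth, truth_labels = generate_roi_image(spec, state, 0)
    bg = imaging.estimate_background(image)
    od = imaging.to_optical_density(image, bg, pixel_size=spec.pixel_size)
    labels = imaging.segment_nuclei(od)
    objects, log = imaging.extract_objects(od, labels, patient_id="P000", roi_id="P000_R0")
    return {
        "spec": spec, "image": image, "truth": truth, "truth_labels": truth_labels,
        "background": bg, "od": od, "labels": labels, "objects": objects, "log": log,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
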