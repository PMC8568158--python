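# nucrisk

Quantitative nuclear phenotypes and a per-cell **nodal risk score (NRS)** for
oral squamous cell carcinoma (OSCC).

Early-stage OSCC patients have roughly a one-in-four risk of occult nodal
disease, and the decision to perform an elective neck dissection is still
guided by subjective markers (grade, depth of invasion). `nucrisk`
implements an objective alternative based on Feulgen-thionin DNA image
cytometry: the per-pixel optical density OD = −log₁₀(I/I_bg) of a
Feulgen-stained section is proportional to local DNA amount, so each
segmented nucleus can be summarised by a quantitative nuclear phenotype
(QNP) vector — morphology, photometric (IOD = ΣOD ∝ DNA content, DNA index
= IOD/median reference IOD), and chromatin organization/texture (discrete
low/medium/high chromatin compartments, grey-level co-occurrence and
run-length statistics, fractal and radial organisation of the OD surface).

A random forest with **smallest-class balanced bootstraps** turns the QNP
vector of each epithelial cancer cell into an NRS ∈ [0, 1] — the fraction of
trees voting that the cell comes from a node-positive (LN+) tumor.  Scores
aggregate hierarchically:

* **cell → ROI**: median NRS per region of interest (~3×3 mm² tumor areas);
* **cell → patient**: percent of "positive" cells (NRS ≥ 0.5); a patient is
  high risk when this percentage exceeds a cutoff selected by ROC analysis
  (Youden's J = sensitivity + specificity − 1) on a patient-level training
  split, with an independent, lower cutoff for poorly differentiated (G3)
  tumors;
* **patient → outcome**: Kaplan–Meier / log-rank comparison of regional
  recurrence by predicted risk group, and a 2-year-landmark analysis of
  disease-specific survival by nodal status.

Because no per-cell data are publicly deposited for this problem, the
package ships a first-class synthetic-cohort generator (`nucrisk.synthetic`)
that draws Feulgen-like tiles (elliptical nuclei with exact IOD ground
truth, junk and lymphocyte-like objects) and/or per-cell feature tables with
a controllable LN+ vs LN0 effect size, intratumor heterogeneity, patient
random effects and survival times, so every stage is testable against known
ground truth.

## Worked example

```python
from nucrisk import CohortSpec, NodalRiskModel
from nucrisk.nrs import RFConfig

res = NodalRiskModel.from_synthetic(
    CohortSpec(seed=17),                      # 30 patients, 3 ROIs, ~300 cells/ROI
    rf_config=RFConfig(n_trees_grid=(100,), mtry_grid=("sqrt",), seed=17),
).fit(seed=17)
print(res.summary())
```

prints

```
Nodal Risk Score results
========================================
cells scored:            24300
forest: 100 trees, mtry=6, OOB error 0.052
cell AUC (train):        100.0%
cell AUC (test):         96.0%
ROI median-NRS AUC:      100.0%
patient %positive AUC:   100.0% (train)
chosen patient cutoff:   97.3% positive cells
  train sens/spec:       100.0% / 100.0%
  test accuracy:         100.0%
G3 pathway (cutoff 25%): accuracy 100.0%
```

The cohort here carries a planted 2-pooled-SD shift on five DNA/texture
features in 90% of LN+ cells, so near-ceiling recovery is the expected
outcome; the held-out cell AUC (96.0%) sits just below the mixture ceiling
of 95% + tree-ensemble variance.  The chosen cutoff is the percent-positive
threshold maximising Youden's J among training patients; test-set accuracy
uses that frozen cutoff.  With the effect set to zero the same pipeline
returns chance-level AUCs (see `tests/test_acceptance.py`).

The staged pipeline (TIFF tiles → OD → segmentation → QNP → triage →
scoring → risk calls → survival) is available as a CLI:

```bash
nucrisk all --seed 6 --outdir run1            # synthetic feature-table route
nucrisk simulate --config img.yaml --outdir run2   # image route, then
nucrisk segment --config img.yaml --outdir run2    # segment/features/triage/...
```

Fixed seeds give byte-identical CSV artifacts.

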