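# Methods

## Problem and model

The package estimates, per patient, the risk of nodal disease in oral
squamous cell carcinoma from the nuclear phenotypes of tumor cells in the
primary lesion.  The underlying biological premise is that of malignancy-
associated changes in DNA cytometry: tumors that have acquired metastatic
competence show measurably different nuclear DNA amount and chromatin
organisation, tumor-wide, so a classifier trained on cells from
node-positive (LN+) vs node-negative (LN0) tumors can score individual
cells, and per-patient summaries of those scores can classify patients.

The pipeline has four stages.

1. **Optical density and segmentation** (`nucrisk.imaging`).  Feulgen-
   thionin staining is stoichiometric for DNA, so OD = −log₁₀(I/I_bg) per
   pixel is proportional to local DNA.  The background (white) level I_bg is
   estimated as the mode of the upper intensity quartile of the tile.  OD is
   clipped to [0, od_max], od_max = 3 (an 8-bit image cannot encode more
   than −log₁₀(1/255) ≈ 2.4 decades).  Nuclei are segmented by smoothing
   (σ = 1 px), thresholding OD, filling holes, and splitting touching
   objects with a distance-transform watershed.  The default threshold 0.25
   is half the diploid mean OD of the synthetic nuclei: thresholding a
   blurred object profile at half maximum recovers the true boundary with
   minimal area bias (measured ≤ 3% on synthetic truth).  The original
   study's in-house segmenter is not publicly described; this is a standard,
   deterministic replacement and its parameters are config values, not
   reproductions.

2. **Quantitative nuclear phenotypes** (`nucrisk.qnp`, `nucrisk.registry`).
   A fixed registry of 46 features in three families:
   * *morphology* — area (μm²), perimeter (Douglas–Peucker-simplified
     contour arc length, which removes rasterisation staircase bias),
     compactness 4πA/P², eccentricity, elongation, solidity, boundary radius
     mean/variance, low-order Fourier boundary harmonics 2–5;
   * *photometric* — IOD, mean/variance/skewness/kurtosis/max of OD;
   * *chromatin texture* — discrete low/med/high chromatin compartments at
     (0.75, 1.25)× the object's mean OD (per state: area and IOD fractions,
     blob count/compactness, radial position); grey-level co-occurrence
     statistics (entropy, energy, contrast, homogeneity, correlation) on the
     Q = 16-level quantized OD under the mask, axial unit offsets, symmetric;
     run-length statistics (SRE, LRE, GLN, RLN, RP) over 4 directions;
     differential box-counting fractal dimension of the OD surface (boxes
     weighted by in-mask fraction so a flat surface gives exactly 2), OD
     centre-of-mass displacement, inner-disk IOD fraction.

   The reference study used 93 phenotypes whose identities are not publicly
   available; this registry is an honest, documented implementation
   of the three named families rather than a reconstruction of that list,
   and the registry hash travels with every feature table and model so that
   mismatched feature sets are refused at scoring time.  Texture operators
   are computed under the nuclear mask only (pairs/runs crossing the
   boundary are discarded), which is why they are implemented here rather
   than with rectangular-image texture routines; each is verified against a
   brute-force enumeration oracle in the tests.  Features that cannot be
   computed on very small objects (fractal family, < 16 px extent) are
   flagged and imputed from the per-slide epithelial median before
   modelling.

3. **Triage and normalization** (`nucrisk.triage`).  Segmented objects are
   classified epithelial / non-squamous / junk by hard rules (area outside
   [6, 400] μm², solidity < 0.85, or boundary-band OD gradient below 0.10 ⇒
   junk) followed by a random-forest stage separating epithelial from
   small dense non-squamous nuclei.  The area floor sits below lymphocyte-
   sized nuclei so they reach the learned stage; the sharpness threshold
   sits between the defocused-junk (~0.08) and in-focus (>0.13) gradient
   modes of the synthetic populations.  Only epithelial cells proceed.
   Photometric features are then normalized by the slide's epithelial
   population: IOD divided by the epithelial median IOD gives the DNA index
   (reference population at 1); other OD-linear features are scaled by the
   same factor (variance by its square), so the normalized features are
   invariant to slide-level staining intensity.  Morphology is never
   rescaled.  Whether the original study normalized all features or only
   photometric ones is not stated; this package normalizes OD-derived
   features only and exposes `normalize_all_od` as a switch.  Normalization
   refuses slides with fewer than 50 epithelial cells.

4. **Nodal risk score and aggregation** (`nucrisk.nrs`, `nucrisk.riskagg`,
   `nucrisk.model`).  Cells from G1/G2 tumors are split 80/20 (train size =
   ⌊0.8n⌋; the split is at cell level by default, patient-grouped mode is
   available — see *Leakage* below).  The forest draws, for every tree, a
   bootstrap of equal size from each LN class (= the smallest class size),
   addressing the strong class imbalance; NRS is the fraction of trees
   voting LN+, so NRS × n_trees is an integer.  Tree count and mtry are
   tuned by stratified 5-fold cross-validated AUC over the grids
   n_trees ∈ {100, 250, 500} and mtry ∈ {√p, p/3, p/5} (single-point grids
   skip the CV pass); out-of-bag error is recorded on the refit model.
   Aggregation: median NRS per ROI; percent of cells with NRS ≥ 0.5 per
   patient.  The patient cutoff is chosen on an 80/20 patient split
   stratified by LN status (each stratum keeps ≥ 1 training patient) as the
   percent-positive threshold maximising Youden's J, ties broken toward
   higher specificity; test patients are evaluated only at the frozen
   training cutoff.  Patient comparator is strict `>` by default (`>=`
   configurable); cell positivity uses `>=` 0.5.  G3 tumors never enter
   training; they are scored by the same forest and classified with an
   independent percent-positive cutoff (default 25%).

5. **Outcomes** (`nucrisk.outcomes`).  Descriptive tables use Pearson
   chi-square *without* continuity correction for categorical variables and
   the Wilcoxon rank-sum test for continuous ones — the convention was
   reverse-engineered by checking that it reproduces all eight recomputable
   printed p-values of the reference cohort table to two decimals (with
   Yates' correction they do not reproduce).  Survival uses the Kaplan–Meier
   product-limit estimator and the log-rank test (via lifelines).  Because
   nodal status is not fixed at surgery, disease-specific survival between
   nodal groups is compared with a 2-year landmark: only patients with
   observation time ≥ 2 years enter, the time origin remains surgery, group
   labels are frozen at the landmark.  Regional-recurrence-free comparison
   between *predicted* risk groups (fixed at surgery) uses no landmark and
   is reported per partition (train/test).

## Synthetic cohorts

`nucrisk.synthetic` emulates the study conditions at desk scale: 30
patients (LN+ prevalence 19/35), 3 ROIs per patient, 300 cells per ROI
(~27k cells; the clinical cohort had 561 ROIs and >468k cells — a ~1/15
scale with the same shape).  Grade and depth-of-invasion distributions are
shaped on the reference cohort (G3 enriched among LN+; DOI ~N(9.8, 6.9) mm
for LN+, N(4.9, 2.8) for LN0).

* **Feature route** — per-cell vectors from class-conditional multivariate
  normals over the registry names: baseline N(0, 1) per feature, a patient-
  level random intercept (SD 0.25) shared by all of a patient's cells, and
  within LN+ tumors a *heterogeneity* fraction of cells receives the mean
  shift (default: 2 pooled SD on five DNA/texture features).  Heterogeneity
  defaults to 0.9: a cell-level classifier's AUC ceiling under this mixture
  is h + (1−h)/2, and 0.9 keeps LN+ tumors genuinely mixed while matching
  the ~0.9+ cell-AUC scale that tumor-wide nuclear-phenotype effects show in
  practice.
* **Image route** — 8-bit tiles with a white level of 235: nuclei are
  harmonic-perturbed ellipses (radius 3–4.5 μm at 0.25 μm/px) whose OD patch
  is correlated noise rescaled so the integrated OD equals the target
  exactly, making photometric ground truth exact by construction; LN+-like
  cells draw from IOD (+50%) and texture-contrast shifted distributions.
  Junk objects are defocused Gaussian blobs (below the sharpness rule
  threshold, by design, so the triage rules have learnable signal);
  non-squamous objects are small round high-OD lymphocyte-like nuclei.
  Placement is non-overlapping with bounded retries; shortfalls on crowded
  tiles are reported in the truth table, never silent.
* **Survival** — exponential event times per nodal arm with administrative
  censoring (defaults: regional recurrence hazard 0.35/yr for LN+, 0.02/yr
  for LN0; disease-specific death 0.15/yr vs 0, matching "all
  disease-specific deaths among LN+"; censoring at 5 years).

What the generator does **not** emulate: tissue architecture, touching-cell
clusters at realistic density, staining gradients within a slide,
section-thickness artefacts, or any real covariance structure among the 46
features.  Passing recovery tests therefore demonstrates that the pipeline
is correct and calibrated — not that the clinical AUCs would reproduce on
real slides.  The real cohort's per-cell data are not deposited, so its
headline AUCs (99.6/90.7 cell, 95.1 ROI, 97.7 patient) are out of scope as
targets; only the printed descriptive statistics and operating-point
arithmetic are recomputable, and the acceptance script recomputes exactly
those.

## Leakage note

The original modelling design splits at the *cell* level, so cells of the
same patient appear in both partitions.  With patient-level random effects
present, a forest can partly memorise patient identity: on effect-free data
the cell-level split yields held-out AUC above 0.5 while the patient-grouped
split stays at chance.  The package implements both modes, defaults to the
original cell-level design for fidelity, and asserts the leakage
differential as a test property; all chance-level calibration checks use the
grouped split.

## Numerical choices

* Even-count medians are the mean of the two middle values (numpy/pandas
  convention).
* ROC thresholds are the observed values, positive prediction at value ≥
  threshold; AUC equals the Mann–Whitney statistic with ties at half credit.
* Youden-tie break prefers the larger threshold (higher specificity).
* Perimeter via Douglas–Peucker simplification at 1 px tolerance; disk
  compactness ≈ 0.99, square ≈ 0.80 (isoperimetric values 1 and π/4).
* Degenerate inputs: empty chromatin states contribute zeros; zero-variance
  patches have skewness/kurtosis/correlation defined as 0; single-pixel
  objects are errors for texture operators; all-junk or single-class inputs
  raise with actionable messages.
* Seeds: every stochastic component takes an explicit seed; child streams
  derive from `SeedSequence((seed, stage, ...))`, so image tiles are
  reproducible independently of generation order.

## Known limitations

* The 46-feature registry is a family-faithful stand-in, not the original
  93-feature list (unpublished); absolute feature values are not comparable
  to the original system's.
* Desk-scale problem sizes throughout (documented per test); forest training
  is single-threaded and the balanced-bootstrap forest is plain Python over
  sklearn trees, adequate to ~10⁵ cells.
* The G1+G2 printed cell counts of the reference study (36,156 + 337,127)
  do not sum to its stated 384,041 total; the partition counts do.  The
  discrepancy is inherited from the source and flagged here, not resolved.
* The landmark DSS comparison of the reference cohort (p = 0.15) is not
  reproducible anywhere because per-patient times are not deposited; the
  machinery is exercised on synthetic survival data instead.
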