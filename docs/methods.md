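# Methods

This note documents the models, the phantom-data generator, the numerical
choices and the known limitations of `dosemap-ntcp`.

## The modelling problem

The endpoint is binary mandibular osteoradionecrosis (ORN) after
head-and-neck radiotherapy. Two model families predict per-subject ORN
probability from the planned dose to the mandible:

1. **DVH + clinical logistic regression** — the field's standard baseline:
   a panel of dose-volume histogram metrics (D2%, D5%–D95% in steps of 5,
   D98%; V5–V70 Gy in steps of 5) plus six clinical covariates (age, gender,
   smoking, pre-RT dental extractions, post-operative RT, chemotherapy),
   reduced by a Spearman correlation filter and selected stepwise.
2. **3D convolutional classifiers** on the masked dose map itself — a
   dose-only DenseNet-40 and a joint-fusion variant that concatenates the
   image features with the six covariates and trains end to end — retaining
   the spatial dose information the DVH discards.

Cohorts are class-balanced case–control sets matched on primary tumour site
and treatment year, so the raw predicted probabilities are not population
ORN risks; they support discrimination and within-design calibration
analysis only.

## Dose-map preprocessing

Fixed order: **mask → EQD2 → crop/resample → normalise → (augment)**.

- *Masking* zeroes everything outside the mandible contour and leaves
  in-mask voxels bit-identical.
- *EQD2* converts physical dose to the equivalent dose in 2-Gy fractions
  under the linear-quadratic model with α/β = 3 Gy (late effects):
  `EQD2 = D·(d + α/β)/(2 + α/β)` with per-voxel fraction dose
  `d = D/n_fx`, i.e. uniform fractionation per voxel using the subject's
  planned fraction count. The conversion is the identity exactly at
  2 Gy/fraction, amplifies hotter fractionation and shrinks colder.
- *Crop/resample*: crop to the mask bounding box plus a margin (default 2
  voxels); crops smaller than the target network shape are zero-padded and
  centred without interpolation, larger crops are resampled (linear for
  dose, nearest-neighbour for the mask). The network input shape is
  configurable; desk-scale runs use 8³–16³, and nothing in the architecture
  ties it to a specific size beyond divisibility by 4 (two 2× poolings).
- *Normalisation* is global min–max to [0, 1], fitted once on the
  development cohort and persisted; external cohorts are transformed with
  the development statistics and clipped. (Fitting across both cohorts is
  supported but not the default, since external data must not influence the
  deployed transform.)
- *Augmentation* (training subjects only): per-axis rotations drawn from
  ±0.1 rad and isotropic zoom from [0.8, 1.2], linear interpolation,
  output clipped back to [0, 1].

The order matters: EQD2 is nonlinear in dose, so swapping it with
normalisation changes the result — an integration test asserts the fixed
order.

## DVH conventions

Dx% is the *minimum dose to the hottest x% of the structure volume*,
computed on the sorted voxel array with `k = ceil(x/100·n)` (no
interpolation by default; a linear-quantile mode is available). VxGy uses
the ≥ convention (equality counts) and is relative volume in percent.
Metrics are computed on EQD2 dose in Gy; the [0, 1] normalisation is a
network-input step only. Curve bin width defaults to 0.1 Gy; all panel
metrics bypass the curve and are exact against a full-sort oracle.

## Logistic baseline

- *Pre-filter*: for every feature pair with |Spearman ρ| > 0.8 the member
  with the smaller absolute rank association with the outcome is dropped
  (earlier column wins without labels). Constant columns are dropped with a
  warning; missing values are rejected outright (no imputation anywhere).
  Filtering is idempotent.
- *Selection*: greedy forward steps; a candidate enters while the AIC
  improves (a likelihood-ratio entry test with configurable p is the
  alternative). Features are standardised internally for stable optimisation
  and coefficients reported on the original scale, which leaves a
  likelihood-based criterion invariant to feature scaling.
- *Separation*: fits whose standardised coefficients exceed 15 in magnitude
  (the MLE running to infinity) are flagged and refit with a small L2
  penalty so reported coefficients stay finite.

## DenseNet-40 classifiers

Trunk: initial 3×3×3 convolution (64 channels), three dense blocks of 12
layers (each BN → ReLU → 3×3×3 conv of growth 32 → dropout, concatenated to
its input), two transitions (BN → ReLU → 1×1×1 conv halving channels →
2×2×2 average pool), final BN/ReLU and global average pooling. Channel
arithmetic: 64 + 384 = 448 → 224; + 384 = 608 → 304; + 384 = **688**.
The dose-only head is a single fully connected layer to 2 softmax classes;
the joint-fusion head concatenates the 6 covariates (binaries as {0, 1},
age min–max scaled on the training set) into a 694-long vector, then a
64-unit hidden layer and the 2-class output. The growth rate, initial
width and compression are the standard DenseNet constants that reproduce
the 688/694 dimensions; the published description names the architecture
family and these dimensions without printing the internal constants.

The engine is a self-contained NumPy implementation: convolution as a sum
of kernel-offset channel-mixing matrix products (BLAS-backed einsums),
explicit backward passes (verified against finite differences), inverted
dropout, batch-norm with running statistics, Adam with coupled L2 weight
decay, categorical cross-entropy. All randomness — initialisation,
shuffling, dropout, augmentation — derives from explicit seeds, so repeated
runs reproduce loss histories exactly on fixed hardware.

The published hyperparameter search grid (dropout {0.6, 0.8}; learning rate
{0.01, 0.001, 0.0001}; batch size {10, 16}; weight decay {0.01, 0.001,
0.0001}; epochs {50, 100, 300}) enumerates 108 combinations. The
weight-decay value printed as "0001" in the source description is read as
0.0001. The inner-CV selection metric is validation AUROC (not stated in
the source; AUROC is the study's primary discrimination measure). Grid ties
break to the first point in enumeration order.

**Desk-scale profile.** Full-width training is not practical on a single
CPU, and none of the package's verifiable claims need it. Training tests
and examples therefore use a narrow trunk (initial 8, growth 4, 3×2 layers)
at 12³ input — chosen as the smallest configuration that reliably recovers
a strongly-planted dose–toxicity signal (validation AUROC > 0.8 at n = 200
within ~25 epochs) — while structural checks (feature dimensions, parameter
counts, softmax contracts) instantiate the full-width architecture.

## Phantom cohorts and the planted truth

The generator emulates the *structure* of a matched ORN case–control
cohort, not mandibular anatomy:

- **Geometry**: a half-torus "horseshoe" (default radius 20 mm, thickness
  5 mm, per-subject jitter ±10%/±15%) on a 32³ grid at 2 mm spacing —
  the minimal shape with a realistic near-target/far-from-target gradient.
- **Dose**: a low-dose bath (6 Gy) plus prescription-scaled anisotropic
  Gaussian lobes (width ≈ 14 mm) centred lateral to the anterior arch; a
  per-subject target-to-mandible proximity term (0–14 mm) spreads the
  in-mask DVHs across the V5–V70 Gy range. Prescriptions are drawn from
  50–70 Gy in {20, 30, 33, 35} fractions, the clinically used range.
- **Covariates**: Bernoulli draws at the development-cohort prevalences
  (male 75%, smoking 37%, extractions 57%, PORT 38%, chemotherapy 63%;
  site mix ≈ 30/57/3/10% oral cavity/oropharynx/larynx/other, years
  2011–2022, age ≈ N(61, 10)). An external profile (smoking 60%,
  extractions 78%, chemotherapy 27%, years 2007–2015) emulates the
  domain shift between a UK and a Danish cohort.
- **Labels**: Bernoulli draws from the planted logistic NTCP on D30% of
  the masked physical dose plus covariate effects (defaults β₀ = −5.5,
  β_dose = 0.10 per Gy, extractions +0.7, smoking +0.4 — a D30%-plus-
  extractions structure mirroring the classic mandible NTCP literature,
  with magnitudes giving a ~30% population ORN rate and a planted AUROC
  near 0.7, i.e. the realistic-difficulty regime).
- **Matching** is exact on (site, year), ties broken by smallest subject
  id; unmatched cases are dropped and counted. Matching tolerance on year
  is configurable in principle but exact by default, since no published
  tolerance exists.

What passing tests on phantoms do **not** show: performance on real
patients. The phantom has no CT anatomy, no teeth/condyles, no
mandibulectomy geometry, no TPS-specific dose texture, and its planted
truth is exactly logistic — so parameter-recovery and leakage results
transfer, headline AUROCs do not.

## Validation design

Stratified nested 5-fold CV (inner j = 5 by default; the source does not
state j): inner folds, built only from each outer training set, drive the
hyperparameter search; the winner is refit on the full outer training set
and scored on the untouched outer test fold. Predictions are pooled across
outer folds for the internal ROC/calibration (per-fold metrics are also
available). The driver records every subject index touched during the
inner search and raises if it intersects the outer test set. External
validation applies frozen models — by default the average of the five
outer-fold models, alternatively a single full-cohort refit — with no
parameter updates; external maps are normalised with the development
statistics and clipped.

## Evaluation statistics

- AUROC by the rank (Mann-Whitney) statistic; 95% CI from the DeLong
  placement-value variance; paired model comparison by the two-sided DeLong
  test. Coverage is verified by simulation (≥ 93% at n = 184).
- Brier score and log loss (probabilities clipped at 1e−15 so confident
  errors stay finite). Threshold metrics at 0.5, ties classified positive.
- Calibration curves: 10 equal-width bins on [0, 1] by default, empty bins
  omitted; quantile binning optional.
- Cohort comparison: Mann-Whitney U (asymptotic, tie-corrected) for
  continuous variables, chi-squared with Yates correction for 2×2 tables,
  Cohen's d with the pooled n−1 SD (continuous) or the pooled Bernoulli SD
  `sqrt((p₁(1−p₁)+p₂(1−p₂))/2)` (binary), sign positive when the ORN+
  group is higher. The binary formula reproduces the published effect-size
  cells that are arithmetically consistent with their printed counts; cells
  that are not reproducible from printed counts under any standard pooled-SD
  convention are not asserted. No multiple-testing correction is applied
  (raw p-values at α = 0.05), and reports say so.

## Numerical and degenerate-input choices

- Min–max normalisation refuses constant cohorts (degenerate range);
  out-of-range values under reused statistics clip to [0, 1].
- Empty masks raise immediately (empty-structure error); a horseshoe that
  misses the grid raises at generation time with a remediation hint.
- DVH curve comparisons use a 1e−9 tolerance at bin edges so doses landing
  exactly on an edge count as covered.
- AvgPool requires even spatial dims; the network reports the minimal
  valid input shape ((4,4,4) for two poolings) on incompatible input.
- Cohen's d for two equal proportions is exactly 0.0 even when both
  variances vanish; identical all-tied samples get Mann-Whitney p = 1.

## Limitations

- No DICOM-RT parsing: volumes are consumed as NIfTI on a common grid.
- Only joint fusion is implemented (no early/late fusion variants), no
  recalibration (Platt/isotonic) on external data, no severity-graded
  endpoints, no saliency/interpretability tooling.
- The NumPy engine targets CPU determinism and desk-scale problems, not
  throughput; full-resolution multi-hundred-epoch training is out of scope.
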