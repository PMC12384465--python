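# Methods

## Problem and model

After thoracic radiotherapy (RT), the pericardium remodels: effusion,
hemorrhagic fluid, fibrous thickening and, rarely, calcification change the
CT attenuation (Hounsfield units, HU) of pericardial tissue in
characteristic ways. `peridose` quantifies this remodeling from a pair of
co-registered CT volumes per patient — a baseline planning scan and a
follow-up scan about six months later — together with a heart mask and a
3-D dose distribution.

The pericardial sac is modeled as the **outermost 4 mm layer of the heart
mask**. This is an operational definition: the true sac is often thinner
than 4 mm, so the shell deliberately includes some adjacent myocardium
(which occupies the same HU range as fibrous tissue; see Limitations).
The shell is computed with a Euclidean distance transform of the mask in
physical millimetres (anisotropic spacing respected): a voxel belongs to
the shell when it is inside the mask and its distance to the nearest
background voxel center is at most the shell thickness. This
center-to-center convention is the standard erosion-by-a-metric-ball
construction; it slightly biases the shell thin (about −2% volume on a
20 mm sphere at 0.5 mm spacing, about −5% at 1 mm spacing), has an exactly
empty shell at zero thickness, and is monotone in thickness.

### Tissue scheme

Integer HU values partition into five composition labels:

| label | HU range | reading |
|---|---|---|
| Calcification | ≥ 130 | calcified/constrictive tissue, malignancy |
| Fibrous | 65 … 129 | fibrosis, constrictive tissue, adjacent myocardium |
| Heme | 13 … 64 | normal/thickened pericardium, hemopericardium |
| Fluid | −5 … 12 | effusion, normal fluid |
| Fat | ≤ −6 | fatty tissue |

The intervals are disjoint and cover [−1000, 1000]; HU is clipped to this
range at ingest and rounded half-away-from-zero before labeling, so every
shell voxel has exactly one label at each timepoint.

### Biomarkers

With ΔHU = HU_baseline − HU_followup per shell voxel v of volume V_v:

1. **ΔHUV** (volume per HU change): for each integer ΔHU value,
   `100 · Σ_{v: ΔHU_v = ΔHU} V_v / Σ_v V_v`. Sums to 100 per patient by
   construction. Curves are averaged unweighted across patients within
   mean-pericardium-dose bins. The scalar used for dose-response testing
   is the curve mean, `Σ ΔHU · ΔHUV(ΔHU) / 100`.
2. **VMC** (voxel-based mass change) per tissue label T and voxel-dose
   bin D: `100 · Σ_{v∈D,T} ΔHU_v V_v / Σ_v (HU_baseline_v + 1000) V_v`.
   Mass is proxied linearly by (HU + 1000)·volume — the water-air offset
   implied by the denominator — with no physical density calibration.
   The denominator runs over **all** shell voxels (total baseline
   pericardial mass), not the cell's own voxels, so cells are comparable
   and sum meaningfully. Positive VMC = mass decrease. Tissue assignment
   defaults to the follow-up HU (where the voxel ended up); baseline
   labeling is available via `label_timepoint`.
3. **ΔV** (tissue volume change): per label,
   `100 · (V_baseline-labeled − V_followup-labeled) / Σ_v V_v`. Because
   labels partition the shell at both timepoints, the five values sum to
   zero exactly; positive = volume loss in that range.

### Dose

Physical dose is converted voxelwise to the equivalent dose in 2 Gy
fractions, `EQD2 = D (d + α/β) / (2 + α/β)`, before any binning, using the
grid's per-fraction map (default: physical dose / number of fractions).
α/β defaults to 3 Gy, the usual late-cardiac-effects value; it is
configurable because the choice is conventional, not measured. Mean-dose
bins are [0, 0.2), [0.2, 2), [2, 5), [5, 12.5), [12.5, 20), ≥20 Gy; the
same edges are reused per voxel for the VMC dose axis.

### Follow-up selection

When several follow-up reconstructions exist, the one whose HU
distribution best matches baseline in an out-of-field region is used: the
region is the part of a 50 mm ring around the heart that received ≤ 1 Gy
physical dose, the distribution is the 2001-bin (1 HU) normalized
histogram, and the distance is L1 (configurable to L2 or absolute
mean-HU difference). Ties break to the lowest candidate index. Center-of-
mass alignment (`com_align`, whole-voxel shifts, −1000 HU padding) is
provided as the registration initialization step only; deformable
registration is assumed done upstream.

### Harmonization

Contrast enhancement shifts perfused-tissue HU, so images form batches:
two batches (CE / non-CE) for baseline-only features, four batches for
longitudinal pair features (both non-CE; both CE; baseline-only CE;
follow-up-only CE). Harmonization is the classic ComBat location/scale
model: standardize each feature to its pooled (batch-size-weighted) mean
and pooled residual variance, estimate per-batch additive and
multiplicative effects, optionally shrink them toward per-batch parametric
priors (normal for location, inverse-gamma for scale, hyperparameters by
method of moments, iterated conditional updates to < 1e−6 or 500
iterations), remove, and restore the pooled location/scale.

Numerical choices that differ from textbook descriptions, and why:

- Per-batch scale estimates use the population (ddof = 0) variance,
  consistent with the pooled /n variance, which makes the non-EB
  transform **exactly idempotent**; `sva::ComBat` uses ddof = 1 and is
  idempotent only to O(1/n). Agreement with `sva::ComBat` on a planted
  two-batch matrix is < 0.3 HU against a 30 HU effect (tested).
- The per-feature grand mean is restored exactly after adjustment; raw
  EB shrinkage otherwise leaves residual grand-mean shifts of order the
  shrinkage times the batch imbalance.
- Features with pooled variance < 1e−12 (e.g. empty histogram bins)
  bypass harmonization and are returned bit-identical.
- No covariates are protected during harmonization (dose is not in the
  design); the batch model is contrast only, scanner tags are carried
  but unused by default.

What EB shrinkage can and cannot do: after EB harmonization the
between-batch **mean** gap is < 2 HU and the overall variance mismatch is
removed, but per-feature variance ratios retain shrinkage noise of order
√(2/n) (≈ ±25% at n = 50/batch). This is inherent to the estimator — the
Bioconductor reference behaves identically — so per-feature variance
equality should only be expected from the non-EB exact mode.

The pipeline harmonizes pair-level biomarker feature vectors (per-tissue
ΔV and VMC totals plus the ΔHUV mean) across the four batches; baseline
histogram harmonization (two batches) is available as a diagnostic. Which
feature set the harmonization should target for longitudinal analyses is
genuinely open; biomarker-level is the default because it matches the
statistics actually computed downstream, and the choice sits in config
(`harmonize_target`).

### Statistics

- Spearman rank correlation (average ranks on ties): exact two-sided
  permutation p for n < 10, t-approximation otherwise. Pearson r with the
  usual n−2 df t test.
- Kaplan–Meier product-limit curves and the two-sample log-rank test go
  through `lifelines`.
- The univariable hazard ratio is a Cox partial-likelihood fit on the
  binary group indicator with **Breslow** tie handling, Newton–Raphson to
  |Δ log-lik| < 1e−8, Wald 95% CI on the log scale. It is hand-implemented
  (lifelines only offers Efron ties) and cross-checked against lifelines
  on tie-free data. Monotone likelihoods (a group with no events, or
  quasi-separation) yield a flagged non-estimable result, never ±∞.
- Cohorts are split at the cohort mean of a covariate; values exactly at
  the mean go to the "≤ mean" group. Survival clock starts at RT end.
  Events on the RT end day itself count as pre-RT (strict inequality);
  the boundary convention is a choice, flagged here because registries
  do not state one.
- CVD events are ICD-10 categories I20–I25 and I50, matched by
  3-character category prefix (so I50.9 counts); events ≤ 28 days after
  the most recently kept event are collapsed onto that first entry
  (greedy scan anchored at kept events).
- No multiple-testing correction is applied by default (per-panel
  reporting); a Benjamini–Hochberg helper can be bolted on by the caller
  via `statsmodels` if desired.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not CT physics:

- 48³ grid at 2 mm spacing; ellipsoidal heart (semi-axes 26/24/22 mm),
  lung-like background at −800 HU, blood pool at 45 HU.
- Shell composition prior: Fat 0.35, Fluid 0.20, Heme 0.25, Fibrous 0.18,
  Calcification 0.02; HU uniform within the class interval plus N(0, 3 HU)
  texture.
- Dose: point source placed 5–75 mm outside the heart surface with
  isotropic exponential falloff (12 mm length); fraction schedules drawn
  from {33×2, 3×22.3, 5×10, 8×7, 30×1.5} Gy. Varying source distance and
  schedule spreads mean pericardial EQD2 across all six dose bins.
- Planted effect: each shell voxel moves one step up the
  Fluid→Heme→Fibrous→Calcification ladder at follow-up with probability
  min(1, β·EQD2/100); β defaults to 0.5. Single-step moves keep the
  planted effect identifiable; Fat never shifts (weight-change
  confounding makes fat uninformative).
- Batch effects: +25 HU (configurable, optionally multiplicative) inside
  the heart when a scan is contrast-enhanced (P = 0.7 per scan,
  independently at each timepoint). The offset is restricted to perfused
  tissue; out-of-field background is unaffected, which is what makes the
  low-dose ring usable for kernel matching, as with real contrast.
- Three follow-up candidates with additive kernel noise σ ∈ {5, 20, 40} HU
  in shuffled order; the σ = 5 candidate is the "matched kernel" recorded
  in the truth table.
- Outcomes: exponential survival with log-hazard offset 0.7 (≈ HR 2) for
  the above-median-dose group; a Poisson ICD-10 CVD event stream with a
  3× rate multiplier for that group; administrative censoring at 1500
  days.

All randomness flows from one master seed through spawned per-patient
substreams; the same seed reproduces the cohort bit-for-bit.

What the generator does **not** emulate: scanner physics and
reconstruction artifacts, anatomy (no chambers, vessels or lungs),
respiratory/cardiac motion, registration error (volumes are generated
aligned), weight-driven fat change, and non-proportional hazards. Passing
tests therefore demonstrate that the estimators recover what they define
on data satisfying their assumptions — not that those assumptions hold in
clinical images.

## Problem sizes and numerical choices

Test and acceptance workloads run at desk scale by design: toy patients of
a few hundred voxels for oracle equivalence (brute-force loops stay
exact), cohorts of 20–60 patients on 48³ grids for recovery and
determinism checks, 20 replicate cohorts for the dose-response power
property, and 200 replicates for log-rank calibration. Smoothing uses a
centered 11-bin moving average with shrinking edge windows (the window is
a heuristic; results are reported raw and smoothed). ΔHU is computed on
integer-rounded HU (half away from zero). Degenerate inputs fail loudly:
empty masks, all-air shells (zero mass denominator), constant covariates,
zero-event survival data and singleton batches all raise validation
errors rather than returning silent zeros.

## Known limitations

- The 4 mm shell mixes pericardium with myocardium and epicardial fat;
  per-compartment attribution is out of scope.
- The mass proxy is linear in HU; no calibration to physical density.
- Harmonization assumes batch effects are location/scale per feature;
  nonlinear contrast effects (e.g. saturation) are not modeled.
- The per-voxel dose bins reuse the mean-dose edges; no claim that these
  are optimal per-voxel strata.
- Survival analyses are univariable by construction; confounding between
  dose, stage and fractionation is not addressed.
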