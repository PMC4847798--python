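# Methods

## Geometry on voxel masks

All image-derived features operate on `MaskVolume` objects: 3-D integer
arrays with a 4×4 affine mapping 0-based voxel indices to world millimetres
(RAS). Masks are treated as sets of voxel *centers*; no sub-voxel surface is
reconstructed. The consequences:

* **Volume** is foreground count × |det(affine[:3,:3])| / 1000 (cm³) — exact.
* **Centroid** is the arithmetic mean of foreground voxel-center world
  coordinates; it may fall outside a non-convex mask, and may fall inside a
  ventricle voxel, in which case CS is defined as 0 and the case is flagged
  (`centroid_in_ventricle`).
* **TS** (tumor edge → ventricle) and **CS** (tumor centroid → ventricle
  edge) are minimum Euclidean distances over voxel centers, computed with a
  KD-tree over the ventricle's world coordinates. This is exact for any
  affine (including anisotropic and oblique grids), and because the minimum
  pairwise distance between two point sets is attained on their boundaries,
  minimising over full foreground sets equals minimising over edges — no
  boundary extraction needed. Agreement with the O(n·m) all-pairs oracle is
  asserted to 1e-6 mm in the tests.
* **Contact** (SVZ involvement) is non-empty overlap of the two masks, so
  contact ⇔ TS = 0 holds by construction and is property-tested.

### Ventricular subregions

The ventricular margin is divided into frontal horn (1), body (2),
occipital horn (3) and temporal horn (4). When an anatomical labeling
exists it is passed through unchanged (`prelabeled` mode — the fidelity
path). Otherwise a heuristic cuts the ventricle along the anterior–
posterior world axis at two fractional planes of its AP extent (defaults
1/3 and 2/3, anterior→posterior) and relabels as temporal horn any
connected component whose centroid lies below a configurable axial
percentile (default the 25th) of the ventricular z-coordinates. All four
parameters sit in `PartitionConfig`. The heuristic is validated against the
phantom generator's ground truth (≥95% voxel agreement required; in
practice it is exact on the default phantom).

The **dominant region** of a tumor touching several subregions is the one
with the greatest overlap voxel count — a volume proxy for "area of
involvement", since the inputs are volumetric masks and no surface-area
procedure is better defined on them. Exact ties break deterministically to
the lowest region code.

## Cohort assembly

Dichotomizations put the boundary value in the group its label names:
age 40 → ≥40; KPS 80 → ≥80 (so `kps_lt80 = 0`); volume 60 cm³ → ≥60;
CS 30 mm → ≤30 ("near"). `cs_le30` and the frontal-horn-vs-others indicator
exist only for SVZ-involved patients and are missing (not 0) otherwise.
PFS must not exceed OS, and a death without observed progression must carry
PFS censored at the date of death; violations raise. Patients with missing
required covariates are excluded listwise with per-field reasons recorded
in the run log — no imputation is attempted.

## Survival analysis

Kaplan–Meier estimation, the unweighted two-sided log-rank test (the
k-group statistic when a comparison has more than two levels), and Cox
proportional-hazards fits are delegated to lifelines. Ties in event times
are handled by Efron's approximation (lifelines' default; recorded in the
run log). Confidence intervals are Wald intervals on the log-hazard scale
at 95%. The modelling cascade mirrors the study design it implements:
group contrasts (involved vs not on all patients; CS ≤30 vs >30 and
frontal-horn vs others within the involved subcohort) are KM/log-rank
only; Cox screening runs within the involved subcohort, and covariates
with univariate p < α (default 0.05) enter a single joint model per
endpoint. A screen with one survivor reports the univariate fit as the
joint model (they are the same model); a screen with none reports no
multivariate section. Per-covariate fit failures (zero variance,
collinearity, non-convergence) are recorded as notes without aborting the
screen.

## Synthetic data

### Ventricle phantom

Default grid 96×96×28 voxels at 0.6×0.6×5 mm (the anisotropic acquisition
geometry of clinical T2 imaging; ~57.6×57.6×140 mm of world space, small
enough for full-cohort simulation at desk scale). Two parallel canals run
along the AP axis at a superior axial level, labeled 1/2/3 by fractional
thirds of the AP extent; two separate inferior ellipsoids form the temporal
horns. The AP extent is nudged so the fractional cut planes never coincide
with a voxel row (which would make the truth/heuristic comparison depend on
floating-point tie direction). The phantom is deterministic given its spec.

### Tumor generator

A tumor is carved by ranking every voxel by a normalized radius in an
ellipsoid frame (principal axis pointing away from the nearest ventricle
point, the most z-aligned perpendicular axis carrying the larger semi-axis)
plus i.i.d. boundary noise (σ = 0.05 of the normalized radius), and keeping
exactly the n voxels implied by the volume target — so volume targets are
met to ±1 voxel by construction. Contacting tumors are unioned with a thin
cylindrical stalk (initial radius 3.2 mm, widened if the voxel lattice
severs it) running from the bulk to the nearest ventricle point: a pure
ellipsoid cannot both touch the ventricle and center 40 mm away on this
grid, while a bulk-plus-stalk shape shifts the centroid only by the stalk's
small mass fraction. Placement starts from a precomputed distance field
(for every grid voxel: distance to, and identity of, the nearest ventricle
voxel, restricted to the requested subregion), and a correction loop
re-measures the candidate with the geometry module and shifts the center
until the measured contact state, CS (±2 mm) and dominant region match;
infeasible targets raise with the retry count. The boundary-noise field is
frozen within a placement attempt so the correction loop converges instead
of chasing a moving surface.

Feasibility on the default grid bounds some joint targets: the maximum
achievable centroid–ventricle distance is ≈46 mm, and only the frontal and
temporal horns possess far-distance shells. The cohort generator therefore
draws far CS targets in (34, 40) mm, restricts far dominant regions to the
frontal/temporal horns, keeps far bulks ≥20 cm³ (a smaller far tumor would
be mostly stalk and could not balance its centroid), and for the
far-and-≥60 cm³ combination draws CS in (33.5, 36.5) mm with volume capped
at 72 cm³. Target bands leave gaps around every dichotomization cut (26–34
mm around CS 30; 45–62 cm³ around volume 60) so the ±2 mm placement
tolerance cannot flip a planted group label.

### Cohort simulation

Binary covariates are drawn independently at the observed cohort
proportions (age ≥40: 0.36; male: 0.68; KPS <80: 0.12; CS ≤30 given
involvement: 0.46; <GTR: 0.72; radiation: 0.75; chemotherapy: 0.19; SVZ
involvement: 0.80), with two exceptions motivated above and by the data:
volume ≥60 cm³ has prevalence 0.53 given involvement and 0.21 otherwise,
and the dominant region is conditioned on the CS stratum. Survival times
are exponential — the simplest model satisfying the proportional-hazards
assumption, with closed-form truth for oracles; a Weibull baseline
would be a straightforward extension but is not implemented. OS hazard is
λ₀·exp(Σβx) with λ₀ = 1.05×10⁻⁴/day and the planted β from the multivariate
effect sizes (ln 2.192 age, ln 2.461 volume, ln 2.260 CS ≤30, ln 5.273
<GTR); PFS has its own baseline (1.6×10⁻⁴/day) and effects (ln 2.430, ln
1.998, ln 4.526) and is truncated at death, mechanically reproducing the
death-censors-progression rule. Administrative censoring comes from uniform
accrual over 7 years with close-out at 8 years; the OS baseline was chosen
analytically so that censoring lands near 30% under the default prevalences
and effects (verified to ±5 points at n ≥ 1000 in the tests). Event days
are rounded to integers, deliberately creating ties so the Efron path is
exercised. Identical spec + seed give byte-identical outputs.

What the generator does *not* emulate: MRI intensities and segmentation
error, anatomical variation of the ventricles across patients (one phantom
serves the whole cohort), correlated covariates beyond the two conditioned
pairs above, non-proportional hazards, and informative censoring. Passing
tests therefore demonstrate correctness of the measurement and inference
machinery under the stated model, not robustness to those real-data
features.

## Simulation-study sizes and checks

The recovery study runs 100 replicates of n = 1000 (≈800 involved) on the
tabular path and checks that the p<0.05 screen retains every planted
covariate and that the multivariate 95% CI covers the planted CS ≤30 HR of
2.260, each in ≥90% of replicates. Screen recovery is assessed as
containment (all planted covariates selected) rather than exact set
equality: with five null candidates a 5%-level screen admits at least one
false positive in ≈23% of replicates by design, and the feasibility-driven
correlation between the far-CS stratum and the frontal/temporal dominant
regions gives the region indicator a real marginal association, so exact
equality has a structural ceiling well below any useful threshold (the
acceptance script still reports the exact-match rate for transparency).
The end-to-end mask path runs at n = 150 and the log-rank size study uses
1000 null simulations of n = 100 (large enough that the chi-square
approximation's small-sample anti-conservatism, ≈5.5% at n = 60, is
negligible). Null-calibration checks use two-group exponential data with
all subjects followed to the event.

## Numerical conventions and degenerate inputs

Empty masks are rejected at read time and by every geometry operation;
all-censored or single-group inputs to the log-rank test raise; constant
and collinear covariates raise typed errors (`ZeroVarianceError`,
`CollinearityError`); a Wald CI that fails to bracket its own HR is treated
as a broken fit and surfaced rather than reported. Grid compatibility
between tumor and ventricle (shape, spacing, affine) is enforced to 1e-6
before any pairwise computation. Report CSVs are written with a fixed float
format and sorted patient order, making pipeline runs byte-reproducible.

## Known limitations

* The heuristic subregion partition is a geometric stand-in for an
  anatomical labeling; on real anatomy the prelabeled path should be
  preferred.
* CS for a centroid inside the ventricle is defined as 0; distances are
  voxel-center-based, so sub-voxel surface distances (≤ half a voxel
  diagonal, up to ≈2.5 mm at 5 mm slices) are not resolved.
* The univariate-screen-then-multivariate strategy is reproduced as
  specified, including its known weaknesses (marginal confounding can
  admit null covariates; screening biases selected-effect estimates).
* Proportional-hazards diagnostics, time-varying covariates and competing
  risks are out of scope.
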