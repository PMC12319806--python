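# Methods

This note documents the models, numerical choices and synthetic-data design
behind `tractgr`, in the spirit of a package reference manual.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The aggregate g-ratio model

A voxel is decomposed into myelin (volume fraction MVF) and non-myelin
water; the water splits into an isotropic free-water pool (fraction ISOVF of
the water) and an anisotropic tissue pool, of which a fraction ICVF is
intra-neurite.  The intra-axonal volume fraction of the whole voxel and the
aggregate g-ratio follow as

    AVF = (1 − MVF)(1 − ISOVF) · ICVF
    g   = sqrt( AVF / (AVF + MVF) )

with g undefined (NaN, not 0) where AVF + MVF = 0, so empty voxels can never
silently enter a mean.  The same expression applies at the tract level with
summed volumes AV, MV in place of the fractions — g is intensive, invariant
to how volume is split among duplicate streamlines.

**MTsat and calibration.**  Magnetization transfer saturation is estimated
from an MT-weighted gradient-echo signal, an S0 and a T1 map as

    MTsat = (S0·a/S_MTw − 1)·TR/T1 − a²/2,   a = flip_angle · B1⁺

(flip angle in radians, TR and T1 in ms).  `simulate_mtw` is the exact
algebraic inverse, so the round trip is an identity to floating-point
precision.  MVF is a linear rescaling MVF = α_calib·MTsat.  The calibration
factor is obtained by inverting the two model equations at a fixed reference
g (0.7, the conventional splenium value) in a calibration region restricted
to FA > 0.8: with c = (1 − ISOVF)·ICVF,

    MVF* = c(1 − g_ref²) / (g_ref² + c(1 − g_ref²)),   factor = MVF*/MTsat

and α_calib is the mean factor over selected voxels.  This closed form is
the unique MVF consistent with the model at g_ref.  For multi-subject
cohorts the intended convention is mean-within-subject then mean-across-
subjects (equal subject weighting); `compute_alpha_calib` operates per
subject and the caller averages the returned factors.  Voxels with
non-positive MTsat are excluded; an empty post-threshold ROI is an error.

## Forward model and the three solves

The diffusion signal of each voxel is a non-negative combination of

* **restricted** sticks — one column per streamline; the entry for voxel v
  and measurement (b, ĝ) is `exp(−b·D∥·(ĝ·û)²) · ℓ`, with û the unit chord
  of the streamline's piece inside v and ℓ its length (mm).  The unknown is
  a cross-sectional area (mm²), constant along the streamline;
* **hindered** zeppelins — per voxel, segment directions are clustered with
  a 15° angular threshold after antipodal identification (û ≡ −û), one
  column per cluster with entries `exp(−b(D⊥ + (D∥−D⊥)(ĝ·û)²))`; the
  unknown is a hindered volume (mm³).  Per-cluster rather than
  per-streamline hindered columns avoid gross rank deficiency and mirror
  peak-based hindered compartments in convex filtering frameworks;
* **isotropic** balls — per voxel and diffusivity, `exp(−b·D_iso)`.

Diffusivities default to D∥ = 1.7e−3, D⊥ = 0.51e−3,
D_iso = {1.7e−3, 3.0e−3} mm²/s.  Column order is deterministic:
streamlines by index, then hindered by voxel/cluster, then isotropic.

The three solves:

1. **Filtering** — raw signal divided by the per-voxel mean b=0 signal
   (voxels with non-positive mean b0 are dropped and logged).  Streamlines
   with weight below 1e−10 × max-weight are removed; solvers produce exact
   zeros only up to round-off, hence a relative rather than literal-zero
   threshold.  The tract ICVF map is fitted restricted volume over
   restricted + hindered volume per voxel (isotropic excluded, the
   intra/(intra+extra) convention), 0 where the denominator vanishes.
   Because the raw fit ignores myelin, this ICVF is biased high relative to
   the phantom's generative value — the motivation for the correction below.
2. **Myelin** — one row per masked voxel: Σᵢ (areaᵢ · ℓᵢᵥ) = MVF·V_voxel.
3. **True axonal** — the b0-normalized signal is multiplied by (1 − MVF)
   (`myelin_correct_signal`), restoring volume units that account for the
   myelin compartment, and refit *without* re-normalization.

**Mask.**  All fits run over a caller-provided mask; the phantom pipeline
uses the voxels traversed by any streamline.  Resolution mismatches between
the diffusion and myelin grids are out of scope at phantom scale: all maps
share one grid, and the mask/affine parameters are the extension point.

**NNLS solver.**  Accelerated projected gradient (FISTA with adaptive
restart), step 1/L with L from 60 power iterations (×1.01 safety), stopping
when the KKT residual max(|∇ᵢ| on the support, max(−∇ᵢ, 0) off it) falls
below tol × ‖Aᵀy‖∞ (tol 1e−8, max_iter 5000 by default).  After
convergence the positive support is polished by an exact least-squares
refit, accepted only if feasible and not KKT-worse; on small
well-conditioned systems the result then matches exhaustive active-set
enumeration to ~1e−8.  Non-convergence returns the best iterate with a
warning and a flag.  On dictionaries with near-duplicate columns (dense
bundles) individual weights are not unique and some true streamlines
legitimately receive zero weight; bundle-summed volumes remain pinned by
the per-voxel volume constraints, which is what the connectome consumes.

## Connectome stage

Endpoints take the label of their containing parcellation voxel, with a
2 mm nearest-labelled-voxel search for background endpoints (a stand-in for
gray-matter-interface cropping, unavailable at phantom scale); ties break
by distance then smaller label.  Edges are undirected (min, max) pairs,
diagonal excluded.  Edge caliber is the sum of member streamlines'
intra-axonal + myelin areas (mm²); the node-volume-scaled caliber divides
by vol(a) + vol(b).

**Caliber filter.**  Pooling calibers across the whole cohort (subjects and
sessions), the threshold is the `floor(keep_fraction·n)`-th largest pooled
value; edges ≥ threshold survive everywhere.  With distinct calibers
exactly that count survives; ties at the threshold are kept (the degenerate
all-equal cohort keeps everything).  **Consensus filter.**  An edge is kept
iff present (nonzero count) in at least `ceil(min_presence·n_subjects)`
subjects — the ceiling resolves odd cohort sizes — and removal applies to
every subject.  Matrix density is non-increasing through both filters.

## Tractometry comparator

The volumetric g map is sampled at arc-length-uniform points (0.5 mm,
matching the tractography step size) with trilinear interpolation; the
per-streamline statistic is the median, the per-edge statistic the mean of
member medians.  Interpolation is NaN-aware: corners that are NaN or
outside the grid are dropped and the remaining weights renormalized, so a
sample is excluded only when no corner is defined.  A naive interpolator
would propagate NaN from zero-weight corners and silently discard every
sample taken on a tissue boundary.

## Synthetic phantoms

`PhantomSpec` describes a voxel grid (default 16³ at 1 mm), bundles, and
noise.  Each bundle is a centerline with per-streamline ground-truth
intra-axonal area a (default 0.004 mm²) and myelin area m fixed by the
target g (m = a(1−g²)/g²).  Streamlines are jittered copies of the
centerline (constant Gaussian perpendicular offset, sd 0.2 × voxel size —
enough to exercise multi-voxel traversal while keeping the bundle
coherent).  Traversing a voxel for ℓ mm deposits a·ℓ intra-axonal and m·ℓ
myelin volume; a proportional hindered pool a·ℓ(1/ICVF_fiber − 1)
(ICVF_fiber = 0.8) fixes the fiber-water ICVF, and the residual non-myelin
water is isotropic free water.  By construction every voxel satisfies the
g-ratio model identities exactly and the b=0 signal equals
(1 − MVF)·V_voxel.  Depositing more tissue than a voxel holds raises a
rejection with the offending voxel and fraction.

The ground-truth FA grid is computed from the fiber water compartments only
(stick + zeppelin mixture tensor), excluding the isotropic remainder: its
sole purpose is discriminating single-fiber from crossing voxels for the
FA > 0.8 calibration and FA > 0.7 single-fiber ROIs, and diluting it with
the bookkeeping-driven isotropic pool would couple that discrimination to
the arbitrary fill fraction.  The measured-FA operation (`compute_fa`, a
log-linear tensor fit on b ≤ 1000 shells) is separate and reflects the full
signal.

**Geometries.**  `two_bundle_spec` (default) has bundle 0 straight along +x
and bundle 1 descending at ~53° into a shared central corridor (~8 mm of a
13 mm tract) before diverging to its own endpoint labels.  Voxels along
most of both tracts then hold two populations with different g — the
pervasive partial-volume situation of in-vivo white matter, where a median
over samples is genuinely affected.  `orthogonal_crossing_spec` provides
the minimal-footprint counterpart (one shared voxel), and
`single_bundle_spec` the crossing-free limit in which the tract-specific
and tractometry branches must agree.  Spurious streamlines are bowed arcs
between endpoint labels of different bundles whose connecting direction
stays ≥ 35° from every bundle orientation; they carry no tissue volume, so
the filtering solve must drive their weights to zero.

**Acquisition.**  The default scheme mirrors a standard in-vivo protocol:
6 b=0 plus 10/30/64 directions at b = 300/1000/2000 s/mm², directions from
a golden-angle hemisphere spiral.  Noise is Rician (magnitude MRI) with a
Gaussian option for linear-regime tests; noiseless runs are bit-
reproducible for a fixed seed.

**What the phantom does not emulate.**  Realistic brain geometry, fiber
dispersion and fanning, axon-diameter distributions within a bundle,
compartment-specific T2 decay, susceptibility/motion/EPI artifacts, and
resolution mismatch between contrasts.  Passing tests therefore demonstrate
correctness of the estimation machinery under the stated generative model,
not in-vivo accuracy.

## Statistics

* **ICC** is ICC(2,1) — two-way random effects, absolute agreement, single
  measurement — the natural scan-rescan convention when the paper-level
  choice between ICC(2,1) and ICC(3,1) is open.
* **Bland–Altman** differences are expressed in percent of the pairwise
  mean, limits mean ± 1.96 sd; a single pair yields NaN limits with a
  warning.
* **CoVa** is sd/mean across subjects per edge (scan/rescan averaged
  first); network- and node-level values are plain means over member edges.
* **Cross-technique correlation** is Pearson, per edge across subjects.
* **Mixed model**: g ~ caliber + length with a per-subject random intercept
  and random length slope, fit by REML (statsmodels MixedLM, lbfgs).  A
  singular random-effects covariance falls back to intercept-only, flagged.
  The reported adjusted R² is *marginal* (fixed effects only) — the
  conditional variant would also credit the random effects, and the
  marginal one matches the "variance explained by caliber and length"
  reading.  `adjusted_g` returns g with the random effects and the other
  fixed effect removed, for partial-effect plots.  The bundled generator
  defaults to the tract-specific coefficients (β₁ = −7.46e−3 per scaled-
  caliber unit, β₂ = 4.04e−4 per mm) with calibers |N(0,1)| and lengths
  uniform on 10–160 mm, spanning plausible tract scales.

## Problem sizes and tolerances

Desk-scale defaults: 16³ voxels, 2 × 50 + 10 streamlines, 110-measurement
scheme; the full two-branch pipeline solves systems of ~3·10⁴ rows and
~10³ columns in seconds.  Recovery checks use 1 % (bundle volumes) and 0.01
absolute (edge g); the solver-equivalence check uses 1e−8; algebraic
identities (MTsat round trip, calibration closure) use 1e−10 relative /
1e−6 absolute.  Mixed-model recovery is checked at 20 subjects × 200 edges
via 95 % confidence-interval coverage and sign.

## Known limitations

Individual streamline weights are non-unique in dense parallel bundles
(only bundle aggregates are identifiable); the hindered clustering angle
(15°) and endpoint search radius (2 mm) are heuristics exposed as
parameters; `compute_fa` loops voxels in Python and is intended for
desk-scale grids; the CLI covers the per-stage workflow but not cohort
orchestration, which is a few lines of the library API.
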