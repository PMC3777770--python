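# Methods

## Model and procedure

`mslseg` treats MS brain segmentation as two coupled problems.

**Lesions** do not follow a Gaussian intensity distribution, so they are
detected non-parametrically: a Parzen-window density is estimated per class
in the (T2, FLAIR) intensity plane from expert (or phantom) training points,
quantized onto a bin grid (the *feature map*), and applied by lookup. Only
the lesion class of this first pass is kept; lesion voxels are removed from
the data before any parametric modelling.

**Normal tissue** (GM/WM/CSF) is modelled parametrically on (T1, T2): class
intensities are multivariate Gaussians, and the label field carries a Potts
prior over the 6-neighbourhood (coupling β) plus an external field given by
the class proportions π. The per-voxel conditional energy is

    U(x_i = k) = −log π_k + ½ log|Σ_k| + ½ (y_i/b_i − μ_k)ᵀ Σ_k⁻¹ (y_i/b_i − μ_k)
                 + β · #{6-neighbours j : x_j ≠ k}

with b_i a smooth multiplicative bias field. EM alternates (a) ICM label
updates, (b) posteriors with the MRF prior frozen at the current labels'
neighbour counts, (c) posterior-weighted updates of (π, μ, Σ), and (d) a
bias-field refit. Keeping −log π in the energy makes the β = 0, bias-off
limit coincide *exactly* with a plain Gaussian-mixture EM, which is the
degeneracy the test suite checks against an independent implementation.

The cerebellum is segmented separately into GM/WM with its own Gaussian
parameters, because cerebellar contrast differs from cerebral contrast; the
atlas cerebellum mask defines the split and the two label maps are disjoint
by construction.

**False-positive cascade.** Hyperintense non-lesion tissue (cortical GM
voxels, choroid plexus) survives the Parzen pass. Rules applied in order:
cortical-GM mask → brain-surface rim (depth 2 voxels) → components ≤ 3
voxels → fuzzy-connectedness growth → dilated lateral-ventricle mask
(choroid → CSF) → deep-GM mask (WM/CSF → GM). Growth is barred from the
CGM/LVC/rim exclusion zones so it cannot undo an earlier rule, and the
≤ 3-voxel rule is re-applied after growth so no sub-threshold fragment can
re-enter. With that ordering the cascade is idempotent (verified by test):
max-min path strength guarantees that any voxel θ-connected to a grown set
was already θ-connected to the original seeds.

**Fuzzy connectedness** uses the standard two-term affinity on face-adjacent
voxels (object term on the mean intensity, gradient term on the intensity
step) and defines connectedness as the maximum over paths of the minimum
affinity along the path, computed by best-first (Dijkstra-style max-min)
propagation. Strength is 1 exactly on seeds and 0 outside the brain mask.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| standard intensity range | [0, 4095] | a.u. | 12-bit convention for the standardized scale |
| deciles used as landmarks | p10…p90 | — | piecewise-linear knots; end segments extended, clamped |
| diffusion iterations / dt | 5 / 1/14 | — | dt ≤ 1/(2·axes) keeps the explicit 3D scheme stable |
| diffusion κ | median |∇| | a.u. | gradient-adaptive conductance scale |
| Parzen bins | 256 × 256 | — | bin width ≈ 16 a.u., well below class separations |
| Parzen bandwidth | Silverman, per axis per class, averaged | a.u. | floored at 0.1% of the range to survive degenerate training sets |
| feature-map tie-break | lowest class code | — | deterministic; ties occur only on symmetric toy data |
| β (Potts coupling) | 0.5 | — | mild spatial smoothing; 0 disables the MRF |
| EM / ICM iterations | 20 / 5 | — | EM stops early at relative pseudo-likelihood change < 1e-4 |
| bias model | order-3 polynomial in log domain, per channel | — | zero-mean log over the mask (gauge), capped at 3× |
| min lesion size | 3 voxels | — | components ≤ 3 voxels reclassified GM |
| rim depth | 2 voxels | — | registration-artefact band at the brain surface |
| LVC dilation | 1 voxel (+ closing) | — | covers partial-volume shell of the ventricles |
| lesion component connectivity | 26 | — | diffuse lesions merge across diagonals; 6 available |
| fuzzy w₁/w₂, θ | 0.5/0.5, 0.8 | — | object/gradient terms weighted equally; θ from pilot runs on the phantom |
| fuzzy m, s, s_g | seed statistics | a.u. | object mean/sd estimated from current lesion voxels; m_g = 0 |

Label codes are fixed: 0 background, 1 CSF, 2 GM, 3 WM, 4 lesion (written
as unsigned 8-bit NIfTI). Voxel coordinates are 0-based (x, y, z) array
indices; all distances are in mm via the per-axis spacing, so anisotropic
grids are supported throughout.

## The synthetic phantom

The generator builds a parametric nested-ellipsoid brain on a 64³ grid
(1 mm isotropic by default): outer CSF rim, 3-voxel cortical GM ribbon, WM
interior, two ellipsoidal lateral ventricles, two thalamus-like deep-GM
blobs, a cerebellum with its own GM/WM contrast offsets, six spherical WM
lesions (radius 3–4.5 mm, ≥ 2 mm clearance from WM borders), and three
choroid-plexus decoys inside the ventricles carrying lesion intensities.
Intensities are class mean × (1 + 0.2·quadratic bias field) + Gaussian
noise (σ = 4 a.u.; Rician available). Default class means respect the
qualitative MS contrast: T2 CSF > lesion > GM > WM; FLAIR lesion > GM > WM
> CSF; T1 WM > GM > CSF ≈ lesion; deep GM is T2-hypointense so that
intensity-only classifiers mislabel it WM — the failure mode the deep-GM
atlas rule exists to fix. Atlas masks derive from the exact geometry
(optionally dilated to mimic registration error), and training points are
sampled from interior voxels of each class's intensity-canonical region
(cortical ribbon for GM, cerebral WM for WM, rim+ventricles for CSF),
emulating an expert picking representative voxels; default counts are
GM 100, WM 111, CSF 124, lesion 168.

What the phantom does **not** emulate: partial-volume mixing at tissue
boundaries, MR acquisition physics (k-space, ringing), anatomical shape
variability, and registration error beyond mask dilation. Passing tests on
the phantom therefore demonstrates correctness of the algorithms under the
stated noise/bias model, not clinical-grade accuracy on scanner data; in
particular lesion boundaries in the phantom are crisp, so the
fuzzy-connectedness growth step is near-neutral here, whereas on real
diffuse lesions it is the step that recovers under-segmented rims.

## Numerical choices

* **ICM schedule**: checkerboard (red–black) sweeps. Under a
  6-neighbourhood the two parities do not interact, so each half-sweep is
  exact coordinate descent and the total energy is non-increasing — the
  property the tests assert. A strict raster scan would give the same
  guarantee but cannot be vectorized.
* **Bias fit**: after decile standardization the lowest class of each
  channel sits near 0 a.u., where log-ratios are meaningless; the fit uses
  only voxels whose intensity and class mean exceed 5% of the channel scale
  and lets the polynomial extrapolate elsewhere. Multiplicative bias and
  class means are identifiable only jointly: the zero-mean-log convention
  fixes the gauge over the fitted mask, so means recovered on a sub-region
  (e.g. cerebellum) absorb that region's average field.
* **Covariance regularization**: ε·I with ε = 1e-6 × mean variance, applied
  only when near-singular (degenerate seeds); class collapse freezes the
  class at its initialization instead of inverting an empty covariance.
* **Boundary definition**: a mask voxel is boundary if any 6-neighbour is
  outside; volume-edge voxels count as boundary. Surface distances use
  exact Euclidean voxel-centre distances (KD-tree), verified against an
  all-pairs brute-force oracle to 1e-9 mm.
* **Morphological closing** treats the volume border as foreground during
  its erosion phase so closing is extensive.
* **Degenerate inputs** raise rather than guess: constant volumes (no
  histogram threshold, no deciles), empty masks/seed sets, non-increasing
  deciles, rim erosion that empties the brain.

## Design decisions

* The deep-GM rule keeps lesion voxels as lesion (configurable): WM lesions
  adjacent to the thalamus should not silently vanish into GM.
* Rim false positives are reclassified to GM, consistent with the
  cortical-GM rule's destination.
* Component-wise TPR/FPR (a reference lesion counts as found if any
  segmented voxel overlaps it) is the default reporting mode; voxel-wise
  rates over an explicit domain are also provided, since the TN domain of a
  voxel-wise FPR is otherwise ambiguous.
* Both per-bin densities and argmax labels are kept in the feature map:
  labels drive classification, densities enable diagnostics.
* Standardization precedes feature-map application in the orchestrator, so
  a single feature map serves every case.

## Problem sizes

The shipped tests and the acceptance script run on the 64³ phantom
(~76 000 brain voxels), where the full pipeline completes in ~10 s on one
CPU; metric and connectivity oracles run on ≤ 12³ and ≤ 5³ grids where
brute-force enumeration is exact and fast. Larger grids work unchanged
(geometry scales with the grid); runtime is dominated by the EM sweeps and
the fuzzy-connectedness heap, both roughly linear in brain voxels.

## Known limitations

Cortical lesions, T1 black holes and gadolinium-enhancing lesions are out
of scope; inter-sequence registration and template deformation are assumed
done upstream (the pipeline consumes co-registered volumes and
subject-space atlas masks); no partial-volume mixture classes; the
evaluation suite compares single segmentations (no multi-rater fusion).
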