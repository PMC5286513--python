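# Methods

This note records the models, numerical choices and their rationale; the
README covers usage. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Shape representation

A structure is represented by its signed Euclidean distance function (SDF)
on the image grid: the exact distance transform of the binary mask and of
its complement are combined as `d_out − d_in`, honoring anisotropic voxel
spacing, with the inside negative. Thresholding at zero recovers the mask
exactly. Two conventions follow from this discretization:

- SDF magnitudes are distances between voxel *centers*, so values at
  boundary voxels are offset by about half a voxel rather than ~0. All
  voxel-level tolerances in the tests are therefore stated in voxel
  diagonals.
- The surface distance between two shapes is computed as the *difference*
  of their SDFs, `φ_B − φ_A`, sampled at A's boundary voxels. For
  near-unit-gradient fields this equals the signed distance between the zero
  level sets and cancels the shared half-voxel offset, so identical shapes
  give exact zeros. Sampling `φ_B` alone would floor every measurement at
  one voxel.

Averaging SDFs across aligned subjects and re-extracting the zero level set
yields the mean shape; because a mean of SDFs is not itself a distance
function, the mean is re-initialized (mask → exact distance transform)
after every averaging step, and the CG mask is intersected with the
prostate mask before re-initialization so the containment invariant holds
on the atlas itself.

## Registration

Subjects are aligned to the atlas by minimizing the three-term scoring
function (intensity + prostate shape + CG shape; the two shape weights
equal, default 1 : 1 : 1) over a growing transform hierarchy. All transforms
are stored as backward maps (atlas point → subject point), the resampling
convention.

**Shape terms.** Mean squared SDF difference over the set of atlas voxels
within ±10 mm of the respective mean surface (a band, so interior voxels do
not dominate). Subject-space SDF values are divided by the linear scale
factor of the transform, det(J)^(1/3), before differencing; without this
conversion a scaling transform trades surface alignment against the
interior SDF-slope mismatch and the recovered scale is biased low by ~2%.

**Intensity term.** Negated normalized cross-correlation over the pooled
band region. Restricting NCC to the band makes it local in the sense that
matters (robust to global intensity scale and shift, evaluated only near
the organ) while keeping every cost evaluation a point-cloud operation; a
Gaussian-windowed local NCC over the full grid was not needed at phantom
contrast levels.

**Initialization.** Translation of the prostate centroid to the atlas
center plus isotropic scaling s = (V_median/V_subject)^(1/3) to the
subpopulation's median prostate volume (lower median for even sizes, for
determinism).

**Affine stage.** Nine parameters — translation (mm), intrinsic XYZ Euler
rotation (deg), per-axis log-scale. Shear is deliberately excluded: the
stage models the pose-and-size residual the initialization leaves behind.
Optimization is multi-resolution (band-point subsampling at 2 500 then
8 000 points) L-BFGS-B with numerical gradients on scaled parameters and a
fixed iteration budget; no stochastic sampling, so registration is
deterministic under a fixed config. The search is box-bounded (±20 mm,
±20°, ±0.35 log-scale by default): prostate-like shapes are nearly
ellipsoidal, so large rotations are weakly identified and an unbounded
search can drift into spurious minima of the rotational ambiguity.

**Elastic stage.** Cubic B-spline free-form deformation. The displacement
at any fixed evaluation point is linear in the control coefficients
(D = W·P with a precomputed sparse weight matrix), so the cost gradient is
exact and optimization uses L-BFGS-B with analytic gradients. Two
constraints realize the "anatomically plausible deformation" contract:

- a hard cap: per-component box bounds of cap/√3 (default cap 10 mm) on
  every coefficient — since the cubic B-spline basis is a nonnegative
  partition of unity, this bounds the Euclidean displacement of every point
  by the cap;
- a bending-energy penalty (squared second differences of the coefficient
  grid, weight 1.0): smooth organ-scale corrections pass nearly free while
  fine-scale chasing of per-subject surface noise and voxelization jitter
  is quadratically punished.

Control-point spacing defaults to 15 mm. This was chosen to separate
scales: the deformation can still express a ~15 mm focal effect, but cannot
absorb the 5–8 mm-scale inter-subject surface variability. A denser grid
(10 mm was tried) aligns every phantom almost perfectly to the atlas, which
collapses the within-group per-voxel SDF variance toward zero and makes the
downstream rank-sum test flag arbitrarily small systematic offsets — the
statistics need the residual variability a constrained deformation leaves
behind. (The bump-recovery property — a 4 mm focal misfit reduced by ≥50%
after the elastic stage — is exercised in the tests at 10 mm control
spacing via the stage's config argument.)

## Atlas construction

One pass per stage (initialize → affine round → elastic round), the atlas
re-averaged after each round; the subject whose prostate volume is the
population median seeds the reference. The atlas grid is isotropic
(default 1.0 mm, configurable) in world millimetres, sized to cover every
normalized prostate with a 12 mm margin, centered on the origin, with axes
x = left–right, y = anterior–posterior (posterior positive),
z = apex–base (base positive).

After each registration round the population-mean transform is removed from
every subject's stage (mean affine parameters; mean B-spline coefficient
field — all subjects share one control grid per round). Without this
*template drift correction*, standard in groupwise template construction,
the atlas inherits the reference subject's random pose, and two
independently built atlases can differ by a real several-degree rotation
that the cross-atlas correction then has to disentangle from the rotational
ambiguity of near-symmetric shapes.

Aligned per-subject masks are re-thresholded at the SDF zero crossing
(sub-voxel accurate) and their SDFs recomputed on the atlas grid, so every
stack entry is a true distance function in atlas millimetres.

## Cross-atlas comparison

Independently built atlases are volume-normalized and centered, so only a
small residual translational/rotational shift between them is plausible;
the cross-atlas correction is therefore **rigid** by default (a 9-dof
linear correction is available behind `dof="affine"`), driven by the
equal-weight prostate + CG shape terms with no intensity term (intensity is
not comparable across scanners). Two safeguards keep the alignment from
absorbing the very differences the comparison is meant to find:

- the search is bounded to ±5 mm / ±5°;
- after a first fit, band points with outlier SDF residuals (beyond
  max(1.5 mm, 4×MAD)) are trimmed and the transform refit on the consensus
  surface, so a localized true effect does not bias the global pose.

A scale-compensating transform is off by default because it partially
absorbs a one-sided effect into a global shrink and delocalizes the
significance map.

**Voxel-wise testing.** At every voxel within ±3 mm of either mean surface
(prostate and CG bands pooled into the Bonferroni count N), a two-sided
Wilcoxon rank-sum test compares the per-subject SDF samples of the two
groups; significance at p < α/N, α = 0.05. Whenever a voxel's combined
sample is tie-free the *exact* null distribution of the Mann–Whitney U
statistic is used (counting recursion, cached per group-size pair);
voxels with ties fall back to the normal approximation with tie and
continuity corrections. The exact path is essential, not cosmetic:
Bonferroni thresholds sit at α/N ≈ 1e-5–1e-6, far into the tail where the
normal approximation at n = 15 + 15 is off by orders of magnitude (its
minimum attainable p is ~3e-6 while the exact floor is 2/C(30,15) ≈
1.3e-8); with the approximation alone a fully separated voxel could fail
the corrected threshold.

**Reporting.** Signed surface-distance maps (mm, positive = A outside B)
on A's boundary voxels, the Bonferroni-thresholded significance masks, and
an anatomical-sector summary over anterior/posterior × apex/mid/base
(posterior = +y; apex/mid/base = thirds of the prostate band's z-extent).

**Detection scoring.** When a ground-truth effect region is available, the
significance mask is scored by Dice after dilating *both* masks by 2 mm,
plus the centroid distance. The truth region (where the expected group
surfaces differ by >1 mm) is a thin inter-surface shell, while any correct
significance region is a band-thick surface patch several times larger;
their undilated Dice is bounded well below 1 even for a perfect detector,
so the symmetric dilation acts as a spatial tolerance rather than an
overlap inflator.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
prostate anatomy per se: ellipsoids admit analytic volume and distance
oracles, which is what the pipeline's correctness claims need.

Per subject: a prostate ellipsoid (default semiaxes 22 × 18 × 20 mm,
≈33 ml) containing an offset CG ellipsoid (14 × 10 × 12 mm, ≈7 ml), posed
by Gaussian rotation (sd 5°) and translation (sd 3 mm), sized by a
log-normal volume factor (`scale_sd`, fractional volume sd). Disease-like
effects: `hypertrophy_factor` multiplies CG volume (semiaxes by its cube
root; generation fails rather than violate CG ⊂ prostate), and
`bump_amplitude` adds a radial outward Gaussian bump (angular width 35°)
at the posterior CG base, propagated to the prostate surface (+1 mm margin)
where it would otherwise exit the gland — the geometry of a peripheral-zone
mass distending the CG border.

Two variability terms make per-voxel group statistics non-degenerate:
per-axis semiaxis spread (`shape_sd`, default 4%) and a smooth per-subject
surface perturbation (`surface_noise_mm`, default 0.8 mm RMS, angular
correlation ~15–25°, realized from the subject seed). Without them every
subject is the same shape up to a similarity transform, the constrained
elastic stage aligns all subjects to bit-identical masks, the within-group
per-voxel SDF variance is exactly zero, and the rank-sum test flags the
entire surface band as significant for any sub-voxel systematic offset.
The 0.8 mm default is a conservative stand-in for residual anatomical
variability after size normalization.

Intensity is a two-compartment T2w-like model (bright shell 180, darker
heterogeneous CG 110 ± 22 of smoothed texture, background 30, additive
Gaussian noise sd 8) with an optional posterior-weighted multiplicative
gain imitating an endorectal coil. No attempt is made to match scanner
statistics; shape, not appearance, carries the analysis.

The second-rater simulator warps both masks with a Gaussian-filtered
white-noise displacement field (smoothness 6 mm, vector-RMS amplitude
`jitter_mm`). The default jitter of 0.6 mm was calibrated once so the
prostate Cohen's κ against the original annotation lands in [0.95, 0.995]
at the default phantom size, and is fixed in the package, not re-tuned per
study.

What the phantoms do **not** emulate: real zonal anatomy and its
asymmetries, lesion-specific deformation patterns, segmentation errors that
correlate with image contrast, scanner- and site-specific intensity
statistics, and non-star-shaped glands. Passing tests therefore demonstrate
that the pipeline recovers geometry and controls error rates under its own
statistical assumptions, not that it is validated on clinical data.

## Agreement statistic

Inter-rater agreement is Cohen's κ on the 2×2 voxel-label contingency,
κ = (p_o − p_e)/(1 − p_e), computed within a per-subject evaluation domain:
the union of both raters' masks dilated by 5 mm. Computing κ over the whole
image inflates agreement through the vast background; the domain choice is
configurable and documented rather than claimed canonical. The degenerate
case p_e = 1 (both raters constant) is defined as κ = 1 when they agree
everywhere and an error otherwise. Study-level summaries report the mean ±
sd of per-subject κ to two decimals.

## Study orchestration

`run_study` builds one atlas per subpopulation in the comparison plan,
down-sampling the larger group with the study seed when compared groups are
unequal (size matching), runs each comparison, computes κ when two raters
are present, and writes a deterministic JSON bundle: rerunning with the
same seed and config is byte-identical.

One caveat on volume reports: post-alignment volumes of phantom cohorts
cluster within ~1–4% of each group's median, so the between-group rank-sum
test on *post*-alignment prostate volumes resolves the sampling difference
between the two groups' medians even when the populations are identical.
With real anatomy the residual spread is larger and this comparison behaves
as a null check; with phantoms it should be read alongside the sd columns.

## Problem sizes and tolerances

The test suite and acceptance script run the study at desk scale, as the
package's own verification conditions: phantom grids 96 × 96 × 48 at
(1, 1, 2) mm; atlas grids at 2 mm isotropic; cohorts of 8 (known-answer
recovery), 9 + 9 (variance reduction/hypertrophy) and 15 + 15 (detection,
rater ordering); 20 permutation replicates for the family-wise error check.
Oracle tolerances are 0.5 voxel diagonals for the distance transform,
1e-12 for exact p-values, 1°/1 mm/2% for affine recovery, 1.5 mm mean
surface distance for atlas recovery, and Dice ≥ 0.3 with centroid ≤ 5 mm
for detection localization.

## Known limitations

- Star-shaped (radial) phantom surfaces only; the pipeline itself has no
  such restriction but is untested on strongly concave shapes.
- The elastic stage optimizes a single resolution level; very large
  deformations rely on the affine stage having done its work.
- The rigid cross-atlas correction assumes atlases are already roughly
  canonical (guaranteed here by drift correction); atlases built by other
  means may need the wider-bound affine mode.
- Bonferroni over band voxels ignores spatial correlation and is
  conservative; no cluster-level or FDR alternative is provided.
- Exact rank-sum p-values are computed only for tie-free voxels; heavy
  ties (e.g. quantized inputs) fall back to the corrected normal
  approximation.
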