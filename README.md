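# shapeatlas

Statistical shape + intensity atlases of the prostate and its central gland
(CG), with voxel-wise localization of shape differences between
subpopulations.

## The problem

Prostate cancer and benign prostatic hyperplasia both deform the gland, but
in different places: peripheral-zone tumours distend the border between the
CG and the peripheral zone, while hyperplasia enlarges the CG itself.  Given
segmented T2-weighted MRI volumes from two groups of men (e.g. biopsy-positive
vs biopsy-negative), the question is *where* on the prostate and CG surfaces
the groups differ, and by how many millimetres — not merely whether summary
volumes differ.  This package is for image-analysis researchers who have
per-subject binary masks of the prostate and CG (plus the intensity scans)
and want population-level, anatomically localized shape statistics.

## The method

Each subject's anatomy is encoded as signed distance functions (SDFs):
φ(x) is the Euclidean distance in mm from voxel x to the structure surface,
negative inside.  A subpopulation atlas is built by aligning all subjects
into a common space with a transform hierarchy of increasing complexity,
each stage minimizing the anatomically constrained scoring function

    C(T) = w_i · D_int(I ∘ T, Ī) + w_p · D_shape(φ_p ∘ T, φ̄_p) + w_cg · D_shape(φ_cg ∘ T, φ̄_cg)

where `D_shape` is the mean squared SDF difference over a ±10 mm band around
the atlas surface, `D_int` is a negated normalized cross-correlation of the
intensities over that band, and the two shape weights are equal
(w_p = w_cg).  The stages are:

1. **initialization** — translate the prostate centroid to the atlas center
   and scale isotropically by s = (V_median / V_subject)^(1/3) to the
   subpopulation's median prostate volume;
2. **affine** — translation + rotation + anisotropic scale;
3. **elastic** — a cubic B-spline free-form deformation with hard-capped
   control-point displacements and a bending-energy penalty, so deformations
   stay anatomically plausible.

After each round the atlas is re-averaged: voxel-wise mean intensity and
voxel-wise mean SDFs (re-initialized to true distance functions), whose zero
level sets are the mean shapes.

Two atlases are compared by rigidly removing their residual relative pose,
then testing at every voxel within ±3 mm of either mean surface: a two-sided
Wilcoxon rank-sum test of the per-subject SDF samples of group A vs group B,
Bonferroni-corrected at p < α / N where N pools the prostate and CG band
voxels.  Outputs are signed surface-distance maps (mm) with the
statistically significant regions outlined and summarized by anatomical
sector (anterior/posterior × apex/mid/base).

Because clinical MRI is not shipped with the package, a synthetic-cohort
module generates phantom populations with the statistical structure the
analysis assumes — pose/size/shape variability, CG hypertrophy, localized
posterior surface bumps, two-rater boundary jitter, endorectal-coil-like
bias — with analytic ellipsoid oracles for volumes and distances.

## Worked example

Simulate two groups of 12 subjects — one with a 5 mm outward bump on the
posterior CG base — build one atlas per group, and localize the difference:

```python
from shapeatlas import (AtlasConfig, GroupSpec, build_atlas, compare_atlases,
                        difference_report, generate_cohort)

cancer_like = GroupSpec(n=12, label="PCaPos", scale_sd=0.2)
benign_like = GroupSpec(n=12, label="BxNeg", institution=2, scale_sd=0.2,
                        bump_amplitude=5.0)
subjects, truth = generate_cohort(cancer_like, benign_like, seed=42)

config = AtlasConfig(spacing_mm=2.0)
atlas_pos = build_atlas([s for s in subjects if s.group == "PCaPos"], config)
atlas_neg = build_atlas([s for s in subjects if s.group == "BxNeg"], config)

result = compare_atlases(atlas_pos, atlas_neg, alpha=0.05)
summary = difference_report(result)
```

This prints (via the summary dict):

```
n_comparisons: 4992
Bonferroni threshold: 1e-05
CG significant voxels: 45
max |surface distance|: 4.00 mm
max significant distance: 3.66 mm
significant-region centroid (x, y, z mm): [0.1, 9.1, 2.9]
dominant sector: posterior-base -> {'n_significant': 6, 'max_abs_distance_mm': 3.66}
```

Reading it: 4992 boundary voxels were tested, so a voxel counts as
significant only below p = 0.05/4992 = 1e-05.  45 CG voxels pass; their
centroid sits at y = +9 mm (posterior) and the dominant sector is the
posterior CG base — exactly where the 5 mm effect was planted (atlas
averaging over a ±5° posed population smooths the apparent peak to ~3.7 mm).
The accompanying volume report shows the alignment at work: pre-alignment
prostate volumes of 36.1 ± 8.6 ml collapse to 33.2 ± 0.7 ml after atlas
construction, while the group contrast in CG volume is preserved.

Note on power: with n per group below ~12 and thousands of tested voxels,
the exact two-sided rank-sum floor 2/C(2n, n) exceeds the Bonferroni
threshold and *no* voxel can be significant — group sizes must be chosen
with the correction in mind.

A command-line interface wraps the same pipeline:

```bash
shapeatlas simulate    --config cohort.yaml --out data/ --seed 7
shapeatlas build-atlas --manifest data/manifest.csv --group PCaPos --rater 1 --out atlases/pos
shapeatlas compare     --atlas-a atlases/pos --atlas-b atlases/neg --alpha 0.05 --out cmp/
shapeatlas run         --config study.yaml
```

Annotated schemas for both YAML files live in `examples/cohort.yaml`
(every `GroupSpec` field plus `two_raters`/`rater_jitter_mm`) and
`examples/study.yaml` (`atlas:`, `comparison:`, a `plan:` of subpopulation
filter pairs, `out`, `seed`).

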