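"""Shared fixtures.

Heavy simulation fixtures are session-scoped so that the atlas-level and
acceptance-level tests share one cohort build each.  Grids are kept at desk
scale (2 mm atlas spacing, the default 96x96x48 phantom grid) so the whole
suite runs on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from shapeatlas.atlas import AtlasConfig, build_atlas
from shapeatlas.comparison import compare_atlases
from shapeatlas.image import GridSpec
from shapeatlas.synthetic import GroupSpec, PhantomParams, generate_cohort, generate_subject

#: asymmetric semiaxes make rotations identifiable in recovery tests
RECOVERY_GEOMETRY = dict(
    prostate_semiaxes=(26.0, 16.0, 20.0),
    cg_semiaxes=(15.0, 9.0, 11.0),
    bump_amplitude=3.0,
)

ATLAS_CFG = AtlasConfig(spacing_mm=2.0)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_subject(PhantomParams(seed=1))


@pytest.fixture(scope="session")
def coarse_grid():
    return GridSpec(shape=(64, 64, 64), spacing=(1.5, 1.5, 1.5), origin=(-47.25, -47.25, -47.25))


@pytest.fixture(scope="session")
def eight_copy_cohort():
    """8 copies of one phantom at random rigid poses (no size/effect spread)."""
    rng = np.random.default_rng(42)
    recs = []
    for i in range(8):
        params = PhantomParams(
            seed=7,  # same anatomy and texture for every copy
            rotation_deg=tuple(rng.normal(0, 6, 3)),
            translation_mm=tuple(rng.normal(0, 4, 3)),
        )
        recs.append(generate_subject(params, subject_id=f"copy{i}"))
    return recs


@pytest.fixture(scope="session")
def eight_copy_atlas(eight_copy_cohort):
    return build_atlas(eight_copy_cohort, ATLAS_CFG)


@pytest.fixture(scope="session")
def hypertrophy_cohort():
    """9+9 subjects, 30% volume spread, 2x CG hypertrophy in the second group."""
    spec_a = GroupSpec(n=9, label="PCaPos", scale_sd=0.3)
    spec_b = GroupSpec(n=9, label="BxNeg", institution=2, scale_sd=0.3, hypertrophy_factor=2.0)
    return generate_cohort(spec_a, spec_b, seed=101)


@pytest.fixture(scope="session")
def hypertrophy_atlases(hypertrophy_cohort):
    records, _ = hypertrophy_cohort
    atlas_a = build_atlas([r for r in records if r.group == "PCaPos"], ATLAS_CFG)
    atlas_b = build_atlas([r for r in records if r.group == "BxNeg"], ATLAS_CFG)
    return records, atlas_a, atlas_b


@pytest.fixture(scope="session")
def detection_cohort():
    """15+15 subjects; 5 mm posterior CG bump in the second group only."""
    spec_a = GroupSpec(n=15, label="PCaPos", scale_sd=0.15)
    spec_b = GroupSpec(n=15, label="BxNeg", institution=2, scale_sd=0.15, bump_amplitude=5.0)
    return generate_cohort(spec_a, spec_b, seed=11)


@pytest.fixture(scope="session")
def detection_result(detection_cohort):
    records, truth = detection_cohort
    atlas_a = build_atlas([r for r in records if r.group == "PCaPos"], ATLAS_CFG)
    atlas_b = build_atlas([r for r in records if r.group == "BxNeg"], ATLAS_CFG)
    result = compare_atlases(atlas_a, atlas_b, alpha=0.05)
    return records, truth, atlas_a, atlas_b, result


@pytest.fixture(scope="session")
def rater_comparison(detection_result):
    """Second-rater re-annotations of the bump-free group, atlas-compared to rater 1."""
    from shapeatlas.synthetic import simulate_rater

    records, _, atlas_a, _, _ = detection_result
    group_a = [r for r in records if r.group == "PCaPos"]
    rng = np.random.default_rng(77)
    rater2 = [simulate_rater(r, seed=int(rng.integers(0, 2**31 - 1))) for r in group_a]
    atlas_r2 = build_atlas(rater2, ATLAS_CFG)
    return compare_atlases(atlas_a, atlas_r2, alpha=0.05)
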