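"""Constrained registration: normalization, cost, affine/elastic recovery."""

from __future__ import annotations

import numpy as np
import pytest

from shapeatlas.image import GridSpec, LabelVolume
from shapeatlas.metrics import signed_distance, surface_distance_map
from shapeatlas.registration import (
    CostWeights,
    FixedTarget,
    MovingSubject,
    RegistrationConfig,
    TransformChain,
    composite_cost,
    initial_normalization,
    make_fixed_target,
    register_affine,
    register_elastic,
)
from shapeatlas.synthetic import PhantomParams, generate_subject

from conftest import RECOVERY_GEOMETRY


@pytest.fixture(scope="module")
def atlas_side(coarse_grid):
    """A canonical asymmetric phantom rendered as the fixed registration target."""
    rec = generate_subject(PhantomParams(seed=3, noise_sd=5.0, grid=coarse_grid, **RECOVERY_GEOMETRY))
    sdf_p = signed_distance(rec.prostate)
    sdf_cg = signed_distance(rec.cg)
    target = make_fixed_target(coarse_grid, rec.intensity.data, sdf_p.data, sdf_cg.data, band_mm=10.0)
    return rec, target


def _moving(**pose) -> MovingSubject:
    rec = generate_subject(PhantomParams(seed=3, noise_sd=5.0, **RECOVERY_GEOMETRY, **pose))
    return MovingSubject.from_record(rec)


CFG = RegistrationConfig()
W = CostWeights()


class TestInitialNormalization:
    def test_median_volume_gives_unit_scale(self, default_phantom):
        stage = initial_normalization(default_phantom, compute_volume_of(default_phantom))
        assert stage.scale == pytest.approx(1.0)

    def test_half_volume_closed_form(self, default_phantom):
        vol = compute_volume_of(default_phantom)
        stage = initial_normalization(default_phantom, vol / 2.0)
        assert stage.scale == pytest.approx(2.0 ** (-1 / 3), abs=1e-4)
        assert stage.scale == pytest.approx(0.7937, abs=5e-4)

    def test_normalized_volume_hits_median(self, default_phantom):
        from shapeatlas.atlas import warp_subject
        from shapeatlas.metrics import compute_volume

        vol = compute_volume_of(default_phantom)
        median = 45.0
        mov = MovingSubject.from_record(default_phantom)
        chain = TransformChain([initial_normalization(mov, median)])
        grid = GridSpec((60, 60, 60), (1.5, 1.5, 1.5), (-44.25, -44.25, -44.25))
        aligned = warp_subject(mov, chain, grid)
        got = float((aligned.sdf_p < 0).sum()) * 1.5**3 / 1000.0
        assert abs(got - median) / median < 0.03
        assert vol != pytest.approx(median)

    def test_zero_volume_rejected(self, default_phantom):
        with pytest.raises(ValueError):
            initial_normalization(default_phantom, 0.0)


def compute_volume_of(rec) -> float:
    from shapeatlas.metrics import compute_volume

    return compute_volume(rec.prostate)


class TestCompositeCost:
    def test_shape_terms_zero_at_self(self, atlas_side, coarse_grid):
        rec, target = atlas_side
        mov = MovingSubject(
            "self",
            rec.intensity,
            signed_distance(rec.prostate),
            signed_distance(rec.cg),
            compute_volume_of(rec),
        )
        c = composite_cost(mov, target, TransformChain([]), CostWeights(w_intensity=0.0))
        assert c == pytest.approx(0.0, abs=0.05)

    def test_translation_increases_cost(self, atlas_side):
        rec, target = atlas_side
        mov = MovingSubject(
            "self",
            rec.intensity,
            signed_distance(rec.prostate),
            signed_distance(rec.cg),
            compute_volume_of(rec),
        )
        from shapeatlas.registration import AffineStage

        shifted = TransformChain([AffineStage(translation=np.array([5.0, 0.0, 0.0]))])
        assert composite_cost(mov, target, shifted, W) > composite_cost(mov, target, TransformChain([]), W)

    def test_equal_weights_symmetric_in_structures(self, atlas_side):
        rec, target = atlas_side
        sdf_p = signed_distance(rec.prostate)
        sdf_cg = signed_distance(rec.cg)
        vol = compute_volume_of(rec)
        w = CostWeights(w_intensity=0.0, w_prostate=1.0, w_cg=1.0)
        mov = MovingSubject("a", rec.intensity, sdf_p, sdf_cg, vol)
        swapped_target = FixedTarget(
            target.grid,
            target.pts,
            target.sel_cg,
            target.sel_prostate,
            target.sdf_cg_vals,
            target.sdf_prostate_vals,
            target.intensity_vals,
        )
        swapped_mov = MovingSubject("b", rec.intensity, sdf_cg, sdf_p, vol)
        c1 = composite_cost(mov, target, TransformChain([]), w)
        c2 = composite_cost(swapped_mov, swapped_target, TransformChain([]), w)
        assert c1 == pytest.approx(c2, rel=1e-9)


class TestAffineRecovery:
    def test_self_registration_near_identity(self, atlas_side):
        _, target = atlas_side
        mov = _moving()
        init = initial_normalization(mov, mov.prostate_volume_ml)
        stage, _ = register_affine(mov, target, W, CFG, TransformChain([init]))
        assert np.abs(stage.translation).max() < 0.5
        assert np.abs(stage.rotation_deg).max() < 0.5

    def test_known_pose_recovered(self, atlas_side):
        _, target = atlas_side
        mov = _moving(rotation_deg=(5, 0, 0), translation_mm=(3, 2, 1))
        init = initial_normalization(mov, mov.prostate_volume_ml)
        stage, history = register_affine(mov, target, W, CFG, TransformChain([init]))
        # centroid translation is handled by the initialization; the affine
        # residual should recover the rotation and leave ~zero translation
        assert abs(stage.rotation_deg[0] - 5.0) < 1.0
        assert np.abs(stage.rotation_deg[1:]).max() < 1.0
        assert np.abs(stage.translation).max() < 1.0
        for level in history:  # quasi-Newton: accepted iterates never increase
            diffs = np.diff(level)
            assert (diffs <= 1e-8).all()

    def test_known_scale_recovered(self, atlas_side):
        _, target = atlas_side
        geo = {
            "prostate_semiaxes": tuple(1.1 * np.asarray(RECOVERY_GEOMETRY["prostate_semiaxes"])),
            "cg_semiaxes": tuple(1.1 * np.asarray(RECOVERY_GEOMETRY["cg_semiaxes"])),
            "bump_amplitude": RECOVERY_GEOMETRY["bump_amplitude"],
        }
        rec = generate_subject(PhantomParams(seed=3, noise_sd=5.0, **geo))
        mov = MovingSubject.from_record(rec)
        # initialization deliberately skips volume normalization (scale 1), so
        # the affine stage must recover the 1.10 linear scale itself
        init = initial_normalization(mov, mov.prostate_volume_ml)
        stage, _ = register_affine(mov, target, W, CFG, TransformChain([init]))
        np.testing.assert_allclose(np.exp(stage.log_scale), 1.10, rtol=0.02)

    def test_shape_terms_alone_suffice(self, atlas_side):
        _, target = atlas_side
        mov = _moving(rotation_deg=(4, 0, 0), translation_mm=(2, -2, 1))
        init = initial_normalization(mov, mov.prostate_volume_ml)
        stage, _ = register_affine(mov, target, CostWeights(w_intensity=0.0), CFG, TransformChain([init]))
        assert abs(stage.rotation_deg[0] - 4.0) < 1.0
        assert np.abs(stage.translation).max() < 1.0

    def test_rigid_dof_freezes_scale(self, atlas_side):
        _, target = atlas_side
        mov = _moving(translation_mm=(2, 1, 0))
        init = initial_normalization(mov, mov.prostate_volume_ml)
        stage, _ = register_affine(mov, target, W, CFG, TransformChain([init]), dof="rigid")
        np.testing.assert_array_equal(stage.log_scale, 0.0)


class TestElastic:
    def test_aligned_subject_small_displacement(self, atlas_side):
        _, target = atlas_side
        mov = _moving()
        init = initial_normalization(mov, mov.prostate_volume_ml)
        stage, _ = register_elastic(mov, target, W, CFG, TransformChain([init]))
        disp = stage.displacement(target.subsample(4000).pts)
        rms = float(np.sqrt((disp**2).sum(axis=1).mean()))
        assert rms < 0.5

    def test_displacement_cap_enforced(self, atlas_side):
        _, target = atlas_side
        mov = _moving(rotation_deg=(8, -4, 6))  # misaligned on purpose
        init = initial_normalization(mov, mov.prostate_volume_ml)
        cfg = RegistrationConfig(elastic_cap_mm=5.0)
        stage, _ = register_elastic(mov, target, W, cfg, TransformChain([init]))
        disp = stage.displacement(target.subsample(6000).pts)
        assert float(np.linalg.norm(disp, axis=1).max()) <= 5.0 + 1e-6

    def test_bump_residual_halved_by_elastic(self, coarse_grid):
        # a 4 mm CG bump against a bump-free atlas: the elastic stage should
        # remove at least half of the post-affine CG surface misfit
        atlas_rec = generate_subject(PhantomParams(seed=3, grid=coarse_grid))
        target = make_fixed_target(
            coarse_grid,
            atlas_rec.intensity.data,
            signed_distance(atlas_rec.prostate).data,
            signed_distance(atlas_rec.cg).data,
            band_mm=10.0,
        )
        mov = MovingSubject.from_record(generate_subject(PhantomParams(seed=3, bump_amplitude=4.0)))
        init = initial_normalization(mov, mov.prostate_volume_ml)
        cfg = RegistrationConfig(elastic_ctrl_spacing_mm=10.0)
        aff, _ = register_affine(mov, target, W, cfg, TransformChain([init]))
        chain_aff = TransformChain([init, aff])

        def mean_cg_dist(chain: TransformChain) -> float:
            pts = coarse_grid.blank().index_grid_world().reshape(-1, 3)
            mask = (mov.sample(mov.sdf_cg, chain.map_points(pts)) < 0).reshape(coarse_grid.shape)
            warped = signed_distance(
                LabelVolume(mask.astype(np.uint8), coarse_grid.spacing, coarse_grid.origin)
            )
            sd = surface_distance_map(warped, signed_distance(atlas_rec.cg))
            return float(np.abs(sd.distances).mean())

        d_affine = mean_cg_dist(chain_aff)
        elastic, residuals = register_elastic(mov, target, W, cfg, chain_aff)
        d_elastic = mean_cg_dist(chain_aff.with_stage(elastic))
        assert d_elastic <= 0.5 * d_affine
        assert "residual_mean_surface_distance_cg_mm" in residuals


class TestEquivariance:
    def test_pre_rotation_shifts_recovered_rotation(self, atlas_side):
        _, target = atlas_side
        base = _moving(rotation_deg=(0, 0, 2))
        init_b = initial_normalization(base, base.prostate_volume_ml)
        st_b, _ = register_affine(base, target, W, CFG, TransformChain([init_b]))
        c_b = composite_cost(base, target, TransformChain([init_b, st_b]), W)

        rot = _moving(rotation_deg=(0, 0, 8))  # extra 6 degrees about z
        init_r = initial_normalization(rot, rot.prostate_volume_ml)
        st_r, _ = register_affine(rot, target, W, CFG, TransformChain([init_r]))
        c_r = composite_cost(rot, target, TransformChain([init_r, st_r]), W)

        assert st_r.rotation_deg[2] - st_b.rotation_deg[2] == pytest.approx(6.0, abs=1.0)
        assert abs(c_r - c_b) <= 0.05 * abs(c_b) + 0.01


class TestSerialization:
    def test_chain_json_roundtrip(self, atlas_side):
        _, target = atlas_side
        mov = _moving(rotation_deg=(3, 1, -2))
        init = initial_normalization(mov, mov.prostate_volume_ml)
        aff, _ = register_affine(mov, target, W, CFG, TransformChain([init]))
        el, _ = register_elastic(mov, target, W, CFG, TransformChain([init, aff]))
        chain = TransformChain([init, aff, el])
        back = TransformChain.from_json(chain.to_json())
        pts = target.subsample(500).pts
        np.testing.assert_allclose(back.map_points(pts), chain.map_points(pts), atol=1e-8)
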