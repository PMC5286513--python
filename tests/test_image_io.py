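"""Image model, file round-trips, manifests and resampling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import SimpleITK as sitk

from shapeatlas.image import (
    FormatError,
    GridMismatchError,
    GridSpec,
    ImageVolume,
    LabelVolume,
    StudyManifest,
    SubjectRecord,
    load_study,
    read_volume,
    resample_to_common_grid,
    resample_volume,
    write_volume,
)
from shapeatlas.metrics import compute_volume, dice


def _sphere_mask(radius_mm: float, spacing, shape) -> LabelVolume:
    origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, spacing))
    vol = ImageVolume(np.zeros(shape, dtype=np.float32), spacing, origin)
    world = vol.index_grid_world()
    data = (np.linalg.norm(world, axis=-1) <= radius_mm).astype(np.uint8)
    return LabelVolume(data, spacing, origin)


class TestWorldMappingProperties:
    """The index<->world mapping is invertible for any valid geometry."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        spacing=st.tuples(*[st.floats(0.1, 5.0)] * 3),
        origin=st.tuples(*[st.floats(-100.0, 100.0)] * 3),
        ijk=st.tuples(st.integers(0, 7), st.integers(0, 7), st.integers(0, 3)),
    )
    @settings(max_examples=50, deadline=None)
    def test_index_world_roundtrip(self, spacing, origin, ijk):
        vol = ImageVolume(np.zeros((8, 8, 4)), spacing=spacing, origin=origin)
        back = vol.world_to_index(vol.index_to_world(np.array(ijk, dtype=float)))
        np.testing.assert_allclose(back, ijk, atol=1e-6)


class TestImageVolume:
    def test_positive_spacing_required(self):
        with pytest.raises(ValueError, match="spacing"):
            ImageVolume(np.zeros((4, 4, 4)), spacing=(1.0, -1.0, 1.0))

    def test_non_3d_rejected(self):
        with pytest.raises(FormatError):
            ImageVolume(np.zeros((4, 4)), spacing=(1, 1, 1))

    def test_world_mapping_roundtrip(self):
        vol = ImageVolume(np.zeros((5, 6, 7)), spacing=(0.7, 1.1, 3.0), origin=(-3, 2, 5))
        ijk = np.array([[0, 0, 0], [4, 5, 6], [2, 3, 1]], dtype=float)
        back = vol.world_to_index(vol.index_to_world(ijk))
        np.testing.assert_allclose(back, ijk, atol=1e-9)

    def test_label_values_restricted(self):
        with pytest.raises(ValueError, match="label"):
            LabelVolume(np.full((3, 3, 3), 2), spacing=(1, 1, 1))


class TestFileRoundTrip:
    @pytest.mark.parametrize("ext", [".nii.gz", ".nii", ".mha"])
    def test_label_roundtrip_exact(self, tmp_path, ext):
        rng = np.random.default_rng(0)
        lab = LabelVolume(
            (rng.random((16, 16, 8)) > 0.5).astype(np.uint8), (0.5, 0.5, 3.0), (1.0, -2.0, 0.5)
        )
        path = tmp_path / f"lab{ext}"
        write_volume(lab, path)
        back = read_volume(path, kind="label")
        assert isinstance(back, LabelVolume)
        np.testing.assert_array_equal(back.data, lab.data)
        np.testing.assert_allclose(back.spacing, lab.spacing)
        np.testing.assert_allclose(back.origin, lab.origin)

    def test_intensity_roundtrip_close(self, tmp_path):
        rng = np.random.default_rng(1)
        vol = ImageVolume(rng.normal(size=(10, 12, 6)).astype(np.float32), (1, 1, 2))
        path = tmp_path / "img.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.data, vol.data, rtol=1e-6)

    def test_4d_file_rejected(self, tmp_path):
        img = sitk.GetImageFromArray(np.zeros((2, 3, 4, 5), dtype=np.float32))
        path = tmp_path / "fourd.nii.gz"
        sitk.WriteImage(img, str(path))
        with pytest.raises(FormatError, match="3D"):
            read_volume(path)

    def test_unreadable_file(self, tmp_path):
        path = tmp_path / "junk.nii"
        path.write_bytes(b"not an image")
        with pytest.raises(FormatError):
            read_volume(path)

    def test_phantom_masks_roundtrip(self, tmp_path, default_phantom):
        for name, mask in (("prostate", default_phantom.prostate), ("cg", default_phantom.cg)):
            p = tmp_path / f"{name}.nii.gz"
            write_volume(mask, p)
            back = read_volume(p, kind="label")
            np.testing.assert_array_equal(back.data, mask.data)


def _write_subject(tmp_path, rec) -> dict:
    paths = {}
    for name, vol in (("intensity", rec.intensity), ("prostate", rec.prostate), ("cg", rec.cg)):
        p = tmp_path / f"{rec.subject_id}_{name}.nii.gz"
        write_volume(vol, p)
        paths[name] = p.name
    return paths


class TestStudyManifest:
    def _manifest(self, tmp_path, recs) -> StudyManifest:
        rows = []
        for rec in recs:
            paths = _write_subject(tmp_path, rec)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    **paths,
                    "group": rec.group,
                    "institution": rec.institution,
                    "rater": rec.rater,
                }
            )
        df = pd.DataFrame(rows)
        csv = tmp_path / "manifest.csv"
        df.to_csv(csv, index=False)
        return StudyManifest.from_csv(csv)

    def test_load_four_subjects_grouped(self, tmp_path, default_phantom):
        from dataclasses import replace

        recs = []
        for i, group in enumerate(["PCaPos", "PCaPos", "BxNeg", "BxNeg"]):
            inst = 1 if group == "PCaPos" else 2
            recs.append(
                replace(default_phantom, subject_id=f"s{i}", group=group, institution=inst)
            )
        loaded = load_study(self._manifest(tmp_path, recs))
        assert len(loaded) == 4
        assert sorted(r.group for r in loaded) == ["BxNeg", "BxNeg", "PCaPos", "PCaPos"]

    def test_cg_outside_prostate_clipped(self, tmp_path, default_phantom):
        from dataclasses import replace

        bad_cg = default_phantom.cg.data.copy()
        outside = np.argwhere(default_phantom.prostate.data == 0)[:3]
        bad_cg[tuple(outside.T)] = 1
        rec = replace(
            default_phantom,
            subject_id="bad",
            cg=LabelVolume(bad_cg, default_phantom.cg.spacing, default_phantom.cg.origin),
        )
        loaded = load_study(self._manifest(tmp_path, [rec]))
        assert (loaded[0].cg.data & ~loaded[0].prostate.data).sum() == 0

    def test_empty_manifest(self, tmp_path):
        df = pd.DataFrame(columns=["subject_id", "intensity", "prostate", "cg", "group", "institution", "rater"])
        csv = tmp_path / "m.csv"
        df.to_csv(csv, index=False)
        assert load_study(StudyManifest.from_csv(csv)) == []

    def test_grid_mismatch_names_subject(self, default_phantom):
        small = LabelVolume(np.ones((4, 4, 4), dtype=np.uint8), (1, 1, 1))
        with pytest.raises(GridMismatchError, match="oddone"):
            SubjectRecord(
                subject_id="oddone",
                intensity=default_phantom.intensity,
                prostate=small,
                cg=small,
                group="PCaPos",
            )

    def test_institution_constraint(self, default_phantom):
        from dataclasses import replace

        with pytest.raises(ValueError, match="institution"):
            replace(default_phantom, group="ClNeg", institution=2)


class TestResampling:
    def test_identity_resample(self, default_phantom):
        g = GridSpec(
            default_phantom.prostate.shape,
            default_phantom.prostate.spacing,
            default_phantom.prostate.origin,
        )
        out = resample_to_common_grid(default_phantom, g)
        np.testing.assert_array_equal(out.prostate.data, default_phantom.prostate.data)
        np.testing.assert_array_equal(out.cg.data, default_phantom.cg.data)

    def test_sphere_volume_preserved_on_coarsening(self):
        sphere = _sphere_mask(10.0, (1, 1, 1), (40, 40, 40))
        coarse = GridSpec((20, 20, 20), (2, 2, 2), sphere.origin)
        out = resample_volume(sphere, coarse, is_label=True)
        v_true = 4.0 / 3.0 * np.pi * 10**3 / 1000.0
        assert abs(compute_volume(out) - v_true) / v_true < 0.05

    def test_up_down_roundtrip_dice(self):
        sphere = _sphere_mask(12.0, (2, 2, 2), (24, 24, 24))
        fine = GridSpec((48, 48, 48), (1, 1, 1), sphere.origin)
        up = resample_volume(sphere, fine, is_label=True)
        back = resample_volume(up, GridSpec(sphere.shape, sphere.spacing, sphere.origin), is_label=True)
        assert dice(back, sphere) >= 0.98

    def test_clipping_target_rejected(self, default_phantom):
        tight = GridSpec((10, 10, 10), (1.0, 1.0, 1.0), (-5.0, -5.0, -5.0))
        with pytest.raises(ValueError, match="clips"):
            resample_to_common_grid(default_phantom, tight)
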