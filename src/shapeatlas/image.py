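"""Spatial image/label data model and medical-image I/O.

Volumes are stored as ``(nx, ny, nz)`` arrays indexed ``[i, j, k]`` with
voxel *centers* carrying world coordinates (millimetres)::

    world(i, j, k) = origin + orientation @ (i * dx, j * dy, k * dz)

The axis convention is axial LPS-like: x = left-right, y = anterior-posterior
(posterior = +y), z = inferior(apex)-superior(base).  File I/O goes through
SimpleITK, so NIfTI (.nii/.nii.gz) and MetaImage (.mha/.mhd) are both
supported with one code path.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage

logger = logging.getLogger(__name__)

GROUPS = ("PCaPos", "BxNeg", "ClNeg")
#: study-design constraint: which institutions may contribute each group
GROUP_INSTITUTIONS = {"PCaPos": (1, 2, 3), "BxNeg": (2, 3), "ClNeg": (1,)}


class FormatError(ValueError):
    """Unreadable or structurally invalid image file."""


class GridMismatchError(ValueError):
    """Volumes that must share one grid do not."""


def _as_tuple3(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in np.asarray(v).ravel())
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class ImageVolume:
    """A 3D scalar grid with anisotropic spacing and a world mapping."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise FormatError(f"volume must be 3D with each axis >= 1, got shape {self.data.shape}")
        self.spacing = _as_tuple3(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be strictly positive: {self.spacing}")
        self.origin = _as_tuple3(self.origin)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)

    # -- geometry -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return np.asarray(self.origin) + (ijk * np.asarray(self.spacing)) @ self.orientation.T

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`index_to_world`; returns continuous indices."""
        xyz = np.asarray(xyz, dtype=float)
        local = (xyz - np.asarray(self.origin)) @ np.linalg.inv(self.orientation).T
        return local / np.asarray(self.spacing)

    def index_grid_world(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (*grid, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n, dtype=float) for n in self.shape], indexing="ij"),
            axis=-1,
        )
        return self.index_to_world(idx)

    def same_grid(self, other: "ImageVolume", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.orientation, other.orientation, atol=atol)
        )

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        """Same grid, new voxel values."""
        return replace(self, data=data)


@dataclass
class LabelVolume(ImageVolume):
    """Binary structure mask (0 = background, 1 = structure)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"label values must be exactly {{0, 1}}, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)

    @property
    def volume_ml(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_mm3 / 1000.0


@dataclass
class GridSpec:
    """Target grid for resampling: shape, spacing, origin (identity orientation)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)  # type: ignore[assignment]
        self.spacing = _as_tuple3(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("target spacing must be positive")
        self.origin = _as_tuple3(self.origin)

    def blank(self, dtype=np.float32) -> ImageVolume:
        return ImageVolume(np.zeros(self.shape, dtype=dtype), self.spacing, self.origin)

    @property
    def world_min(self) -> np.ndarray:
        return np.asarray(self.origin)

    @property
    def world_max(self) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)


@dataclass
class SubjectRecord:
    """One subject: intensity volume + prostate/CG masks + metadata."""

    subject_id: str
    intensity: ImageVolume
    prostate: LabelVolume
    cg: LabelVolume
    group: str
    institution: int = 1
    rater: int = 1

    def __post_init__(self) -> None:
        for name, vol in (("prostate", self.prostate), ("cg", self.cg)):
            if not self.intensity.same_grid(vol):
                raise GridMismatchError(
                    f"subject {self.subject_id}: {name} grid does not match intensity grid"
                )
        if self.group in GROUP_INSTITUTIONS and self.institution not in GROUP_INSTITUTIONS[self.group]:
            raise ValueError(
                f"subject {self.subject_id}: group {self.group} not acquired at "
                f"institution {self.institution} in this study design"
            )

    def enforce_cg_inside_prostate(self) -> int:
        """Clip CG voxels outside the prostate; returns the clipped count."""
        outside = (self.cg.data == 1) & (self.prostate.data == 0)
        n = int(outside.sum())
        if n:
            data = self.cg.data.copy()
            data[outside] = 0
            self.cg = replace(self.cg, data=data)
            logger.warning("subject %s: clipped %d CG voxels outside prostate", self.subject_id, n)
        return n


# ----------------------------------------------------------------------
# File I/O
# ----------------------------------------------------------------------

def _sitk_to_volume(img: sitk.Image, kind: str) -> ImageVolume:
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 1:
        raise FormatError(
            f"expected a scalar 3D image, got {img.GetDimension()}D with "
            f"{img.GetNumberOfComponentsPerPixel()} components"
        )
    # sitk arrays come out (z, y, x); transpose to (x, y, z)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise FormatError(f"expected a 3D voxel array, got shape {arr.shape}")
    arr = arr.transpose(2, 1, 0)
    spacing = img.GetSpacing()
    origin = img.GetOrigin()
    orientation = np.asarray(img.GetDirection()).reshape(3, 3)
    if kind == "label":
        uniq = np.unique(arr)
        binar = (arr > 0.5).astype(np.uint8)
        if len(uniq) > 2:
            logger.warning("label file has %d distinct values; mapping > 0.5 to 1", len(uniq))
        return LabelVolume(binar, spacing, origin, orientation)
    return ImageVolume(arr.astype(np.float32), spacing, origin, orientation)


def read_volume(path: str | Path, kind: str = "intensity") -> ImageVolume:
    """Read a NIfTI or MetaImage file as an :class:`ImageVolume` or :class:`LabelVolume`.

    Parameters
    ----------
    path:
        ``.nii``, ``.nii.gz``, ``.mha`` or ``.mhd`` file.
    kind:
        ``"intensity"`` or ``"label"``; label data are binarized at 0.5.
    """
    if kind not in ("intensity", "label"):
        raise ValueError(f"kind must be 'intensity' or 'label', got {kind!r}")
    try:
        img = sitk.ReadImage(os.fspath(path))
    except RuntimeError as exc:  # sitk wraps unreadable files in RuntimeError
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    return _sitk_to_volume(img, kind)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write a volume to NIfTI or MetaImage (format chosen by extension)."""
    arr = vol.data
    if isinstance(vol, LabelVolume):
        arr = arr.astype(np.uint8)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    img.SetDirection(tuple(vol.orientation.ravel()))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, os.fspath(path))


# ----------------------------------------------------------------------
# Study manifests
# ----------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "intensity", "prostate", "cg", "group", "institution", "rater"]


@dataclass
class StudyManifest:
    """Table of subjects and their on-disk volumes."""

    table: pd.DataFrame
    root: Path | None = None

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        dup = self.table.duplicated(subset=["subject_id", "rater"])
        if dup.any():
            raise ValueError(
                f"duplicate (subject_id, rater) rows: {self.table.loc[dup, 'subject_id'].tolist()}"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "StudyManifest":
        return cls(pd.read_csv(path), root=Path(path).parent)

    def to_csv(self, path: str | Path) -> None:
        self.table[MANIFEST_COLUMNS].to_csv(path, index=False)

    def _resolve(self, p: str) -> Path:
        q = Path(p)
        if not q.is_absolute() and self.root is not None:
            q = self.root / q
        return q

    def validate_files(self) -> None:
        for _, row in self.table.iterrows():
            for col in ("intensity", "prostate", "cg"):
                p = self._resolve(row[col])
                if not p.exists():
                    raise FileNotFoundError(f"subject {row['subject_id']}: missing file {p}")


def load_study(manifest: StudyManifest) -> list[SubjectRecord]:
    """Load every subject in the manifest, enforcing the CG-inside-prostate invariant.

    CG voxels outside the prostate are clipped with a logged count; a grid
    mismatch between a subject's volumes is a hard error naming the subject.
    """
    manifest.validate_files()
    records: list[SubjectRecord] = []
    for _, row in manifest.table.iterrows():
        rec = SubjectRecord(
            subject_id=str(row["subject_id"]),
            intensity=read_volume(manifest._resolve(row["intensity"]), "intensity"),
            prostate=read_volume(manifest._resolve(row["prostate"]), "label"),  # type: ignore[arg-type]
            cg=read_volume(manifest._resolve(row["cg"]), "label"),  # type: ignore[arg-type]
            group=str(row["group"]),
            institution=int(row["institution"]),
            rater=int(row["rater"]),
        )
        rec.enforce_cg_inside_prostate()
        records.append(rec)
    return records


def select_subjects(
    records: Iterable[SubjectRecord],
    group: str | None = None,
    institution: int | None = None,
    rater: int | None = None,
) -> list[SubjectRecord]:
    out = []
    for r in records:
        if group is not None and r.group != group:
            continue
        if institution is not None and r.institution != institution:
            continue
        if rater is not None and r.rater != rater:
            continue
        out.append(r)
    return out


# ----------------------------------------------------------------------
# Resampling
# ----------------------------------------------------------------------

def _sample_linear(vol: ImageVolume, world_pts: np.ndarray, cval: float = 0.0) -> np.ndarray:
    """Trilinear interpolation of `vol` at world points of shape (..., 3)."""
    idx = vol.world_to_index(world_pts)
    coords = np.moveaxis(idx, -1, 0)
    return ndimage.map_coordinates(
        vol.data.astype(np.float32), coords, order=1, mode="constant", cval=cval
    )


def resample_volume(vol: ImageVolume, target: GridSpec, is_label: bool | None = None) -> ImageVolume:
    """Resample one volume to a target grid (trilinear; labels re-thresholded at 0.5)."""
    if is_label is None:
        is_label = isinstance(vol, LabelVolume)
    tgt = target.blank()
    pts = tgt.index_grid_world()
    vals = _sample_linear(vol, pts)
    if is_label:
        return LabelVolume((vals > 0.5).astype(np.uint8), target.spacing, target.origin)
    return ImageVolume(vals.astype(np.float32), target.spacing, target.origin)


def resample_to_common_grid(
    subject: SubjectRecord, target: GridSpec, margin_mm: float = 5.0
) -> SubjectRecord:
    """Resample a subject's three volumes to a common target grid.

    The target must cover the prostate bounding box with at least
    ``margin_mm`` on every side; otherwise an error lists the clipped extent.
    Labels are resampled by trilinear interpolation of the binary map followed
    by a 0.5 threshold, which reduces stair-casing at coarse slice spacings.
    """
    mask_idx = np.argwhere(subject.prostate.data > 0)
    if mask_idx.size == 0:
        raise ValueError(f"subject {subject.subject_id}: empty prostate mask")
    corners = subject.prostate.index_to_world(mask_idx)
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    t_lo, t_hi = target.world_min, target.world_max
    clip_lo = np.maximum(t_lo + margin_mm - lo, 0.0)
    clip_hi = np.maximum(hi + margin_mm - t_hi, 0.0)
    if (clip_lo > 0).any() or (clip_hi > 0).any():
        raise ValueError(
            f"target grid clips prostate (+{margin_mm} mm margin) by "
            f"{clip_lo.round(2).tolist()} mm (low) / {clip_hi.round(2).tolist()} mm (high)"
        )
    rec = SubjectRecord(
        subject_id=subject.subject_id,
        intensity=resample_volume(subject.intensity, target, is_label=False),
        prostate=resample_volume(subject.prostate, target, is_label=True),  # type: ignore[arg-type]
        cg=resample_volume(subject.cg, target, is_label=True),  # type: ignore[arg-type]
        group=subject.group,
        institution=subject.institution,
        rater=subject.rater,
    )
    rec.enforce_cg_inside_prostate()
    return rec
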