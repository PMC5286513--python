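"""Core shape computations: volumes, signed distances, overlap agreement, surface distances.

The signed distance function (SDF) is the substrate of all atlas work here:
each voxel carries its Euclidean distance in millimetres to the structure
surface, negative inside.  Averaging SDFs over a population and extracting
the zero level set yields a mean shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import ImageVolume, LabelVolume


@dataclass
class SignedDistanceMap(ImageVolume):
    """Per-voxel signed Euclidean distance (mm) to a structure surface.

    Sign convention: strictly negative inside, strictly positive outside
    (``inside_negative`` records it).  Thresholding at 0 recovers the source
    mask.
    """

    inside_negative: bool = True

    def mask(self) -> LabelVolume:
        """Zero-level-set extraction back to a binary mask."""
        inside = self.data < 0 if self.inside_negative else self.data > 0
        return LabelVolume(inside.astype(np.uint8), self.spacing, self.origin, self.orientation)


def compute_volume(mask: LabelVolume) -> float:
    """Structure volume in ml: voxel count x (dx * dy * dz) / 1000."""
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume_mm3 / 1000.0


def signed_distance(mask: LabelVolume) -> SignedDistanceMap:
    """Exact Euclidean SDF on the anisotropic grid, inside negative.

    Combines the outside distance transform (distance of background voxels to
    the structure) with the inside transform (distance of structure voxels to
    the background).  Raises on empty or full masks, which have no surface.
    """
    m = mask.data > 0
    n_in = int(m.sum())
    if n_in == 0 or n_in == m.size:
        raise ValueError("mask is empty or fills the grid: no surface to measure from")
    d_out = ndimage.distance_transform_edt(~m, sampling=mask.spacing)
    d_in = ndimage.distance_transform_edt(m, sampling=mask.spacing)
    return SignedDistanceMap(
        (d_out - d_in).astype(np.float32), mask.spacing, mask.origin, mask.orientation
    )


def dice(mask_a: LabelVolume | np.ndarray, mask_b: LabelVolume | np.ndarray) -> float:
    a = (mask_a.data if isinstance(mask_a, ImageVolume) else np.asarray(mask_a)) > 0
    b = (mask_b.data if isinstance(mask_b, ImageVolume) else np.asarray(mask_b)) > 0
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


# ----------------------------------------------------------------------
# Inter-rater agreement
# ----------------------------------------------------------------------

def default_kappa_domain(mask_a: LabelVolume, mask_b: LabelVolume, dilation_mm: float = 5.0) -> LabelVolume:
    """Evaluation domain for kappa: union of both masks dilated by `dilation_mm`.

    Computing kappa over the whole image inflates agreement through the vast
    background; restricting to a neighbourhood of the structures keeps the
    chance-correction meaningful.
    """
    union = (mask_a.data > 0) | (mask_b.data > 0)
    d = ndimage.distance_transform_edt(~union, sampling=mask_a.spacing)
    dom = union | (d <= dilation_mm)
    return LabelVolume(dom.astype(np.uint8), mask_a.spacing, mask_a.origin, mask_a.orientation)


def cohen_kappa(
    mask_a: LabelVolume, mask_b: LabelVolume, domain: LabelVolume | None = None
) -> float:
    """Cohen's kappa on the 2x2 voxel-label contingency within `domain`.

    kappa = (p_o - p_e) / (1 - p_e); bounded in [-1, 1], 1 iff the masks are
    identical on the domain.  If both raters are constant on the domain
    (p_e = 1), kappa is 1 when they agree everywhere and an error otherwise.
    """
    if not (mask_a.same_grid(mask_b)):
        raise ValueError("kappa requires both masks on one grid")
    if domain is None:
        domain = default_kappa_domain(mask_a, mask_b)
    dom = domain.data > 0
    if not dom.any():
        raise ValueError("empty evaluation domain")
    a = mask_a.data[dom] > 0
    b = mask_b.data[dom] > 0
    n = dom.sum()
    n11 = float((a & b).sum())
    n10 = float((a & ~b).sum())
    n01 = float((~a & b).sum())
    n00 = float((~a & ~b).sum())
    p_o = (n11 + n00) / n
    p_e = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (n * n)
    if p_e >= 1.0 - 1e-12:
        if p_o >= 1.0 - 1e-12:
            return 1.0
        raise ValueError("degenerate contingency: both raters constant but not in agreement")
    return (p_o - p_e) / (1.0 - p_e)


def kappa_from_contingency(n11: float, n10: float, n01: float, n00: float) -> float:
    """Closed-form Cohen's kappa from 2x2 counts (agreement cells n11, n00)."""
    n = n11 + n10 + n01 + n00
    p_o = (n11 + n00) / n
    p_e = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / (n * n)
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class AgreementResult:
    """Per-subject, per-structure kappa values with study-level summaries."""

    per_subject: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["subject_id", "structure", "kappa"])
    )

    def add(self, subject_id: str, structure: str, kappa: float) -> None:
        self.per_subject.loc[len(self.per_subject)] = [subject_id, structure, float(kappa)]

    def summary(self) -> pd.DataFrame:
        g = self.per_subject.groupby("structure")["kappa"]
        out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1).fillna(0.0), "n": g.count()})
        return out

    def formatted(self) -> dict[str, str]:
        """Mean +/- sd to two decimals per structure, e.g. '0.98 ± 0.03'."""
        return {
            s: f"{row['mean']:.2f} ± {row['sd']:.2f}" for s, row in self.summary().iterrows()
        }


# ----------------------------------------------------------------------
# Surface distances
# ----------------------------------------------------------------------

def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean map of structure voxels with at least one background face-neighbour."""
    m = np.asarray(mask) > 0
    # border_value=1 so voxels touching the array edge are not spuriously
    # flagged: the distance transform likewise sees no background beyond it
    eroded = ndimage.binary_erosion(
        m, structure=ndimage.generate_binary_structure(3, 1), border_value=1
    )
    return m & ~eroded


@dataclass
class SurfaceDistanceMap:
    """Signed distance (mm) from each boundary voxel of shape A to shape B's surface.

    Positive values mean A's surface lies outside B at that point.
    """

    indices: np.ndarray  # (N, 3) voxel indices on A's boundary
    distances: np.ndarray  # (N,) signed mm
    grid: ImageVolume  # carries shape/spacing/origin of the common grid

    def as_volume(self, background: float = 0.0) -> ImageVolume:
        out = np.full(self.grid.shape, background, dtype=np.float32)
        out[tuple(self.indices.T)] = self.distances
        return ImageVolume(out, self.grid.spacing, self.grid.origin, self.grid.orientation)

    @property
    def max_abs(self) -> float:
        return float(np.abs(self.distances).max()) if self.distances.size else 0.0

    def world_points(self) -> np.ndarray:
        return self.grid.index_to_world(self.indices)


def surface_distance_map(sdf_a: SignedDistanceMap, sdf_b: SignedDistanceMap) -> SurfaceDistanceMap:
    """Signed distance from A's surface to B's surface at A's boundary voxels.

    Both SDFs are near-unit-gradient fields, so the distance between their
    zero level sets is their pointwise difference ``sdfB - sdfA`` evaluated
    near A's surface.  Using the difference (rather than sampling ``sdfB``
    alone) cancels the half-voxel offset both discrete transforms share, so
    identical shapes give exact zeros.
    """
    if not sdf_a.same_grid(sdf_b):
        raise ValueError("surface distance requires both SDFs on one grid")
    bnd = boundary_voxels(sdf_a.data < 0)
    idx = np.argwhere(bnd)
    if idx.size == 0:
        raise ValueError("shape A has an empty zero level set")
    vals = (sdf_b.data[bnd] - sdf_a.data[bnd]).astype(np.float64)
    return SurfaceDistanceMap(indices=idx, distances=vals, grid=sdf_a)
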