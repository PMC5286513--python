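"""Synthetic phantom cohorts with the statistical structure the atlas analysis assumes.

Subjects are ellipsoid prostates containing an ellipsoid central gland (CG),
posed with random rotation/translation and random overall size.  Disease-like
group effects are modelled as (a) CG hypertrophy — the benign-hyperplasia-like
volume contrast in which one group's CG is about twice the other's — and
(b) a localized radial outward bump on the posterior CG surface of up to a few
millimetres, the kind of focal boundary distension a peripheral-zone tumour
produces against the CG.  Ellipsoids are used instead of learned prostate
shapes because they admit analytic volume and distance oracles; the pipeline's
correctness claims are geometric and statistical, not anatomical.

Intensity is a two-compartment T2w-like model: bright outside-CG shell, darker
heterogeneous CG, dark background, additive Gaussian noise, and an optional
posterior-weighted multiplicative gain imitating an endorectal receiver coil.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image import GridSpec, ImageVolume, LabelVolume, SubjectRecord

#: default phantom grid: anisotropic slices at desk scale
DEFAULT_GRID = GridSpec(shape=(96, 96, 48), spacing=(1.0, 1.0, 2.0), origin=(-47.5, -47.5, -47.0))

#: rater boundary jitter (mm RMS of the displacement magnitude) calibrated once
#: so that prostate kappa against the original annotation lands in [0.95, 0.995]
#: at the default phantom size; fixed here, not re-tuned per study.
DEFAULT_RATER_JITTER_MM = 0.6

_INTENSITY = {"background": 30.0, "shell": 180.0, "cg": 110.0, "cg_texture": 22.0}


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def _rotation_matrix(angles_deg) -> np.ndarray:
    """Intrinsic XYZ Euler rotation, angles in degrees."""
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cx, sx, cy, sy, cz, sz = np.cos(ax), np.sin(ax), np.cos(ay), np.sin(ay), np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass
class PhantomParams:
    """Geometry, pose, effect and appearance of one phantom subject.

    Semiaxes are in mm; the default prostate (22, 18, 20) mm is ~33 ml,
    inside the 30-80 ml range typical of the gland.  ``bump_center`` points
    posterior-superior by default (posterior CG base, where focal effects are
    placed).  ``hypertrophy_factor`` multiplies CG *volume* (semiaxes scale by
    its cube root).
    """

    prostate_semiaxes: tuple[float, float, float] = (22.0, 18.0, 20.0)
    cg_semiaxes: tuple[float, float, float] = (14.0, 10.0, 12.0)
    cg_offset: tuple[float, float, float] = (0.0, -2.0, 2.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    bump_amplitude: float = 0.0
    bump_center: tuple[float, float, float] = (0.0, 1.0, 0.5)
    bump_width_deg: float = 35.0
    hypertrophy_factor: float = 1.0
    surface_noise_mm: float = 0.0
    noise_sd: float = 8.0
    bias_field: str = "none"  # {"none", "endorectal"}
    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: DEFAULT_GRID)

    def __post_init__(self) -> None:
        if self.bump_amplitude < 0:
            raise ValueError("bump_amplitude must be >= 0")
        if self.hypertrophy_factor <= 0:
            raise ValueError("hypertrophy_factor must be > 0")
        if self.bias_field not in ("none", "endorectal"):
            raise ValueError(f"unknown bias_field {self.bias_field!r}")

    @property
    def cg_semiaxes_effective(self) -> np.ndarray:
        return np.asarray(self.cg_semiaxes) * self.hypertrophy_factor ** (1.0 / 3.0)

    def validate_geometry(self, n_dirs: int = 800) -> None:
        """Fail if the (pre-bump) CG ellipsoid is not strictly inside the prostate."""
        dirs = _fibonacci_sphere(n_dirs)
        a_cg = self.cg_semiaxes_effective
        r_cg = 1.0 / np.sqrt(((dirs / a_cg) ** 2).sum(axis=1))
        pts = np.asarray(self.cg_offset) + dirs * r_cg[:, None]
        q = ((pts / np.asarray(self.prostate_semiaxes)) ** 2).sum(axis=1)
        if (q >= 1.0).any():
            raise ValueError(
                "CG ellipsoid (after offset and hypertrophy "
                f"{self.hypertrophy_factor:g}) is not strictly inside the prostate"
            )


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _sphere_field(rng: np.random.Generator, dirs: np.ndarray, rms_mm: float) -> np.ndarray:
    """Smooth zero-mean random field on the unit sphere, sampled at `dirs`.

    Band-limited by construction (Gaussian-filtered white noise on a coarse
    3D grid, evaluated on the sphere), with angular correlation of roughly
    15-25 degrees — inter-subject surface variability that a coarse
    free-form deformation cannot fully absorb.
    """
    grid = ndimage.gaussian_filter(rng.standard_normal((16, 16, 16)), sigma=2.0, mode="wrap")
    coords = (dirs.reshape(-1, 3).T + 1.0) * 7.0  # map [-1, 1] into the grid
    vals = ndimage.map_coordinates(grid, coords, order=1, mode="wrap")
    vals = vals - vals.mean()
    rms = max(np.sqrt((vals**2).mean()), 1e-9)
    return (vals * (rms_mm / rms)).reshape(dirs.shape[:-1])


def _radial_masks(params: PhantomParams, world: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (prostate, cg) membership for world points of shape (..., 3).

    Both structures are star-shaped radial surfaces: an ellipsoid radius plus
    (for the CG) a radial outward Gaussian bump around ``bump_center`` and
    (for both) a smooth per-subject surface perturbation of RMS
    ``surface_noise_mm``.  Wherever the CG surface would exit the prostate,
    the prostate surface is pushed out to CG + 1 mm, i.e. the bump propagates
    to the outer gland boundary rather than violating CG inside prostate.
    """
    rot = _rotation_matrix(params.rotation_deg)
    local = (world - np.asarray(params.translation_mm)) @ rot  # R^T applied to rows
    noise_rng = np.random.default_rng(params.seed + 777_001)

    def _radial(centered: np.ndarray, semiaxes: np.ndarray, extra=None) -> np.ndarray:
        """surface radius minus point radius (>= 0 means inside)."""
        r = np.linalg.norm(centered, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = centered / np.where(r[..., None] > 0, r[..., None], 1.0)
        r_surf = 1.0 / np.sqrt(((u / semiaxes) ** 2).sum(axis=-1))
        if extra is not None:
            r_surf = r_surf + extra(u)
        if params.surface_noise_mm > 0:
            r_surf = r_surf + _sphere_field(noise_rng, u, params.surface_noise_mm)
        return r_surf - r

    def _bump(u: np.ndarray) -> np.ndarray:
        cosang = np.clip(u @ _unit(params.bump_center), -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
        return params.bump_amplitude * np.exp(-0.5 * (ang / params.bump_width_deg) ** 2)

    margin_p = _radial(local, np.asarray(params.prostate_semiaxes, dtype=float))
    margin_cg = _radial(
        local - np.asarray(params.cg_offset),
        params.cg_semiaxes_effective,
        extra=_bump if params.bump_amplitude > 0 else None,
    )
    cg = margin_cg >= 0
    # propagate any CG excursion to the prostate surface (+1 mm margin)
    prostate = (margin_p >= 0) | (margin_cg >= -1.0)
    return prostate, cg


def generate_subject(
    params: PhantomParams,
    subject_id: str = "phantom",
    group: str = "PCaPos",
    institution: int = 1,
    rater: int = 1,
) -> SubjectRecord:
    """Rasterize one phantom subject; deterministic given ``params.seed``."""
    params.validate_geometry()
    rng = np.random.default_rng(params.seed)
    grid = params.grid
    blank = grid.blank()
    world = blank.index_grid_world()
    pro, cg = _radial_masks(params, world)
    cg &= pro

    inten = np.full(grid.shape, _INTENSITY["background"], dtype=np.float32)
    inten[pro] = _INTENSITY["shell"]
    texture = ndimage.gaussian_filter(rng.standard_normal(grid.shape), sigma=3.0)
    texture /= max(texture.std(), 1e-9)
    inten[cg] = _INTENSITY["cg"] + _INTENSITY["cg_texture"] * texture[cg]
    if params.bias_field == "endorectal":
        y = world[..., 1]
        gain = 1.0 + 1.0 * np.exp(-(((y.max() - y) / 30.0) ** 2))
        inten *= gain.astype(np.float32)
    if params.noise_sd > 0:
        inten = inten + rng.normal(0.0, params.noise_sd, grid.shape).astype(np.float32)

    return SubjectRecord(
        subject_id=subject_id,
        intensity=ImageVolume(inten.astype(np.float32), grid.spacing, grid.origin),
        prostate=LabelVolume(pro.astype(np.uint8), grid.spacing, grid.origin),
        cg=LabelVolume(cg.astype(np.uint8), grid.spacing, grid.origin),
        group=group,
        institution=institution,
        rater=rater,
    )


# ----------------------------------------------------------------------
# Cohorts
# ----------------------------------------------------------------------

@dataclass
class GroupSpec:
    """A subpopulation recipe: base phantom, population spread, and group effect.

    ``scale_sd`` is the fractional standard deviation of the *volume* scale
    factor (drawn log-normal; semiaxes scale by its cube root), so
    ``scale_sd=0.3`` produces ~30% volume spread.  ``shape_sd`` is the
    fractional per-axis semiaxis spread (anatomical shape variability beyond
    overall size) and ``surface_noise_mm`` the RMS of each subject's smooth
    surface irregularity; together they provide the residual between-subject
    variability that survives registration, without which per-voxel group
    statistics would be degenerate.  ``bump_amplitude`` and
    ``hypertrophy_factor`` are the group-level effect means.
    """

    n: int
    label: str = "PCaPos"
    institution: int = 1
    base: PhantomParams = field(default_factory=PhantomParams)
    scale_sd: float = 0.15
    shape_sd: float = 0.04
    surface_noise_mm: float = 0.8
    rotation_sd_deg: float = 5.0
    translation_sd_mm: float = 3.0
    bump_amplitude: float = 0.0
    hypertrophy_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size n must be >= 1")
        for name in ("scale_sd", "shape_sd", "surface_noise_mm", "rotation_sd_deg", "translation_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class EffectGroundTruth:
    """World-space region where the two groups' expected CG surfaces differ by > 1 mm."""

    mask: LabelVolume
    threshold_mm: float = 1.0

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.data.any())

    def centroid_world(self) -> np.ndarray:
        idx = np.argwhere(self.mask.data > 0)
        if idx.size == 0:
            raise ValueError("empty effect region has no centroid")
        return self.mask.index_to_world(idx).mean(axis=0)


def _canonical_params(spec: GroupSpec) -> PhantomParams:
    return replace(
        spec.base,
        rotation_deg=(0.0, 0.0, 0.0),
        translation_mm=(0.0, 0.0, 0.0),
        bump_amplitude=spec.bump_amplitude,
        hypertrophy_factor=spec.hypertrophy_factor,
        noise_sd=0.0,
    )


def effect_ground_truth(
    spec_a: GroupSpec, spec_b: GroupSpec, threshold_mm: float = 1.0
) -> EffectGroundTruth:
    """Expected between-group CG difference region at the canonical pose.

    Both groups are rendered with their mean parameters (no pose/size noise);
    the effect region is where CG membership differs and the CG signed
    distances disagree by more than ``threshold_mm``.
    """
    from .metrics import signed_distance  # local import to avoid a cycle

    rec_a = generate_subject(_canonical_params(spec_a), "gtA")
    rec_b = generate_subject(_canonical_params(spec_b), "gtB")
    sdf_a = signed_distance(rec_a.cg)
    sdf_b = signed_distance(rec_b.cg)
    differ = (sdf_a.data < 0) != (sdf_b.data < 0)
    region = differ & (np.abs(sdf_a.data - sdf_b.data) > threshold_mm)
    mask = LabelVolume(
        region.astype(np.uint8), rec_a.cg.spacing, rec_a.cg.origin, rec_a.cg.orientation
    )
    return EffectGroundTruth(mask=mask, threshold_mm=threshold_mm)


def _draw_params(spec: GroupSpec, rng: np.random.Generator, seed: int) -> PhantomParams:
    vol_scale = float(np.exp(rng.normal(0.0, np.log1p(spec.scale_sd))))
    lin = vol_scale ** (1.0 / 3.0)
    # per-axis shape factors, clipped at 2 sd so CG-inside-prostate stays feasible
    sig = np.log1p(spec.shape_sd)
    ax_p = np.exp(np.clip(rng.normal(0.0, sig, 3), -2 * sig, 2 * sig))
    ax_cg = np.exp(np.clip(rng.normal(0.0, sig, 3), -2 * sig, 2 * sig))
    return replace(
        spec.base,
        prostate_semiaxes=tuple(np.asarray(spec.base.prostate_semiaxes) * lin * ax_p),
        cg_semiaxes=tuple(np.asarray(spec.base.cg_semiaxes) * lin * ax_cg),
        rotation_deg=tuple(rng.normal(0.0, spec.rotation_sd_deg, 3)),
        translation_mm=tuple(rng.normal(0.0, spec.translation_sd_mm, 3)),
        bump_amplitude=spec.bump_amplitude,
        hypertrophy_factor=spec.hypertrophy_factor,
        surface_noise_mm=spec.surface_noise_mm,
        seed=seed,
    )


def generate_cohort(
    spec_a: GroupSpec, spec_b: GroupSpec, seed: int = 0
) -> tuple[list[SubjectRecord], EffectGroundTruth]:
    """Draw both groups' subjects and the ground-truth effect region.

    Per-subject parameters come from the spec's population distributions
    (log-normal size, Gaussian rotation/translation); all randomness flows
    from ``seed`` so cohorts are bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    for spec, prefix in ((spec_a, "A"), (spec_b, "B")):
        for i in range(spec.n):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            params = _draw_params(spec, rng, sub_seed)
            records.append(
                generate_subject(
                    params,
                    subject_id=f"{prefix}{i:03d}",
                    group=spec.label,
                    institution=spec.institution,
                )
            )
    return records, effect_ground_truth(spec_a, spec_b)


# ----------------------------------------------------------------------
# Rater simulation
# ----------------------------------------------------------------------

def simulate_rater(
    subject: SubjectRecord,
    jitter_mm: float = DEFAULT_RATER_JITTER_MM,
    seed: int = 0,
    smoothness_mm: float = 6.0,
) -> SubjectRecord:
    """Re-annotate a subject with a second rater's smooth boundary jitter.

    A Gaussian-filtered white-noise displacement field, scaled so the RMS of
    its vector magnitude is ``jitter_mm``, warps both masks; the CG-inside-
    prostate invariant is re-enforced and the rater tag set to 2.
    """
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be >= 0")
    if jitter_mm == 0:
        return replace(subject, rater=2)
    rng = np.random.default_rng(seed)
    spacing = np.asarray(subject.prostate.spacing)
    shape = subject.prostate.shape
    sigma_vox = smoothness_mm / spacing
    disp = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox) for _ in range(3)]
    )
    rms = np.sqrt((disp**2).sum(axis=0).mean())
    disp *= jitter_mm / max(rms, 1e-12)  # mm

    idx = np.indices(shape, dtype=np.float32)
    coords = idx + disp / spacing[:, None, None, None]

    def _warp(mask: LabelVolume) -> LabelVolume:
        vals = ndimage.map_coordinates(
            mask.data.astype(np.float32), coords, order=1, mode="constant", cval=0.0
        )
        return LabelVolume((vals > 0.5).astype(np.uint8), mask.spacing, mask.origin, mask.orientation)

    rec = replace(subject, prostate=_warp(subject.prostate), cg=_warp(subject.cg), rater=2)
    rec.enforce_cg_inside_prostate()
    return rec
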