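"""Anatomically constrained subject-to-atlas registration.

The registration aligns one subject to an atlas by minimizing a three-term
scoring function

    cost = w_i * D_int + w_p * D_shape(prostate) + w_cg * D_shape(CG)

where each shape term is the mean squared difference between the subject's
signed distance function (SDF), sampled through the transform, and the atlas
mean SDF, restricted to a band around the atlas surface; the intensity term
is the negated normalized cross-correlation of the T2w-like intensities over
the same band region.  The two shape weights are equal by default.

The transform hierarchy grows in complexity:

1. initialization — translation of the prostate centroid to the atlas
   center plus isotropic scaling to a common (median) prostate volume;
2. affine — translation + rotation + anisotropic scale;
3. elastic — a cubic B-spline free-form deformation whose control-point
   displacements are hard-bounded, the concrete anatomical constraint that
   prevents unrealistic deformations.

All transforms are stored as backward maps (atlas-space point -> subject-space
point), the convention used for resampling.  Optimization is deterministic:
quasi-Newton with fixed iteration budgets and no stochastic sampling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize, sparse

from .image import GridSpec, ImageVolume, SubjectRecord
from .metrics import SignedDistanceMap, compute_volume, signed_distance

logger = logging.getLogger(__name__)

_PENALTY = 1.0e6


# ----------------------------------------------------------------------
# Transform stages
# ----------------------------------------------------------------------

def _rotation_matrix_deg(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cx, sx, cy, sy, cz, sz = np.cos(ax), np.sin(ax), np.cos(ay), np.sin(ay), np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass
class SimilarityStage:
    """Initialization: atlas point -> subject point about the prostate centroid.

    ``scale`` is the forward volume-normalization factor s =
    (median_volume / subject_volume)^(1/3); the backward map divides by it.
    """

    centroid: np.ndarray
    scale: float

    kind = "similarity"

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(self.centroid) + pts / self.scale

    def jacobian(self) -> np.ndarray:
        return np.eye(3) / self.scale

    def to_dict(self) -> dict:
        return {"kind": self.kind, "centroid": list(map(float, self.centroid)), "scale": float(self.scale)}


@dataclass
class AffineStage:
    """Affine backward map about the atlas center: x' = R S x + t.

    Parameterized by translation (mm), intrinsic XYZ Euler angles (deg) and
    per-axis log-scales.  Shears are deliberately excluded: the stage models
    the pose-and-size residual the initialization leaves behind.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    log_scale: np.ndarray = field(default_factory=lambda: np.zeros(3))
    converged: bool = True

    kind = "affine"

    @classmethod
    def from_params(cls, p: np.ndarray) -> "AffineStage":
        p = np.asarray(p, dtype=float)
        return cls(translation=p[0:3].copy(), rotation_deg=p[3:6].copy(), log_scale=p[6:9].copy())

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation_deg, self.log_scale])

    def matrix(self) -> np.ndarray:
        return _rotation_matrix_deg(self.rotation_deg) @ np.diag(np.exp(self.log_scale))

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.matrix().T + self.translation

    def jacobian(self) -> np.ndarray:
        return self.matrix()

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "translation": self.translation.tolist(),
            "rotation_deg": self.rotation_deg.tolist(),
            "log_scale": self.log_scale.tolist(),
            "converged": bool(self.converged),
        }


def _bspline_basis(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis values B0..B3 at fractional offsets t, shape (4, ...)."""
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ]
    )


@dataclass
class ElasticStage:
    """Cubic B-spline free-form deformation: x' = x + D(x) in atlas space.

    ``coefficients`` has shape (ncx, ncy, ncz, 3) (mm).  Because the cubic
    B-spline basis is a nonnegative partition of unity, bounding every
    coefficient component by cap/sqrt(3) bounds the Euclidean displacement of
    every point by ``displacement_cap_mm``.
    """

    ctrl_origin: np.ndarray
    ctrl_spacing: float
    ctrl_shape: tuple[int, int, int]
    coefficients: np.ndarray
    displacement_cap_mm: float = 10.0
    converged: bool = True

    kind = "elastic"

    def weights_matrix(self, pts: np.ndarray) -> sparse.csr_matrix:
        """Sparse (npts x ncontrol) cubic B-spline interpolation weights."""
        u = (np.asarray(pts) - self.ctrl_origin) / self.ctrl_spacing
        base = np.floor(u).astype(int) - 1
        t = u - np.floor(u)
        w = [_bspline_basis(t[:, ax]) for ax in range(3)]  # each (4, npts)
        ncx, ncy, ncz = self.ctrl_shape
        npts = pts.shape[0]
        rows, cols, vals = [], [], []
        for l in range(4):
            ix = np.clip(base[:, 0] + l, 0, ncx - 1)
            for m in range(4):
                iy = np.clip(base[:, 1] + m, 0, ncy - 1)
                wlm = w[0][l] * w[1][m]
                for nn in range(4):
                    iz = np.clip(base[:, 2] + nn, 0, ncz - 1)
                    rows.append(np.arange(npts))
                    cols.append((ix * ncy + iy) * ncz + iz)
                    vals.append(wlm * w[2][nn])
        mat = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(npts, ncx * ncy * ncz),
        )
        return mat.tocsr()

    def displacement(self, pts: np.ndarray) -> np.ndarray:
        w = self.weights_matrix(pts)
        return w @ self.coefficients.reshape(-1, 3)

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        return pts + self.displacement(pts)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "ctrl_origin": self.ctrl_origin.tolist(),
            "ctrl_spacing": float(self.ctrl_spacing),
            "ctrl_shape": list(self.ctrl_shape),
            "coefficients": self.coefficients.tolist(),
            "displacement_cap_mm": float(self.displacement_cap_mm),
            "converged": bool(self.converged),
        }


def _stage_from_dict(d: dict):
    kind = d["kind"]
    if kind == "similarity":
        return SimilarityStage(np.asarray(d["centroid"]), float(d["scale"]))
    if kind == "affine":
        return AffineStage(
            np.asarray(d["translation"]),
            np.asarray(d["rotation_deg"]),
            np.asarray(d["log_scale"]),
            bool(d.get("converged", True)),
        )
    if kind == "elastic":
        return ElasticStage(
            np.asarray(d["ctrl_origin"]),
            float(d["ctrl_spacing"]),
            tuple(d["ctrl_shape"]),
            np.asarray(d["coefficients"]),
            float(d.get("displacement_cap_mm", 10.0)),
            bool(d.get("converged", True)),
        )
    raise ValueError(f"unknown stage kind {kind!r}")


@dataclass
class TransformChain:
    """Ordered stages (initialization, affine, elastic) as one backward map.

    Stage composition order is fixed: the elastic deformation acts first (in
    atlas space), then the affine, then the initialization into subject space.
    """

    stages: list = field(default_factory=list)

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        out = np.asarray(pts, dtype=float)
        for stage in reversed(self.stages):
            out = stage.map_points(out)
        return out

    def linear_jacobian(self) -> np.ndarray:
        """Jacobian of the linear (init + affine) part of the chain."""
        jac = np.eye(3)
        for stage in self.stages:
            if stage.kind in ("similarity", "affine"):
                jac = jac @ stage.jacobian()
        return jac

    def with_stage(self, stage) -> "TransformChain":
        return TransformChain(stages=[*self.stages, stage])

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps({"stages": [st.to_dict() for st in self.stages]})
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "TransformChain":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):  # a path, not inline JSON
            text = Path(text).read_text()
        d = json.loads(text)
        return cls(stages=[_stage_from_dict(s) for s in d["stages"]])


# ----------------------------------------------------------------------
# Registration data carriers
# ----------------------------------------------------------------------

@dataclass
class CostWeights:
    """Nonnegative weights of the three scoring-function terms.

    The prostate and CG shape terms carry the same weight by default; only
    the intensity-to-shape ratio is meant to be tuned.
    """

    w_intensity: float = 1.0
    w_prostate: float = 1.0
    w_cg: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_intensity, self.w_prostate, self.w_cg) < 0:
            raise ValueError("cost weights must be nonnegative")


@dataclass
class RegistrationConfig:
    band_mm: float = 10.0  # shape terms evaluated within this distance of the atlas surface
    affine_levels: tuple[int, ...] = (2500, 8000)  # band points per multi-resolution level
    affine_maxiter: int = 50
    # search-box bounds on the linear stage; near-symmetric glands make large
    # rotations ill-posed, so the search stays in the basin around identity
    affine_trans_bound_mm: float = 20.0
    affine_rot_bound_deg: float = 20.0
    affine_log_scale_bound: float = 0.35
    elastic_ctrl_spacing_mm: float = 15.0
    elastic_cap_mm: float = 10.0
    elastic_points: int = 16000
    elastic_maxiter: int = 60
    # bending-energy weight on the control grid: smooth organ-scale
    # corrections are nearly free, fine-scale noise-chasing is penalized
    elastic_bending: float = 1.0


@dataclass
class MovingSubject:
    """Subject-side fields sampled through candidate transforms."""

    subject_id: str
    intensity: ImageVolume
    sdf_prostate: SignedDistanceMap
    sdf_cg: SignedDistanceMap
    prostate_volume_ml: float

    @classmethod
    def from_record(cls, rec: SubjectRecord) -> "MovingSubject":
        return cls(
            subject_id=rec.subject_id,
            intensity=rec.intensity,
            sdf_prostate=signed_distance(rec.prostate),
            sdf_cg=signed_distance(rec.cg),
            prostate_volume_ml=compute_volume(rec.prostate),
        )

    def sample(self, vol: ImageVolume, pts: np.ndarray, order: int = 1) -> np.ndarray:
        idx = vol.world_to_index(pts)
        return ndimage.map_coordinates(
            vol.data.astype(np.float32), idx.T, order=order, mode="nearest"
        )

    def inside_fraction(self, pts: np.ndarray) -> float:
        idx = self.sdf_prostate.world_to_index(pts)
        shp = np.asarray(self.sdf_prostate.shape)
        ok = ((idx >= 0) & (idx <= shp - 1)).all(axis=1)
        return float(ok.mean())


@dataclass
class FixedTarget:
    """Atlas-side quantities precomputed once per registration round.

    Band points are the atlas voxels within ``band_mm`` of the prostate or CG
    mean surface; the shape terms average over each structure's band and the
    intensity NCC runs over their union.
    """

    grid: GridSpec
    pts: np.ndarray  # (N, 3) world coords of the pooled band
    sel_prostate: np.ndarray  # boolean masks into pts
    sel_cg: np.ndarray
    sdf_prostate_vals: np.ndarray
    sdf_cg_vals: np.ndarray
    intensity_vals: np.ndarray

    def subsample(self, max_points: int) -> "FixedTarget":
        n = self.pts.shape[0]
        if n <= max_points:
            return self
        keep = np.linspace(0, n - 1, max_points).astype(int)
        return FixedTarget(
            self.grid,
            self.pts[keep],
            self.sel_prostate[keep],
            self.sel_cg[keep],
            self.sdf_prostate_vals[keep],
            self.sdf_cg_vals[keep],
            self.intensity_vals[keep],
        )


def make_fixed_target(
    grid: GridSpec,
    intensity: np.ndarray,
    sdf_prostate: np.ndarray,
    sdf_cg: np.ndarray,
    band_mm: float = 10.0,
) -> FixedTarget:
    band = (np.abs(sdf_prostate) <= band_mm) | (np.abs(sdf_cg) <= band_mm)
    idx = np.argwhere(band)
    blank = grid.blank()
    pts = blank.index_to_world(idx)
    sp = sdf_prostate[band]
    sc = sdf_cg[band]
    return FixedTarget(
        grid=grid,
        pts=pts,
        sel_prostate=np.abs(sp) <= band_mm,
        sel_cg=np.abs(sc) <= band_mm,
        sdf_prostate_vals=sp.astype(np.float64),
        sdf_cg_vals=sc.astype(np.float64),
        intensity_vals=intensity[band].astype(np.float64),
    )


# ----------------------------------------------------------------------
# Cost function
# ----------------------------------------------------------------------

def _neg_ncc(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom < 1e-12:
        return 0.0
    return -float(ac @ bc / denom)


def composite_cost(
    moving: MovingSubject,
    target: FixedTarget,
    chain: TransformChain,
    weights: CostWeights,
) -> float:
    """Three-term scoring function; lower is better; both shape terms are 0
    at perfect alignment.  Subject-space SDF values are converted to
    atlas-space millimetres by the linear scale factor of the chain
    (det^(1/3) of the linear jacobian) before differencing — without this a
    scaling transform is biased, trading surface alignment against the
    interior SDF slope mismatch.  If the transform throws the prostate
    essentially off the subject grid a large penalty is returned with a
    warning."""
    mapped = chain.map_points(target.pts)
    if moving.inside_fraction(mapped[target.sel_prostate]) < 0.1:
        logger.warning("subject %s: transform maps prostate outside the grid", moving.subject_id)
        return _PENALTY
    k = float(np.abs(np.linalg.det(chain.linear_jacobian()))) ** (1.0 / 3.0)
    cost = 0.0
    if weights.w_prostate > 0:
        r = moving.sample(moving.sdf_prostate, mapped[target.sel_prostate]) / k - target.sdf_prostate_vals[target.sel_prostate]
        cost += weights.w_prostate * float((r * r).mean())
    if weights.w_cg > 0:
        r = moving.sample(moving.sdf_cg, mapped[target.sel_cg]) / k - target.sdf_cg_vals[target.sel_cg]
        cost += weights.w_cg * float((r * r).mean())
    if weights.w_intensity > 0:
        vals = moving.sample(moving.intensity, mapped)
        cost += weights.w_intensity * _neg_ncc(vals, target.intensity_vals)
    return cost


# ----------------------------------------------------------------------
# Stage optimizers
# ----------------------------------------------------------------------

def initial_normalization(
    subject: SubjectRecord | MovingSubject, median_volume_ml: float
) -> SimilarityStage:
    """Translation of the prostate centroid to the atlas center plus isotropic
    scaling to the common (median) prostate volume: s = (median / subject)^(1/3)."""
    if median_volume_ml <= 0:
        raise ValueError("median volume must be positive")
    if isinstance(subject, MovingSubject):
        vol_ml = subject.prostate_volume_ml
        mask_vol = subject.sdf_prostate
        idx = np.argwhere(mask_vol.data < 0)
    else:
        vol_ml = compute_volume(subject.prostate)
        idx = np.argwhere(subject.prostate.data > 0)
        mask_vol = subject.prostate
    if vol_ml <= 0 or idx.size == 0:
        raise ValueError("zero-volume prostate cannot be normalized")
    centroid = mask_vol.index_to_world(idx).mean(axis=0)
    scale = (median_volume_ml / vol_ml) ** (1.0 / 3.0)
    return SimilarityStage(centroid=centroid, scale=scale)


_AFFINE_SCALES = np.array([1.0] * 3 + [1.0] * 3 + [0.01] * 3)  # mm, deg, log-scale


def register_affine(
    moving: MovingSubject,
    target: FixedTarget,
    weights: CostWeights,
    config: RegistrationConfig,
    chain: TransformChain,
    dof: str = "affine",
) -> tuple[AffineStage, list[list[float]]]:
    """Optimize the linear stage by multi-resolution quasi-Newton descent on
    the composite cost.  ``dof="affine"`` optimizes translation + rotation +
    anisotropic scale (9 parameters); ``dof="rigid"`` freezes the scales.
    Deterministic: no random restarts.  Returns the stage and the accepted
    cost history per resolution level."""
    if dof not in ("affine", "rigid"):
        raise ValueError(f"dof must be 'affine' or 'rigid', got {dof!r}")
    n_par = 6 if dof == "rigid" else 9
    z = np.zeros(n_par)
    history: list[list[float]] = []
    converged = True
    for level, max_pts in enumerate(config.affine_levels):
        # later levels start warm from the coarse solution and need fewer steps
        maxiter = config.affine_maxiter if level == 0 else max(config.affine_maxiter // 2, 10)
        tgt = target.subsample(max_pts)

        def f(zv: np.ndarray) -> float:
            p = np.zeros(9)
            p[:n_par] = zv * _AFFINE_SCALES[:n_par]
            return composite_cost(moving, tgt, chain.with_stage(AffineStage.from_params(p)), weights)

        bounds_phys = (
            [config.affine_trans_bound_mm] * 3
            + [config.affine_rot_bound_deg] * 3
            + [config.affine_log_scale_bound] * 3
        )
        bounds = [
            (-b / s, b / s) for b, s in zip(bounds_phys[:n_par], _AFFINE_SCALES[:n_par])
        ]
        level_hist: list[float] = [f(z)]
        res = optimize.minimize(
            f,
            z,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "eps": 1e-3, "ftol": 1e-9},
            callback=lambda zv: level_hist.append(f(zv)),
        )
        history.append(level_hist)
        z = res.x
        converged = converged and bool(res.success)
    p = np.zeros(9)
    p[:n_par] = z * _AFFINE_SCALES[:n_par]
    stage = AffineStage.from_params(p)
    stage.converged = bool(converged)
    if not converged:
        logger.warning("subject %s: affine stage returned best-so-far without convergence", moving.subject_id)
    return stage, history


def _make_control_grid(pts: np.ndarray, spacing_mm: float) -> tuple[np.ndarray, tuple[int, int, int]]:
    lo = pts.min(axis=0) - 2 * spacing_mm
    hi = pts.max(axis=0) + 2 * spacing_mm
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing_mm)) + 4 for i in range(3))
    return lo, shape  # type: ignore[return-value]


def register_elastic(
    moving: MovingSubject,
    target: FixedTarget,
    weights: CostWeights,
    config: RegistrationConfig,
    chain: TransformChain,
) -> tuple[ElasticStage, dict]:
    """Optimize the B-spline free-form deformation under the displacement cap.

    The displacement field at the fixed band points is linear in the control
    coefficients (D = W P), so the shape-term gradients are exact sparse
    products; L-BFGS-B box bounds of cap/sqrt(3) per coefficient component
    realize the anatomical constraint.  Returns the stage and a residual
    report (mean |SDF residual| near each structure surface).
    """
    tgt = target.subsample(config.elastic_points)
    origin, cshape = _make_control_grid(tgt.pts, config.elastic_ctrl_spacing_mm)
    nctrl = int(np.prod(cshape))
    stage0 = ElasticStage(
        ctrl_origin=np.asarray(origin),
        ctrl_spacing=config.elastic_ctrl_spacing_mm,
        ctrl_shape=cshape,
        coefficients=np.zeros((*cshape, 3)),
        displacement_cap_mm=config.elastic_cap_mm,
    )
    w_mat = stage0.weights_matrix(tgt.pts)  # (N, nctrl)
    jac_lin = chain.linear_jacobian()
    k = float(np.abs(np.linalg.det(jac_lin))) ** (1.0 / 3.0)  # subject->atlas mm conversion

    # subject-space gradients of the sampled fields (world mm units)
    grads = {}
    for name, vol in (("p", moving.sdf_prostate), ("cg", moving.sdf_cg), ("int", moving.intensity)):
        g = np.gradient(vol.data.astype(np.float32), *vol.spacing)
        grads[name] = (vol, [gi for gi in g])

    def sample_grad(name: str, pts: np.ndarray) -> np.ndarray:
        vol, gs = grads[name]
        idx = vol.world_to_index(pts).T
        return np.stack(
            [ndimage.map_coordinates(g, idx, order=1, mode="nearest") for g in gs], axis=1
        )

    n_p = int(tgt.sel_prostate.sum())
    n_cg = int(tgt.sel_cg.sum())

    lam = config.elastic_bending

    def _bending(coeff: np.ndarray) -> tuple[float, np.ndarray]:
        """Discrete bending energy of the coefficient grid with its gradient."""
        pen = 0.0
        grad = np.zeros_like(coeff)
        for ax in range(3):
            d2 = np.diff(coeff, n=2, axis=ax)
            m = max(d2.size, 1)
            pen += float((d2**2).sum()) / m
            t = (2.0 / m) * d2
            sl = [slice(None)] * coeff.ndim
            for offset, sign in ((0, 1.0), (1, -2.0), (2, 1.0)):
                sl[ax] = slice(offset, coeff.shape[ax] - 2 + offset)
                grad[tuple(sl)] += sign * t
        return pen, grad

    def fg(pvec: np.ndarray) -> tuple[float, np.ndarray]:
        coeff = pvec.reshape(nctrl, 3)
        disp = w_mat @ coeff
        atlas_pts = tgt.pts + disp
        mapped = chain.map_points(atlas_pts)
        cost = 0.0
        dc_dd = np.zeros_like(disp)  # dCost/d displacement at each band point
        for name, sel, ref, n_sel, w in (
            ("p", tgt.sel_prostate, tgt.sdf_prostate_vals, n_p, weights.w_prostate),
            ("cg", tgt.sel_cg, tgt.sdf_cg_vals, n_cg, weights.w_cg),
        ):
            if w <= 0:
                continue
            vol = grads[name][0]
            vals = moving.sample(vol, mapped[sel]) / k
            r = vals - ref[sel]
            cost += w * float((r * r).mean())
            g = sample_grad(name, mapped[sel]) / k  # subject-space gradient, atlas mm
            dc_dd[sel] += (2.0 * w / n_sel) * r[:, None] * (g @ jac_lin)
        if weights.w_intensity > 0:
            vals = moving.sample(moving.intensity, mapped)
            ac = vals - vals.mean()
            bc = tgt.intensity_vals - tgt.intensity_vals.mean()
            na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
            if na > 1e-9 and nb > 1e-9:
                ncc = float(ac @ bc / (na * nb))
                cost += weights.w_intensity * (-ncc)
                dncc_da = bc / (na * nb) - ncc * ac / (na * na)
                g = sample_grad("int", mapped)
                dc_dd += weights.w_intensity * (-(dncc_da[:, None])) * (g @ jac_lin)
        grad = (w_mat.T @ dc_dd).ravel()
        if lam > 0:
            pen, pen_grad = _bending(coeff.reshape(*cshape, 3))
            cost += lam * pen
            grad = grad + lam * pen_grad.reshape(nctrl, 3).ravel()
        return cost, grad

    bound = config.elastic_cap_mm / np.sqrt(3.0)
    res = optimize.minimize(
        fg,
        np.zeros(nctrl * 3),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-bound, bound)] * (nctrl * 3),
        options={"maxiter": config.elastic_maxiter, "ftol": 1e-10},
    )
    stage = ElasticStage(
        ctrl_origin=np.asarray(origin),
        ctrl_spacing=config.elastic_ctrl_spacing_mm,
        ctrl_shape=cshape,
        coefficients=res.x.reshape(*cshape, 3),
        displacement_cap_mm=config.elastic_cap_mm,
        converged=bool(res.success),
    )

    # residual mean surface distance per structure, on the near-surface points
    final_chain = chain.with_stage(stage)
    mapped = final_chain.map_points(tgt.pts)
    report = {}
    near_mm = float(np.linalg.norm(target.grid.spacing))  # one voxel diagonal
    for name, sel, ref, vol in (
        ("prostate", tgt.sel_prostate, tgt.sdf_prostate_vals, moving.sdf_prostate),
        ("cg", tgt.sel_cg, tgt.sdf_cg_vals, moving.sdf_cg),
    ):
        near = sel & (np.abs(ref) <= near_mm)
        if near.any():
            vals = moving.sample(vol, mapped[near]) / k
            report[f"residual_mean_surface_distance_{name}_mm"] = float(np.abs(vals - ref[near]).mean())
    return stage, report
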