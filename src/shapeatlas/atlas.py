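"""Iterative subpopulation atlas construction.

An atlas is the population average of aligned subjects: a mean T2w-like
intensity volume plus mean signed distance functions (SDFs) for the prostate
and the central gland, whose zero level sets are the mean shapes.  Alignment
proceeds in rounds of increasing transform complexity:

1. every subject is translated to the atlas center and isotropically scaled
   to the median prostate volume of the subpopulation; the subject whose
   volume *is* the median seeds the reference;
2. an affine round registers each subject to the reference and the atlas is
   re-averaged;
3. an elastic round registers each subject to the affine-average atlas and
   the final atlas is averaged from the elastically aligned subjects.

Mean SDFs are reinitialized to true distance functions after averaging (an
average of SDFs is not itself an SDF), and the CG-inside-prostate invariant
is re-imposed on the extracted mean shapes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .image import GridSpec, ImageVolume, LabelVolume, SubjectRecord, read_volume, write_volume
from .metrics import SignedDistanceMap, compute_volume, signed_distance
from .registration import (
    CostWeights,
    FixedTarget,
    MovingSubject,
    RegistrationConfig,
    TransformChain,
    initial_normalization,
    make_fixed_target,
    register_affine,
    register_elastic,
)
from .stats import rank_sum_test

logger = logging.getLogger(__name__)


@dataclass
class AtlasConfig:
    """Grid and registration settings for atlas construction."""

    spacing_mm: float = 1.0
    margin_mm: float = 12.0
    weights: CostWeights = field(default_factory=CostWeights)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    affine_rounds: int = 1
    elastic_rounds: int = 1
    max_exclusion_fraction: float = 0.2
    enforce_homogeneous: bool = True  # require one group and one rater per atlas

    def digest(self) -> str:
        blob = json.dumps(
            {
                "spacing": self.spacing_mm,
                "margin": self.margin_mm,
                "weights": vars(self.weights),
                "registration": vars(self.registration),
                "rounds": [self.affine_rounds, self.elastic_rounds],
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class Atlas:
    """Population-average intensity + shape model with per-subject provenance."""

    grid: GridSpec
    intensity_mean: ImageVolume
    sdf_prostate_mean: SignedDistanceMap
    sdf_cg_mean: SignedDistanceMap
    stack_prostate: np.ndarray  # (n_subjects, *grid.shape) aligned SDFs
    stack_cg: np.ndarray
    stack_intensity: np.ndarray
    transforms: list[TransformChain]
    subject_ids: list[str]
    provenance: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def prostate_mask(self) -> LabelVolume:
        return self.sdf_prostate_mean.mask()

    def cg_mask(self) -> LabelVolume:
        return self.sdf_cg_mean.mask()


def atlas_grid_for(
    subjects: list[SubjectRecord], median_volume_ml: float, spacing_mm: float, margin_mm: float
) -> GridSpec:
    """Isotropic grid centered on the atlas origin, sized to hold every
    normalized prostate with margin."""
    half = 0.0
    for rec in subjects:
        idx = np.argwhere(rec.prostate.data > 0)
        world = rec.prostate.index_to_world(idx)
        centroid = world.mean(axis=0)
        s = (median_volume_ml / compute_volume(rec.prostate)) ** (1.0 / 3.0)
        half = max(half, float(np.abs((world - centroid) * s).max()))
    half += margin_mm
    n = 2 * int(np.ceil(half / spacing_mm)) + 1
    origin = -(n - 1) / 2.0 * spacing_mm
    return GridSpec(shape=(n, n, n), spacing=(spacing_mm,) * 3, origin=(origin,) * 3)


@dataclass
class _Aligned:
    intensity: np.ndarray
    sdf_p: np.ndarray
    sdf_cg: np.ndarray


def warp_subject(moving: MovingSubject, chain: TransformChain, grid: GridSpec) -> _Aligned:
    """Render a subject on the atlas grid through its transform chain.

    Masks are recovered by thresholding the sampled SDFs at zero (sub-voxel
    accurate) and the aligned SDFs recomputed on the atlas grid so they are
    true distance functions in atlas millimetres.
    """
    blank = grid.blank()
    pts = chain.map_points(blank.index_grid_world().reshape(-1, 3))
    inten = moving.sample(moving.intensity, pts).reshape(grid.shape)
    mask_p = (moving.sample(moving.sdf_prostate, pts) < 0).reshape(grid.shape)
    mask_cg = (moving.sample(moving.sdf_cg, pts) < 0).reshape(grid.shape) & mask_p
    if not mask_p.any():
        raise RuntimeError(f"subject {moving.subject_id}: transform left an empty prostate on the atlas grid")
    spacing = grid.spacing
    sdf_p = signed_distance(LabelVolume(mask_p.astype(np.uint8), spacing, grid.origin))
    sdf_cg = signed_distance(LabelVolume(mask_cg.astype(np.uint8), spacing, grid.origin))
    return _Aligned(inten.astype(np.float32), sdf_p.data, sdf_cg.data)


def update_atlas_average(
    aligned: list[_Aligned], grid: GridSpec
) -> tuple[ImageVolume, SignedDistanceMap, SignedDistanceMap]:
    """Voxelwise mean of intensities and of per-structure SDFs, with the mean
    SDFs reinitialized from their zero level sets."""
    if not aligned:
        raise ValueError("cannot average an empty subject list")
    inten = np.mean([a.intensity for a in aligned], axis=0).astype(np.float32)
    mean_p = np.mean([a.sdf_p for a in aligned], axis=0)
    mean_cg = np.mean([a.sdf_cg for a in aligned], axis=0)
    mask_p = mean_p < 0
    mask_cg = (mean_cg < 0) & mask_p
    sdf_p = signed_distance(LabelVolume(mask_p.astype(np.uint8), grid.spacing, grid.origin))
    sdf_cg = signed_distance(LabelVolume(mask_cg.astype(np.uint8), grid.spacing, grid.origin))
    return ImageVolume(inten, grid.spacing, grid.origin), sdf_p, sdf_cg


def _target_from(fields, grid: GridSpec, band_mm: float) -> FixedTarget:
    inten, sdf_p, sdf_cg = fields
    return make_fixed_target(grid, np.asarray(inten.data), sdf_p.data, sdf_cg.data, band_mm)


def build_atlas(subjects: list[SubjectRecord], config: AtlasConfig | None = None) -> Atlas:
    """Construct a subpopulation atlas; see the module docstring for the rounds.

    Subjects failing registration are excluded with a logged reason as long
    as the excluded fraction stays below ``config.max_exclusion_fraction``;
    otherwise the build aborts.
    """
    config = config or AtlasConfig()
    if not subjects:
        raise ValueError("need at least one subject")
    if config.enforce_homogeneous:
        if len({r.group for r in subjects}) > 1 or len({r.rater for r in subjects}) > 1:
            raise ValueError("an atlas is built from one group and one rater")

    vols = np.array([compute_volume(r.prostate) for r in subjects])
    order = np.argsort(vols, kind="stable")
    ref_idx = int(order[(len(subjects) - 1) // 2])  # lower median for even n
    median_vol = float(vols[ref_idx])

    movings = [MovingSubject.from_record(r) for r in subjects]
    chains = [TransformChain([initial_normalization(m, median_vol)]) for m in movings]
    grid = atlas_grid_for(subjects, median_vol, config.spacing_mm, config.margin_mm)
    logger.info("atlas grid %s at %.2f mm; median prostate volume %.1f ml", grid.shape, config.spacing_mm, median_vol)

    active = list(range(len(subjects)))
    excluded: dict[str, str] = {}

    def _drop(i: int, reason: str) -> None:
        excluded[movings[i].subject_id] = reason
        active.remove(i)
        logger.warning("excluding subject %s: %s", movings[i].subject_id, reason)
        if len(excluded) > config.max_exclusion_fraction * len(subjects):
            raise RuntimeError(
                f"too many registration failures ({len(excluded)}/{len(subjects)}): "
                + "; ".join(f"{k}: {v}" for k, v in excluded.items())
            )

    # round 1: reference from the median-volume subject, everyone normalized
    ref_aligned = warp_subject(movings[ref_idx], chains[ref_idx], grid)
    fields = update_atlas_average([ref_aligned], grid)

    if len(subjects) > 1:
        for _ in range(config.affine_rounds):
            target = _target_from(fields, grid, config.registration.band_mm)
            stages: dict[int, object] = {}
            for i in list(active):
                try:
                    stage, _ = register_affine(movings[i], target, config.weights, config.registration, chains[i])
                    stages[i] = stage
                except Exception as exc:  # noqa: BLE001 — registration robustness boundary
                    _drop(i, f"affine failure: {exc}")
            # template drift correction: remove the population-mean transform
            # so the atlas sits at the mean pose/size, not the reference's
            if stages:
                for name in ("translation", "rotation_deg", "log_scale"):
                    mean = np.mean([getattr(s, name) for s in stages.values()], axis=0)
                    for s in stages.values():
                        setattr(s, name, getattr(s, name) - mean)
            for i, stage in stages.items():
                chains[i] = chains[i].with_stage(stage)
            fields = update_atlas_average([warp_subject(movings[i], chains[i], grid) for i in active], grid)

        for _ in range(config.elastic_rounds):
            target = _target_from(fields, grid, config.registration.band_mm)
            el_stages: dict[int, object] = {}
            for i in list(active):
                try:
                    stage, residuals = register_elastic(
                        movings[i], target, config.weights, config.registration, chains[i]
                    )
                    el_stages[i] = stage
                    logger.info("subject %s elastic residuals: %s", movings[i].subject_id, residuals)
                except Exception as exc:  # noqa: BLE001
                    _drop(i, f"elastic failure: {exc}")
            # drift correction for the deformation: every subject shares one
            # control grid per round, so the mean coefficient field is removable
            if el_stages:
                mean_coeff = np.mean([s.coefficients for s in el_stages.values()], axis=0)
                for s in el_stages.values():
                    s.coefficients = s.coefficients - mean_coeff
            for i, stage in el_stages.items():
                chains[i] = chains[i].with_stage(stage)
            fields = update_atlas_average([warp_subject(movings[i], chains[i], grid) for i in active], grid)

    final = [warp_subject(movings[i], chains[i], grid) for i in active]
    inten, sdf_p, sdf_cg = update_atlas_average(final, grid)
    return Atlas(
        grid=grid,
        intensity_mean=inten,
        sdf_prostate_mean=sdf_p,
        sdf_cg_mean=sdf_cg,
        stack_prostate=np.stack([a.sdf_p for a in final]).astype(np.float32),
        stack_cg=np.stack([a.sdf_cg for a in final]).astype(np.float32),
        stack_intensity=np.stack([a.intensity for a in final]).astype(np.float32),
        transforms=[chains[i] for i in active],
        subject_ids=[movings[i].subject_id for i in active],
        provenance={
            "group": subjects[0].group,
            "rater": subjects[0].rater,
            "n_subjects": len(active),
            "median_prostate_volume_ml": median_vol,
            "reference_subject": movings[ref_idx].subject_id,
            "excluded": excluded,
            "config_digest": config.digest(),
        },
    )


# ----------------------------------------------------------------------
# Volume report
# ----------------------------------------------------------------------

@dataclass
class VolumeReport:
    """Pre/post-alignment volumes with group summaries and between-group tests."""

    table: pd.DataFrame
    group_summary: pd.DataFrame
    between_group_p: dict[str, float]
    shrinkage: dict[str, bool]

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_subject": self.table.to_dict(orient="records"),
                "group_summary": self.group_summary.reset_index().to_dict(orient="records"),
                "between_group_p": self.between_group_p,
                "post_mean_below_pre": self.shrinkage,
            },
            indent=2,
            sort_keys=True,
        )


def volume_report(groups: dict[str, tuple[list[SubjectRecord], Atlas]]) -> VolumeReport:
    """Tabulate prostate/CG volumes before and after atlas alignment.

    ``groups`` maps a label to (subjects, atlas built from them).  With
    exactly two groups, two-sided Wilcoxon rank-sum p-values compare the
    groups pre- and post-alignment for each structure.  The report also flags
    whether alignment shrank the mean volume, the systematic tendency of
    groupwise alignment toward the (smaller) median gland.
    """
    rows = []
    for label, (subjects, atlas) in groups.items():
        by_id = {r.subject_id: r for r in subjects}
        voxvol = float(np.prod(atlas.grid.spacing))
        for k, sid in enumerate(atlas.subject_ids):
            rec = by_id[sid]
            rows.append(
                {
                    "subject_id": sid,
                    "group": label,
                    "structure": "prostate",
                    "pre_ml": compute_volume(rec.prostate),
                    "post_ml": float((atlas.stack_prostate[k] < 0).sum()) * voxvol / 1000.0,
                }
            )
            rows.append(
                {
                    "subject_id": sid,
                    "group": label,
                    "structure": "cg",
                    "pre_ml": compute_volume(rec.cg),
                    "post_ml": float((atlas.stack_cg[k] < 0).sum()) * voxvol / 1000.0,
                }
            )
    table = pd.DataFrame(rows)
    summary = table.groupby(["group", "structure"]).agg(
        pre_mean=("pre_ml", "mean"),
        pre_sd=("pre_ml", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        post_mean=("post_ml", "mean"),
        post_sd=("post_ml", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
        n=("pre_ml", "count"),
    )
    shrink = {
        f"{g}/{s}": bool(row["post_mean"] < row["pre_mean"]) for (g, s), row in summary.iterrows()
    }
    pvals: dict[str, float] = {}
    labels = list(groups)
    if len(labels) == 2:
        for structure in ("prostate", "cg"):
            for phase in ("pre_ml", "post_ml"):
                a = table.query("group == @labels[0] and structure == @structure")[phase]
                b = table.query("group == @labels[1] and structure == @structure")[phase]
                pvals[f"{structure}_{phase[:-3]}"] = rank_sum_test(a.values, b.values)
    return VolumeReport(table=table, group_summary=summary, between_group_p=pvals, shrinkage=shrink)


# ----------------------------------------------------------------------
# Atlas persistence
# ----------------------------------------------------------------------

def save_atlas(atlas: Atlas, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "aligned_stack").mkdir(parents=True, exist_ok=True)
    (out / "transforms").mkdir(parents=True, exist_ok=True)
    write_volume(atlas.intensity_mean, out / "intensity_mean.nii.gz")
    write_volume(atlas.sdf_prostate_mean, out / "sdf_prostate_mean.nii.gz")
    write_volume(atlas.sdf_cg_mean, out / "sdf_cg_mean.nii.gz")
    g = atlas.grid
    for k, sid in enumerate(atlas.subject_ids):
        for name, stack in (
            ("prostate", atlas.stack_prostate),
            ("cg", atlas.stack_cg),
            ("intensity", atlas.stack_intensity),
        ):
            write_volume(
                ImageVolume(stack[k], g.spacing, g.origin), out / "aligned_stack" / f"{sid}_{name}.nii.gz"
            )
        atlas.transforms[k].to_json(out / "transforms" / f"{sid}.json")
    (out / "provenance.yaml").write_text(
        yaml.safe_dump({**atlas.provenance, "subject_ids": atlas.subject_ids, "grid": {
            "shape": list(g.shape), "spacing": list(g.spacing), "origin": list(g.origin)}})
    )


def load_atlas(in_dir: str | Path) -> Atlas:
    src = Path(in_dir)
    prov = yaml.safe_load((src / "provenance.yaml").read_text())
    grid = GridSpec(**prov.pop("grid"))
    subject_ids = prov.pop("subject_ids")
    inten = read_volume(src / "intensity_mean.nii.gz")

    def _sdf(name: str) -> SignedDistanceMap:
        v = read_volume(src / name)
        return SignedDistanceMap(v.data, v.spacing, v.origin, v.orientation)

    stacks = {"prostate": [], "cg": [], "intensity": []}
    transforms = []
    for sid in subject_ids:
        for name in stacks:
            stacks[name].append(read_volume(src / "aligned_stack" / f"{sid}_{name}.nii.gz").data)
        transforms.append(TransformChain.from_json(src / "transforms" / f"{sid}.json"))
    return Atlas(
        grid=grid,
        intensity_mean=inten,
        sdf_prostate_mean=_sdf("sdf_prostate_mean.nii.gz"),
        sdf_cg_mean=_sdf("sdf_cg_mean.nii.gz"),
        stack_prostate=np.stack(stacks["prostate"]),
        stack_cg=np.stack(stacks["cg"]),
        stack_intensity=np.stack(stacks["intensity"]),
        transforms=transforms,
        subject_ids=subject_ids,
        provenance=prov,
    )
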