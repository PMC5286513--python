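"""End-to-end study orchestration.

A *study* is: a cohort (simulated or loaded from a manifest), one atlas per
subpopulation appearing in the comparison plan, the planned atlas-vs-atlas
comparisons (disease contrasts, institution strata, rater-vs-rater), volume
reports, inter-rater agreement if two raters are present, and one structured
JSON summary.  Everything is deterministic given the study seed and config.

Compared groups are size-matched: when two subpopulations in a comparison
have unequal subject counts, the larger is down-sampled with the study seed,
mirroring designs that take the same number of subjects per stratum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .atlas import Atlas, AtlasConfig, build_atlas, save_atlas, volume_report
from .comparison import compare_atlases, difference_report
from .image import SubjectRecord, StudyManifest, load_study, select_subjects, write_volume
from .metrics import AgreementResult, cohen_kappa, default_kappa_domain
from .registration import CostWeights, RegistrationConfig
from .synthetic import (
    DEFAULT_RATER_JITTER_MM,
    EffectGroundTruth,
    GroupSpec,
    PhantomParams,
    generate_cohort,
    simulate_rater,
)

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# Configuration
# ----------------------------------------------------------------------

@dataclass
class SubpopulationFilter:
    group: str
    rater: int = 1
    institution: int | None = None

    @property
    def label(self) -> str:
        inst = f"_inst{self.institution}" if self.institution is not None else ""
        return f"{self.group}{inst}_r{self.rater}"


@dataclass
class SimulationSpec:
    groups: list[GroupSpec]
    two_raters: bool = False
    rater_jitter_mm: float = DEFAULT_RATER_JITTER_MM

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        groups = []
        for g in d["groups"]:
            g = dict(g)
            base = PhantomParams(**g.pop("base", {}))
            groups.append(GroupSpec(base=base, **g))
        return cls(
            groups=groups,
            two_raters=bool(d.get("two_raters", False)),
            rater_jitter_mm=float(d.get("rater_jitter_mm", DEFAULT_RATER_JITTER_MM)),
        )


@dataclass
class StudyConfig:
    """Validated study recipe; see ``StudyConfig.from_yaml`` for the schema."""

    out_dir: Path
    seed: int = 0
    simulation: SimulationSpec | None = None
    manifest: Path | None = None
    atlas: AtlasConfig = field(default_factory=AtlasConfig)
    alpha: float = 0.05
    band_mm: float = 3.0
    plan: list[tuple[SubpopulationFilter, SubpopulationFilter]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.manifest is None):
            raise ValueError("exactly one of `simulation` or `manifest` must be given")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        atlas_d = dict(d.get("atlas", {}))
        weights = CostWeights(**atlas_d.pop("weights", {}))
        reg = RegistrationConfig(**atlas_d.pop("registration", {}))
        atlas_cfg = AtlasConfig(weights=weights, registration=reg, **atlas_d)
        comp = d.get("comparison", {})
        plan = [
            (SubpopulationFilter(**p["a"]), SubpopulationFilter(**p["b"]))
            for p in d.get("plan", [])
        ]
        return cls(
            out_dir=Path(d["out"]),
            seed=int(d.get("seed", 0)),
            simulation=SimulationSpec.from_dict(d["simulation"]) if "simulation" in d else None,
            manifest=Path(d["manifest"]) if "manifest" in d else None,
            atlas=atlas_cfg,
            alpha=float(comp.get("alpha", 0.05)),
            band_mm=float(comp.get("band_mm", 3.0)),
            plan=plan,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ----------------------------------------------------------------------
# Cohort acquisition
# ----------------------------------------------------------------------

def simulate_study_cohort(
    sim: SimulationSpec, seed: int
) -> tuple[list[SubjectRecord], EffectGroundTruth | None]:
    """Simulate all groups (pairwise ground truth only for exactly two groups)."""
    if len(sim.groups) == 2:
        records, truth = generate_cohort(sim.groups[0], sim.groups[1], seed=seed)
    else:
        records = []
        truth = None
        rng = np.random.default_rng(seed)
        for spec in sim.groups:
            solo, _ = generate_cohort(spec, spec, seed=int(rng.integers(0, 2**31 - 1)))
            records.extend([r for r in solo if r.subject_id.startswith("A")])
    if sim.two_raters:
        rng = np.random.default_rng(seed + 1)
        second = [
            simulate_rater(r, jitter_mm=sim.rater_jitter_mm, seed=int(rng.integers(0, 2**31 - 1)))
            for r in records
        ]
        records = records + second
    return records, truth


# ----------------------------------------------------------------------
# Inter-rater analysis
# ----------------------------------------------------------------------

def inter_rater_agreement(
    rater1: list[SubjectRecord], rater2: list[SubjectRecord]
) -> AgreementResult:
    """Per-subject Cohen's kappa for prostate and CG between two raters."""
    by_id1 = {r.subject_id: r for r in rater1}
    by_id2 = {r.subject_id: r for r in rater2}
    if set(by_id1) != set(by_id2):
        raise ValueError("rater subject_id sets differ")
    result = AgreementResult()
    for sid in sorted(by_id1):
        a, b = by_id1[sid], by_id2[sid]
        domain = default_kappa_domain(a.prostate, b.prostate)
        result.add(sid, "prostate", cohen_kappa(a.prostate, b.prostate, domain))
        result.add(sid, "cg", cohen_kappa(a.cg, b.cg, domain))
    return result


def inter_rater_study(
    rater1: list[SubjectRecord],
    rater2: list[SubjectRecord],
    config: StudyConfig,
) -> dict:
    """Kappa table plus a rater-atlas comparison for one subpopulation.

    Builds one atlas per rater from the same subjects and compares them the
    same way disease groups are compared, quantifying how much apparent shape
    difference annotation variability alone produces.
    """
    agreement = inter_rater_agreement(rater1, rater2)
    atlas1 = build_atlas(rater1, config.atlas)
    atlas2 = build_atlas(rater2, config.atlas)
    res = compare_atlases(atlas1, atlas2, alpha=config.alpha, band_mm=config.band_mm)
    summary = difference_report(res)
    return {
        "kappa": {
            "per_subject": agreement.per_subject.to_dict(orient="records"),
            "summary": agreement.summary().reset_index().to_dict(orient="records"),
            "formatted": agreement.formatted(),
        },
        "rater_comparison": summary,
    }


# ----------------------------------------------------------------------
# Study driver
# ----------------------------------------------------------------------

def _size_matched(
    subjects: list[SubjectRecord], n_target: int, seed: int
) -> list[SubjectRecord]:
    if len(subjects) <= n_target:
        return subjects
    rng = np.random.default_rng(seed)
    keep = sorted(rng.choice(len(subjects), size=n_target, replace=False))
    logger.info("size-matching: down-sampled %d -> %d subjects", len(subjects), n_target)
    return [subjects[i] for i in keep]


def run_study(config: StudyConfig) -> dict:
    """Execute the full study plan; returns (and writes) the summary bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.simulation is not None:
        records, truth = simulate_study_cohort(config.simulation, config.seed)
        if truth is not None and not truth.is_empty:
            write_volume(truth.mask, out / "effect_ground_truth.nii.gz")
    else:
        records = load_study(StudyManifest.from_csv(config.manifest))

    summary: dict = {"seed": config.seed, "n_subjects": len(records), "comparisons": {}}

    # inter-rater agreement when both raters are present
    r1 = select_subjects(records, rater=1)
    r2 = select_subjects(records, rater=2)
    if r2:
        agreement = inter_rater_agreement(r1, r2)
        summary["kappa"] = {
            "summary": agreement.summary().reset_index().to_dict(orient="records"),
            "formatted": agreement.formatted(),
        }
        agreement.per_subject.to_csv(out / "kappa_per_subject.csv", index=False)

    atlases: dict[str, tuple[list[SubjectRecord], Atlas]] = {}

    def _atlas_for(filt: SubpopulationFilter, n_target: int) -> tuple[list[SubjectRecord], Atlas]:
        subs = select_subjects(
            records, group=filt.group, rater=filt.rater, institution=filt.institution
        )
        if len(subs) < 2:
            raise ValueError(f"subpopulation {filt.label} selects fewer than 2 subjects")
        subs = _size_matched(subs, n_target, config.seed)
        key = f"{filt.label}_n{len(subs)}"
        if key not in atlases:
            logger.info("building atlas %s (%d subjects)", key, len(subs))
            atlas = build_atlas(subs, config.atlas)
            save_atlas(atlas, out / "atlases" / key)
            atlases[key] = (subs, atlas)
        return atlases[key]

    for filt_a, filt_b in config.plan:
        n_a = len(select_subjects(records, group=filt_a.group, rater=filt_a.rater, institution=filt_a.institution))
        n_b = len(select_subjects(records, group=filt_b.group, rater=filt_b.rater, institution=filt_b.institution))
        n_target = min(n_a, n_b)
        subs_a, atlas_a = _atlas_for(filt_a, n_target)
        subs_b, atlas_b = _atlas_for(filt_b, n_target)
        name = f"{filt_a.label}_vs_{filt_b.label}"
        logger.info("comparing %s", name)
        result = compare_atlases(atlas_a, atlas_b, alpha=config.alpha, band_mm=config.band_mm)
        comp_summary = difference_report(result, out / "comparisons" / name, render_png=True)
        vr = volume_report({filt_a.label: (subs_a, atlas_a), filt_b.label: (subs_b, atlas_b)})
        (out / "comparisons" / name / "volume_report.json").write_text(vr.to_json())
        vr.table.to_csv(out / "comparisons" / name / "volumes.csv", index=False)
        summary["comparisons"][name] = {
            "shape": comp_summary,
            "volumes": json.loads(vr.to_json()),
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
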