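"""Configuration-driven orchestration of the full analysis.

``run_pipeline`` drives: read -> realign -> motion QC (exclusion rule) ->
smooth -> atlas registration/segmentation -> voxelwise CO2-response stats ->
per-region VOA -> group estimation statistics with region-family FDR ->
condition x time mixed ANOVA, writing every stage's outputs (and a run
manifest with config echo, seeds and output hashes) before the next stage
starts.  ``simulate_and_run`` prepends phantom-cohort generation and appends
a truth-vs-estimate report.

All statistical outputs are deterministic functions of the inputs and the
master seed, including bootstrap confidence intervals.  Per-subject work is
cached under a content key (input-file hash + stage-relevant config), so
rerunning a completed stage with unchanged inputs is a no-op.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import TimecourseTable, mixed_anova
from .io import (
    BoldSeries,
    LabelAtlas,
    read_atlas,
    read_bold,
    read_manifest,
)
from .phantom import (
    MotionTrajectory,
    NoiseModel,
    ResponseProfile,
    _label_contrast,
    generate_cohort,
    make_demo_atlas,
)
from .realign import RealignConfig, motion_qc, realign_series, smooth_gaussian
from .register import register_affine, segment_subject
from .voa import compute_voa, group_compare, region_fdr
from .voxelstats import WindowDesign, analyze_subject

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "StageError",
    "run_pipeline",
    "simulate_from_config",
    "simulate_and_run",
]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries stage name and subject id."""

    def __init__(self, stage: str, subject: str | None, cause: Exception):
        self.stage, self.subject = stage, subject
        who = f" (subject {subject})" if subject else ""
        super().__init__(f"stage {stage!r}{who}: {cause}")


@dataclass
class PipelineConfig:
    """All analysis settings; defaults are the reference study's values."""

    manifest: str = "manifest.tsv"
    atlas_volume: str = "atlas.nii"
    atlas_table: str = "regions.tsv"
    out_dir: str = "results"
    window: WindowDesign = field(default_factory=WindowDesign)
    realign: RealignConfig = field(default_factory=RealignConfig)
    do_realign: bool = True
    register_mode: str = "skip"  # "skip" (atlas-space phantoms) or "fit"
    smoothing_fwhm: float = 0.8
    alpha: float = 0.05
    q: float = 0.05
    percent_threshold: float = 1.0
    fdr_method: str = "fdr_bh"
    ci_method: str = "bootstrap"
    n_boot: int = 5000
    max_pixels: float = 1.0
    anova_composites: list[str] = field(default_factory=list)
    seed: int = 0
    write_maps: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.window, (list, tuple, dict)):
            self.window = (WindowDesign(**self.window)
                           if isinstance(self.window, dict)
                           else WindowDesign(*self.window))
        if isinstance(self.realign, dict):
            self.realign = RealignConfig(**self.realign)
        if self.register_mode not in ("skip", "fit"):
            raise ValueError(f"register_mode must be 'skip' or 'fit', got "
                             f"{self.register_mode!r}")
        for name in ("alpha", "q"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.percent_threshold < 0:
            raise ValueError("percent_threshold must be >= 0")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self)))


@dataclass
class PipelineResult:
    """In-memory handle on a completed run."""

    out_dir: Path
    voa_table: pd.DataFrame
    comparisons: dict
    region_significance: pd.Series
    anova: dict
    excluded: list[str]
    subject_summaries: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _intensity_template(atlas: LabelAtlas, contrast: float = 0.15) -> np.ndarray:
    """Synthetic intensity template in atlas space (same per-label contrast
    model the phantom generator uses), for the 9-DOF registration fit."""
    tpl = np.zeros(atlas.labels.shape)
    tissue = atlas.labels > 0
    tpl[tissue] = _label_contrast(atlas.labels[tissue], contrast)
    return tpl


def _write_map(data: np.ndarray, atlas: LabelAtlas, path: Path) -> None:
    aff = np.diag([*atlas.geometry.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), aff), path)


def _subject_stage_key(path: Path, config: PipelineConfig) -> str:
    relevant = {
        k: v for k, v in config.to_dict().items()
        if k not in ("manifest", "out_dir", "write_maps")
    }
    payload = json.dumps({"input": _sha256(path), "config": relevant},
                         sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _process_subject(
    sid: str,
    condition: str,
    path: Path,
    atlas: LabelAtlas,
    template: np.ndarray | None,
    config: PipelineConfig,
    sub_dir: Path,
    composites: list[str],
) -> dict:
    """Run all per-subject stages; returns the cached record (VOA rows,
    summary, QC verdict, per-composite leaf timecourses)."""
    series = read_bold(path)

    qc_record = None
    if config.do_realign:
        try:
            series, motion_table = realign_series(series, config.realign)
        except ValueError as exc:
            raise StageError("realign", sid, exc) from exc
        motion_table.to_csv(sub_dir / "motion.tsv", sep="\t", index=False)
        qc = motion_qc(motion_table, atlas.geometry.voxel_size[0],
                       config.max_pixels)
        qc_record = qc.to_dict()
        (sub_dir / "qc.json").write_text(json.dumps(qc_record, indent=1))
        if not qc.passed:
            return {"subject_id": sid, "condition": condition,
                    "excluded": True, "qc": qc_record}

    if config.smoothing_fwhm > 0:
        series = smooth_gaussian(series, config.smoothing_fwhm)

    if config.register_mode == "fit":
        try:
            transform = register_affine(series.data.mean(axis=-1), template,
                                        atlas.geometry)
        except ValueError as exc:
            raise StageError("register", sid, exc) from exc
        transform.to_json(sub_dir / "transform.json", atlas.geometry)
    else:
        transform = None
    seg = segment_subject(atlas, transform)

    try:
        result = analyze_subject(
            series, config.window, seg.labels > 0,
            alpha=config.alpha, q=config.q,
            percent_threshold=config.percent_threshold,
            fdr_method=config.fdr_method,
        )
    except ValueError as exc:
        raise StageError("voxel_stats", sid, exc) from exc

    if config.write_maps:
        _write_map(result.delta, atlas, sub_dir / "delta_pct.nii")
        _write_map(result.t, atlas, sub_dir / "tstat.nii")
        _write_map(result.p, atlas, sub_dir / "pval.nii")
        _write_map(result.activated.astype(np.float64), atlas,
                   sub_dir / "activation.nii")

    voa = compute_voa(result.activated, seg.labels, atlas, sid, condition)
    voa.to_csv(sub_dir / "voa.tsv", sep="\t", index=False)
    summary = result.summary()
    (sub_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    logger.info("%s: %d masked, %d rejected, %d activated voxels", sid,
                summary["masked_voxels"], summary["fdr_rejected_voxels"],
                summary["activated_voxels"])

    # leaf-mean % BOLD timecourses for the requested composites
    from .voxelstats import percent_change

    pct, valid = percent_change(series, config.window, seg.labels > 0)
    tc_records = {}
    for comp in composites:
        rows = {}
        for leaf in atlas.leaves_of(comp):
            vox = (seg.labels == atlas.label_of(leaf)) & valid
            if not vox.any():
                logger.warning("%s: leaf %s empty in subject space; unit "
                               "dropped", sid, leaf)
                continue
            rows[leaf] = pct[vox].mean(axis=0)
        tc_records[comp] = rows
    for comp, rows in tc_records.items():
        if rows:
            pd.DataFrame(rows).to_csv(sub_dir / f"timecourse_{comp}.tsv",
                                      sep="\t", index=False)

    return {
        "subject_id": sid,
        "condition": condition,
        "excluded": False,
        "qc": qc_record,
        "voa": voa.to_dict(orient="list"),
        "summary": summary,
        "timecourses": {
            comp: {leaf: series_.tolist() for leaf, series_ in rows.items()}
            for comp, rows in tc_records.items()
        },
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Subjects failing the motion-QC exclusion rule are dropped (and listed in
    the QC report); the run aborts only if a condition retains fewer than two
    subjects.  Returns a :class:`PipelineResult`; all tables are also written
    under ``config.out_dir``.
    """
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    try:
        manifest = read_manifest(config.manifest)
        atlas = read_atlas(config.atlas_volume, config.atlas_table)
    except (OSError, ValueError) as exc:
        raise StageError("load_inputs", None, exc) from exc

    composites = (config.anova_composites
                  if config.anova_composites else [])
    unknown = [c for c in composites if c not in atlas.composite_regions]
    if unknown:
        raise StageError("load_inputs", None,
                         ValueError(f"unknown ANOVA composites: {unknown}"))
    template = (_intensity_template(atlas)
                if config.register_mode == "fit" else None)

    records: list[dict] = []
    excluded: list[str] = []
    for row in manifest.table.itertuples():
        sid, condition, path = row.subject_id, row.condition, Path(row.path)
        sub_dir = out_dir / "subjects" / sid
        sub_dir.mkdir(parents=True, exist_ok=True)
        key = _subject_stage_key(path, config)
        cache_file = sub_dir / "cache.json"
        if cache_file.exists():
            cached = json.loads(cache_file.read_text())
            if cached.get("stage_key") == key:
                logger.info("%s: cached result reused", sid)
                records.append(cached["record"])
                if cached["record"].get("excluded"):
                    excluded.append(sid)
                continue
        record = _process_subject(sid, condition, path, atlas, template,
                                  config, sub_dir, composites)
        cache_file.write_text(json.dumps({"stage_key": key, "record": record}))
        records.append(record)
        if record["excluded"]:
            excluded.append(sid)
            logger.warning("%s excluded by motion QC", sid)

    included = [r for r in records if not r["excluded"]]
    counts = pd.Series([r["condition"] for r in included]).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise StageError(
            "group_stats", None,
            ValueError(f"fewer than 2 subjects per condition after QC "
                       f"exclusions: {counts.to_dict()}"),
        )

    voa_table = pd.concat(
        [pd.DataFrame(r["voa"]) for r in included], ignore_index=True
    )
    voa_table.to_csv(out_dir / "voa.tsv", sep="\t", index=False)

    comparisons = {}
    leaf_frames = []
    for comp in atlas.composite_regions:
        gc = group_compare(voa_table, comp, n_boot=config.n_boot,
                           seed=config.seed, ci_method=config.ci_method)
        comparisons[comp] = gc
        lt = gc.leaf_table.copy()
        lt.insert(0, "composite_region", comp)
        leaf_frames.append(lt)
    comp_table = pd.DataFrame([gc.to_dict() for gc in comparisons.values()])
    significance = region_fdr(
        pd.Series({c: gc.p_value for c, gc in comparisons.items()}),
        q=config.q,
    )
    comp_table["significant_fdr"] = significance.to_numpy()
    comp_table.to_csv(out_dir / "group_comparison.tsv", sep="\t", index=False)
    pd.concat(leaf_frames, ignore_index=True).to_csv(
        out_dir / "estimation_graph.tsv", sep="\t", index=False
    )

    anova_results = {}
    for comp in composites:
        data, conds, ids = [], [], []
        for r in included:
            for leaf, tc in r["timecourses"].get(comp, {}).items():
                data.append(tc)
                conds.append(r["condition"])
                ids.append(f"{r['subject_id']}:{leaf}")
        table = TimecourseTable(data=np.array(data),
                                condition=np.array(conds), unit_id=ids)
        res = mixed_anova(table)
        anova_results[comp] = res.to_dict()
        table.group_mean_se().to_csv(
            out_dir / f"timecourse_mean_se_{comp}.tsv", sep="\t", index=False
        )
    if anova_results:
        (out_dir / "anova.json").write_text(json.dumps(anova_results, indent=1))

    qc_report = {
        "excluded": excluded,
        "included": [r["subject_id"] for r in included],
        "per_subject": {r["subject_id"]: r.get("qc") for r in records},
    }
    (out_dir / "qc_report.json").write_text(json.dumps(qc_report, indent=1))

    outputs = sorted(
        str(p.relative_to(out_dir))
        for p in out_dir.rglob("*")
        if p.is_file() and p.name != "run_manifest.json"
    )
    run_manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "started": t0,
        "finished": time.time(),
        "output_hashes": {name: _sha256(out_dir / name) for name in outputs},
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1))

    return PipelineResult(
        out_dir=out_dir,
        voa_table=voa_table,
        comparisons=comparisons,
        region_significance=significance,
        anova=anova_results,
        excluded=excluded,
        subject_summaries={r["subject_id"]: r.get("summary") for r in included},
    )


def _profiles_from_dict(d: dict) -> dict[str, ResponseProfile]:
    out = {}
    for region, spec in d.items():
        if isinstance(spec, (int, float)):
            out[region] = ResponseProfile(amplitude=float(spec))
        else:
            spec = dict(spec)
            if "bump_window" in spec and spec["bump_window"] is not None:
                spec["bump_window"] = tuple(spec["bump_window"])
            out[region] = ResponseProfile(**spec)
    return out


def simulate_from_config(sim: dict, out_dir: str | Path):
    """Generate a phantom cohort from a plain-dict (YAML-friendly) config.

    Recognized keys: shape, voxel_size, composites, semiaxis_frac, n_per_group,
    n_volumes, seed, tissue_contrast, percent_threshold, motion,
    noise {sigma, rho, drift_per_volume, baseline_mean},
    conditions {sham: {region: amplitude-or-profile}, injured: {...}}.
    """
    atlas = make_demo_atlas(
        shape=tuple(sim.get("shape", (96, 96, 22))),
        voxel_size=tuple(sim.get("voxel_size", (0.3125, 0.3125, 1.0))),
        composites=sim.get("composites"),
        semiaxis_frac=tuple(sim.get("semiaxis_frac", (0.3125, 0.208, 0.273))),
    )
    noise = NoiseModel(**sim.get("noise", {}))
    conditions = {
        cond: _profiles_from_dict(profs)
        for cond, profs in sim.get("conditions", {}).items()
    }
    motion = sim.get("motion", "none")
    if isinstance(motion, list):
        motion = MotionTrajectory(np.asarray(motion))
    return generate_cohort(
        atlas,
        conditions,
        noise=noise,
        motion=motion,
        n_per_group=int(sim.get("n_per_group", 7)),
        out_dir=out_dir,
        seed=int(sim.get("seed", 0)),
        n_volumes=int(sim.get("n_volumes", 150)),
        tissue_contrast=float(sim.get("tissue_contrast", 0.15)),
        percent_threshold=float(sim.get("percent_threshold", 1.0)),
    )


def simulate_and_run(
    sim: dict, config: PipelineConfig
) -> tuple[PipelineResult, pd.DataFrame, dict]:
    """Generate a cohort, run the pipeline on it, and score it against truth.

    Returns the pipeline result, a per-(subject, leaf) truth-vs-estimate
    table (true VOA, estimated VOA, error) and a planted-effect recovery
    verdict per composite whose two conditions were given different response
    amplitudes.
    """
    sim_dir = Path(config.out_dir) / "sim"
    manifest, truths = simulate_from_config(sim, sim_dir)
    config.manifest = str(sim_dir / "manifest.tsv")
    config.atlas_volume = str(sim_dir / "atlas.nii")
    config.atlas_table = str(sim_dir / "regions.tsv")
    result = run_pipeline(config)

    rows = []
    for sid, truth in truths.items():
        if sid in result.excluded:
            continue
        est = result.voa_table.loc[result.voa_table["subject_id"] == sid]
        est_map = dict(zip(est["leaf_region"], est["voa"]))
        for leaf, true_voa in truth.true_voa.items():
            e = int(est_map.get(leaf, 0))
            rows.append({"subject_id": sid, "leaf_region": leaf,
                         "true_voa": true_voa, "estimated_voa": e,
                         "error": e - true_voa})
    tve = pd.DataFrame(rows)
    tve.to_csv(Path(config.out_dir) / "truth_vs_estimate.tsv", sep="\t",
               index=False)

    atlas = read_atlas(config.atlas_volume, config.atlas_table)
    verdicts = {}
    cond_profiles = {
        cond: _profiles_from_dict(profs)
        for cond, profs in sim.get("conditions", {}).items()
    }
    for comp in atlas.composite_regions:
        amp = {}
        for cond, profs in cond_profiles.items():
            leaf_amps = [
                profs[name].amplitude
                for name in ([comp] if comp in profs else atlas.leaves_of(comp))
                if name in profs
            ]
            amp[cond] = float(np.mean(leaf_amps)) if leaf_amps else 0.0
        planted = amp.get("injured", 0.0) - amp.get("sham", 0.0)
        if planted == 0.0:
            continue
        gc = result.comparisons[comp]
        detected = gc.p_value < config.alpha
        sign_ok = np.sign(gc.mean_difference) == np.sign(planted)
        verdicts[comp] = {
            "planted_amplitude_difference": planted,
            "mean_difference": gc.mean_difference,
            "p_value": gc.p_value,
            "verdict": ("detected, correct sign" if detected and sign_ok
                        else "detected, wrong sign" if detected
                        else "not detected"),
        }
    (Path(config.out_dir) / "recovery_verdict.json").write_text(
        json.dumps(verdicts, indent=1)
    )
    return result, tve, verdicts
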