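"""Calibration and recovery experiments for the whole pipeline.

Each function here runs a simulation study against the phantom generator's
ground truth and returns summary numbers: false-discovery calibration under
a global null, type-I calibration of the region-level comparison, power to
recover a planted condition difference, motion-trajectory recovery, the
mixed-ANOVA df structure, brute-force oracle agreement, and the noiseless
end-to-end identity.  They are used by the test suite and the acceptance
script, and are part of the public API so users can re-run the package's own
validation at other settings.

Problem sizes default to the scales described in docs/methods.md: the
full ~15,000-voxel brain for the voxelwise null calibration, and cropped
grids with the same brain-to-grid proportions for cohort-level studies.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .anova import TimecourseTable, mixed_anova
from .io import LabelAtlas
from .phantom import (
    MotionTrajectory,
    NoiseModel,
    ResponseProfile,
    generate_subject,
    make_demo_atlas,
)
from .pipeline import PipelineConfig, simulate_and_run
from .realign import motion_qc, realign_series
from .voa import compute_voa, group_compare
from .voxelstats import WindowDesign, analyze_subject

__all__ = [
    "fdr_null_calibration",
    "region_null_rejection_rate",
    "planted_effect_power",
    "motion_recovery",
    "anova_df_structure",
    "oracle_agreement",
    "noiseless_identity",
]

# cropped grids keeping the reference brain-to-grid proportions
FULL_BRAIN_SHAPE = (60, 60, 16)          # ~15,000 brain voxels
FULL_BRAIN_FRAC = (0.45, 0.30, 0.46)
COHORT_SHAPE = (32, 32, 10)              # ~2,600 brain voxels
COHORT_FRAC = (0.45, 0.30, 0.46)


def _seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence([master, *key]).generate_state(1)[0] % (2**31))


def fdr_null_calibration(
    n_phantoms: int = 200,
    seed: int = 0,
    shape: tuple[int, int, int] = FULL_BRAIN_SHAPE,
    semiaxis_frac: tuple[float, float, float] = FULL_BRAIN_FRAC,
    q: float = 0.05,
) -> dict:
    """False-discovery calibration of the voxelwise cascade under a global
    null: phantoms with no CO2 response, AR(1) noise at the generator default.

    Every rejection is a false discovery, so the realized FDP of one phantom
    is 1 if anything is rejected and 0 otherwise.  Also reports the mean
    *fraction* of masked voxels rejected, the quantity bounded by q for the
    map as a whole.
    """
    atlas = make_demo_atlas(shape=shape, semiaxis_frac=semiaxis_frac)
    noise = NoiseModel(drift_per_volume=0.0)  # pure AR(1) noise, no trend
    design = WindowDesign()
    fdps, fractions = [], []
    for i in range(n_phantoms):
        series, _ = generate_subject(atlas, {}, noise=noise,
                                     seed=_seed(seed, 1, i))
        res = analyze_subject(series, design, atlas.brain_mask, q=q)
        n_rej = int(res.fdr_rejected.sum())
        fdps.append(1.0 if n_rej > 0 else 0.0)
        fractions.append(n_rej / int(res.mask.sum()))
    fdps = np.asarray(fdps)
    return {
        "n_phantoms": n_phantoms,
        "n_masked_voxels": int(atlas.brain_mask.sum()),
        "mean_fdp": float(fdps.mean()),
        "mc_se": float(fdps.std(ddof=1) / np.sqrt(n_phantoms)),
        "mean_fraction_rejected": float(np.mean(fractions)),
        "q": q,
    }


def _simulate_cohort_voa(
    atlas: LabelAtlas,
    profiles_by_condition: dict[str, dict[str, ResponseProfile]],
    n_per_group: int,
    seed: int,
    design: WindowDesign,
) -> pd.DataFrame:
    rows = []
    counter = 0
    for condition in sorted(profiles_by_condition):
        for i in range(n_per_group):
            counter += 1
            sid = f"{condition}_{i + 1:02d}"
            series, _ = generate_subject(
                atlas, profiles_by_condition[condition],
                seed=_seed(seed, counter),
            )
            res = analyze_subject(series, design, atlas.brain_mask)
            rows.append(compute_voa(res.activated, atlas.labels, atlas, sid,
                                    condition))
    return pd.concat(rows, ignore_index=True)


def region_null_rejection_rate(
    n_cohorts: int = 200,
    n_per_group: int = 7,
    amplitude: float = 2.0,
    seed: int = 0,
    alpha: float = 0.05,
    shape: tuple[int, int, int] = COHORT_SHAPE,
) -> dict:
    """Type-I calibration of the composite-region comparison under a true
    null: both conditions share identical (nonzero) response profiles, so
    per-subject VOA varies with noise but has no group difference.

    The amplitude is chosen off floor and ceiling so the Welch statistic on
    per-subject composite means is non-degenerate.
    """
    atlas = make_demo_atlas(shape=shape, semiaxis_frac=COHORT_FRAC)
    profiles = {c: ResponseProfile(amplitude) for c in atlas.composite_regions}
    both = {"sham": profiles, "injured": profiles}
    design = WindowDesign()
    n_tests = 0
    n_reject = 0
    for k in range(n_cohorts):
        voa = _simulate_cohort_voa(atlas, both, n_per_group,
                                   _seed(seed, 2, k), design)
        for comp in atlas.composite_regions:
            p = group_compare(voa, comp, ci_method="welch").p_value
            n_tests += 1
            n_reject += p < alpha
    return {
        "n_cohorts": n_cohorts,
        "n_tests": n_tests,
        "rejection_rate": n_reject / n_tests,
        "alpha": alpha,
    }


def planted_effect_power(
    n_replicates: int = 50,
    n_per_group: int = 7,
    sham_amplitude: float = 3.0,
    injured_amplitude: float = 1.5,
    composite: str = "prefrontal_cortex",
    seed: int = 0,
    alpha: float = 0.05,
    shape: tuple[int, int, int] = COHORT_SHAPE,
) -> dict:
    """Recovery of a planted hypo-reactivity: the injured group's response in
    one composite is halved; everything else responds equally.

    Reports how often the comparison is significant with the correct
    (negative, injured - sham) sign.
    """
    atlas = make_demo_atlas(shape=shape, semiaxis_frac=COHORT_FRAC)
    base = {c: ResponseProfile(sham_amplitude) for c in atlas.composite_regions}
    injured = dict(base)
    injured[composite] = ResponseProfile(injured_amplitude)
    design = WindowDesign()
    detected = 0
    negative_md = 0
    mds = []
    for k in range(n_replicates):
        voa = _simulate_cohort_voa(
            atlas, {"sham": base, "injured": injured}, n_per_group,
            _seed(seed, 3, k), design,
        )
        gc = group_compare(voa, composite, ci_method="welch")
        mds.append(gc.mean_difference)
        negative_md += gc.mean_difference < 0
        detected += (gc.p_value < alpha) and (gc.mean_difference < 0)
    return {
        "n_replicates": n_replicates,
        "detection_rate": detected / n_replicates,
        "negative_md_rate": negative_md / n_replicates,
        "mean_md": float(np.mean(mds)),
        "alpha": alpha,
    }


def motion_recovery(
    n_volumes: int = 20,
    seed: int = 0,
    shape: tuple[int, int, int] = (96, 96, 22),
) -> dict:
    """Recovery of an injected sub-voxel rigid trajectory (max displacement
    drawn from the 27-70 um range) at the full in-plane geometry, plus the
    one-pixel QC exclusion check on a >0.3 mm displacement."""
    atlas = make_demo_atlas(shape=shape)
    traj = MotionTrajectory.realistic(n_volumes, seed=_seed(seed, 4))
    series, _ = generate_subject(atlas, {}, motion=traj,
                                 seed=_seed(seed, 4, 1), n_volumes=n_volumes)
    _, table = realign_series(series)
    est = table[["tx", "ty", "tz"]].to_numpy()
    resid = est - traj.params[:, :3]
    resid -= resid.mean(axis=0)  # trajectory identified up to a constant
    rms = float(np.sqrt((resid**2).mean()))
    qc_good = motion_qc(table, atlas.geometry.voxel_size[0])

    bad_traj = MotionTrajectory.rejected(12, displaced_volume=6, offset_mm=0.4)
    bad_series, _ = generate_subject(atlas, {}, motion=bad_traj,
                                     seed=_seed(seed, 4, 2), n_volumes=12)
    _, bad_table = realign_series(bad_series)
    qc_bad = motion_qc(bad_table, atlas.geometry.voxel_size[0])
    return {
        "n_volumes": n_volumes,
        "max_injected_displacement_mm": traj.max_displacement,
        "rms_residual_mm": rms,
        "qc_passes_subvoxel_motion": bool(qc_good.passed),
        "qc_excludes_large_displacement": bool(not qc_bad.passed),
        "qc_offending_volume": (qc_bad.offending_volumes[0]
                                if qc_bad.offending_volumes else None),
    }


def anova_df_structure(seed: int = 0) -> dict:
    """Mixed-ANOVA df brackets on simulated balanced designs: 2 conditions x
    7 subjects x {8, 17} leaf regions x 150 timepoints."""
    out = {}
    for n_leaves in (8, 17):
        n_units = 2 * 7 * n_leaves
        rng = np.random.default_rng(_seed(seed, 5, n_leaves))
        table = TimecourseTable(
            rng.standard_normal((n_units, 150)),
            np.array(["sham"] * (n_units // 2) + ["injured"] * (n_units // 2)),
            [f"u{i}" for i in range(n_units)],
        )
        res = mixed_anova(table)
        out[n_leaves] = {
            "condition": res.df("condition"),
            "interaction": res.df("interaction"),
            "n_units": n_units,
        }
    return out


def oracle_agreement(seed: int = 0) -> dict:
    """Maximum deviation of Welch t, BH rejections and mixed-ANOVA F from
    independent brute-force computations on small fixtures."""
    from scipy import stats

    rng = np.random.default_rng(_seed(seed, 6))

    # Welch: explicit textbook formula on 5+5 samples
    welch_dev = 0.0
    for _ in range(20):
        x, y = rng.standard_normal(5), rng.standard_normal(5) + rng.uniform(0, 2)
        nx, ny = 5, 5
        vx = sum((v - x.mean()) ** 2 for v in x) / (nx - 1)
        vy = sum((v - y.mean()) ** 2 for v in y) / (ny - 1)
        se2 = vx / nx + vy / ny
        t_ref = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p_ref = 2 * stats.t.sf(abs(t_ref), df)
        from .voxelstats import voxel_window_test

        design = WindowDesign((1, 5), (6, 10), None)
        _, t_got, p_got, _ = voxel_window_test(
            np.concatenate([y, x])[np.newaxis, :], design
        )
        welch_dev = max(welch_dev, abs(t_got[0] - t_ref), abs(p_got[0] - p_ref))

    # BH: try-every-k step-up on <=10 p-values
    from .voxelstats import fdr_filter

    bh_mismatches = 0
    for _ in range(50):
        m = int(rng.integers(2, 11))
        p = rng.uniform(0, 1, m) ** 2
        got = fdr_filter(p, 0.05)
        order = np.argsort(p, kind="stable")
        k_max = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= 0.05 * k / m:
                k_max = k
        want = np.zeros(m, bool)
        want[order[:k_max]] = True
        bh_mismatches += int((got != want).sum())

    # mixed ANOVA: explicit means on a 4-unit, 3-timepoint table
    y = rng.standard_normal((4, 3)) + np.array([[0], [0], [1.0], [1.0]])
    cond = np.array(["sham", "sham", "injured", "injured"])
    res = mixed_anova(TimecourseTable(y, cond, list("abcd")))
    grand = y.mean()
    ss_cond = sum(2 * 3 * (y[cond == c].mean() - grand) ** 2
                  for c in ("sham", "injured"))
    ss_units = sum(
        3 * (y[u].mean() - y[cond == cond[u]].mean()) ** 2 for u in range(4)
    )
    ss_time = sum(4 * (y[:, j].mean() - grand) ** 2 for j in range(3))
    ss_int = sum(
        2 * (y[cond == c][:, j].mean() - y[cond == c].mean()
             - y[:, j].mean() + grand) ** 2
        for c in ("sham", "injured") for j in range(3)
    )
    ss_err = float(((y - grand) ** 2).sum()) - ss_cond - ss_units - ss_time - ss_int
    f_cond = (ss_cond / 1) / (ss_units / 2)
    f_time = (ss_time / 2) / (ss_err / 4)
    f_int = (ss_int / 2) / (ss_err / 4)
    anova_dev = max(
        abs(res.f("condition") - f_cond),
        abs(res.f("time") - f_time),
        abs(res.f("interaction") - f_int),
    )
    return {
        "welch_max_abs_dev": float(welch_dev),
        "bh_mismatched_decisions": int(bh_mismatches),
        "anova_max_abs_dev": float(anova_dev),
    }


def noiseless_identity(
    seed: int = 0,
    shape: tuple[int, int, int] = COHORT_SHAPE,
    workdir: str | Path | None = None,
) -> dict:
    """End-to-end exactness: zero noise, zero motion, smoothing off ->
    estimated VOA equals the planted ground truth in every region."""
    sim = {
        "shape": list(shape),
        "semiaxis_frac": list(COHORT_FRAC),
        "n_per_group": 2,
        "n_volumes": 150,
        "seed": _seed(seed, 7),
        "noise": {"sigma": 0.0, "rho": 0.0, "drift_per_volume": 0.0},
        "conditions": {
            "sham": {"prefrontal_cortex": 3.0, "cerebellum": 3.0},
            "injured": {"prefrontal_cortex": 3.0, "cerebellum": 3.0},
        },
    }

    def _run(base: Path) -> dict:
        config = PipelineConfig(
            out_dir=str(base),
            do_realign=False,
            register_mode="skip",
            smoothing_fwhm=0.0,
            n_boot=200,
            write_maps=False,
            seed=_seed(seed, 7, 1),
        )
        _, tve, _ = simulate_and_run(sim, config)
        return {
            "n_region_subject_pairs": int(len(tve)),
            "max_abs_voa_error": int(tve["error"].abs().max()),
            "total_true_voa": int(tve["true_voa"].sum()),
            "total_estimated_voa": int(tve["estimated_voa"].sum()),
        }

    if workdir is not None:
        return _run(Path(workdir))
    with tempfile.TemporaryDirectory() as tmp:
        return _run(Path(tmp))
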