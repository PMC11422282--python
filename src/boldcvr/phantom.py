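"""Synthetic 4D BOLD phantoms with known ground truth.

The generator emulates the block-design hypercapnic-challenge study this
package analyzes: a 5 min baseline (volumes 1-50), 5 min of 5% CO2 breathing
(volumes 51-100) and 5 min recovery (volumes 101-150) at TR 6 s, on a brain
of ~15,000 voxels segmented into 171 leaf regions grouped into composite
regions.  Each leaf region responds with a configurable % BOLD amplitude per
condition; optional features model the phenomena seen in the injured and sham
groups respectively: a sustained post-challenge elevation (no return to
baseline) and a late one-minute "bump".  Noise is AR(1) in time plus a linear
drift; motion is a small per-volume rigid-body trajectory applied *after*
signal synthesis by linear resampling, so realignment faces realistic
interpolation loss.

Every subject carries a :class:`GroundTruth` (true responder mask and true
per-region volume of activation) so downstream stages can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as _signal

from ._transforms import resample_volume, rotation_matrix
from .io import (
    BoldSeries,
    CohortManifest,
    LabelAtlas,
    VolumeGeometry,
    write_atlas,
    write_bold,
    write_manifest,
)

__all__ = [
    "ResponseProfile",
    "NoiseModel",
    "MotionTrajectory",
    "GroundTruth",
    "DEFAULT_COMPOSITES",
    "make_demo_atlas",
    "response_curve",
    "generate_subject",
    "generate_cohort",
]


@dataclass(frozen=True)
class ResponseProfile:
    """Shape of one region's CO2 response in % BOLD change.

    ``amplitude`` is the plateau % BOLD change during the challenge window
    (volumes ``onset_volume``..``offset_volume``, 1-based inclusive).  The
    boxcar is convolved with a single-exponential rise/decay of time constant
    ``ramp_tau`` volumes (0 = pure boxcar).  ``sustain_offset`` is the % BOLD
    level the signal relaxes to after the challenge instead of 0 (models the
    injured group's failure to return to baseline).  ``bump_amplitude`` over
    ``bump_window`` adds a late transient (models the sham group's end-of-run
    bump).
    """

    amplitude: float = 0.0
    onset_volume: int = 51
    offset_volume: int = 100
    ramp_tau: float = 3.0
    sustain_offset: float = 0.0
    bump_amplitude: float = 0.0
    bump_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.onset_volume <= self.offset_volume):
            raise ValueError(
                f"need 1 <= onset ({self.onset_volume}) <= offset "
                f"({self.offset_volume})"
            )
        if self.ramp_tau < 0:
            raise ValueError(f"ramp_tau must be >= 0, got {self.ramp_tau}")
        for name in ("amplitude", "sustain_offset", "bump_amplitude"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.bump_window is not None and self.bump_window[0] > self.bump_window[1]:
            raise ValueError(f"bump_window out of order: {self.bump_window}")


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise: AR(1) in time plus a linear drift.

    ``sigma`` is the innovation standard deviation in raw intensity units,
    ``rho`` the AR(1) coefficient, ``drift_per_volume`` a linear drift in % of
    baseline per volume, ``baseline_mean`` the raw tissue intensity.  Defaults
    (sigma 20 on baseline 1000 = 2% voxel noise, rho 0.2, drift 0.002 %/vol)
    are the package's model of awake-rodent spin-echo data at ~312 um.
    """

    sigma: float = 20.0
    rho: float = 0.2
    drift_per_volume: float = 0.002
    baseline_mean: float = 1000.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if self.baseline_mean <= 0:
            raise ValueError(f"baseline_mean must be > 0, got {self.baseline_mean}")


@dataclass
class MotionTrajectory:
    """Per-volume rigid motion: columns (tx, ty, tz) mm, (rx, ry, rz) rad."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"trajectory must be (n_volumes, 6), got {self.params.shape}"
            )

    def __len__(self) -> int:
        return self.params.shape[0]

    @property
    def displacements(self) -> np.ndarray:
        """Per-volume total translation magnitude in mm."""
        return np.linalg.norm(self.params[:, :3], axis=1)

    @property
    def max_displacement(self) -> float:
        return float(self.displacements.max())

    @classmethod
    def none(cls, n_volumes: int) -> "MotionTrajectory":
        return cls(np.zeros((n_volumes, 6)))

    @classmethod
    def sinusoidal(
        cls,
        n_volumes: int,
        amplitude_mm: float = 0.05,
        axis: int = 0,
        period: float = 40.0,
        phase: float = 0.0,
    ) -> "MotionTrajectory":
        p = np.zeros((n_volumes, 6))
        t = np.arange(n_volumes)
        p[:, axis] = amplitude_mm * np.sin(2 * np.pi * t / period + phase)
        return cls(p)

    @classmethod
    def realistic(
        cls,
        n_volumes: int,
        seed: int = 0,
        displacement_range_mm: tuple[float, float] = (0.027, 0.070),
        max_rotation_deg: float = 0.2,
    ) -> "MotionTrajectory":
        """Smooth random drift scaled to the displacement range seen in
        well-acclimated awake rats (tens of microns, i.e. sub-voxel)."""
        rng = np.random.default_rng(seed)
        steps = rng.standard_normal((n_volumes, 6))
        walk = np.cumsum(steps, axis=0)
        # low-pass so successive volumes move smoothly
        kernel = np.ones(9) / 9.0
        walk = np.apply_along_axis(
            lambda c: np.convolve(c, kernel, mode="same"), 0, walk
        )
        walk -= walk.mean(axis=0, keepdims=True)
        disp = np.linalg.norm(walk[:, :3], axis=1)
        target = rng.uniform(*displacement_range_mm)
        scale = target / disp.max() if disp.max() > 0 else 0.0
        walk[:, :3] *= scale
        rot_scale = np.deg2rad(max_rotation_deg) / max(
            np.abs(walk[:, 3:]).max(), 1e-12
        )
        walk[:, 3:] *= rot_scale
        return cls(walk)

    @classmethod
    def rejected(
        cls, n_volumes: int, displaced_volume: int = 75, offset_mm: float = 0.4
    ) -> "MotionTrajectory":
        """Preset violating the one-pixel exclusion rule at one volume."""
        p = np.zeros((n_volumes, 6))
        p[displaced_volume - 1, 0] = offset_mm
        return cls(p)


@dataclass
class GroundTruth:
    """What was planted: per-voxel responder mask and per-region true VOA."""

    amplitude_map: np.ndarray
    responder_mask: np.ndarray
    true_voa: dict[str, int]
    trajectory: MotionTrajectory
    percent_threshold: float = 1.0

    @property
    def total_responders(self) -> int:
        return int(self.responder_mask.sum())


#: Composite-region scheme of the bundled demo atlas: 171 leaf regions in 12
#: composites, matching the stated counts (prefrontal cortex = 8 areas,
#: somatosensory cortex = 17, thalamus = 26, cerebellum = 17, ...).
DEFAULT_COMPOSITES: dict[str, int] = {
    "prefrontal_cortex": 8,
    "somatosensory_cortex": 17,
    "basal_ganglia": 12,
    "thalamus": 26,
    "hypothalamus": 12,
    "hippocampus": 12,
    "amygdala": 9,
    "olfactory_system": 10,
    "midbrain": 14,
    "brainstem": 20,
    "cerebellum": 17,
    "other_cortex": 14,
}


def make_demo_atlas(
    shape: tuple[int, int, int] = (96, 96, 22),
    voxel_size: tuple[float, float, float] = (0.3125, 0.3125, 1.0),
    composites: dict[str, int] | None = None,
    semiaxis_frac: tuple[float, float, float] = (0.3125, 0.208, 0.273),
    tr: float = 6.0,
) -> LabelAtlas:
    """Build a synthetic labeled atlas: an ellipsoidal brain partitioned into
    leaf regions grouped into composite regions.

    This is a stand-in with the same hierarchy *semantics* as a real rat
    atlas (not its anatomy).  At the default reference geometry the ellipsoid
    holds ~15,000 voxels, matching the in-brain voxel count of the study it
    emulates; leaf regions are near-equal raster-contiguous chunks.
    """
    composites = dict(composites) if composites is not None else dict(DEFAULT_COMPOSITES)
    n_regions = sum(composites.values())
    if n_regions < 1:
        raise ValueError("need at least one leaf region")
    dims = np.asarray(shape, dtype=float)
    semi = dims * np.asarray(semiaxis_frac, dtype=float)
    center = (dims - 1) / 2.0
    grid = np.indices(shape, dtype=float)
    d2 = sum(((grid[k] - center[k]) / semi[k]) ** 2 for k in range(3))
    mask = d2 <= 1.0
    n_vox = int(mask.sum())
    if n_vox < n_regions:
        raise ValueError(
            f"brain of {n_vox} voxels cannot hold {n_regions} leaf regions"
        )
    labels = np.zeros(shape, dtype=np.int32)
    coords = np.argwhere(mask)  # raster (x, y, z) order -> contiguous chunks
    base, extra = divmod(n_vox, n_regions)
    sizes = np.full(n_regions, base, dtype=int)
    sizes[:extra] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    rows = []
    label_id = 0
    for comp, n_leaves in composites.items():
        for j in range(n_leaves):
            label_id += 1
            sl = coords[bounds[label_id - 1] : bounds[label_id]]
            labels[sl[:, 0], sl[:, 1], sl[:, 2]] = label_id
            rows.append(
                {
                    "label_id": label_id,
                    "leaf_region": f"{comp}_{j + 1:02d}",
                    "composite_region": comp,
                }
            )
    geometry = VolumeGeometry(tuple(shape), tuple(voxel_size), tr=tr)
    return LabelAtlas(geometry=geometry, labels=labels, region_table=pd.DataFrame(rows))


def response_curve(profile: ResponseProfile, n_volumes: int) -> np.ndarray:
    """% BOLD response at volumes 1..n_volumes for one region."""
    if profile.offset_volume > n_volumes:
        raise ValueError(
            f"offset volume {profile.offset_volume} exceeds series length "
            f"{n_volumes}"
        )
    r = np.zeros(n_volumes)
    on, off, tau = profile.onset_volume, profile.offset_volume, profile.ramp_tau
    k = np.arange(0, off - on + 1, dtype=float)
    if tau > 0:
        rise = 1.0 - np.exp(-(k + 1.0) / tau)
    else:
        rise = np.ones_like(k)
    r[on - 1 : off] = profile.amplitude * rise
    r_off = r[off - 1]
    if off < n_volumes:
        j = np.arange(1, n_volumes - off + 1, dtype=float)
        if tau > 0:
            decay = np.exp(-j / tau)
        else:
            decay = np.zeros_like(j)
        r[off:] = profile.sustain_offset + (r_off - profile.sustain_offset) * decay
    if profile.bump_amplitude != 0.0 and profile.bump_window is not None:
        a, b = profile.bump_window
        a = max(1, a)
        b = min(n_volumes, b)
        r[a - 1 : b] += profile.bump_amplitude
    return r


def _label_contrast(label_ids: np.ndarray, contrast: float) -> np.ndarray:
    """Deterministic per-label multiplicative intensity factor in
    [1-contrast, 1+contrast]; gives the phantom anatomical texture so
    intensity-based registration has structure to lock onto."""
    u = np.sin(label_ids.astype(float) * 12.9898 + 78.233) * 43758.5453
    u = 2.0 * (u - np.floor(u)) - 1.0
    return 1.0 + contrast * u


def _resolve_profiles(
    atlas: LabelAtlas, profiles: dict[str, ResponseProfile]
) -> dict[str, ResponseProfile]:
    """Expand composite-level profiles to leaves; leaf-level entries win."""
    leaves = set(atlas.leaf_regions)
    comps = set(atlas.composite_regions)
    resolved: dict[str, ResponseProfile] = {}
    for name, prof in profiles.items():
        if name in comps:
            for leaf in atlas.leaves_of(name):
                resolved.setdefault(leaf, prof)
        elif name not in leaves:
            raise KeyError(
                f"profile refers to unknown region {name!r} (neither leaf nor "
                "composite)"
            )
    for name, prof in profiles.items():
        if name in leaves:
            resolved[name] = prof
    return resolved


def _ar1_noise(
    rng: np.random.Generator, n_series: int, n_volumes: int, sigma: float, rho: float
) -> np.ndarray:
    """Stationary AR(1) series, innovations N(0, sigma^2)."""
    if sigma == 0 or n_series == 0:
        return np.zeros((n_series, n_volumes))
    e = rng.standard_normal((n_series, n_volumes)) * sigma
    if rho == 0:
        return e
    x_prev = rng.standard_normal(n_series) * sigma / np.sqrt(1.0 - rho**2)
    zi = (rho * x_prev)[:, np.newaxis]
    out, _ = _signal.lfilter([1.0], [1.0, -rho], e, axis=1, zi=zi)
    return out


def generate_subject(
    atlas: LabelAtlas,
    profiles: dict[str, ResponseProfile],
    noise: NoiseModel | None = None,
    motion: MotionTrajectory | None = None,
    seed: int = 0,
    n_volumes: int = 150,
    tissue_contrast: float = 0.15,
    percent_threshold: float = 1.0,
) -> tuple[BoldSeries, GroundTruth]:
    """Synthesize one subject's 4D series plus its ground truth.

    Tissue voxels follow ``baseline * (1 + drift(t)/100 + response(t)/100)``
    plus stationary AR(1) noise; background stays at zero.  Motion, if given,
    is applied last by rigid resampling of each volume (linear interpolation),
    so the clean signal exists only before resampling -- exactly the situation
    realignment faces on real data.  Identical inputs and seed give identical
    output.
    """
    noise = noise if noise is not None else NoiseModel()
    if motion is not None and len(motion) != n_volumes:
        raise ValueError(
            f"motion trajectory has {len(motion)} volumes, series has {n_volumes}"
        )
    resolved = _resolve_profiles(atlas, profiles)
    max_label = int(atlas.labels.max())
    curves = np.zeros((max_label + 1, n_volumes))
    amplitudes = np.zeros(max_label + 1)
    for leaf, prof in resolved.items():
        lid = atlas.label_of(leaf)
        curves[lid] = response_curve(prof, n_volumes)
        amplitudes[lid] = prof.amplitude

    rng = np.random.default_rng(seed)
    labels = atlas.labels
    tissue = labels > 0
    drift = noise.drift_per_volume * np.arange(n_volumes, dtype=float)  # in %

    base = np.zeros(labels.shape)
    base[tissue] = noise.baseline_mean * _label_contrast(
        labels[tissue], tissue_contrast
    )

    # (n_tissue, T) signal, then scatter into the 4D volume
    pct = curves[labels[tissue]]  # (n_tissue, T)
    series_tissue = base[tissue][:, np.newaxis] * (
        1.0 + drift[np.newaxis, :] / 100.0 + pct / 100.0
    )
    series_tissue += _ar1_noise(rng, series_tissue.shape[0], n_volumes,
                                noise.sigma, noise.rho)
    data = np.zeros((*labels.shape, n_volumes))
    data[tissue] = series_tissue

    if motion is not None and np.any(motion.params):
        for t in range(n_volumes):
            p = motion.params[t]
            if not np.any(p):
                continue
            r = rotation_matrix(*p[3:])
            data[..., t] = resample_volume(
                data[..., t], r, p[:3], atlas.geometry.voxel_size, order=1
            )

    geometry = atlas.geometry.with_volumes(n_volumes)
    amplitude_map = amplitudes[labels]
    responder = amplitude_map >= percent_threshold
    counts = np.bincount(labels[responder], minlength=max_label + 1)
    true_voa = {
        row.leaf_region: int(counts[row.label_id])
        for row in atlas.region_table.itertuples()
    }
    truth = GroundTruth(
        amplitude_map=amplitude_map,
        responder_mask=responder,
        true_voa=true_voa,
        trajectory=motion if motion is not None else MotionTrajectory.none(n_volumes),
        percent_threshold=percent_threshold,
    )
    return BoldSeries(geometry=geometry, data=data), truth


def _child_seed(master_seed: int, counter: int) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, counter]).generate_state(1)[0])


def _motion_for(
    motion: MotionTrajectory | str | dict | None,
    subject_id: str,
    counter: int,
    n_volumes: int,
    master_seed: int,
) -> MotionTrajectory | None:
    if motion is None or motion == "none":
        return None
    if isinstance(motion, MotionTrajectory):
        return motion
    if isinstance(motion, dict):
        return motion.get(subject_id)
    if motion == "realistic":
        return MotionTrajectory.realistic(
            n_volumes, seed=_child_seed(master_seed, 10_000 + counter)
        )
    raise ValueError(f"unknown motion spec {motion!r}")


def generate_cohort(
    atlas: LabelAtlas,
    condition_profiles: dict[str, dict[str, ResponseProfile]],
    noise: NoiseModel | None = None,
    motion: MotionTrajectory | str | dict | None = None,
    n_per_group: int = 7,
    out_dir: str | Path = ".",
    seed: int = 0,
    n_volumes: int = 150,
    tissue_contrast: float = 0.15,
    percent_threshold: float = 1.0,
) -> tuple[CohortManifest, dict[str, GroundTruth]]:
    """Write a cohort of ``n_per_group`` subjects per condition to disk.

    Produces ``sub-<id>.nii`` per subject, the atlas (``atlas.nii`` +
    ``regions.tsv``), ``manifest.tsv``, ``ground_truth.json`` and an echo of
    all generation parameters (``phantom_params.yaml``).  Per-subject seeds
    derive deterministically from the master seed by counter, so a fixed seed
    reproduces the cohort byte for byte.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    noise = noise if noise is not None else NoiseModel()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    write_atlas(atlas, out_dir / "atlas.nii", out_dir / "regions.tsv")
    rows = []
    truths: dict[str, GroundTruth] = {}
    counter = 0
    for condition in sorted(condition_profiles):
        profiles = condition_profiles[condition]
        for i in range(n_per_group):
            counter += 1
            sid = f"{condition}_{i + 1:02d}"
            traj = _motion_for(motion, sid, counter, n_volumes, seed)
            series, truth = generate_subject(
                atlas,
                profiles,
                noise=noise,
                motion=traj,
                seed=_child_seed(seed, counter),
                n_volumes=n_volumes,
                tissue_contrast=tissue_contrast,
                percent_threshold=percent_threshold,
            )
            path = out_dir / f"sub-{sid}.nii"
            write_bold(series, path)
            rows.append({"subject_id": sid, "condition": condition, "path": str(path)})
            truths[sid] = truth
    manifest = CohortManifest(pd.DataFrame(rows))
    write_manifest(manifest, out_dir / "manifest.tsv")

    truth_records = {
        sid: {
            "true_voa": t.true_voa,
            "total_responders": t.total_responders,
            "max_displacement_mm": t.trajectory.max_displacement,
        }
        for sid, t in truths.items()
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth_records, fh, indent=1)
    params = {
        "seed": seed,
        "n_per_group": n_per_group,
        "n_volumes": n_volumes,
        "tissue_contrast": tissue_contrast,
        "percent_threshold": percent_threshold,
        "noise": dataclasses.asdict(noise),
        "conditions": {
            cond: {name: dataclasses.asdict(p) for name, p in profs.items()}
            for cond, profs in condition_profiles.items()
        },
        "motion": motion if isinstance(motion, (str, type(None))) else "custom",
    }
    with open(out_dir / "phantom_params.yaml", "w") as fh:
        # json round-trip turns tuples into lists, which YAML can represent
        yaml.safe_dump(json.loads(json.dumps(params)), fh, sort_keys=True)
    return manifest, truths
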