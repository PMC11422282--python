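"""Rigid-body motion correction and spatial smoothing.

The realignment follows the classic register-to-mean scheme: every volume is
first registered to the first volume, a mean image is rebuilt from the
aligned series, and all volumes are re-registered to that mean before being
resliced once with a high-order B-spline.  Estimation minimizes a
least-squares intensity mismatch by Gauss-Newton on the six rigid parameters
with analytic image gradients, after pre-smoothing, on a sampling grid of
configurable spatial separation from which a ``quality`` fraction of points
is retained.  Defaults reproduce the standard settings used for awake-rodent
data: quality 0.97, separation 0.45 mm, pre-smoothing FWHM 0.65 mm,
2nd-degree B-spline for estimation and 4th-degree for reslicing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._transforms import (
    center_voxel,
    d_rotation_matrix,
    euler_from_matrix,
    resample_volume,
    rotation_matrix,
    sample_at,
)
from .io import BoldSeries, VolumeGeometry

__all__ = [
    "RigidTransform",
    "RealignConfig",
    "MotionQCReport",
    "estimate_rigid",
    "realign_series",
    "smooth_gaussian",
    "motion_qc",
    "fwhm_to_sigma",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))

# fixed seed for the quality subsampling of grid points: realignment output
# must be a deterministic function of its inputs
_SUBSAMPLE_SEED = 12345


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return fwhm / FWHM_FACTOR


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid transform: translations (mm) and extrinsic x-y-z
    rotations (rad) about the volume center."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_params(cls, p: np.ndarray) -> "RigidTransform":
        return cls(*(float(v) for v in p))

    @property
    def params(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    @property
    def rotation(self) -> np.ndarray:
        return rotation_matrix(self.rx, self.ry, self.rz)

    @property
    def displacement(self) -> float:
        """Total translation magnitude in mm."""
        return float(np.linalg.norm(self.translation))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        r = self.rotation @ other.rotation
        t = self.rotation @ other.translation + self.translation
        return RigidTransform(*t, *euler_from_matrix(r))

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        t = -r @ self.translation
        return RigidTransform(*t, *euler_from_matrix(r))


@dataclass(frozen=True)
class RealignConfig:
    """Estimation settings (see module docstring for the rationale)."""

    quality: float = 0.97
    separation: float = 0.45
    smoothing_fwhm: float = 0.65
    interp_degree_estimate: int = 2
    interp_degree_reslice: int = 4
    max_iter: int = 30
    tol_mm: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.quality <= 1):
            raise ValueError(f"quality must be in (0, 1], got {self.quality}")
        if self.separation <= 0:
            raise ValueError(f"separation must be > 0, got {self.separation}")
        if self.smoothing_fwhm < 0:
            raise ValueError(f"smoothing_fwhm must be >= 0, got {self.smoothing_fwhm}")


def _presmooth(volume: np.ndarray, fwhm_mm: float,
               voxel_size: tuple[float, float, float]) -> np.ndarray:
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float)
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / v for v in voxel_size]
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma_vox,
                                   mode="reflect")


def _sample_grid(
    dims: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    separation_mm: float,
    quality: float,
) -> np.ndarray:
    """Voxel-index sampling grid with ~``separation_mm`` spacing, with a
    ``quality`` fraction of points retained (fixed-seed subsampling)."""
    axes = [
        np.arange(0.0, dims[k] - 1e-9, max(separation_mm / voxel_size[k], 1.0))
        for k in range(3)
    ]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=0).reshape(3, -1)
    if quality < 1.0:
        n = pts.shape[1]
        keep = max(int(round(quality * n)), 6)
        idx = np.random.default_rng(_SUBSAMPLE_SEED).permutation(n)[:keep]
        pts = pts[:, np.sort(idx)]
    return pts


def estimate_rigid(
    moving: np.ndarray,
    reference: np.ndarray,
    geometry: VolumeGeometry,
    config: RealignConfig | None = None,
    init: RigidTransform | None = None,
) -> RigidTransform:
    """Estimate the rigid transform T minimizing
    ``sum (moving(T(x)) - reference(x))^2`` over the sampling grid.

    Gauss-Newton with analytic gradients; both volumes are pre-smoothed at
    ``config.smoothing_fwhm`` before estimation.  Raises on a flat (zero
    variance) reference; warns and returns the best iterate if the iteration
    limit is reached without meeting the tolerance.
    """
    config = config if config is not None else RealignConfig()
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError(
            f"moving {moving.shape} and reference {reference.shape} differ"
        )
    if reference.std() == 0:
        raise ValueError("reference volume has zero variance; cannot register")
    vs = geometry.voxel_size
    ref_s = _presmooth(reference, config.smoothing_fwhm, vs)
    mov_s = _presmooth(moving, config.smoothing_fwhm, vs)

    order = config.interp_degree_estimate
    mov_pref = ndimage.spline_filter(mov_s, order=order) if order > 1 else mov_s
    # image gradients in mm^-1, interpolated linearly during iteration
    grads = np.gradient(mov_s, *vs)

    pts = _sample_grid(moving.shape, vs, config.separation, config.quality)
    c = center_voxel(moving.shape)
    vs_a = np.asarray(vs)
    w_pts = (pts - c[:, None]) * vs_a[:, None]  # world coords of grid points
    ref_vals = sample_at(ref_s, pts, order=1, prefilter=False)

    p = (init.params.copy() if init is not None else np.zeros(6))
    best_p, best_cost = p.copy(), np.inf
    converged = False
    for _ in range(config.max_iter):
        r = rotation_matrix(*p[3:])
        w_t = r @ w_pts + p[:3, None]
        idx_t = w_t / vs_a[:, None] + c[:, None]
        inside = np.all((idx_t >= 0) & (idx_t <= (np.asarray(moving.shape)[:, None] - 1)),
                        axis=0)
        if inside.sum() < 12:
            raise ValueError("transform moved the sampling grid out of the volume")
        mov_vals = sample_at(mov_pref, idx_t, order=order, prefilter=False)
        resid = mov_vals - ref_vals
        resid[~inside] = 0.0
        cost = float(resid @ resid)
        if cost < best_cost:
            best_cost, best_p = cost, p.copy()

        g = np.stack([sample_at(gk, idx_t, order=1, prefilter=False) for gk in grads])
        g[:, ~inside] = 0.0
        drs = d_rotation_matrix(*p[3:])
        jac = np.empty((6, pts.shape[1]))
        jac[0:3] = g  # d residual / d translation
        for k in range(3):
            jac[3 + k] = np.einsum("ij,jn,in->n", drs[k], w_pts, g)
        jtj = jac @ jac.T
        jtr = jac @ resid
        jtj[np.diag_indices_from(jtj)] *= 1.0 + 1e-8
        try:
            delta = np.linalg.solve(jtj, jtr)
        except np.linalg.LinAlgError:
            break
        p = p - delta
        # convergence: translation step in mm, rotation step scaled by the
        # farthest grid point so both are commensurate displacements
        lever = float(np.abs(w_pts).max())
        step = max(float(np.abs(delta[:3]).max()),
                   float(np.abs(delta[3:]).max()) * lever)
        if step < config.tol_mm:
            converged = True
            r = rotation_matrix(*p[3:])
            w_t = r @ w_pts + p[:3, None]
            idx_t = w_t / vs_a[:, None] + c[:, None]
            mov_vals = sample_at(mov_pref, idx_t, order=order, prefilter=False)
            resid = mov_vals - ref_vals
            cost = float(resid @ resid)
            if cost < best_cost:
                best_cost, best_p = cost, p.copy()
            break
    if not converged:
        warnings.warn(
            "rigid estimation hit the iteration limit; returning best iterate",
            RuntimeWarning,
        )
    return RigidTransform.from_params(best_p)


def _reslice(volume: np.ndarray, transform: RigidTransform,
             geometry: VolumeGeometry, order: int) -> np.ndarray:
    return resample_volume(
        volume, transform.rotation, transform.translation,
        geometry.voxel_size, order=order,
    )


def realign_series(
    series: BoldSeries, config: RealignConfig | None = None
) -> tuple[BoldSeries, pd.DataFrame]:
    """Two-pass rigid realignment of a 4D series to its mean image.

    Pass 1 registers every volume to the first and rebuilds the mean; pass 2
    re-registers every volume to that mean.  Output volumes are resliced once
    with the reslicing B-spline degree.  Returns the realigned series and a
    QC table with 1-based volume index, the six parameters and the total
    displacement in mm.
    """
    config = config if config is not None else RealignConfig()
    n_vol = series.geometry.n_volumes
    if n_vol < 2:
        raise ValueError("realignment needs at least 2 volumes")
    geo3 = series.geometry
    data = series.data

    transforms: list[RigidTransform] = []
    reference = data[..., 0]
    for t in range(n_vol):
        if t == 0:
            transforms.append(RigidTransform.identity())
            continue
        try:
            transforms.append(
                estimate_rigid(data[..., t], reference, geo3, config)
            )
        except ValueError as exc:
            raise ValueError(f"volume {t + 1}: {exc}") from exc

    aligned = np.stack(
        [
            _reslice(data[..., t], transforms[t], geo3,
                     config.interp_degree_estimate)
            for t in range(n_vol)
        ],
        axis=-1,
    )
    mean_img = aligned.mean(axis=-1)

    out = np.empty_like(data)
    rows = []
    final: list[RigidTransform] = []
    for t in range(n_vol):
        try:
            tr = estimate_rigid(data[..., t], mean_img, geo3, config,
                                init=transforms[t])
        except ValueError as exc:
            raise ValueError(f"volume {t + 1}: {exc}") from exc
        final.append(tr)
        if np.any(tr.params):
            out[..., t] = _reslice(data[..., t], tr, geo3,
                                   config.interp_degree_reslice)
        else:
            out[..., t] = data[..., t]
        # report the *motion* estimate (inverse of the correction pull map),
        # so the table is directly comparable to an injected trajectory
        mv = tr.inverse()
        rows.append(
            {
                "volume": t + 1,
                "tx": mv.tx, "ty": mv.ty, "tz": mv.tz,
                "rx": mv.rx, "ry": mv.ry, "rz": mv.rz,
                "displacement": mv.displacement,
            }
        )
    table = pd.DataFrame(rows)
    return BoldSeries(geometry=series.geometry, data=out), table


def smooth_gaussian(series: BoldSeries, fwhm_mm: float = 0.8) -> BoldSeries:
    """Per-volume 3D Gaussian smoothing; ``fwhm_mm = 0`` is the identity.

    Sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` converted to voxel units;
    boundaries are handled by reflection, which preserves the volume mean.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return BoldSeries(geometry=series.geometry, data=series.data.copy())
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / v for v in series.geometry.voxel_size]
    out = ndimage.gaussian_filter(series.data, sigma=(*sigma_vox, 0.0),
                                  mode="reflect")
    return BoldSeries(geometry=series.geometry, data=out)


@dataclass
class MotionQCReport:
    """Verdict of the one-pixel motion exclusion rule plus summary stats."""

    passed: bool
    threshold_mm: float
    max_displacement_mm: float
    mean_displacement_mm: float
    offending_volumes: list[int]

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "threshold_mm": self.threshold_mm,
            "max_displacement_mm": self.max_displacement_mm,
            "mean_displacement_mm": self.mean_displacement_mm,
            "offending_volumes": self.offending_volumes,
        }


def motion_qc(
    table: pd.DataFrame,
    voxel_size_inplane_mm: float = 0.3125,
    max_pixels: float = 1.0,
) -> MotionQCReport:
    """Apply the subject-exclusion rule: fail iff any volume's total
    translation magnitude exceeds ``max_pixels`` in-plane voxels."""
    if len(table) == 0:
        raise ValueError("empty motion table")
    disp = np.asarray(table["displacement"], dtype=float)
    threshold = max_pixels * voxel_size_inplane_mm
    offending = [int(v) for v in table.loc[disp > threshold, "volume"]]
    return MotionQCReport(
        passed=len(offending) == 0,
        threshold_mm=float(threshold),
        max_displacement_mm=float(disp.max()),
        mean_displacement_mm=float(disp.mean()),
        offending_volumes=offending,
    )
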