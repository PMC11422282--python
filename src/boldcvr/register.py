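"""Affine subject-to-atlas registration and label back-projection.

The subject's mean functional image is aligned to the atlas template with a
9-parameter transform -- translation, rotation and scaling independently in
all three dimensions -- by Gauss-Newton least squares on normalized
intensities.  The fitted transform embeds the subject in atlas space; the
same mapping, evaluated in the pull direction with nearest-neighbor
interpolation, tags every subject voxel with its atlas region (the
inverse-transform step of the classic atlas-segmentation workflow), so label
values are preserved or shrunk, never invented.

Composition convention: scale, then rotate, then translate, about the volume
center (``w_atlas = R S w_subject + t``); serialized alongside the transform.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np


from ._transforms import (
    center_voxel,
    d_rotation_matrix,
    resample_volume,
    rotation_matrix,
    sample_at,
)
from .io import LabelAtlas, VolumeGeometry
from .realign import _presmooth, _sample_grid

__all__ = [
    "AffineTransform",
    "SubjectSegmentation",
    "AffineConfig",
    "register_affine",
    "segment_subject",
]


@dataclass(frozen=True)
class AffineTransform:
    """9-parameter affine: translations (mm), extrinsic x-y-z rotations (rad)
    and per-axis scales; ``matrix = R @ diag(scale)`` about the volume center."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    sx: float = 1.0
    sy: float = 1.0
    sz: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sx, self.sy, self.sz) <= 0:
            raise ValueError(
                f"scales must be positive, got {(self.sx, self.sy, self.sz)}"
            )

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls()

    @classmethod
    def from_params(cls, p: np.ndarray) -> "AffineTransform":
        return cls(*(float(v) for v in p))

    @property
    def params(self) -> np.ndarray:
        return np.array(
            [self.tx, self.ty, self.tz, self.rx, self.ry, self.rz,
             self.sx, self.sy, self.sz]
        )

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    @property
    def scale(self) -> np.ndarray:
        return np.array([self.sx, self.sy, self.sz])

    @property
    def matrix(self) -> np.ndarray:
        return rotation_matrix(self.rx, self.ry, self.rz) @ np.diag(self.scale)

    def apply(self, w: np.ndarray) -> np.ndarray:
        """Map world coordinates (3, N) through the transform."""
        return self.matrix @ w + self.translation[:, np.newaxis]

    def inverse_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(A_inv, t_inv) with ``w_subject = A_inv @ w_atlas + t_inv``."""
        a = self.matrix
        a_inv = np.linalg.inv(a)
        return a_inv, -a_inv @ self.translation

    def to_json(self, path: str | Path, geometry: VolumeGeometry | None = None) -> None:
        payload = {
            "convention": "scale, then rotate (extrinsic x-y-z), then "
                          "translate, about the volume center; maps subject "
                          "world mm to atlas world mm",
            "translation_mm": [self.tx, self.ty, self.tz],
            "rotation_rad": [self.rx, self.ry, self.rz],
            "scale": [self.sx, self.sy, self.sz],
        }
        if geometry is not None:
            payload["geometry"] = {
                "dims": list(geometry.dims),
                "voxel_size_mm": list(geometry.voxel_size),
            }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class AffineConfig:
    """Estimation settings for the 9-DOF fit."""

    smoothing_fwhm: float = 1.0
    separation: float = 0.625
    quality: float = 1.0
    max_iter: int = 60
    tol: float = 1e-6


@dataclass
class SubjectSegmentation:
    """Per-voxel leaf labels in subject space plus the fitted transform."""

    labels: np.ndarray
    transform: AffineTransform
    geometry: VolumeGeometry


def _normalize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        raise ValueError("volume has zero variance; cannot register")
    return (v - v.mean()) / s


def register_affine(
    subject_mean: np.ndarray,
    atlas_template: np.ndarray,
    geometry: VolumeGeometry,
    config: AffineConfig | None = None,
    init: AffineTransform | None = None,
) -> AffineTransform:
    """Fit the 9-parameter transform T minimizing
    ``sum (template(T(x)) - subject(x))^2`` on normalized intensities.

    Deterministic given its inputs.  Raises on constant input volumes.
    """
    config = config if config is not None else AffineConfig()
    subject = np.asarray(subject_mean, dtype=float)
    template = np.asarray(atlas_template, dtype=float)
    if subject.shape != template.shape:
        raise ValueError(
            f"subject {subject.shape} and template {template.shape} differ"
        )
    vs = np.asarray(geometry.voxel_size)
    sub_n = _normalize(_presmooth(subject, config.smoothing_fwhm, geometry.voxel_size))
    tpl_n = _normalize(_presmooth(template, config.smoothing_fwhm, geometry.voxel_size))
    grads = np.gradient(tpl_n, *geometry.voxel_size)

    pts = _sample_grid(subject.shape, geometry.voxel_size, config.separation,
                       config.quality)
    c = center_voxel(subject.shape)
    w_pts = (pts - c[:, None]) * vs[:, None]
    sub_vals = sample_at(sub_n, pts, order=1, prefilter=False)

    p = init.params.copy() if init is not None else AffineTransform.identity().params
    best_p, best_cost = p.copy(), np.inf
    converged = False
    for _ in range(config.max_iter):
        r_mat = rotation_matrix(*p[3:6])
        s_diag = np.diag(p[6:9])
        a = r_mat @ s_diag
        w_t = a @ w_pts + p[:3, None]
        idx_t = w_t / vs[:, None] + c[:, None]
        inside = np.all(
            (idx_t >= 0) & (idx_t <= (np.asarray(subject.shape)[:, None] - 1)), axis=0
        )
        tpl_vals = sample_at(tpl_n, idx_t, order=1, prefilter=False)
        # closed-form intensity gain/offset so the geometric parameters never
        # absorb an amplitude mismatch (e.g. from content leaving the volume)
        tv, sv = tpl_vals[inside], sub_vals[inside]
        var_t = tv.var()
        gain = float(np.cov(tv, sv)[0, 1] / var_t) if var_t > 0 else 1.0
        offset = float(sv.mean() - gain * tv.mean())
        resid = gain * tpl_vals + offset - sub_vals
        resid[~inside] = 0.0
        cost = float(resid @ resid)
        if cost < best_cost:
            best_cost, best_p = cost, p.copy()

        g = gain * np.stack(
            [sample_at(gk, idx_t, order=1, prefilter=False) for gk in grads]
        )
        g[:, ~inside] = 0.0
        sw = s_diag @ w_pts
        drs = d_rotation_matrix(*p[3:6])
        jac = np.empty((9, pts.shape[1]))
        jac[0:3] = g
        for k in range(3):
            jac[3 + k] = np.einsum("ij,jn,in->n", drs[k], sw, g)
        for k in range(3):  # d/d scale_k: R e_k w_k
            jac[6 + k] = (r_mat[:, k][:, None] * w_pts[k][None, :] * g).sum(axis=0)
        jtj = jac @ jac.T
        jtr = jac @ resid
        jtj[np.diag_indices_from(jtj)] *= 1.0 + 1e-8
        try:
            delta = np.linalg.solve(jtj, jtr)
        except np.linalg.LinAlgError:
            break
        p = p - delta
        p[6:9] = np.clip(p[6:9], 0.2, 5.0)
        lever = float(np.abs(w_pts).max())
        step = max(
            float(np.abs(delta[:3]).max()),
            float(np.abs(delta[3:6]).max()) * lever,
            float(np.abs(delta[6:9]).max()) * lever,
        )
        if step < config.tol * lever:
            converged = True
            break
    if not converged:
        warnings.warn(
            "affine estimation hit the iteration limit; returning best iterate",
            RuntimeWarning,
        )
    return AffineTransform.from_params(best_p)


def segment_subject(
    atlas: LabelAtlas, transform: AffineTransform | None = None
) -> SubjectSegmentation:
    """Tag each subject voxel with its atlas leaf label.

    ``transform`` maps subject space into atlas space (as fitted by
    :func:`register_affine`); labels are pulled back to the subject grid with
    nearest-neighbor interpolation, so the label set can only shrink.  With
    the identity (or ``None``, the atlas-space phantom default) the
    segmentation equals the atlas labels.
    """
    if transform is None or not np.any(
        transform.params - AffineTransform.identity().params
    ):
        return SubjectSegmentation(
            labels=atlas.labels.copy(),
            transform=AffineTransform.identity(),
            geometry=atlas.geometry,
        )
    a = transform.matrix
    if abs(np.linalg.det(a)) < 1e-12:
        raise ValueError("non-invertible affine transform")
    labels = resample_volume(
        atlas.labels.astype(np.int32),
        a,
        transform.translation,
        atlas.geometry.voxel_size,
        order=0,
        cval=0,
        prefilter=False,
    ).astype(np.int32)
    return SubjectSegmentation(labels=labels, transform=transform,
                               geometry=atlas.geometry)
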