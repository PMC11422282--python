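"""Shared numerics for rigid/affine transforms and volume resampling.

Conventions used throughout the package:

* voxel index ``i`` maps to world mm coordinates ``w = (i - c) * voxel_size``
  where ``c`` is the volume center in voxel units;
* rotations are extrinsic x-y-z Euler angles, ``R = Rz @ Ry @ Rx``, applied
  about the volume center;
* a transform with matrix ``A`` and translation ``t`` maps output-space world
  coordinates to input-space world coordinates, ``w_in = A @ w_out + t``
  (pull/resampling convention).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Extrinsic x-y-z rotation matrix, R = Rz @ Ry @ Rx."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rx_m = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry_m = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz_m = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz_m @ ry_m @ rx_m


def euler_from_matrix(r: np.ndarray) -> tuple[float, float, float]:
    """Recover extrinsic x-y-z Euler angles from a rotation matrix."""
    ry = np.arctan2(-r[2, 0], np.hypot(r[0, 0], r[1, 0]))
    if np.isclose(np.cos(ry), 0.0):  # gimbal lock: fold rz into rx
        rx = np.arctan2(-r[1, 2], r[1, 1])
        rz = 0.0
    else:
        rx = np.arctan2(r[2, 1], r[2, 2])
        rz = np.arctan2(r[1, 0], r[0, 0])
    return float(rx), float(ry), float(rz)


def d_rotation_matrix(rx: float, ry: float, rz: float) -> list[np.ndarray]:
    """Analytic derivatives of ``rotation_matrix`` w.r.t. each angle."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rx_m = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry_m = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz_m = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    drx = np.array([[0, 0, 0], [0, -sx, -cx], [0, cx, -sx]])
    dry = np.array([[-sy, 0, cy], [0, 0, 0], [-cy, 0, -sy]])
    drz = np.array([[-sz, -cz, 0], [cz, -sz, 0], [0, 0, 0]])
    return [rz_m @ ry_m @ drx, rz_m @ dry @ rx_m, drz @ ry_m @ rx_m]


def center_voxel(dims: tuple[int, int, int]) -> np.ndarray:
    return (np.asarray(dims, dtype=float) - 1.0) / 2.0


def world_to_index_map(
    matrix: np.ndarray,
    translation_mm: np.ndarray,
    dims: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a world-space map ``w_in = A w_out + t`` to voxel-index space.

    Returns (B, s) such that ``i_in = B @ i_out + s``.
    """
    vs = np.asarray(voxel_size, dtype=float)
    t = np.asarray(translation_mm, dtype=float)
    c = center_voxel(dims)
    # i_in = (A @ ((i_out - c) * vs) + t) / vs + c
    b = (matrix * vs[np.newaxis, :]) / vs[:, np.newaxis]
    s = (t - matrix @ (c * vs)) / vs + c
    return b, s


def index_grid(dims: tuple[int, int, int]) -> np.ndarray:
    """All voxel indices of a volume as a (3, N) float array."""
    grid = np.indices(dims, dtype=float)
    return grid.reshape(3, -1)


def resample_volume(
    volume: np.ndarray,
    matrix: np.ndarray,
    translation_mm: np.ndarray,
    voxel_size: tuple[float, float, float],
    order: int = 1,
    cval: float = 0.0,
    prefilter: bool = True,
) -> np.ndarray:
    """Resample ``volume`` under a world-space pull map ``w_in = A w_out + t``.

    The output grid equals the input grid; out-of-volume samples get ``cval``.
    """
    b, s = world_to_index_map(matrix, translation_mm, volume.shape, voxel_size)
    coords = b @ index_grid(volume.shape) + s[:, np.newaxis]
    out = ndimage.map_coordinates(
        volume, coords, order=order, mode="constant", cval=cval, prefilter=prefilter
    )
    return out.reshape(volume.shape)


def sample_at(
    volume: np.ndarray,
    coords: np.ndarray,
    order: int = 1,
    cval: float = 0.0,
    prefilter: bool = True,
) -> np.ndarray:
    """Interpolate ``volume`` at voxel-index coordinates (3, N)."""
    return ndimage.map_coordinates(
        volume, coords, order=order, mode="constant", cval=cval, prefilter=prefilter
    )
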