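"""Reading and writing the pipeline's on-disk artifacts.

4D BOLD series and 3D label atlases travel as NIfTI-1 (via nibabel); the
region-hierarchy table and the cohort manifest are tab-separated text with a
header row.  Voxel indices are 0-based internally; acquisition (volume)
indices are 1-based in all user-facing output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGeometry",
    "BoldSeries",
    "LabelAtlas",
    "CohortManifest",
    "REFERENCE_GEOMETRY",
    "read_bold",
    "write_bold",
    "read_atlas",
    "write_atlas",
    "read_manifest",
    "write_manifest",
]

REGION_TABLE_COLUMNS = ("label_id", "leaf_region", "composite_region")
MANIFEST_COLUMNS = ("subject_id", "condition", "path")
CONDITIONS = ("sham", "injured")


@dataclass(frozen=True)
class VolumeGeometry:
    """Grid geometry of an acquisition: matrix size, voxel size (mm), TR (s)."""

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    tr: float
    n_volumes: int = 1

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.n_volumes < 1:
            raise ValueError(f"n_volumes must be >= 1, got {self.n_volumes}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def shape4d(self) -> tuple[int, int, int, int]:
        return (*self.dims, self.n_volumes)

    def with_volumes(self, n_volumes: int) -> "VolumeGeometry":
        return VolumeGeometry(self.dims, self.voxel_size, self.tr, n_volumes)


#: Acquisition geometry of the reference study: 96x96 matrix, 22 slices of
#: 1 mm at 312.5 um in-plane, one volume every 6 s, repeated 150 times.
REFERENCE_GEOMETRY = VolumeGeometry((96, 96, 22), (0.3125, 0.3125, 1.0), 6.0, 150)


@dataclass
class BoldSeries:
    """A 4D BOLD acquisition: intensities indexed (x, y, z, volume)."""

    geometry: VolumeGeometry
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.geometry.shape4d:
            raise ValueError(
                f"data shape {self.data.shape} does not match geometry "
                f"{self.geometry.shape4d}"
            )
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                "non-finite intensity at voxel "
                f"({bad[0]}, {bad[1]}, {bad[2]}), volume {bad[3] + 1}"
            )


@dataclass
class LabelAtlas:
    """A labeled 3D volume plus the table mapping labels to the region hierarchy.

    ``labels`` holds non-negative integers, 0 = background.  ``region_table``
    has one row per leaf region with columns (label_id, leaf_region,
    composite_region); composite regions partition the leaf regions.
    """

    geometry: VolumeGeometry
    labels: np.ndarray
    region_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.allclose(self.labels, rounded):
                raise ValueError("atlas label volume is not integer-valued")
            self.labels = rounded.astype(np.int32)
        if self.labels.shape != self.geometry.dims:
            raise ValueError(
                f"label volume shape {self.labels.shape} does not match geometry "
                f"{self.geometry.dims}"
            )
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative (0 = background)")
        tbl = pd.DataFrame(self.region_table)
        missing = [c for c in REGION_TABLE_COLUMNS if c not in tbl.columns]
        if missing:
            raise ValueError(f"region table missing columns: {missing}")
        tbl = tbl.loc[:, list(REGION_TABLE_COLUMNS)].copy()
        tbl["label_id"] = tbl["label_id"].astype(int)
        if tbl["label_id"].duplicated().any():
            dupes = sorted(tbl.loc[tbl["label_id"].duplicated(), "label_id"])
            raise ValueError(f"duplicate label ids in region table: {dupes}")
        if tbl["leaf_region"].duplicated().any():
            dupes = sorted(tbl.loc[tbl["leaf_region"].duplicated(), "leaf_region"])
            raise ValueError(f"leaf region listed under more than one label: {dupes}")
        in_volume = set(np.unique(self.labels).tolist()) - {0}
        in_table = set(tbl["label_id"].tolist())
        orphans_vol = sorted(in_volume - in_table)
        orphans_tbl = sorted(in_table - in_volume)
        if orphans_vol:
            raise ValueError(
                f"labels present in volume but absent from table: {orphans_vol}"
            )
        if orphans_tbl:
            raise ValueError(
                f"labels present in table but absent from volume: {orphans_tbl}"
            )
        self.region_table = tbl.reset_index(drop=True)

    @property
    def leaf_regions(self) -> list[str]:
        return list(self.region_table["leaf_region"])

    @property
    def composite_regions(self) -> list[str]:
        return list(dict.fromkeys(self.region_table["composite_region"]))

    def leaves_of(self, composite: str) -> list[str]:
        sel = self.region_table["composite_region"] == composite
        if not sel.any():
            raise KeyError(f"unknown composite region {composite!r}")
        return list(self.region_table.loc[sel, "leaf_region"])

    def label_of(self, leaf_region: str) -> int:
        sel = self.region_table["leaf_region"] == leaf_region
        if not sel.any():
            raise KeyError(f"unknown leaf region {leaf_region!r}")
        return int(self.region_table.loc[sel, "label_id"].iloc[0])

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class CohortManifest:
    """Subject roster: one row of (subject_id, condition, path) per subject."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        tbl = pd.DataFrame(self.table)
        missing = [c for c in MANIFEST_COLUMNS if c not in tbl.columns]
        if missing:
            raise ValueError(f"cohort manifest missing columns: {missing}")
        tbl = tbl.loc[:, list(MANIFEST_COLUMNS)].copy()
        if tbl["subject_id"].duplicated().any():
            dupes = sorted(tbl.loc[tbl["subject_id"].duplicated(), "subject_id"])
            raise ValueError(f"duplicate subject ids: {dupes}")
        bad = sorted(set(tbl["condition"]) - set(CONDITIONS))
        if bad:
            raise ValueError(
                f"unknown conditions {bad}; expected one of {list(CONDITIONS)}"
            )
        self.table = tbl.reset_index(drop=True)

    @property
    def subjects(self) -> list[str]:
        return list(self.table["subject_id"])

    def condition_of(self, subject_id: str) -> str:
        sel = self.table["subject_id"] == subject_id
        if not sel.any():
            raise KeyError(f"unknown subject {subject_id!r}")
        return str(self.table.loc[sel, "condition"].iloc[0])

    def path_of(self, subject_id: str) -> Path:
        sel = self.table["subject_id"] == subject_id
        if not sel.any():
            raise KeyError(f"unknown subject {subject_id!r}")
        return Path(self.table.loc[sel, "path"].iloc[0])


def _affine_from_geometry(geometry: VolumeGeometry) -> np.ndarray:
    aff = np.diag([*geometry.voxel_size, 1.0])
    return aff


def write_bold(series: BoldSeries, path: str | Path) -> Path:
    """Write a 4D series as NIfTI-1 with voxel size and TR in the header."""
    path = Path(path)
    img = nib.Nifti1Image(series.data, _affine_from_geometry(series.geometry))
    img.header.set_zooms((*series.geometry.voxel_size, series.geometry.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, path)
    return path


def read_bold(path: str | Path, tr: float | None = None) -> BoldSeries:
    """Read a 4D NIfTI-1 series.

    The repetition time is taken from ``pixdim[4]`` when the header carries
    one; ``tr`` overrides it (and is required if the header has none).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such BOLD series: {path}")
    img = nib.load(path)
    if img.ndim != 4:
        raise ValueError(
            f"{path} has {img.ndim} dimensions; a 4D (x, y, z, volume) series "
            "is required"
        )
    data = np.asarray(img.dataobj, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise ValueError(
            f"{path}: non-finite intensity at voxel ({bad[0]}, {bad[1]}, "
            f"{bad[2]}), volume {bad[3] + 1}"
        )
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr is None:
        if header_tr <= 0:
            raise ValueError(f"{path}: header carries no TR; pass tr= explicitly")
        tr = header_tr
    geometry = VolumeGeometry(
        dims=tuple(int(d) for d in data.shape[:3]),
        voxel_size=tuple(float(z) for z in zooms[:3]),
        tr=float(tr),
        n_volumes=int(data.shape[3]),
    )
    return BoldSeries(geometry=geometry, data=data)


def write_atlas(atlas: LabelAtlas, volume_path: str | Path, table_path: str | Path) -> None:
    """Write the label volume (NIfTI, int32) and the region table (TSV)."""
    img = nib.Nifti1Image(
        atlas.labels.astype(np.int32), _affine_from_geometry(atlas.geometry)
    )
    img.header.set_zooms(atlas.geometry.voxel_size)
    nib.save(img, Path(volume_path))
    atlas.region_table.to_csv(table_path, sep="\t", index=False)


def read_atlas(
    volume_path: str | Path, table_path: str | Path, tr: float = 1.0
) -> LabelAtlas:
    """Read a label volume plus its region-hierarchy table; validates both ways.

    Every nonzero label in the volume must appear exactly once in the table and
    vice versa; violations raise with the orphan labels listed.
    """
    volume_path, table_path = Path(volume_path), Path(table_path)
    if not volume_path.exists():
        raise FileNotFoundError(f"no such atlas volume: {volume_path}")
    if not table_path.exists():
        raise FileNotFoundError(f"no such region table: {table_path}")
    img = nib.load(volume_path)
    if img.ndim != 3:
        raise ValueError(f"{volume_path} has {img.ndim} dimensions; expected 3")
    labels = np.asarray(img.dataobj)
    table = pd.read_csv(table_path, sep="\t")
    geometry = VolumeGeometry(
        dims=tuple(int(d) for d in labels.shape),
        voxel_size=tuple(float(z) for z in img.header.get_zooms()[:3]),
        tr=tr,
    )
    return LabelAtlas(geometry=geometry, labels=labels, region_table=table)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    manifest.table.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cohort manifest: {path}")
    return CohortManifest(pd.read_csv(path, sep="\t"))
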