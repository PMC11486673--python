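"""Imaging and tabular I/O: NIfTI volumes, 4D dynamic series, masks, CSV tables.

All volumes carry a NIfTI affine; analysis happens after everything has been
resampled onto a common reference grid (conventionally the post-contrast
T1-weighted grid that masks were drawn on). Voxel indices are 0-based; world
coordinates come from the affine.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from ._errors import ConfigError, InputError

__all__ = [
    "DynamicSeries",
    "VolumeMap",
    "MaskVOI",
    "read_series",
    "read_map",
    "read_mask",
    "write_series",
    "write_map",
    "write_mask",
    "write_table",
    "read_table",
    "resample_to_reference",
    "load_config",
    "config_hash",
]

MASK_LABELS = ("tumour", "tumour_CE", "control", "artery", "brain")


@dataclasses.dataclass
class DynamicSeries:
    """A 4D dynamic contrast-enhanced acquisition.

    data
        Signal array indexed (x, y, z, t), arbitrary scanner units.
    frame_times
        Seconds from the first acquisition; strictly increasing, one per frame.
    tr, te
        Repetition / echo time in ms.
    flip_angle
        Excitation flip angle in degrees.
    """

    data: np.ndarray
    frame_times: np.ndarray
    tr: float
    te: float
    flip_angle: float
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.data.ndim != 4:
            raise InputError(f"dynamic series must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] != len(self.frame_times):
            raise InputError(
                f"series has {self.data.shape[3]} frames but "
                f"{len(self.frame_times)} frame times were given"
            )
        if self.data.shape[3] < 3:
            raise InputError("dynamic series needs at least 3 frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise InputError("frame times must be strictly increasing")
        if not self.tr > 0:
            raise InputError(f"tr must be positive, got {self.tr}")
        if not 0 < self.flip_angle < 90:
            raise InputError(f"flip angle must be in (0, 90) degrees, got {self.flip_angle}")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


@dataclasses.dataclass
class VolumeMap:
    """A 3D scalar map (T1, Ktrans, rBF, ...). NaN marks excluded voxels."""

    data: np.ndarray
    affine: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise InputError(f"volume map must be 3D, got {self.data.ndim}D")
        if np.any(np.isinf(self.data)):
            raise InputError("volume map entries must be finite or NaN")
        self.affine = np.asarray(self.affine, dtype=np.float64)


@dataclasses.dataclass
class MaskVOI:
    """A binary volume of interest on the reference grid."""

    data: np.ndarray
    affine: np.ndarray
    label: str = "tumour"

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise InputError(f"mask must be 3D, got {arr.ndim}D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise InputError(f"mask values must be 0/1, found {vals[:5]}")
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# NIfTI round-trips


def read_series(
    path: str | Path,
    timing: Sequence[float],
    *,
    tr: float,
    te: float = 0.0,
    flip_angle: float,
) -> DynamicSeries:
    """Read a 4D NIfTI dynamic series; frame timing must be supplied (seconds).

    NIfTI headers do not reliably carry per-frame timestamps, so timing always
    comes from configuration, never guessed from TR.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise InputError(f"{path}: expected a 4D NIfTI, got {data.ndim}D")
    if len(timing) != data.shape[3]:
        raise InputError(
            f"{path}: series has {data.shape[3]} frames but timing has "
            f"{len(timing)} entries"
        )
    zooms = img.header.get_zooms()[:3]
    return DynamicSeries(
        data=data,
        frame_times=np.asarray(timing, dtype=np.float64),
        tr=tr,
        te=te,
        flip_angle=flip_angle,
        voxel_size=tuple(float(z) for z in zooms),
        affine=img.affine,
    )


def write_series(series: DynamicSeries, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(series.data, series.affine), str(path))
    return path


def read_map(path: str | Path, name: str = "", units: str = "") -> VolumeMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return VolumeMap(data=data, affine=img.affine, name=name or Path(path).stem, units=units)


def write_map(vmap: VolumeMap, path: str | Path, sidecar: bool = True) -> Path:
    """Write a scalar map as NIfTI; a JSON sidecar records name and units."""
    path = Path(path)
    nib.save(nib.Nifti1Image(vmap.data, vmap.affine), str(path))
    if sidecar:
        meta = {"name": vmap.name, "units": vmap.units}
        side = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
        side.write_text(json.dumps(meta, sort_keys=True) + "\n")
    return path


def read_mask(path: str | Path, label: str = "tumour") -> MaskVOI:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return MaskVOI(data=(data > 0.5).astype(np.uint8), affine=img.affine, label=label)


def write_mask(mask: MaskVOI, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))
    return path


# ---------------------------------------------------------------------------
# Resampling

def resample_to_reference(moving, reference: VolumeMap, mode: str = "linear"):
    """Resample ``moving`` (VolumeMap or MaskVOI) onto the grid of ``reference``.

    Scalar maps use trilinear interpolation; masks must use nearest-neighbour,
    which preserves binarity. Voxels that fall outside the moving image are
    NaN for maps and 0 for masks.
    """
    if mode not in ("linear", "nearest"):
        raise InputError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    is_mask = isinstance(moving, MaskVOI)
    if is_mask and mode != "nearest":
        raise InputError("masks must be resampled with nearest mode")
    try:
        mov_inv = np.linalg.inv(moving.affine)
    except np.linalg.LinAlgError as e:
        raise InputError(f"singular affine on moving image: {e}") from None
    # voxel(ref) -> world -> voxel(moving)
    xform = mov_inv @ reference.affine
    shape = reference.data.shape
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    coords = np.stack([ii, jj, kk, np.ones_like(ii)], axis=0).reshape(4, -1)
    mov_idx = (xform @ coords)[:3]
    order = 1 if mode == "linear" else 0
    data = ndimage.map_coordinates(
        moving.data.astype(np.float64),
        mov_idx,
        order=order,
        mode="constant",
        cval=0.0 if is_mask else np.nan,
    ).reshape(shape)
    if is_mask:
        return MaskVOI(data=(data > 0.5).astype(np.uint8), affine=reference.affine, label=moving.label)
    return VolumeMap(data=data, affine=reference.affine, name=moving.name, units=moving.units)


# ---------------------------------------------------------------------------
# Tables and configuration

TABLE_COLUMNS = [
    "subject",
    "group",
    "voi_label",
    "n_voxels",
    "n_excluded",
    "mean_ktrans",
    "mean_rbf",
    "voi_volume",
]


def write_table(rows, path: str | Path) -> Path:
    """Write per-subject VOI summaries to CSV (UTF-8, '.' decimal).

    ``rows`` may be a list of objects with the table's field names (e.g.
    ``VOISummary``) or an iterable of dicts; an empty list yields a
    header-only file.
    """
    records = []
    for r in rows:
        if isinstance(r, dict):
            records.append({c: r.get(c) for c in TABLE_COLUMNS})
        else:
            records.append({c: getattr(r, c, None) for c in TABLE_COLUMNS})
    df = pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse config {path}: {e}") from None
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping at top level")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance logging."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
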