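"""On-disk I/O and the gridded/tabular domain types shared by all QC metrics.

Volumes, masks and parcellations are NIfTI-1 files handled through nibabel;
motion and censor files are plain whitespace-delimited text; run configuration
is a flat YAML mapping.  World coordinates are always derived from the NIfTI
affine, so seed placement and centroid computation are unambiguous regardless
of the on-disk axis order or polarity.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .motionqc import MotionTrace

__all__ = [
    "VolumeGrid",
    "Volume4D",
    "BrainMask",
    "Parcellation",
    "RunConfig",
    "read_volume4d",
    "write_volume4d",
    "read_volume3d",
    "write_volume3d",
    "read_mask",
    "write_mask",
    "read_parcellation",
    "read_motion",
    "write_motion",
    "read_censor",
    "write_censor",
    "check_acquisition_consistency",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Spatial sampling grid: dimensions, voxel size and world mapping.

    ``affine`` is the 4x4 voxel-index -> world (mm) transform in the NIfTI
    convention (RAS+ world axes).
    """

    dims: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", affine)
        if len(self.dims) != 3 or any(int(d) <= 0 for d in self.dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def orientation(self) -> str:
        """Anatomical axis codes for the three array axes, e.g. 'RAS'."""
        return "".join(nib.orientations.aff2axcodes(self.affine))

    @property
    def is_oblique(self) -> bool:
        """True when the rotation part is not a signed permutation matrix."""
        rot = self.affine[:3, :3] / self.voxel_size_mm
        return not np.allclose(np.abs(rot).max(axis=0), 1.0, atol=1e-4)

    def axis_for(self, code: str) -> int:
        """Array axis mapped to the anatomical axis ``code`` ('L'/'R', ...)."""
        pairs = {"L": "LR", "R": "LR", "P": "PA", "A": "PA", "I": "IS", "S": "IS"}
        want = pairs[code]
        for ax, c in enumerate(self.orientation):
            if c in want:
                return ax
        raise ValueError(f"no axis maps to {code!r} in orientation {self.orientation}")

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """World (mm) coordinates of voxel indices, shape (..., 3)."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(self.affine, other.affine, atol=atol)


@dataclass
class Volume4D:
    """A 4D functional time series on a grid (signal units arbitrary)."""

    grid: VolumeGrid
    values: np.ndarray  # (x, y, z, t)
    nonfinite_warning: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(f"Volume4D requires a 4D array, got ndim={self.values.ndim}")
        if self.values.shape[:3] != self.grid.dims:
            raise ValueError("array shape does not match grid dims")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[3]


@dataclass
class BrainMask:
    grid: VolumeGrid
    member: np.ndarray  # boolean (x, y, z)

    def __post_init__(self):
        self.member = np.asarray(self.member).astype(bool)
        if self.member.shape != self.grid.dims:
            raise ValueError("mask shape does not match grid dims")

    @property
    def n_voxels(self) -> int:
        return int(self.member.sum())

    def require_nonempty(self):
        if not self.member.any():
            raise ValueError("mask is empty")


@dataclass
class Parcellation:
    """Labeled volume dividing the brain into regions (0 = background)."""

    grid: VolumeGrid
    labels: np.ndarray  # nonnegative int (x, y, z)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.dims:
            raise ValueError("label array shape does not match grid dims")
        if np.any(self.labels < 0):
            raise ValueError("labels must be nonnegative")

    @property
    def region_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def centroids_mm(self) -> np.ndarray:
        """Mean world coordinate of each region's member voxels, (R, 3)."""
        out = np.empty((self.n_regions, 3))
        for k, rid in enumerate(self.region_ids):
            ijk = np.argwhere(self.labels == rid)
            out[k] = self.grid.world_coords(ijk).mean(axis=0)
        return out

    def region_means(self, values: np.ndarray) -> np.ndarray:
        """Mean time course over each region, (T, R), from a 4D array."""
        T = values.shape[3]
        out = np.empty((T, self.n_regions))
        flat = values.reshape(-1, T)
        lab = self.labels.ravel()
        for k, rid in enumerate(self.region_ids):
            out[:, k] = flat[lab == rid].mean(axis=0)
        return out


@dataclass
class RunConfig:
    """Per-study processing parameters and exclusion cutoffs.

    Defaults follow the reference analysis: 0.4 mm censoring, band-pass
    0.01-0.1 Hz realized as stop-band regression, quadratic detrending, the
    full nuisance set with derivatives, smoothing to 8 mm FWHM, and Table-1
    style cutoffs of 15 residual degrees of freedom, 240 s of good data and
    a 3 mm maximum volume-to-volume motion flag.
    """

    tr_s: float = 2.5
    censor_threshold_mm: float = 0.4
    band_hz: tuple[float, float] | None = (0.01, 0.1)
    poly_order: int = 2
    nuisance_global: bool = True
    nuisance_wm: bool = True
    nuisance_csf: bool = True
    nuisance_motion: bool = True
    nuisance_derivatives: bool = True
    fwhm_target_mm: float | None = 8.0
    dof_cutoff: int = 15
    min_good_seconds: float = 240.0
    max_enorm_mm: float = 3.0
    strict_max_enorm: bool = False
    outlier_mad_k: float = 4.0

    def __post_init__(self):
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        for name in ("censor_threshold_mm", "min_good_seconds", "max_enorm_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.band_hz is not None:
            lo, hi = self.band_hz
            nyq = 1.0 / (2.0 * self.tr_s)
            if not (0.0 < lo < hi < nyq):
                raise ValueError(
                    f"band ({lo}, {hi}) must satisfy 0 < low < high < Nyquist={nyq:g}"
                )
            self.band_hz = (float(lo), float(hi))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "band_hz" in raw and raw["band_hz"] is not None:
            raw["band_hz"] = tuple(raw["band_hz"])
        return cls(**raw)

    def to_yaml(self, path):
        data = dataclasses.asdict(self)
        if data["band_hz"] is not None:
            data["band_hz"] = list(data["band_hz"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# NIfTI volumes

def _load_nifti(path):
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise ValueError(f"cannot read NIfTI file {path}: {exc}") from exc
    return img


def read_volume4d(path) -> Volume4D:
    """Read a 4D NIfTI time series; rejects 3D files explicitly."""
    img = _load_nifti(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"{path}: expected a 4D volume, file has {data.ndim} dimensions"
        )
    grid = VolumeGrid(dims=data.shape[:3], affine=np.asarray(img.affine))
    bad = not np.all(np.isfinite(data))
    if bad:
        warnings.warn(f"{path}: volume contains non-finite voxels", stacklevel=2)
    return Volume4D(grid=grid, values=data, nonfinite_warning=bad)


def write_volume4d(vol: Volume4D, path):
    img = nib.Nifti1Image(vol.values.astype(np.float32), vol.grid.affine)
    nib.save(img, str(path))


def read_volume3d(path) -> tuple[VolumeGrid, np.ndarray]:
    img = _load_nifti(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, file has {data.ndim} dimensions")
    return VolumeGrid(dims=data.shape, affine=np.asarray(img.affine)), data


def write_volume3d(grid: VolumeGrid, values: np.ndarray, path):
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid.affine)
    nib.save(img, str(path))


def read_mask(path) -> BrainMask:
    grid, data = read_volume3d(path)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError(f"{path}: mask values must be 0/1, found {uniq[:5]}")
    return BrainMask(grid=grid, member=data > 0.5)


def write_mask(mask: BrainMask, path):
    img = nib.Nifti1Image(mask.member.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def read_parcellation(path) -> Parcellation:
    grid, data = read_volume3d(path)
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6) or rounded.min() < 0:
        raise ValueError(f"{path}: parcellation labels must be nonnegative integers")
    return Parcellation(grid=grid, labels=rounded.astype(np.int32))


def write_parcellation(parc: Parcellation, path):
    img = nib.Nifti1Image(parc.labels.astype(np.int32), parc.grid.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Motion and censor text files

#: column orders accepted for 6-parameter rigid-body motion files
MOTION_CONVENTIONS = ("rotations-first", "translations-first")


def read_motion(path, tr_s: float, column_convention: str = "rotations-first") -> MotionTrace:
    """Read a whitespace-delimited 6-column realignment-parameter file.

    The stored trace always has rotations (degrees) in columns 0-2 and
    translations (mm) in columns 3-5; ``column_convention`` declares the
    on-disk order.
    """
    if column_convention not in MOTION_CONVENTIONS:
        raise ValueError(f"unknown column convention {column_convention!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 columns, found {len(tokens)}"
                )
            try:
                rows.append([float(t) for t in tokens])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric token: {exc}") from exc
    if len(rows) < 2:
        raise ValueError(f"{path}: motion file must have at least 2 rows")
    params = np.asarray(rows)
    if column_convention == "translations-first":
        params = params[:, [3, 4, 5, 0, 1, 2]]
    return MotionTrace(params=params, tr_s=tr_s)


def write_motion(trace: MotionTrace, path, column_convention: str = "rotations-first"):
    params = trace.params
    if column_convention == "translations-first":
        params = params[:, [3, 4, 5, 0, 1, 2]]
    elif column_convention != "rotations-first":
        raise ValueError(f"unknown column convention {column_convention!r}")
    np.savetxt(str(path), params, fmt="%.6f")


def read_censor(path):
    """Read a censor file (one 0/1 token per line; 1 = keep)."""
    from .motionqc import CensorMask

    keep = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            if tok not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: censor token must be 0 or 1, got {tok!r}")
            keep.append(tok == "1")
    if not keep:
        raise ValueError(f"{path}: empty censor file")
    return CensorMask(keep=np.asarray(keep, dtype=bool))


def write_censor(mask, path):
    with open(path, "w") as fh:
        for k in mask.keep:
            fh.write("1\n" if k else "0\n")


# ---------------------------------------------------------------------------
# Acquisition-parameter consistency

#: parameters compared against the within-site mode
CONSISTENCY_PARAMS = ("matrix_size", "voxel_size_mm", "tr_s", "oblique", "n_timepoints")


def check_acquisition_consistency(param_table: pd.DataFrame) -> pd.DataFrame:
    """Flag subjects whose acquisition parameters deviate from the site mode.

    ``param_table`` needs columns ``subject_id``, ``site`` and any of
    ``matrix_size``, ``voxel_size_mm``, ``tr_s``, ``oblique``,
    ``n_timepoints``.  Returns one row per deviation with the modal and
    observed values.  Sites with fewer than 2 subjects are skipped.
    """
    if param_table is None or len(param_table) == 0:
        raise ValueError("empty acquisition-parameter table")
    required = {"subject_id", "site"}
    if not required.issubset(param_table.columns):
        raise ValueError(f"table must contain columns {sorted(required)}")
    records = []
    for site, group in param_table.groupby("site", sort=True):
        if len(group) < 2:
            continue
        for param in CONSISTENCY_PARAMS:
            if param not in group.columns:
                continue
            col = group[param].map(
                lambda v: tuple(v) if isinstance(v, (list, tuple, np.ndarray)) else v
            )
            modal = col.mode().iloc[0]
            for sid, value in zip(group["subject_id"], col):
                if value != modal and not (pd.isna(value) and pd.isna(modal)):
                    records.append(
                        {
                            "site": site,
                            "subject_id": sid,
                            "parameter": param,
                            "modal_value": modal,
                            "observed_value": value,
                        }
                    )
    return pd.DataFrame(records, columns=["site", "subject_id", "parameter", "modal_value", "observed_value"])


def write_subject_qc_json(record: dict, path):
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
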