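"""Voxel volumes, VOI masks and NIfTI-1 I/O.

All imaging operations in this package assume co-registered inputs: the CT,
the PET and every mask live on one shared voxel grid (registration is done
upstream). :func:`validate_alignment` enforces that contract and is called by
every operation that pairs a volume with a mask.

Conventions
-----------
* Arrays are indexed ``(x, y, z)`` fastest-to-slowest as stored.
* CT values are Hounsfield units stored as integers (``int16`` on disk);
  non-integer CT input is rounded half away from zero.
* PET values are floating point (``float32`` on disk), in activity
  concentration (kBq/mL) or SUV.
* No resampling is ever performed; grid mismatch is an error, not a warning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from bmatquant.errors import AlignmentError, VolumeIOError

MODALITIES = ("CT", "PET", "UCT")

#: Default physical units per modality.
MODALITY_UNITS = {"CT": "HU", "UCT": "HU", "PET": "kBq/mL"}

SPACING_ATOL_MM = 1e-6


def round_hu(values: np.ndarray) -> np.ndarray:
    """Round to integer HU, halves away from zero (symmetric about 0 HU)."""
    arr = np.asarray(values, dtype=float)
    return (np.sign(arr) * np.floor(np.abs(arr) + 0.5)).astype(np.int32)


@dataclass
class VoxelVolume:
    """A 3-D scalar grid with physical spacing, origin and modality tag.

    Parameters
    ----------
    values
        3-D array. Integer HU for CT/UCT; float for PET.
    spacing
        Voxel size in mm per axis (positive).
    origin
        Physical offset of the first voxel in mm.
    modality
        One of ``CT``, ``PET``, ``UCT``.
    units
        Physical units of ``values``; defaults per modality.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise VolumeIOError(
                f"volume must be 3-D, got {self.values.ndim}-D with shape {self.values.shape}"
            )
        if self.modality not in MODALITIES:
            raise VolumeIOError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"voxel spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(np.asarray(self.values, dtype=float))):
            raise VolumeIOError("volume contains non-finite values")
        if self.modality in ("CT", "UCT") and not np.issubdtype(self.values.dtype, np.integer):
            self.values = round_hu(self.values)
        if not self.units:
            self.units = MODALITY_UNITS[self.modality]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class VOIMask:
    """Integer label image aligned to a :class:`VoxelVolume`.

    Label 0 is reserved for background; ``region_names`` maps every positive
    label to a region name (e.g. ``sternum_BM``, ``vertebrae_BM``, ``rod_1``).
    """

    labels: np.ndarray
    region_names: dict[int, str]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeIOError(f"mask must be 3-D, got {self.labels.ndim}-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeIOError("mask labels must be integers")
        self.region_names = {int(k): str(v) for k, v in self.region_names.items()}
        if 0 in self.region_names:
            raise VolumeIOError("label 0 is reserved for background")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def label_of(self, region: str) -> int:
        for label, name in self.region_names.items():
            if name == region:
                return label
        from bmatquant.errors import RegionLookupError

        raise RegionLookupError(
            f"region {region!r} not in mask (known regions: {sorted(self.region_names.values())})"
        )

    def region_indices(self, region: str) -> np.ndarray:
        """Flat indices of the voxels labeled ``region``."""
        label = self.label_of(region)
        return np.flatnonzero(self.labels.ravel() == label)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_volume(volume: VoxelVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (int16 for CT/UCT, float32 for PET)."""
    path = Path(path)
    dtype = np.int16 if volume.modality in ("CT", "UCT") else np.float32
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=dtype), _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    try:
        nib.save(img, path)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise VolumeIOError(f"cannot write volume to {path}: {exc}") from exc
    return path


def read_volume(path: str | Path, expected_modality: str = "CT") -> VoxelVolume:
    """Read a NIfTI-1 volume, tagging it with the caller's modality."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"volume file not found: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise VolumeIOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3-D volume, got {data.ndim}-D shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelVolume(values=data, spacing=spacing, origin=origin, modality=expected_modality)


def write_mask(mask: VOIMask, path: str | Path) -> Path:
    """Write a label mask as NIfTI-1 plus a JSON sidecar with region names.

    The sidecar ``<stem>.json`` holds ``{label_id: name}``.
    """
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask.labels, dtype=np.int16), _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, path)
    sidecar = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
    sidecar.write_text(json.dumps({str(k): v for k, v in mask.region_names.items()}, indent=1))
    return path


def read_mask(path: str | Path) -> VOIMask:
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"mask file not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    sidecar = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
    if sidecar.exists():
        names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    else:
        names = {int(v): f"region_{int(v)}" for v in np.unique(data) if v != 0}
    return VOIMask(
        labels=data.astype(np.int32),
        region_names=names,
        spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
        origin=tuple(float(v) for v in img.affine[:3, 3]),
    )


def validate_alignment(volume: VoxelVolume, mask: VOIMask | VoxelVolume) -> None:
    """Enforce the shared-grid contract: equal shapes, spacing within 1e-6 mm.

    Raises
    ------
    AlignmentError
        If shapes differ or spacing differs by more than 1e-6 mm on any axis.
    """
    if volume.shape != mask.shape:
        raise AlignmentError(
            f"grid shape mismatch: volume {volume.shape} vs mask {mask.shape}"
        )
    if not np.allclose(volume.spacing, mask.spacing, atol=SPACING_ATOL_MM, rtol=0.0):
        raise AlignmentError(
            f"voxel spacing mismatch: volume {volume.spacing} mm vs mask {mask.spacing} mm"
        )
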