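"""Reading and writing of volumes, masks, label maps, heatmaps and displacement fields.

All in-memory grids use ``(x, y, z)`` index order with 0-based, voxel-centred
coordinates: the physical position of index ``i`` along an axis is
``origin + i * spacing``.  On disk, volumes are NIfTI-1 (``.nii``/``.nii.gz``)
or MetaImage (``.mha``/``.mhd``); displacement fields are 4-D NIfTI with the
last axis holding the three vector components (mm).  SimpleITK handles both
formats; its ``GetArrayFromImage`` returns ``(z, y, x)``, which is transposed
on the way in and out so that a single convention holds everywhere in memory.

Storage dtypes: HU volumes ``int16``, label maps ``uint8``, fields and
heatmaps ``float32``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger("prm3d")

HU_MIN = -1100.0
HU_MAX = 3100.0

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


class FormatError(ValueError):
    """Unreadable file or unsupported on-disk layout."""


class GeometryError(ValueError):
    """Grids that are required to share geometry do not."""


@dataclass
class CTVolume:
    """A 3-D scalar grid in Hounsfield units with voxel geometry.

    ``voxels`` is indexed ``(x, y, z)``; ``spacing`` and ``origin`` are mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3-D grid, got {self.voxels.ndim}-D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_geometry(self, other: "CTVolume | LungMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LungMask:
    """Binary lung segmentation sharing geometry with its CT volume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3-D mask, got {self.voxels.ndim}-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class DisplacementField:
    """Per-voxel displacement u (mm) on the expiration grid.

    Mapping convention: ``x_insp = x_exp + u(x_exp)`` in physical mm.
    ``vectors`` has shape ``(nx, ny, nz, 3)``.
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    reference: str = "expiration"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float32)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise FormatError(
                f"displacement field must be (nx, ny, nz, 3), got {self.vectors.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(f"unsupported format: {path.name}")


def read_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI or MetaImage scalar volume.

    Integer on-disk dtypes are preserved (label maps stay exact); the array
    is returned in ``(x, y, z)`` order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - corrupt file branch
        raise FormatError(f"could not read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(
            f"expected a 3-D volume, got {img.GetDimension()}-D in {path.name}"
        )
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    voxels = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return CTVolume(
        voxels=voxels,
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def write_volume(vol: CTVolume | np.ndarray, path: str | Path, *, dtype=None) -> None:
    """Write a volume, label grid or heatmap.

    Integer arrays round-trip bit-identically; floats are stored as float32.
    """
    path = Path(path)
    _check_suffix(path)
    if isinstance(vol, CTVolume):
        voxels, spacing, origin = vol.voxels, vol.spacing, vol.origin
    else:
        voxels = np.asarray(vol)
        spacing, origin = (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)
    if dtype is None:
        dtype = voxels.dtype if np.issubdtype(voxels.dtype, np.integer) else np.float32
    arr = voxels.astype(dtype).transpose(2, 1, 0)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise IOError(f"could not write {path}: {exc}") from exc


def write_mask(mask: LungMask, path: str | Path) -> None:
    write_volume(
        CTVolume(mask.voxels.astype(np.uint8), mask.spacing, mask.origin), path,
        dtype=np.uint8,
    )


def read_mask(path: str | Path) -> LungMask:
    vol = read_volume(path)
    return LungMask(vol.voxels > 0, vol.spacing, vol.origin)


def read_field(path: str | Path) -> DisplacementField:
    """Read a displacement field stored as 4-D NIfTI (last axis = 3 components)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 4:
        raise FormatError(f"expected a 4-D field, got {img.GetDimension()}-D")
    arr = sitk.GetArrayFromImage(img)  # (t, z, y, x) with t = component
    if arr.shape[0] != 3:
        raise FormatError(f"expected 3 vector components, got {arr.shape[0]}")
    vectors = np.ascontiguousarray(arr.transpose(3, 2, 1, 0)).astype(np.float32)
    spacing = tuple(img.GetSpacing())[:3]
    origin = tuple(img.GetOrigin())[:3]
    return DisplacementField(vectors=vectors, spacing=spacing, origin=origin)


def write_field(fld: DisplacementField, path: str | Path) -> None:
    path = Path(path)
    arr = fld.vectors.astype(np.float32).transpose(3, 2, 1, 0)  # (c, z, y, x)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr), isVector=False)
    img.SetSpacing(tuple(float(s) for s in fld.spacing) + (1.0,))
    img.SetOrigin(tuple(float(o) for o in fld.origin) + (0.0,))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
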