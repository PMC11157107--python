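"""Volume I/O and grid conditioning.

Reads and writes NIfTI-1 volumes, reorients them to one canonical
anatomical axis order, and provides the preprocessing primitives that put
two orthogonal acquisitions onto a single isotropic, identically shaped,
consistently scaled grid: isotropic resampling, centered zero-padding, and
98th-percentile intensity normalization.

All grids are index-addressed 0-based; voxel (0, 0, 0) is the grid corner.
Canonical orientation is RAS ("closest canonical" in nibabel terms), so the
three array axes carry the anatomical labels LR, AP, SI in that order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Anatomical labels of the canonical (RAS) axis order.
CANONICAL_AXIS_LABELS = ("LR", "AP", "SI")


class VolumeError(ValueError):
    """Raised for invalid volumes or volume operations."""


@dataclass(frozen=True)
class Volume:
    """A 3D scalar image with voxel spacing and axis metadata.

    Parameters
    ----------
    data : ndarray
        Real-valued 3D grid, arbitrary intensity units.
    spacing : tuple of float
        Per-axis voxel size in mm, strictly positive.
    axis_labels : tuple of str
        Ordered anatomical axis names, three distinct entries.
    name : str
        Free-text provenance tag.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    axis_labels: tuple[str, str, str] = CANONICAL_AXIS_LABELS
    name: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VolumeError(f"volume data must be 3D, got {data.ndim}D")
        if any(n < 2 for n in data.shape):
            raise VolumeError(f"every axis needs length >= 2, got shape {data.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be 3 positive values, got {self.spacing}")
        if len(self.axis_labels) != 3 or len(set(self.axis_labels)) != 3:
            raise VolumeError(f"axis_labels must be 3 distinct names, got {self.axis_labels}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "axis_labels", tuple(self.axis_labels))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, name: str | None = None) -> "Volume":
        return replace(self, data=data, name=self.name if name is None else name)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Resolution geometry of one anisotropic 3D acquisition.

    ``slice_axis`` indexes the under-sampled (through-plane) axis in the
    canonical axis order; the remaining two axes are in-plane.
    """

    in_plane_mm: float
    slice_mm: float
    slice_axis: int

    def __post_init__(self) -> None:
        if not self.in_plane_mm > 0:
            raise VolumeError(f"in_plane_mm must be > 0, got {self.in_plane_mm}")
        if self.slice_mm < self.in_plane_mm:
            raise VolumeError(
                f"slice_mm ({self.slice_mm}) must be >= in_plane_mm ({self.in_plane_mm})"
            )
        if self.slice_axis not in (0, 1, 2):
            raise VolumeError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")


def read_volume(path: str | Path) -> Volume:
    """Load a NIfTI-1 volume, reoriented to the canonical axis order.

    The image is reoriented to the closest canonical (RAS) orientation so
    that two scans acquired in different planes share axis semantics; the
    voxel spacing is taken from the reoriented header.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    VolumeError
        If the image is not 3D or the header cannot be read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise VolumeError(f"could not read NIfTI header of {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise VolumeError(f"{path} is {len(img.shape)}D; only 3D volumes are supported")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, axis_labels=CANONICAL_AXIS_LABELS, name=path.name)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a diagonal RAS affine from its spacing."""
    path = Path(path)
    if not path.parent.exists():
        raise VolumeError(f"parent directory does not exist: {path.parent}")
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def _round_half_away(x: float) -> int:
    """Round half away from zero (deterministic extent rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def resample_isotropic(vol: Volume, target_mm: float, method: str = "nearest") -> Volume:
    """Resample a volume onto an isotropic grid of ``target_mm`` spacing.

    The output extent per axis is the physical extent divided by the target
    spacing, rounded half away from zero. ``method`` selects nearest-neighbor
    or trilinear interpolation; sample positions map the grid corner of the
    output to the grid corner of the input.
    """
    if not target_mm > 0:
        raise VolumeError(f"target_mm must be > 0, got {target_mm}")
    if method not in ("nearest", "linear"):
        raise VolumeError(f"method must be 'nearest' or 'linear', got {method!r}")
    if any(n < 2 for n in vol.shape):
        raise VolumeError(f"degenerate input shape {vol.shape}")

    if all(abs(s - target_mm) < 1e-12 for s in vol.spacing):
        return replace(vol, spacing=(target_mm,) * 3)

    out_shape = tuple(
        max(2, _round_half_away(n * s / target_mm)) for n, s in zip(vol.shape, vol.spacing)
    )
    grids = np.meshgrid(
        *[np.arange(n) * target_mm / s for n, s in zip(out_shape, vol.spacing)],
        indexing="ij",
    )
    order = 0 if method == "nearest" else 1
    data = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=np.float64), np.stack(grids), order=order, mode="nearest"
    )
    return Volume(data=data, spacing=(target_mm,) * 3, axis_labels=vol.axis_labels, name=vol.name)


def pad_to_shape(vol: Volume, shape: tuple[int, int, int]) -> Volume:
    """Zero-pad a volume, centered, to a uniform target shape.

    The centering offset per axis is ``floor((target - current) / 2)``.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3:
        raise VolumeError(f"target shape must have 3 entries, got {shape}")
    if any(t < c for t, c in zip(shape, vol.shape)):
        raise VolumeError(f"target shape {shape} smaller than input {vol.shape}")
    pads = []
    for t, c in zip(shape, vol.shape):
        lo = (t - c) // 2
        pads.append((lo, t - c - lo))
    data = np.pad(vol.data, pads, mode="constant", constant_values=0)
    return vol.with_data(data)


def normalize_p98(vol: Volume) -> Volume:
    """Divide all intensities by the 98th percentile of the nonzero voxels.

    The percentile support is restricted to nonzero voxels so that
    zero-padded or masked-out background does not drag the divisor down;
    values above the percentile are kept, not clipped.
    """
    nz = vol.data[vol.data != 0]
    if nz.size == 0:
        raise VolumeError("cannot normalize an all-zero volume")
    divisor = float(np.percentile(nz, 98))
    if divisor == 0:
        raise VolumeError("98th percentile of nonzero voxels is zero")
    return vol.with_data(vol.data / divisor)
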