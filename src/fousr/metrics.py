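"""Image-quality metrics for lesion-bearing MRI volumes.

SNR, CNR and lesion conspicuity measure lesion visibility against
normal-appearing white matter (NAWM) and background noise; sharpness is the
standard deviation of the discrete 3D Laplacian response (variance-of-
Laplacian family), computed over the whole image or over dilated per-lesion
neighborhoods.

Conventions: the Laplacian is the 6-neighbor second-difference stencil with
edge replication at the borders; connected components and dilation use
26-connectivity; lesion sharpness is reported on the natural-log scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .volume import Volume

#: 26-connectivity structuring element for 3D lesion analysis.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class MetricError(ValueError):
    """Raised for invalid masks or degenerate metric inputs."""


class LesionSharpness(NamedTuple):
    lesion_id: int
    voxel_count: int
    log_sharpness: float  # NaN when the ROI has zero Laplacian variance


@dataclass(frozen=True)
class RoiSet:
    """Lesion / NAWM / background-noise masks on a shared grid.

    NAWM is white matter with lesions subtracted, so the lesion and NAWM
    masks must be disjoint.  ``lesion_labels`` holds connected-component
    IDs (0 = background), consecutive from 1, all inside the lesion mask.
    """

    lesion_mask: np.ndarray
    nawm_mask: np.ndarray
    noise_mask: np.ndarray
    lesion_labels: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lesion = np.asarray(self.lesion_mask, dtype=bool)
        nawm = np.asarray(self.nawm_mask, dtype=bool)
        noise = np.asarray(self.noise_mask, dtype=bool)
        if not (lesion.shape == nawm.shape == noise.shape):
            raise MetricError("all ROI grids must share one shape")
        if np.any(lesion & nawm):
            raise MetricError("lesion and NAWM masks overlap; NAWM excludes lesions")
        labels = self.lesion_labels
        if labels is None:
            labels = split_lesions(lesion)
        labels = np.asarray(labels)
        if labels.shape != lesion.shape:
            raise MetricError("lesion_labels shape mismatch")
        if np.any((labels > 0) & ~lesion):
            raise MetricError("positive lesion labels must lie inside the lesion mask")
        ids = np.unique(labels[labels > 0])
        if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise MetricError("lesion labels must be consecutive from 1")
        object.__setattr__(self, "lesion_mask", lesion)
        object.__setattr__(self, "nawm_mask", nawm)
        object.__setattr__(self, "noise_mask", noise)
        object.__setattr__(self, "lesion_labels", labels.astype(np.int32))

    @property
    def n_lesions(self) -> int:
        return int(self.lesion_labels.max())


@dataclass
class QualityReport:
    """Per-method quality metrics plus per-lesion sharpness records."""

    method_name: str
    snr: float
    cnr: float
    conspicuity: float
    image_sharpness: float
    lesion_sharpness: list[LesionSharpness] = field(default_factory=list)


def _as_mask(grid: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(grid)
    if arr.dtype != bool:
        values = np.unique(arr)
        if not np.all(np.isin(values, (0, 1))):
            raise MetricError(f"{what} must be binary, found values {values[:5]}")
        arr = arr.astype(bool)
    if arr.ndim != 3:
        raise MetricError(f"{what} must be 3D")
    return arr


def split_lesions(lesion_mask: np.ndarray) -> np.ndarray:
    """Label connected lesion clusters 1..K under 26-connectivity.

    Labels are assigned in lexicographic order of each component's first
    voxel (C order), so the labeling is deterministic.
    """
    mask = _as_mask(lesion_mask, "lesion mask")
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n > 1:
        # relabel by each component's first voxel in C order
        flat_first = ndimage.minimum(
            np.arange(labels.size).reshape(labels.shape), labels, index=np.arange(1, n + 1)
        )
        remap = np.zeros(n + 1, dtype=np.int32)
        order = np.argsort(flat_first)  # old labels (0-based) sorted by first voxel
        for new_id, old_idx in enumerate(order, start=1):
            remap[old_idx + 1] = new_id
        labels = remap[labels]
    return labels.astype(np.int32)


def _masked(vol: Volume | np.ndarray, mask: np.ndarray) -> np.ndarray:
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol)
    if data.shape != mask.shape:
        raise MetricError(f"mask shape {mask.shape} does not match volume {data.shape}")
    return data[mask]


def snr(vol: Volume, signal_mask: np.ndarray, noise_mask: np.ndarray) -> float:
    """Mean signal over the signal ROI divided by the noise-ROI standard deviation."""
    signal = _masked(vol, _as_mask(signal_mask, "signal mask"))
    noise = _masked(vol, _as_mask(noise_mask, "noise mask"))
    if signal.size == 0 or noise.size == 0:
        raise MetricError("signal and noise masks must be nonempty")
    noise_std = float(np.std(noise))
    if noise_std == 0:
        raise MetricError("noise region has zero variance")
    return float(np.mean(signal)) / noise_std


def cnr(
    vol: Volume,
    lesion_mask: np.ndarray,
    nawm_mask: np.ndarray,
    noise_mask: np.ndarray,
) -> float:
    """|mean(lesion) - mean(NAWM)| relative to the background-noise standard deviation."""
    lesion = _masked(vol, _as_mask(lesion_mask, "lesion mask"))
    nawm = _masked(vol, _as_mask(nawm_mask, "NAWM mask"))
    noise = _masked(vol, _as_mask(noise_mask, "noise mask"))
    if lesion.size == 0 or nawm.size == 0 or noise.size == 0:
        raise MetricError("all masks must be nonempty")
    noise_std = float(np.std(noise))
    if noise_std == 0:
        raise MetricError("noise region has zero variance")
    return abs(float(np.mean(lesion)) - float(np.mean(nawm))) / noise_std


def conspicuity(vol: Volume, lesion_mask: np.ndarray, nawm_mask: np.ndarray) -> float:
    """(mean lesion - mean NAWM) / (mean lesion + mean NAWM): a noise-free visibility index."""
    lesion = _masked(vol, _as_mask(lesion_mask, "lesion mask"))
    nawm = _masked(vol, _as_mask(nawm_mask, "NAWM mask"))
    if lesion.size == 0 or nawm.size == 0:
        raise MetricError("lesion and NAWM masks must be nonempty")
    m_lesion = float(np.mean(lesion))
    m_nawm = float(np.mean(nawm))
    denom = m_lesion + m_nawm
    if denom == 0:
        raise MetricError("conspicuity undefined: mean(lesion) + mean(NAWM) is zero")
    return (m_lesion - m_nawm) / denom


def laplacian_response(vol: Volume | np.ndarray) -> np.ndarray:
    """6-neighbor discrete 3D Laplacian with edge replication."""
    data = vol.data if isinstance(vol, Volume) else np.asarray(vol, dtype=np.float64)
    if data.ndim != 3 or any(n < 3 for n in data.shape):
        raise MetricError(f"need a 3D volume with >= 3 voxels per axis, got shape {data.shape}")
    return ndimage.laplace(np.asarray(data, dtype=np.float64), mode="nearest")


def laplacian_sharpness(vol: Volume, roi: np.ndarray | None = None) -> float:
    """Standard deviation of the Laplacian response over an ROI (whole grid if absent).

    Sharper edges produce larger second-derivative excursions, hence a
    larger dispersion; blurring lowers it.
    """
    response = laplacian_response(vol)
    if roi is None:
        return float(np.std(response))
    roi = _as_mask(roi, "ROI")
    values = _masked(response, roi)
    if values.size == 0:
        raise MetricError("ROI is empty")
    return float(np.std(values))


def lesion_sharpness(
    vol: Volume, lesion_labels: np.ndarray, dilation_voxels: int = 1
) -> list[LesionSharpness]:
    """Per-lesion sharpness: Laplacian std over each dilated lesion, natural-log scale.

    Each label's mask is dilated by ``dilation_voxels`` applications of the
    26-connectivity structuring element so the ROI straddles the lesion
    boundary.  A lesion whose ROI has zero Laplacian variance (no edge at
    all) gets ``log_sharpness = NaN`` — an explicit missing value.
    """
    labels = np.asarray(lesion_labels)
    data = vol.data
    if labels.shape != data.shape:
        raise MetricError(f"label grid shape {labels.shape} does not match volume {data.shape}")
    if dilation_voxels < 0:
        raise MetricError("dilation_voxels must be >= 0")
    n = int(labels.max())
    if n < 1:
        raise MetricError("no lesion labels present")
    response = laplacian_response(vol)
    records: list[LesionSharpness] = []
    for lesion_id in range(1, n + 1):
        mask = labels == lesion_id
        roi = (
            ndimage.binary_dilation(mask, structure=_STRUCT_26, iterations=dilation_voxels)
            if dilation_voxels > 0
            else mask
        )
        value = float(np.std(response[roi]))
        log_value = math.log(value) if value > 0 else float("nan")
        records.append(LesionSharpness(lesion_id, int(mask.sum()), log_value))
    return records
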