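"""Digital phantoms and simulated orthogonal anisotropic acquisitions.

The phantom is a piecewise-constant head-like object: an ellipsoid of
tissue in a dark background, carrying hyperintense spherical lesions and a
set of bar gratings at several spatial scales (the classic resolution
pattern).  Exact lesion, NAWM and background-noise masks come for free.

An acquisition is modeled in k-space: a thick-slice scan with slice
thickness ``slice_mm`` and in-plane resolution ``in_plane_mm`` retains only
the central ``round(extent * in_plane / slice)`` spectral planes along its
slice axis (ideal truncation — resolution as spectral support).  Complex
Gaussian noise of a chosen standard deviation is added to the real and
imaginary channels of the inverse transform before the magnitude is taken,
giving Rician magnitude statistics (Rayleigh in signal-free background).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import AcquisitionGeometry, Volume, _round_half_away
from .metrics import RoiSet, split_lesions


class PhantomError(ValueError):
    """Raised for invalid phantom specs or impossible lesion placement."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensities of a synthetic ground-truth volume.

    Intensities are nonnegative; lesions must differ from tissue to be
    visible.  ``lesion_radius_range`` is in mm; ``spacing_mm`` sets the
    isotropic voxel size of the truth grid.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    background_level: float = 0.0
    tissue_level: float = 1.0
    lesion_level: float = 1.6
    n_lesions: int = 8
    lesion_radius_range: tuple[float, float] = (2.5, 6.0)
    spacing_mm: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.shape):
            raise PhantomError(f"phantom shape too small: {self.shape}")
        if min(self.background_level, self.tissue_level, self.lesion_level) < 0:
            raise PhantomError("intensities must be nonnegative")
        if self.tissue_level == self.lesion_level:
            raise PhantomError("tissue_level must differ from lesion_level")
        if self.n_lesions < 0:
            raise PhantomError("n_lesions must be >= 0")
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise PhantomError(f"invalid lesion_radius_range {self.lesion_radius_range}")
        if self.spacing_mm <= 0:
            raise PhantomError("spacing_mm must be positive")


@dataclass(frozen=True)
class AcquisitionSim:
    """One simulated anisotropic acquisition: geometry, noise level, seed.

    ``shift_voxels`` applies a rigid integer-voxel shift to the object
    before acquisition — off by default; turning it on demonstrates the
    ringing artifacts that residual registration mismatch produces in the
    fused image.
    """

    geometry: AcquisitionGeometry
    noise_sigma: float = 0.0
    seed: int = 0
    shift_voxels: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise PhantomError("noise_sigma must be >= 0")
        if len(self.shift_voxels) != 3:
            raise PhantomError("shift_voxels needs 3 entries")


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def make_phantom(spec: PhantomSpec) -> tuple[Volume, RoiSet]:
    """Build the ground-truth volume and its exact ROI set.

    Deterministic under ``spec.seed``.  Lesions are non-overlapping spheres
    placed inside the tissue ellipsoid away from the bar gratings; NAWM is
    the uniform tissue (ellipsoid minus lesions minus gratings); the noise
    mask is a background corner box guaranteed signal-free.

    Raises
    ------
    PhantomError
        If a lesion cannot be placed without overlap after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    center = tuple((n - 1) / 2.0 for n in shape)
    semiaxes = tuple(0.40 * n for n in shape)

    data = np.full(shape, spec.background_level, dtype=np.float64)
    tissue = _ellipsoid_mask(shape, center, semiaxes)
    data[tissue] = spec.tissue_level

    # Bar gratings at several spatial scales, hypointense relative to tissue,
    # confined to a slab in the lower third of the ellipsoid.
    bar_level = 0.5 * (spec.background_level + spec.tissue_level)
    bars = np.zeros(shape, dtype=bool)
    z0 = int(0.22 * shape[2])
    z1 = int(0.36 * shape[2])
    x = np.arange(shape[0])
    x_start = int(0.25 * shape[0])
    for k, period in enumerate((2, 3, 5)):
        y0 = int((0.30 + 0.14 * k) * shape[1])
        y1 = y0 + max(2, int(0.08 * shape[1]))
        stripe = ((x - x_start) // period) % 2 == 0
        region = np.zeros(shape, dtype=bool)
        region[x_start : int(0.75 * shape[0]), y0:y1, z0:z1] = True
        region &= stripe[:, None, None]
        bars |= region & tissue
    data[bars] = bar_level

    # Spherical lesions inside the tissue, clear of bars and of each other.
    lesion_mask = np.zeros(shape, dtype=bool)
    placed = 0
    attempts = 0
    max_attempts = 400 * max(1, spec.n_lesions)
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    while placed < spec.n_lesions:
        attempts += 1
        if attempts > max_attempts:
            raise PhantomError(
                f"could not place {spec.n_lesions} non-overlapping lesions "
                f"after {max_attempts} attempts"
            )
        r_mm = rng.uniform(*spec.lesion_radius_range)
        r_vox = r_mm / spec.spacing_mm
        # center uniformly inside the ellipsoid shrunk by the lesion radius
        u = rng.uniform(-1, 1, size=3)
        if np.sum(u**2) > 1:
            continue
        c = [
            center[i] + u[i] * max(semiaxes[i] - r_vox - 1, 1) for i in range(3)
        ]
        dist2 = sum(((g - ci) / r_vox) ** 2 for g, ci in zip(grids, c))
        sphere = dist2 <= 1.0
        if not sphere.any():
            continue
        if np.any(sphere & ~tissue) or np.any(sphere & bars) or np.any(sphere & lesion_mask):
            continue
        lesion_mask |= sphere
        placed += 1
    data[lesion_mask] = spec.lesion_level

    nawm = tissue & ~lesion_mask & ~bars

    # Background-noise box in the (0,0,0) corner, strictly outside the tissue.
    box = max(4, int(0.18 * min(shape)))
    noise_mask = np.zeros(shape, dtype=bool)
    noise_mask[:box, :box, :box] = True
    if np.any(noise_mask & tissue):
        raise PhantomError("noise box intersects the tissue ellipsoid")

    truth = Volume(
        data=data, spacing=(spec.spacing_mm,) * 3, name=f"phantom(seed={spec.seed})"
    )
    rois = RoiSet(
        lesion_mask=lesion_mask,
        nawm_mask=nawm,
        noise_mask=noise_mask,
        lesion_labels=split_lesions(lesion_mask),
    )
    return truth, rois


def retained_band_width(extent: int, in_plane_mm: float, slice_mm: float) -> int:
    """Spectral planes a thick-slice scan retains along its slice axis."""
    return min(extent, max(1, _round_half_away(extent * in_plane_mm / slice_mm)))


def truncate_spectrum(truth: Volume, geometry: AcquisitionGeometry):
    """Centered spectrum of ``truth`` truncated along the slice axis.

    This is the noise-free k-space content a thick-slice acquisition
    measures: the central ``retained_band_width`` planes along
    ``geometry.slice_axis``, zero outside.  Exact in the complex domain;
    the magnitude reconstruction in :func:`simulate_acquisition` is applied
    on top of it.
    """
    from .fusion import FrequencyVolume, forward_spectrum

    if any(s > geometry.in_plane_mm + 1e-9 for s in truth.spacing):
        raise PhantomError(
            f"truth spacing {truth.spacing} coarser than in-plane {geometry.in_plane_mm} mm"
        )
    axis = geometry.slice_axis
    extent = truth.shape[axis]
    width = retained_band_width(extent, geometry.in_plane_mm, geometry.slice_mm)
    spec = forward_spectrum(truth).data
    start = extent // 2 - width // 2
    keep = np.zeros(extent, dtype=bool)
    keep[start : start + width] = True
    index = [np.newaxis] * 3
    index[axis] = slice(None)
    return FrequencyVolume(data=spec * keep[tuple(index)], source_spacing=truth.spacing)


def simulate_acquisition(truth: Volume, sim: AcquisitionSim) -> Volume:
    """Simulate one anisotropic scan of ``truth`` by k-space truncation plus Rician noise.

    The truth grid must be isotropic at a resolution no coarser than the
    in-plane resolution; the output stays on the truth grid (perfectly
    registered), with spectral support truncated along the slice axis.
    """
    geom = sim.geometry
    if any(sim.shift_voxels):
        truth = truth.with_data(np.roll(truth.data, sim.shift_voxels, axis=(0, 1, 2)))
    truncated = truncate_spectrum(truth, geom)
    complex_image = np.fft.ifftn(np.fft.ifftshift(truncated.data))
    if sim.noise_sigma > 0:
        rng = np.random.default_rng(sim.seed)
        complex_image = complex_image + (
            rng.normal(0.0, sim.noise_sigma, truth.shape)
            + 1j * rng.normal(0.0, sim.noise_sigma, truth.shape)
        )
    return Volume(
        data=np.abs(complex_image),
        spacing=truth.spacing,
        axis_labels=truth.axis_labels,
        name=f"sim(axis={geom.slice_axis},slice={geom.slice_mm}mm,seed={sim.seed})",
    )


def simulate_orthogonal_pair(
    truth: Volume, sim_a: AcquisitionSim, sim_b: AcquisitionSim
) -> tuple[Volume, Volume]:
    """Two co-registered simulated scans of the same truth with orthogonal slice axes."""
    if sim_a.geometry.slice_axis == sim_b.geometry.slice_axis:
        raise PhantomError("the two simulated scans must have different slice axes")
    return simulate_acquisition(truth, sim_a), simulate_acquisition(truth, sim_b)
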