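# Methods

## Signal model

A 3D magnitude MRI volume ρ(x, y, z) and its k-space S(kx, ky, kz) are
related by the discrete Fourier transform. An anisotropic acquisition with
in-plane resolution `p` and slice thickness `s` along one axis has full
spectral support on its in-plane axes but, along the slice axis of extent
`N` lines, only the central `round(N / (s/p))` lines carry genuine signal —
resolution is spectral support. Two scans acquired in orthogonal planes
therefore measure two orthogonal slabs of the same object's spectrum whose
union covers strictly more of k-space than either alone.

All spectra in the package are *centered*: the zero-frequency coefficient
sits at index `floor(N/2)` on each axis (`fftshift` convention).

## The fusion splice

Given a preprocessed, co-registered base/donor pair on one grid, the fused
spectrum is

    S_fused = M · S_donor + (1 − M) · S_base

with `M` the indicator of the centered band of `w` planes along the
*donor's* slice axis: indices `[c − floor(w/2), c − floor(w/2) + w)`,
`c = floor(N/2)`. The base fills everything outside the band; the donor
contributes exactly the through-plane content it measured. The fused image
is the magnitude of the inverse transform.

Design choices made here, where several readings were defensible:

- **Band semantics.** Each scan contributes only the k-space region it
  genuinely measured; the spectral coverage of the output is the union of
  two orthogonal slabs. Under this reading, on noiseless simulated pairs
  the fused spectrum equals the ground-truth spectrum on the entire union
  (verified exactly, in the complex domain, in the tests).
- **Band centering with even extents** uses the floor convention above; it
  is deterministic but (for even `w`) one plane asymmetric about the
  center. The splice itself is agnostic to this; tests pin the convention.
- **Magnitude output.** Two independently acquired magnitude images have
  unmatched phases, so the spliced spectrum is generally not Hermitian and
  its inverse has an imaginary residue; taking the complex magnitude
  matches MRI magnitude-image conventions. Consequences: self-fusion is
  the identity to FFT tolerance, but splice idempotence and exact
  spectral-coverage statements hold at the *spectrum* level, not after a
  magnitude round-trip — the tests distinguish the two levels explicitly.
- **Default band width** is the band-count rule `round(N / (s/p))` (54 for
  a 160-line 5 mm / 1.7 mm protocol) because it generalizes across
  protocols; empirically tuned widths (e.g. 64 for that protocol) are
  passed as an explicit override, and `band_sweep` scores candidate widths
  by whole-image Laplacian sharpness (ties broken toward the smaller
  width, preferring less donor contrast contamination). On noiseless
  simulations the sweep maximizer lands within ±2 planes of the donor's
  true measured band width for grids ≥ 64; on very small grids (≤ 48) the
  magnitude reconstruction leaks enough energy past the measured band to
  shift it by ~3.
- The fusion operates on preprocessed magnitude images, not raw scanner
  k-space; raw-trajectory operation is out of scope.

## Preprocessing

Fixed order: resample → pad → normalize.

- **Resampling** to isotropic `target_mm` (default 1.7 mm) with
  nearest-neighbor interpolation (linear available); output extent per
  axis is `round(extent_mm / target_mm)`, rounded half away from zero.
  Sample positions map grid corner to grid corner.
- **Padding** centers the volume in zeros with offset
  `floor((target − current)/2)` per axis.
- **Normalization** divides by the 98th percentile (linear-interpolation
  definition) of the *nonzero* voxels — zero-padded or masked background
  would otherwise dominate the percentile. Values above the percentile are
  not clipped. Normalization is idempotent and scale-invariant.
- **Orientation.** Volumes are reoriented at load to the closest canonical
  RAS order, axes labeled LR/AP/SI; a coronal acquisition's slice axis is
  AP (index 1), an axial one's is SI (index 2). Registration is an
  external precondition: the package validates only grid compatibility.

## Quality metrics

On a volume plus ROI masks (lesion, normal-appearing white matter = WM
minus lesions, background noise):

- `SNR = mean(lesion) / std(noise)`,
  `CNR = |mean(lesion) − mean(NAWM)| / std(noise)`,
  `conspicuity = (mean(lesion) − mean(NAWM)) / (mean(lesion) + mean(NAWM))`.
  All standard deviations are population (ddof 0). All three are invariant
  to global positive intensity scaling.
- **Sharpness** is the standard deviation of the response of the
  6-neighbor second-difference Laplacian (the canonical discrete 3D
  Laplacian, scipy's `laplace`) with edge replication at borders; the
  standard deviation — not the variance — is the reported number.
  Sharpness scales linearly with intensity, which is why the pipeline
  normalizes every method to its own 98th percentile before comparison.
- **Per-lesion sharpness**: lesion clusters are split under
  26-connectivity with deterministic label order (lexicographic by first
  voxel); each cluster is dilated by 1 voxel (26-connectivity structuring
  element, configurable) and the Laplacian std over the dilated ROI is
  reported on the natural-log scale. A lesion with zero Laplacian variance
  (no edge in its ROI) reports NaN — an explicit missing value, not an
  error.

## Phantom simulator

`make_phantom` builds a piecewise-constant volume: a tissue ellipsoid
(semi-axes 0.40 of each extent, level 1.0) in a zero background, bar
gratings at half-periods 2/3/5 voxels (level 0.5) in a lower slab, and
non-overlapping hyperintense spherical lesions (level 1.6, radii drawn
from 2.5–6 mm) placed by seeded rejection sampling inside the ellipsoid,
clear of the gratings; placement failure after bounded retries is an
error, not a silent shortfall. NAWM is the uniform tissue (ellipsoid minus
lesions minus gratings); the noise ROI is a background corner box verified
disjoint from the tissue. The default grid is 96³ at 1.7 mm — large enough
for a ~33-plane measured band, small enough that every simulation-based
check runs in seconds on one CPU.

`simulate_acquisition` models the scan as ideal k-space truncation along
the slice axis (retaining `round(N·p/s)` central planes) — a sinc slice
profile, not a slab-select Gaussian — followed by complex Gaussian noise
of std σ added to the real and imaginary channels of the inverse
transform, then magnitude. Background magnitude noise is therefore
Rayleigh with std σ·sqrt(2 − π/2), which the tests verify against the
closed form. The truncation operator is exposed separately
(`truncate_spectrum`) because its band equality with the ground-truth
spectrum is exact in the complex domain, while the magnitude
reconstruction perturbs the spectrum at the few-percent level (ringing
lobes rectified by `abs`).

For noisy comparisons the noise level is derived, not tuned: σ =
lesion_level / (SNR_target · sqrt(2 − π/2)) puts the single-scan SNR near
the chosen target (40, the magnitude seen in clinical ULF comparisons).

What the simulator does *not* emulate: real anatomy and texture, partial
volume, B0 inhomogeneity, coil sensitivity, slab-select profiles, or
compressed-sensing noise structure. Inputs are perfectly co-registered by
construction; an optional integer-voxel rigid shift on one acquisition
(off by default) demonstrates the ringing that residual registration
mismatch produces in the fused image, but no sub-voxel or nonlinear motion
is modeled. Passing simulation tests therefore demonstrates the spectral
mechanics of the method — recovery of truly measured frequencies, the
sharpness/SNR trade-off of splicing versus averaging — not clinical image
quality or robustness to registration failure, which on real data
manifests as ringing artifacts.

## Comparators

- `average_comparator`: voxelwise mean of the two preprocessed scans.
- `sharpened_average_comparator`: each input unsharp-masked
  (`v ← v − weight·Laplacian(v)`, default 2 iterations, weight 0.3 —
  unconstrained choices, exposed in config) and then averaged. This is a
  deliberately simple sharpen-then-combine stand-in so reports carry a
  sharpened-average column; it is labeled as such in output and is not a
  reimplementation of registration-based template-construction SR tools.

## Problem sizes and numerical checks

Test and acceptance workloads use 48³ fixtures for unit-level checks, 64³
for band-sweep localization, and 96³ phantoms for recovery and
metric-ordering properties (10 seeds), keeping the full suite under ten
seconds of compute. Spectrum transforms are validated against a direct
triple-sum DFT on every grid up to 6³ (tolerance 1e−9), the splice against
an independently constructed band mask (exact complex equality), the
Laplacian against a direct stencil oracle (1e−12), and metric formulas
against hand-built closed-form cases.

## Known limitations

- Registration and skull-stripping are external; grid compatibility is
  the only validated precondition.
- The magnitude convention makes image-level idempotence and linearity
  approximate for phase-mismatched inputs (exact at the spectrum level).
- The band-count rule assumes both scans share in-plane resolution after
  resampling; mixed-resolution protocols need an explicit band width.
- Absolute metric values from the simulator are not comparable to
  clinical numbers; only orderings and ratios are meaningful.
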