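# fousr

Fourier-domain super-resolution fusion of orthogonal anisotropic MRI
volumes, with the matching image-quality evaluation suite and a
digital-phantom acquisition simulator.

## The problem

Ultra-low-field (ULF, < 0.1 T) MRI trades signal-to-noise for
accessibility. To keep SNR usable, ULF protocols acquire anisotropic 3D
volumes — fine in-plane resolution (e.g. 1.7 × 1.7 mm) but thick slices
(e.g. 5 mm) — which blurs small features such as white-matter lesions along
the slice direction. Acquiring a *second* scan in an orthogonal plane
provides exactly the spatial frequencies the first scan is missing.

`fousr` fuses the two scans in k-space. A thick-slice acquisition measures
only the central band of the spectrum along its slice axis: if the slice
thickness is `s` and the in-plane resolution is `p`, an axis of `N`
spectral lines contains only `round(N / (s/p))` genuinely measured lines.
The fusion keeps the base scan's spectrum everywhere except that centered
inner band along the *donor's* slice axis, substitutes the donor's spectrum
there, and inverse-transforms:

```
S_fused(k) = M(k) · S_donor(k) + (1 − M(k)) · S_base(k)
```

where `M` selects the centered band of width `w` along the donor's slice
axis. The result is an isotropic volume whose spectral support is the
union of the two measured slabs — sharper in both slice directions than
either input or their voxelwise average, which halves the amplitude of
every frequency only one scan measured.

For the 5 mm / 1.7 mm protocol on a 160-line axis, the rule gives a
2.94-fold resolution deficit and `w = 54` measured lines; the band width is
also settable explicitly (a sweep utility scores candidate widths by
image sharpness) since slightly wider bands can score better on real data.

The evaluation suite computes the standard lesion-visibility metrics — SNR
(mean lesion signal / noise std), CNR (|lesion − NAWM| / noise std), lesion
conspicuity ((lesion − NAWM)/(lesion + NAWM)) — and sharpness as the
standard deviation of the 3D Laplacian response, whole-image or per-lesion
over dilated lesion masks (natural-log scale).

The phantom simulator builds a piecewise-constant head-like volume with
spherical lesions and multi-scale bar gratings, then simulates anisotropic
acquisitions as k-space truncation along the slice axis plus Rician
magnitude noise, so the whole pipeline is testable end-to-end with exact
ground truth and exact ROI masks.

## Worked example

```python
import numpy as np
from fousr import (AcquisitionGeometry, AcquisitionSim, PhantomSpec,
                   average_comparator, compute_band_count, fuse,
                   make_fusion_plan, make_phantom, simulate_orthogonal_pair)

coronal = AcquisitionGeometry(in_plane_mm=1.7, slice_mm=5.0, slice_axis=1)
axial   = AcquisitionGeometry(in_plane_mm=1.7, slice_mm=5.0, slice_axis=2)

print(compute_band_count(5.0, 1.7, 160))   # (2.94, 54)

truth, rois = make_phantom(PhantomSpec(shape=(96, 96, 96), n_lesions=8, seed=1))
base, donor = simulate_orthogonal_pair(
    truth,
    AcquisitionSim(coronal, noise_sigma=0.0, seed=2),
    AcquisitionSim(axial,   noise_sigma=0.0, seed=3),
)
plan = make_fusion_plan(coronal, axial, truth.shape)   # band width 33 on a 96 grid
fused = fuse(base, donor, plan)

rmse = lambda v: float(np.sqrt(np.mean((v.data - truth.data) ** 2)))
print(round(rmse(base), 4), round(rmse(donor), 4),
      round(rmse(average_comparator(base, donor)), 4), round(rmse(fused), 4))
# 0.0544 0.0537 0.0472 0.0412
```

The fused volume is closer to ground truth (RMSE 0.0412) than either
single scan (0.0544, 0.0537) or their average (0.0472): the splice
genuinely recovers information from the under-sampled slice directions
rather than just denoising. On noisy simulations the qualitative pattern
of a clinical comparison reappears: averaging wins on SNR (≈ 53 vs ≈ 37–38
for single scans at this noise level) while fusion wins on sharpness
(≈ 1.4× the averaged volume's Laplacian-std).

## Command line

```sh
fousr simulate --shape 96 --n-lesions 8 --noise-sigma 0.05 --seed 1 --out sim/
fousr fuse --base sim/scan_coronal.nii.gz --donor sim/scan_axial.nii.gz \
      --lesion-mask sim/lesion_mask.nii.gz --nawm-mask sim/nawm_mask.nii.gz \
      --noise-mask sim/noise_mask.nii.gz --out run/
fousr sweep --base sim/scan_coronal.nii.gz --donor sim/scan_axial.nii.gz \
      --widths 26:40 --out sweep.csv
fousr profile --image run/fousr.nii.gz --image run/average.nii.gz \
      --axis SI --fixed 48,48 --out profile.csv
```

`fuse` writes the fused NIfTI, all comparator volumes, CSV metric reports,
a run log and a provenance JSON recording every resolved parameter
(including the automatic band width).

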