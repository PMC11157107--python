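"""Spectrum transforms, band-count rule and the k-space splice."""

import numpy as np
import pytest

from fousr import (
    FrequencyVolume,
    FusionError,
    FusionPlan,
    Volume,
    band_sweep,
    compute_band_count,
    forward_spectrum,
    fuse,
    fuse_spectra,
    inverse_spectrum,
    make_fusion_plan,
    retained_band_width,
)
from fousr.phantom import AcquisitionSim, simulate_orthogonal_pair

from conftest import GEOM_AXIAL, GEOM_CORONAL, random_volume


def brute_force_dft(data: np.ndarray) -> np.ndarray:
    """Direct triple-sum centered DFT: S[k] = sum_n v[n] exp(-2πi (k-c)·n / N)."""
    nx, ny, nz = data.shape
    cx, cy, cz = nx // 2, ny // 2, nz // 2
    out = np.zeros(data.shape, dtype=np.complex128)
    for kx in range(nx):
        for ky in range(ny):
            for kz in range(nz):
                acc = 0.0 + 0.0j
                for x in range(nx):
                    for y in range(ny):
                        for z in range(nz):
                            phase = (
                                (kx - cx) * x / nx
                                + (ky - cy) * y / ny
                                + (kz - cz) * z / nz
                            )
                            acc += data[x, y, z] * np.exp(-2j * np.pi * phase)
                out[kx, ky, kz] = acc
    return out


def band_mask_oracle(shape, axis, width) -> np.ndarray:
    """Independent index arithmetic for the centered replacement band."""
    n = shape[axis]
    mask = np.zeros(shape, dtype=bool)
    center = n // 2
    lo = center - width // 2
    for i in range(n):
        if lo <= i < lo + width:
            index = [slice(None)] * 3
            index[axis] = i
            mask[tuple(index)] = True
    return mask


class TestSpectrumTransforms:
    def test_constant_volume_is_dc_only(self):
        c, n = 3.5, 6
        freq = forward_spectrum(Volume(data=np.full((n, n, n), c), spacing=(1, 1, 1)))
        center = (n // 2,) * 3
        assert abs(freq.data[center]) == pytest.approx(c * n**3)
        off = freq.data.copy()
        off[center] = 0
        assert np.abs(off).max() < 1e-9

    def test_matches_brute_force_dft_4cube(self, rng):
        vol = random_volume(rng, (4, 4, 4))
        freq = forward_spectrum(vol)
        expected = brute_force_dft(vol.data)
        assert np.abs(freq.data - expected).max() < 1e-9

    @pytest.mark.parametrize("shape", [(2, 3, 4), (5, 5, 5), (3, 6, 2), (6, 4, 5)])
    def test_matches_brute_force_dft_mixed_shapes(self, rng, shape):
        vol = random_volume(rng, shape)
        assert np.abs(forward_spectrum(vol).data - brute_force_dft(vol.data)).max() < 1e-9

    def test_hermitian_symmetry_of_real_input(self, rng):
        vol = random_volume(rng, (6, 6, 6))
        s = forward_spectrum(vol).data
        n = 6
        c = n // 2
        for idx in np.ndindex(s.shape):
            mirror = tuple(2 * c - i for i in idx)
            if all(0 <= m < n for m in mirror):
                assert s[idx] == pytest.approx(np.conj(s[mirror]), abs=1e-9)

    def test_round_trip_identity(self, rng):
        vol = random_volume(rng, (32, 32, 32))
        back = inverse_spectrum(forward_spectrum(vol))
        assert np.abs(back.data - vol.data).max() < 1e-9
        assert back.spacing == vol.spacing

    def test_inverse_of_zero_spectrum_is_zero(self):
        freq = FrequencyVolume(data=np.zeros((4, 4, 4), complex), source_spacing=(1, 1, 1))
        np.testing.assert_array_equal(inverse_spectrum(freq).data, 0.0)

    def test_parseval_energy(self, rng):
        vol = random_volume(rng, (8, 8, 8))
        freq = forward_spectrum(vol)
        assert np.sum(np.abs(freq.data) ** 2) == pytest.approx(
            np.sum(vol.data**2) * vol.data.size, rel=1e-12
        )

    def test_rejects_non_3d(self):
        with pytest.raises(FusionError):
            FrequencyVolume(data=np.zeros((4, 4), complex), source_spacing=(1, 1, 1))


class TestBandCount:
    def test_study_protocol_values(self):
        """5 mm / 1.7 mm over 160 lines: 2.94-fold deficit, 54 measured lines."""
        factor, n_lines = compute_band_count(5.0, 1.7, 160)
        assert factor == pytest.approx(2.94)
        assert n_lines == 54

    @pytest.mark.parametrize(
        "slice_mm,in_plane,extent,factor,lines",
        [(5.0, 5.0, 160, 1.0, 160), (3.4, 1.7, 128, 2.0, 64)],
    )
    def test_arithmetic_cases(self, slice_mm, in_plane, extent, factor, lines):
        got_factor, got_lines = compute_band_count(slice_mm, in_plane, extent)
        assert got_factor == pytest.approx(factor)
        assert got_lines == lines

    def test_rejects_bad_resolutions(self):
        with pytest.raises(FusionError):
            compute_band_count(0.0, 1.7, 160)
        with pytest.raises(FusionError):
            compute_band_count(1.0, 1.7, 160)


class TestFusionPlan:
    def test_override_and_auto_widths(self):
        plan = make_fusion_plan(GEOM_CORONAL, GEOM_AXIAL, (160, 160, 160),
                                band_width_override=64)
        assert plan.replacement_axis == 2 and plan.band_width == 64
        auto = make_fusion_plan(GEOM_CORONAL, GEOM_AXIAL, (160, 160, 160))
        assert auto.band_width == 54

    def test_full_axis_override_allowed(self):
        plan = make_fusion_plan(GEOM_CORONAL, GEOM_AXIAL, (12, 12, 12),
                                band_width_override=12)
        assert plan.band_slice(12) == slice(0, 12)

    def test_rejects_parallel_scans_and_oversize_band(self):
        with pytest.raises(FusionError, match="orthogonal"):
            make_fusion_plan(GEOM_AXIAL, GEOM_AXIAL, (160, 160, 160))
        with pytest.raises(FusionError):
            make_fusion_plan(GEOM_CORONAL, GEOM_AXIAL, (12, 12, 12),
                             band_width_override=13)

    def test_band_is_contiguous_and_centered(self):
        for n in (7, 8, 160):
            for w in (1, 2, 5, n):
                band = FusionPlan(replacement_axis=0, band_width=w).band_slice(n)
                assert band.stop - band.start == w
                assert band.start == n // 2 - w // 2


class TestFuse:
    def test_self_fusion_is_identity(self, rng):
        vol = random_volume(rng, (12, 12, 12))
        plan = FusionPlan(replacement_axis=2, band_width=5)
        assert np.abs(fuse(vol, vol, plan).data - vol.data).max() < 1e-9

    def test_full_band_reduces_to_donor(self, rng):
        base, donor = random_volume(rng, (10, 10, 10)), random_volume(rng, (10, 10, 10))
        plan = FusionPlan(replacement_axis=1, band_width=10)
        assert np.abs(fuse(base, donor, plan).data - donor.data).max() < 1e-9

    @pytest.mark.parametrize("width", range(1, 9))
    def test_spectrum_matches_mask_oracle_all_widths(self, rng, width):
        """Fused spectrum equals M*S_donor + (1-M)*S_base, M by independent index arithmetic."""
        base, donor = random_volume(rng, (8, 8, 8)), random_volume(rng, (8, 8, 8))
        plan = FusionPlan(replacement_axis=2, band_width=width)
        fused = fuse_spectra(forward_spectrum(base), forward_spectrum(donor), plan)
        mask = band_mask_oracle((8, 8, 8), 2, width)
        expected = np.where(mask, forward_spectrum(donor).data, forward_spectrum(base).data)
        np.testing.assert_array_equal(fused.data, expected)

    def test_splice_is_idempotent(self, rng):
        """Re-splicing changes nothing: the band stays the donor's, the rest stays put."""
        base, donor = random_volume(rng, (8, 8, 8)), random_volume(rng, (8, 8, 8))
        plan = FusionPlan(replacement_axis=0, band_width=3)
        donor_freq = forward_spectrum(donor)
        once = fuse_spectra(forward_spectrum(base), donor_freq, plan)
        twice = fuse_spectra(once, donor_freq, plan)
        np.testing.assert_array_equal(twice.data, once.data)

    def test_linear_in_intensity_scale(self, rng):
        base, donor = random_volume(rng, (8, 8, 8)), random_volume(rng, (8, 8, 8))
        plan = FusionPlan(replacement_axis=1, band_width=4)
        a = 3.7
        scaled = fuse(base.with_data(a * base.data), donor.with_data(a * donor.data), plan)
        np.testing.assert_allclose(scaled.data, a * fuse(base, donor, plan).data, rtol=1e-9)

    def test_rejects_mismatched_grids(self, rng):
        base = random_volume(rng, (8, 8, 8))
        plan = FusionPlan(replacement_axis=0, band_width=2)
        with pytest.raises(FusionError):
            fuse(base, random_volume(rng, (8, 8, 9)), plan)
        with pytest.raises(FusionError):
            fuse(base, random_volume(rng, (8, 8, 8), spacing=(2, 1, 1)), plan)

    def test_recovers_truth_spectrum_on_union_coverage(self, small_phantom):
        """Where either scan measured k-space, the fused spectrum equals the truth's.

        Uses the measured (complex, noise-free) spectra directly so the
        comparison is exact; the magnitude reconstruction of each scan is a
        separate, image-domain concern.
        """
        from fousr import truncate_spectrum

        truth, _ = small_phantom
        base_spec = truncate_spectrum(truth, GEOM_CORONAL)
        donor_spec = truncate_spectrum(truth, GEOM_AXIAL)
        plan = make_fusion_plan(GEOM_CORONAL, GEOM_AXIAL, truth.shape)
        fused = fuse_spectra(base_spec, donor_spec, plan)
        truth_spec = forward_spectrum(truth).data
        n = truth.shape[0]
        w = retained_band_width(n, 1.7, 5.0)
        band_a = band_mask_oracle(truth.shape, 1, w)
        band_b = band_mask_oracle(truth.shape, 2, plan.band_width)
        covered = band_b | (band_a & ~band_b)
        assert covered.sum() > 0
        np.testing.assert_array_equal(fused.data[covered], truth_spec[covered])
        # and nothing outside the union was invented
        outside = ~(band_a | band_b)
        np.testing.assert_array_equal(fused.data[outside], 0.0)


class TestBandSweep:
    def test_table_contract(self, rng):
        base, donor = random_volume(rng, (10, 10, 10)), random_volume(rng, (10, 10, 10))
        table = band_sweep(base, donor, 2, list(range(3, 9)))
        assert list(table["width"]) == list(range(3, 9))
        assert np.isfinite(table["score"]).all()
        assert table["selected"].sum() == 1

    def test_full_width_scores_like_donor(self, rng):
        from fousr import laplacian_sharpness

        base, donor = random_volume(rng, (10, 10, 10)), random_volume(rng, (10, 10, 10))
        table = band_sweep(base, donor, 1, [10])
        assert table["score"].iloc[0] == pytest.approx(laplacian_sharpness(donor), rel=1e-9)

    def test_maximizer_near_true_measured_width(self):
        """On a noiseless pair the sharpest width sits near the donor's true band.

        Uses a 64-cube so the measured band is wide enough for the +-2-plane
        localization to be meaningful.
        """
        from fousr import PhantomSpec, make_phantom

        truth, _ = make_phantom(PhantomSpec(shape=(64, 64, 64), n_lesions=4, seed=7))
        base, donor = simulate_orthogonal_pair(
            truth,
            AcquisitionSim(GEOM_CORONAL, noise_sigma=0.0, seed=0),
            AcquisitionSim(GEOM_AXIAL, noise_sigma=0.0, seed=0),
        )
        w_true = retained_band_width(truth.shape[2], 1.7, 5.0)
        widths = list(range(w_true - 6, w_true + 7))
        table = band_sweep(base, donor, 2, widths)
        best = int(table.loc[table["selected"], "width"].iloc[0])
        assert abs(best - w_true) <= 2

    def test_rejects_empty_and_invalid_widths(self, rng):
        base, donor = random_volume(rng, (8, 8, 8)), random_volume(rng, (8, 8, 8))
        with pytest.raises(FusionError):
            band_sweep(base, donor, 0, [])
        with pytest.raises(FusionError):
            band_sweep(base, donor, 0, [9])
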