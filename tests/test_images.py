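"""Texture generator, patch extraction, whitening and the Gabor bank."""

import numpy as np
import pytest

from infomaxnet.images import (
    GaborBank,
    WhiteningModel,
    compose_feedforward,
    extract_patches,
    fit_whitening,
    gabor_bank,
    gabor_patch,
    load_image,
    save_images,
    synth_textures,
)


@pytest.fixture(scope="module")
def textures():
    return synth_textures(6, side=128, seed=0)


@pytest.fixture(scope="module")
def patches(textures):
    return extract_patches(textures, patch_side=25, n=3000, seed=1)


@pytest.fixture(scope="module")
def whitening(patches):
    return fit_whitening(patches, d=15)


class TestSynthTextures:
    def test_byte_range_and_shape(self, textures):
        assert textures.shape == (6, 128, 128)
        assert textures.dtype == np.uint8

    def test_seed_determinism(self):
        a = synth_textures(2, side=64, seed=5)
        b = synth_textures(2, side=64, seed=5)
        assert np.array_equal(a, b)

    def test_power_spectrum_slope(self):
        # periodogram fit: radially averaged power should fall as f^-2
        img = synth_textures(1, side=256, spectrum_exponent=2.0,
                             contrast_scale=0.2, seed=3)[0].astype(float)
        F = np.fft.fft2(img - img.mean())
        power = np.abs(F) ** 2
        fy = np.fft.fftfreq(256)[:, None]
        fx = np.fft.fftfreq(256)[None, :]
        f = np.hypot(fy, fx).ravel()
        p = power.ravel()
        bins = np.logspace(np.log10(2 / 256), np.log10(0.4), 18)
        centers, means = [], []
        for lo, hi in zip(bins[:-1], bins[1:]):
            sel = (f >= lo) & (f < hi)
            if sel.sum() > 4:
                centers.append(np.sqrt(lo * hi))
                means.append(p[sel].mean())
        slope = np.polyfit(np.log(centers), np.log(means), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.3)

    def test_contrast_scale_sets_rms(self):
        img = synth_textures(1, side=128, contrast_scale=0.02, seed=1)[0]
        rms = np.std(img.astype(float) / 255.0)
        assert rms == pytest.approx(0.02, rel=0.2)

    def test_png_roundtrip(self, textures, tmp_path):
        paths = save_images(textures[:2], tmp_path)
        back = load_image(paths[0])
        assert np.array_equal(back, textures[0])


class TestExtractPatches:
    def test_shape_contract(self, patches):
        assert patches.patches.shape == (3000, 625)
        assert patches.patch_side == 25

    def test_values_in_byte_range(self, patches):
        assert patches.patches.min() >= 0
        assert patches.patches.max() <= 255

    def test_seed_determinism(self, textures):
        a = extract_patches(textures, 25, 20, seed=7).patches
        b = extract_patches(textures, 25, 20, seed=7).patches
        assert np.array_equal(a, b)

    def test_color_converted_by_luminance(self):
        rgb = np.zeros((64, 64, 3))
        rgb[..., 1] = 200.0  # pure green
        ps = extract_patches([rgb], 25, 5, seed=0)
        assert np.allclose(ps.patches, 0.587 * 200.0)

    def test_too_small_image_named_in_error(self):
        with pytest.raises(ValueError, match="image #1"):
            extract_patches([np.zeros((64, 64)), np.zeros((10, 10))], 25, 5)


class TestWhitening:
    def test_reduces_to_d_components(self, whitening, patches):
        codes = whitening.transform(patches.patches)
        assert codes.shape == (3000, 15)

    def test_training_codes_have_identity_covariance(self, whitening, patches):
        codes = whitening.transform(patches.patches)
        cov = np.cov(codes.T)
        assert np.allclose(np.diag(cov), 1.0, atol=0.05)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 0.05

    def test_roundtrip_residual_equals_discarded_variance(self, patches):
        # PCA identity: residual variance after project+reconstruct equals
        # the sum of the discarded eigenvalues
        P = patches.patches / 255.0
        Pc = P - P.mean(axis=0)
        cov = (Pc.T @ Pc) / (P.shape[0] - 1)
        all_evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        model = fit_whitening(patches, d=15)
        codes = model.transform(patches.patches)
        recon = model.reconstruct(codes)
        resid = Pc - recon
        resid_var = np.sum(resid ** 2) / (P.shape[0] - 1)
        expected = np.sum(all_evals[15:])
        assert resid_var == pytest.approx(expected, rel=1e-6)

    def test_eigenvalues_sorted_positive(self, whitening):
        assert np.all(np.diff(whitening.eigenvalues) <= 0)
        assert np.all(whitening.eigenvalues > 0)

    def test_too_few_patches_rejected(self, textures):
        ps = extract_patches(textures, 25, 10, seed=0)
        with pytest.raises(ValueError):
            fit_whitening(ps, d=15)

    def test_serialization_roundtrip(self, whitening, tmp_path):
        whitening.save(tmp_path / "wm")
        back = WhiteningModel.load(tmp_path / "wm")
        assert np.array_equal(back.eigenvalues, whitening.eigenvalues)
        assert np.array_equal(back.eigenvectors, whitening.eigenvectors)
        assert back.patch_side == 25


def grating(patch_side, orientation, wavelength):
    half = (patch_side - 1) / 2.0
    coords = np.arange(patch_side) - half
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    across = xx * np.cos(orientation) + yy * np.sin(orientation)
    return np.cos(2 * np.pi * across / wavelength).ravel()


class TestGaborBank:
    def test_orientation_spacing(self):
        bank = gabor_bank(380)
        spacing = np.diff(bank.orientations_deg)
        assert np.allclose(spacing, 180.0 / 380)
        assert spacing[0] == pytest.approx(0.4737, abs=1e-3)

    def test_rows_normalized_and_zero_mean(self):
        bank = gabor_bank(16)
        assert np.allclose(np.linalg.norm(bank.filters, axis=1), 1.0)
        assert np.allclose(bank.filters.mean(axis=1), 0.0, atol=1e-12)

    def test_each_filter_prefers_its_own_grating(self):
        bank = gabor_bank(24, wavelength=6.0, sigma=5.0)
        for i, ori in enumerate(bank.orientations):
            matched = abs(bank.filters[i] @ grating(25, ori, 6.0))
            ortho = abs(bank.filters[i] @ grating(25, ori + np.pi / 2, 6.0))
            assert matched > ortho

    def test_rotating_first_filter_approximates_others(self):
        # resample filter 0 on a rotated grid; mid-range orientations should
        # match the directly constructed filters closely
        from scipy.ndimage import rotate
        M = 12
        bank = gabor_bank(M, wavelength=6.0, sigma=5.0)
        f0 = bank.filters[0].reshape(25, 25)
        for i in [3, 4, 5, 6]:
            angle_deg = np.degrees(bank.orientations[i])
            rot = rotate(f0, -angle_deg, reshape=False, order=3)
            rot = rot - rot.mean()
            rot = rot / np.linalg.norm(rot)
            overlap = abs(np.sum(rot.ravel() * bank.filters[i]))
            assert overlap > 0.95

    def test_serialization_roundtrip(self, tmp_path):
        bank = gabor_bank(8)
        bank.save(tmp_path / "bank")
        back = GaborBank.load(tmp_path / "bank")
        assert np.array_equal(back.filters, bank.filters)
        assert back.wavelength == bank.wavelength


class TestComposeFeedforward:
    def test_shapes(self, whitening):
        bank = gabor_bank(60, wavelength=6.0, sigma=5.0)
        W = compose_feedforward(bank, whitening)
        assert W.shape == (60, 15)

    def test_associativity_identity(self, whitening, rng):
        bank = gabor_bank(20, wavelength=6.0, sigma=5.0)
        W = compose_feedforward(bank, whitening)
        c = rng.standard_normal(15)
        via_patch = bank.filters @ whitening.reconstruct(c)[0]
        assert np.allclose(W @ c, via_patch, atol=1e-10)
        assert np.allclose(W @ np.zeros(15), 0.0)

    def test_patch_size_mismatch_rejected(self, whitening):
        bank = gabor_bank(8, patch_side=11)
        with pytest.raises(ValueError):
            compose_feedforward(bank, whitening)


class TestGaborPatch:
    def test_unit_norm_zero_mean(self):
        g = gabor_patch(25, 0.3)
        assert np.linalg.norm(g) == pytest.approx(1.0)
        assert g.mean() == pytest.approx(0.0, abs=1e-12)
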