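"""PCA spectral basis, score regression, per-pixel reconstruction, cube IO."""

import numpy as np
import pytest

from vishsi import calibration as cal
from vishsi import colorimetry as cm
from vishsi import metrics as mx
from vishsi import reconstruction as rec
from vishsi import synthetic as syn


def _rank3_spectra(n=24, seed=0):
    rng = np.random.default_rng(seed)
    basis = np.stack([syn.gaussian_bump(c, 50.0) for c in (450, 550, 650)])
    return rng.uniform(0.1, 0.9, (n, 3)) @ basis / 3.0


class TestSpectralBasis:
    def test_rank3_data_fully_explained_by_three_components(self):
        basis = rec.fit_spectral_basis(_rank3_spectra(), n_components=12)
        assert basis.explained_ratio[:3].sum() == pytest.approx(1.0, abs=1e-10)

    def test_explained_ratios_sum_to_one_at_full_rank(self):
        rng = np.random.default_rng(1)
        spectra = rng.uniform(0, 1, (10, 401))
        basis = rec.fit_spectral_basis(spectra, n_components=9)
        assert basis.explained_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_components_orthonormal_and_ratios_nonincreasing(self, checker24):
        basis = rec.fit_spectral_basis(checker24, n_components=12)
        gram = basis.components @ basis.components.T
        assert np.allclose(gram, np.eye(12), atol=1e-8)
        assert np.all(np.diff(basis.explained_ratio) <= 1e-12)

    def test_full_rank_projection_reproduces_training_data(self):
        spectra = _rank3_spectra(24, 2) + 0.2
        basis = rec.fit_spectral_basis(spectra, n_components=12)
        back = basis.inverse(basis.scores(spectra))
        assert np.allclose(back, spectra, atol=1e-8)

    def test_too_few_spectra_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            rec.fit_spectral_basis(np.ones((5, 401)), n_components=12)

    def test_sign_convention_deterministic(self, checker24):
        b1 = rec.fit_spectral_basis(checker24, 12)
        b2 = rec.fit_spectral_basis(checker24, 12)
        assert np.array_equal(b1.components, b2.components)
        peak = np.abs(b1.components).argmax(axis=1)
        assert np.all(b1.components[np.arange(12), peak] > 0)


class TestColorBasis:
    def test_ones_and_zeros(self):
        assert np.allclose(rec.build_color_basis([1.0, 1.0, 1.0]), 1.0)
        assert np.allclose(rec.build_color_basis([0.0, 0.0, 0.0]), 0.0)

    def test_hand_evaluated_terms(self):
        v = rec.build_color_basis([0.5, 1.0, 0.0])
        assert np.allclose(v, [0.0, 0.5, 0.0, 0.0, 0.5, 1.0, 0.0])

    def test_order_matches_spec(self):
        assert rec.COLOR_BASIS_NAMES == ("XYZ", "XY", "XZ", "YZ", "X", "Y", "Z")


class TestFitReconstruction:
    def test_linear_family_reconstructed_to_truncation_error(self, cmf, d65):
        # scores linear in XYZ: regression reaches the pure PCA truncation
        spectra = _rank3_spectra(24, 3)
        xyz = cm.spectrum_to_xyz(spectra, d65, cmf)
        basis = rec.fit_spectral_basis(spectra, 12, uncentered=True)
        model = rec.fit_reconstruction(basis, xyz, spectra)
        recon = rec.reconstruct_spectrum(model, xyz)
        truncation = basis.inverse(basis.scores(spectra))
        assert np.allclose(recon, truncation, atol=1e-8)

    def test_identical_spectra_collapse_to_mean(self, cmf, d65):
        spectra = np.tile(_rank3_spectra(1, 4) + 0.1, (24, 1))
        xyz = cm.spectrum_to_xyz(spectra, d65, cmf)
        basis = rec.fit_spectral_basis(spectra, 12)  # centered
        model = rec.fit_reconstruction(basis, xyz, spectra)
        assert np.allclose(model.M, 0.0, atol=1e-10)
        recon = rec.reconstruct_spectrum(model, xyz[:1])
        assert np.allclose(recon, basis.mean_spectrum, atol=1e-10)

    def test_patch_order_invariance(self, cmf, d65, checker24):
        xyz = cm.spectrum_to_xyz(checker24, d65, cmf)
        basis = rec.fit_spectral_basis(checker24, 12, uncentered=True)
        perm = np.random.default_rng(5).permutation(24)
        m1 = rec.fit_reconstruction(basis, xyz, checker24).M
        m2 = rec.fit_reconstruction(basis, xyz[perm], checker24[perm]).M
        assert np.allclose(m1, m2, atol=1e-12)

    def test_nested_components_rmse_monotone(self, cmf, d65, checker24):
        xyz = cm.spectrum_to_xyz(checker24, d65, cmf)
        rmses = []
        for k in range(1, 13):
            basis = rec.fit_spectral_basis(checker24, k, uncentered=True)
            model = rec.fit_reconstruction(basis, xyz, checker24)
            recon = rec.reconstruct_spectrum(model, xyz)
            rmses.append(np.sqrt(np.mean((recon - checker24) ** 2)))
        assert np.all(np.diff(rmses) <= 1e-10)

    def test_misaligned_inputs_rejected(self, checker24):
        basis = rec.fit_spectral_basis(checker24, 12)
        with pytest.raises(ValueError):
            rec.fit_reconstruction(basis, np.ones((23, 3)), checker24)


class TestReconstructSpectrum:
    def test_zero_scores_return_mean_spectrum(self, checker24):
        basis = rec.fit_spectral_basis(checker24, 12)  # centered
        model = rec.ReconstructionModel(basis=basis, M=np.zeros((12, 7)))
        out = rec.reconstruct_spectrum(model, [30.0, 40.0, 50.0])
        assert np.allclose(out, np.clip(basis.mean_spectrum, 0, None))

    def test_shape_and_nonnegativity_on_random_inputs(self, noiseless_pipeline):
        rng = np.random.default_rng(6)
        xyz = rng.uniform(0.0, 110.0, (1000, 3))
        out = rec.reconstruct_spectrum(noiseless_pipeline.reconstruction, xyz)
        assert out.shape == (1000, 401)
        assert out.min() >= 0.0

    def test_colorimetric_consistency_on_training_patches(
        self, noiseless_pipeline, noiseless_target, cmf
    ):
        # XYZ of the reconstruction stays within the training ΔE00 spread
        cam_xyz = cm.srgb_to_xyz(noiseless_target.rgb8, noiseless_target.source_white)
        recon = noiseless_pipeline.reconstruct_xyz(cam_xyz)
        white = noiseless_target.source_white
        ref_xyz = cm.spectrum_to_xyz(
            noiseless_target.reference_spectra, noiseless_target.illuminant, cmf
        )
        rec_xyz = cm.spectrum_to_xyz(recon, noiseless_target.illuminant, cmf)
        de = cm.delta_e_2000(cm.xyz_to_lab(rec_xyz, white), cm.xyz_to_lab(ref_xyz, white))
        tf = noiseless_pipeline.reconstruction.training_fidelity
        assert np.mean(de) <= tf["mean_de00"] + 3 * np.std(de) + 1e-9

    def test_roundtrip_exact_xyz_path_below_1e3_de00(self, cmf, d65):
        # noiseless linear family via exact XYZ: mean dE00 < 1e-3
        spectra = _rank3_spectra(24, 7)
        xyz = cm.spectrum_to_xyz(spectra, d65, cmf)
        basis = rec.fit_spectral_basis(spectra, 12, uncentered=True)
        model = rec.fit_reconstruction(basis, xyz, spectra, illuminant=d65, cmf=cmf)
        assert model.training_fidelity["mean_de00"] < 1e-3


class TestCube:
    def test_constant_image_has_one_spectrum(self, noiseless_pipeline):
        img = np.full((4, 5, 3), 120, dtype=np.uint8)
        cube = noiseless_pipeline.reconstruct_image(img)
        assert np.allclose(cube.spectra, cube.spectra[0, 0])

    def test_cube_matches_scalar_path(self, noiseless_pipeline):
        rng = np.random.default_rng(8)
        img = rng.integers(0, 256, (2, 2, 3), dtype=np.uint8)
        cube = noiseless_pipeline.reconstruct_image(img)
        for r in range(2):
            for c in range(2):
                xyz = cm.srgb_to_xyz(img[r, c], noiseless_pipeline.source_white)
                one = noiseless_pipeline.reconstruct_xyz(xyz)
                assert np.allclose(cube.spectra[r, c], one, atol=1e-12)

    def test_cache_bitwise_identical(self, noiseless_pipeline):
        rng = np.random.default_rng(9)
        img = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        c1 = noiseless_pipeline.reconstruct_image(img, cache=True)
        c2 = noiseless_pipeline.reconstruct_image(img, cache=False)
        assert np.array_equal(c1.spectra, c2.spectra)

    def test_wrong_channel_count_rejected(self, noiseless_pipeline):
        with pytest.raises(ValueError):
            noiseless_pipeline.reconstruct_image(np.zeros((4, 4, 2), dtype=np.uint8))

    def test_npz_and_envi_roundtrip(self, tmp_path, noiseless_pipeline):
        rng = np.random.default_rng(10)
        img = rng.integers(0, 256, (6, 7, 3), dtype=np.uint8)
        cube = noiseless_pipeline.reconstruct_image(img)
        f32 = cube.spectra.astype(np.float32)

        npz = tmp_path / "cube.npz"
        cube.save_npz(npz)
        back = rec.HyperCube.load_npz(npz)
        assert np.array_equal(back.spectra, f32)

        hdr = tmp_path / "cube.hdr"
        cube.save_envi(hdr)
        back2 = rec.HyperCube.load_envi(hdr)
        assert np.array_equal(back2.spectra.astype(np.float32), f32)
        assert np.array_equal(back2.wavelengths, cube.wavelengths)

    def test_model_json_roundtrip(self, tmp_path, noiseless_pipeline):
        model = noiseless_pipeline.reconstruction
        path = tmp_path / "recon.json"
        model.to_json(path)
        back = rec.ReconstructionModel.from_json(path)
        assert np.allclose(back.M, model.M)
        assert np.allclose(back.basis.components, model.basis.components)
        xyz = np.array([40.0, 50.0, 60.0])
        assert np.allclose(
            rec.reconstruct_spectrum(back, xyz), rec.reconstruct_spectrum(model, xyz)
        )
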