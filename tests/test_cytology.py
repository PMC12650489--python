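"""ROI extraction, cell-level PCA scores, and class separation reports."""

import numpy as np
import pytest

from vishsi import cytology as cyto
from vishsi import synthetic as syn
from vishsi.reconstruction import HyperCube


def _constant_cube(value=0.5, h=20, w=20):
    return HyperCube(spectra=np.full((h, w, 401), value))


def _template_cells(n_per_class=8, seed=11, noise=0.003):
    """24 mean spectra from 3 well-separated class templates + small noise."""
    rng = np.random.default_rng(seed)
    templates = syn.default_cell_templates()
    labels, spectra = [], []
    for lab in ("normal", "non_normal", "malignant"):
        t = templates[(lab, "nucleus")]
        for _ in range(n_per_class):
            spectra.append(t + rng.normal(0.0, noise, 401))
            labels.append(lab)
    return np.clip(np.stack(spectra), 0, 1), labels


class TestExtractRoi:
    def test_default_size_yields_100_spectra(self):
        cube = _constant_cube()
        assert cyto.extract_roi(cube, (3, 4)).shape == (100, 401)

    def test_size_one_is_single_pixel(self):
        cube = _constant_cube()
        cube.spectra[5, 6, :] = 0.123
        roi = cyto.extract_roi(cube, (5, 6), size=1)
        assert roi.shape == (1, 401)
        assert np.allclose(roi[0], 0.123)

    def test_row_major_flattening(self):
        cube = _constant_cube()
        cube.spectra[2, 3, 0] = 11.0
        cube.spectra[2, 4, 0] = 22.0
        cube.spectra[3, 3, 0] = 33.0
        roi = cyto.extract_roi(cube, (2, 3), size=2)
        assert list(roi[:, 0]) == [11.0, 22.0, 33.0, 0.5]

    @pytest.mark.parametrize("origin", [(-1, 0), (0, -1), (15, 0), (0, 15)])
    def test_out_of_bounds_rejected(self, origin):
        with pytest.raises(ValueError, match=str(origin[0])):
            cyto.extract_roi(_constant_cube(), origin, size=10)


class TestMeanSpectrum:
    def test_identical_rows(self):
        row = np.linspace(0, 1, 401)
        assert np.allclose(cyto.mean_spectrum(np.tile(row, (5, 1))), row)

    def test_two_rows_average(self):
        stack = np.stack([np.zeros(401), np.ones(401)])
        assert np.allclose(cyto.mean_spectrum(stack), 0.5)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 1, (100, 401))
        oracle = np.array([sum(stack[i, j] for i in range(100)) / 100 for j in range(401)])
        assert np.allclose(cyto.mean_spectrum(stack), oracle, atol=1e-12)

    def test_constant_cube_roi_mean_is_constant(self):
        cube = _constant_cube(0.37)
        roi = cyto.extract_roi(cube, (0, 0), size=10)
        assert np.allclose(cyto.mean_spectrum(roi), 0.37)


class TestPcaScores:
    def test_score_columns_centered(self):
        spectra, labels = _template_cells()
        table = cyto.pca_scores(spectra, 3, labels=labels)
        assert np.allclose(table.scores.mean(axis=0), 0.0, atol=1e-8)

    def test_two_cells_give_opposite_scores(self):
        spectra = np.stack([np.full(401, 0.3), np.full(401, 0.7)])
        table = cyto.pca_scores(spectra, 1)
        assert table.scores[0, 0] == pytest.approx(-table.scores[1, 0])

    def test_class_centroids_well_separated(self):
        spectra, labels = _template_cells(seed=11)
        table = cyto.pca_scores(spectra, 2, labels=labels)
        arr = np.asarray(labels)
        cents = {lab: table.scores[arr == lab].mean(axis=0) for lab in set(labels)}
        within_sd = max(
            table.scores[arr == lab].std(axis=0).max() for lab in set(labels)
        )
        labs = sorted(cents)
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                dist = np.linalg.norm(cents[labs[i]] - cents[labs[j]])
                assert dist > 3 * within_sd

    def test_low_rank_data_has_no_variance_beyond_rank(self):
        rng = np.random.default_rng(1)
        basis = np.stack([syn.gaussian_bump(c, 60.0) for c in (470, 590)])
        spectra = rng.uniform(0, 1, (12, 2)) @ basis
        table = cyto.pca_scores(spectra, 8)
        assert np.all(table.explained_ratio[2:] <= 1e-10)

    def test_scores_invariant_to_constant_offset(self):
        spectra, _ = _template_cells(seed=3)
        t1 = cyto.pca_scores(spectra, 3)
        t2 = cyto.pca_scores(spectra + 0.05, 3)
        # invariance up to component sign
        for k in range(3):
            col1, col2 = t1.scores[:, k], t2.scores[:, k]
            assert np.allclose(col1, col2, atol=1e-8) or np.allclose(col1, -col2, atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            cyto.pca_scores(np.random.default_rng(0).uniform(0, 1, (5, 401)), 5)


class TestScoreSpaceReport:
    def test_single_class_separation_undefined(self):
        spectra, _ = _template_cells(n_per_class=4)
        table = cyto.pca_scores(spectra[:4], 2, labels=["normal"] * 4)
        rep = cyto.score_space_report(table, (1, 2))
        assert np.isnan(rep["separation_index"])

    def test_collapsed_centroids_give_near_zero_index(self):
        rng = np.random.default_rng(4)
        spectra = np.clip(0.5 + rng.normal(0, 0.01, (30, 401)), 0, 1)
        labels = ["normal", "non_normal", "malignant"] * 10
        table = cyto.pca_scores(spectra, 2, labels=labels)
        rep = cyto.score_space_report(table, (1, 2))
        assert abs(rep["separation_index"]) < 0.2

    def test_separable_fixture_reports_distinct_centroids(self, tmp_path):
        spectra, labels = _template_cells(seed=11)
        table = cyto.pca_scores(spectra, 3, labels=labels)
        rep = cyto.score_space_report(table, (1, 2), out_dir=tmp_path)
        assert rep["separation_index"] > 0.5
        cents = [np.array(v) for v in rep["centroids"].values()]
        assert len(cents) == 3
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(cents[i] - cents[j]) > 0
        assert (tmp_path / "score_space.png").exists()
        assert (tmp_path / "score_space_centroids.csv").exists()

    def test_unavailable_pcs_rejected(self):
        spectra, labels = _template_cells()
        table = cyto.pca_scores(spectra, 2, labels=labels)
        with pytest.raises(ValueError):
            cyto.score_space_report(table, (2, 3))


class TestNearestCentroid:
    def test_cell_at_centroid_gets_its_class(self):
        spectra, labels = _template_cells(seed=11)
        table = cyto.pca_scores(spectra, 2, labels=labels)
        pred = cyto.nearest_centroid_assign(table)
        assert pred == labels

    def test_equidistant_tie_breaks_alphabetically(self):
        table = cyto.ScoreTable(
            cell_ids=["a", "b", "c"],
            labels=["normal", "malignant", "normal"],
            scores=np.array([[1.0], [-1.0], [0.0]]),
            explained_ratio=np.array([1.0]),
            loadings=np.zeros((1, 401)),
        )
        # cell "c" sits exactly between both centroids
        pred = cyto.nearest_centroid_assign(table, ["normal", "malignant", None])
        assert pred[2] == "malignant"  # alphabetically first

    def test_leave_one_out_perfect_on_separable_fixture(self):
        spectra, labels = _template_cells(seed=11)
        table = cyto.pca_scores(spectra, 2, labels=labels)
        correct = 0
        for i in range(len(labels)):
            train = list(labels)
            train[i] = None
            pred = cyto.nearest_centroid_assign(table, train)
            correct += pred[i] == labels[i]
        assert correct == len(labels)

    def test_missing_class_rejected(self):
        spectra, labels = _template_cells()
        table = cyto.pca_scores(spectra, 2, labels=labels)
        with pytest.raises(ValueError):
            cyto.nearest_centroid_assign(table, [None] * len(labels))


class TestCellRecord:
    def test_mean_autocomputed_and_invariants(self):
        rng = np.random.default_rng(5)
        pix = rng.uniform(0, 1, (100, 401))
        recd = cyto.CellRecord(
            cell_id="c1",
            label="malignant",
            compartment="nucleus",
            roi_origin=(0, 0),
            roi_size=10,
            pixel_spectra=pix,
        )
        assert np.allclose(recd.mean_spectrum, pix.mean(axis=0), atol=1e-10)

    def test_wrong_pixel_count_rejected(self):
        with pytest.raises(ValueError):
            cyto.CellRecord(
                cell_id="c1",
                label="normal",
                compartment="nucleus",
                roi_origin=(0, 0),
                roi_size=10,
                pixel_spectra=np.zeros((99, 401)),
            )
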