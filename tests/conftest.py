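import warnings

import numpy as np
import pytest

from vishsi import colorimetry as cm
from vishsi import cytology as cyto
from vishsi import reconstruction as rec
from vishsi import synthetic as syn


@pytest.fixture(scope="session")
def cmf():
    return cm.cie_1931_cmf()


@pytest.fixture(scope="session")
def d65():
    return cm.d65_illuminant()


@pytest.fixture(scope="session")
def checker24():
    """The 24-patch checker reflectance set used throughout."""
    return syn.generate_checker_spectra(24, seed=42)


@pytest.fixture(scope="session")
def noiseless_target(cmf):
    """Calibration session under an ideal camera (no dark current, no noise)."""
    camera = syn.CameraModel(dark_offset=0.0, noise_sd=0.0, seed=0)
    return syn.make_calibration_target(24, seed=42, camera=camera, cmf=cmf)


@pytest.fixture(scope="session")
def noiseless_pipeline(noiseless_target, cmf):
    return rec.fit_pipeline(noiseless_target, cmf)


@pytest.fixture(scope="session")
def cell_scene_render():
    """24-cell (8 per class) synthetic slide imaged through a noisy camera."""
    scene = syn.CellSceneSpec.demo(n_per_class=8, seed=11)
    camera = syn.CameraModel(dark_offset=2.0, noise_sd=0.5, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return syn.generate_cell_image(scene, camera)


@pytest.fixture(scope="session")
def cell_score_table(cell_scene_render):
    records = cyto.cells_from_cube(
        cell_scene_render.truth_cube, cell_scene_render.roi_annotations
    )
    means = np.stack([r.mean_spectrum for r in records])
    labels = [r.label for r in records]
    return cyto.pca_scores(means, 3, labels=labels), records
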