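"""Spectral reconstruction: corrected XYZ -> full 380-780 nm spectrum.

The reference reflectance spectra are compressed by mean-centred PCA to a
small orthonormal basis EV (12 components by default).  The principal-
component scores of the training patches are then regressed on the 7-term
colour polynomial of their corrected XYZ values,

    V_Color = [XYZ XY XZ YZ X Y Z]ᵀ,      M = Score · pinv(V_Color),

so that any corrected XYZ maps to an analog spectrum

    S(λ) = mean(λ) + EV · (M · V_Color).

Applying this per pixel of a corrected RGB image yields a hyperspectral
cube.  An ``uncentered=True`` switch drops the mean term and projects raw
spectra instead, reproducing the plain matrix formulation without the mean
offset.
"""

from __future__ import annotations

import base64
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from . import calibration as cal
from . import colorimetry as cm

__all__ = [
    "COLOR_BASIS_NAMES",
    "SpectralBasis",
    "ReconstructionModel",
    "HyperCube",
    "fit_spectral_basis",
    "build_color_basis",
    "fit_reconstruction",
    "reconstruct_spectrum",
    "reconstruct_cube",
    "CalibratedPipeline",
    "fit_pipeline",
]

COLOR_BASIS_NAMES = ("XYZ", "XY", "XZ", "YZ", "X", "Y", "Z")


@dataclass
class SpectralBasis:
    """Orthonormal PCA basis of the reference spectra."""

    components: np.ndarray        # (k, 401), rows orthonormal
    mean_spectrum: np.ndarray     # (401,); zeros in uncentered mode
    explained_ratio: np.ndarray   # (k,), nonincreasing
    centered: bool = True

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        self.mean_spectrum = cm.validate_spectrum(self.mean_spectrum, "mean_spectrum")
        self.explained_ratio = np.asarray(self.explained_ratio, dtype=float)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def scores(self, spectra) -> np.ndarray:
        """Project spectra onto the basis: (n, 401) -> (n, k)."""
        arr = cm.validate_spectrum(spectra, "spectra")
        return (arr - self.mean_spectrum) @ self.components.T

    def inverse(self, scores) -> np.ndarray:
        """Scores back to spectra: (n, k) -> (n, 401).

        Fixed-order summation (einsum) so results are bitwise independent
        of the batch size — required for the colour-cache equivalence in
        :func:`reconstruct_cube`.
        """
        s = np.atleast_2d(np.asarray(scores, dtype=float))
        out = np.einsum("ij,jk->ik", s, self.components) + self.mean_spectrum
        return out if np.asarray(scores).ndim > 1 else out[0]


def fit_spectral_basis(spectra, n_components: int = 12, *, uncentered: bool = False) -> SpectralBasis:
    """Mean-centred PCA of reference spectra (SVD, deterministic sign).

    Each component's largest-magnitude element is made positive so the
    basis is reproducible across platforms.
    """
    arr = cm.validate_spectrum(spectra, "spectra")
    if arr.ndim != 2:
        raise ValueError("spectra must be a 2-D (n, 401) array")
    n = arr.shape[0]
    if n < n_components:
        raise ValueError(
            f"need at least n_components={n_components} spectra, got {n}; "
            "lower n_components"
        )
    if uncentered:
        # Plain truncated SVD of the raw matrix; mean term is zero.
        _, s, vt = np.linalg.svd(arr, full_matrices=False)
        comps = vt[:n_components]
        var = s**2
        ratio = var[:n_components] / var.sum()
        mean = np.zeros(cm.N_WAVELENGTHS)
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        pca.fit(arr)
        comps = pca.components_
        ratio = pca.explained_variance_ratio_
        mean = pca.mean_
    flip = np.sign(comps[np.arange(comps.shape[0]), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    return SpectralBasis(comps, mean, ratio, centered=not uncentered)


def build_color_basis(xyz) -> np.ndarray:
    """The 7-term colour polynomial [XYZ, XY, XZ, YZ, X, Y, Z] (no constant).

    Operates on the [0,1]-rescaled XYZ convention shared with calibration.
    Accepts a 3-vector or (n, 3); returns (7,) or (n, 7).
    """
    arr = np.asarray(xyz, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) XYZ, got shape {arr.shape}")
    X, Y, Z = arr[:, 0], arr[:, 1], arr[:, 2]
    v = np.stack([X * Y * Z, X * Y, X * Z, Y * Z, X, Y, Z], axis=1)
    return v[0] if squeeze else v


@dataclass
class ReconstructionModel:
    basis: SpectralBasis
    M: np.ndarray  # (k, 7)
    color_basis_spec: tuple = COLOR_BASIS_NAMES
    training_fidelity: dict = field(default_factory=dict)
    clip_negative: bool = True
    scale: float = 100.0

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.shape != (self.basis.n_components, len(self.color_basis_spec)):
            raise ValueError(
                f"M must be {self.basis.n_components}x{len(self.color_basis_spec)}, "
                f"got {self.M.shape}"
            )

    def to_json(self, path) -> None:
        def b64(a):
            return base64.b64encode(np.ascontiguousarray(a, dtype=np.float64).tobytes()).decode()

        payload = {
            "color_basis_spec": list(self.color_basis_spec),
            "M_shape": list(self.M.shape),
            "M_b64": b64(self.M),
            "components_shape": list(self.basis.components.shape),
            "components_b64": b64(self.basis.components),
            "mean_spectrum_b64": b64(self.basis.mean_spectrum),
            "explained_ratio": self.basis.explained_ratio.tolist(),
            "centered": self.basis.centered,
            "training_fidelity": self.training_fidelity,
            "clip_negative": self.clip_negative,
            "scale": self.scale,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "ReconstructionModel":
        payload = json.loads(Path(path).read_text())

        def arr(key, shape):
            return np.frombuffer(base64.b64decode(payload[key]), dtype=np.float64).reshape(shape)

        basis = SpectralBasis(
            components=arr("components_b64", payload["components_shape"]),
            mean_spectrum=arr("mean_spectrum_b64", (cm.N_WAVELENGTHS,)),
            explained_ratio=np.array(payload["explained_ratio"]),
            centered=payload["centered"],
        )
        return cls(
            basis=basis,
            M=arr("M_b64", payload["M_shape"]),
            color_basis_spec=tuple(payload["color_basis_spec"]),
            training_fidelity=payload["training_fidelity"],
            clip_negative=payload["clip_negative"],
            scale=payload["scale"],
        )


def fit_reconstruction(
    basis: SpectralBasis,
    corrected_xyz,
    reference_spectra,
    illuminant=None,
    cmf: cm.CMFTable | None = None,
    rcond: float = 1e-10,
) -> ReconstructionModel:
    """Regress PCA scores on V_Color: M = Score · pinv(V_Color).

    ``corrected_xyz`` is on the 0-100 scale and patch-aligned with
    ``reference_spectra``.  Training fidelity (mean ΔE00 / ΔE76 under the
    illuminant, mean spectral RMSE) is evaluated by reconstructing every
    training patch; it is skipped when no illuminant is given.
    """
    xyz = np.atleast_2d(np.asarray(corrected_xyz, dtype=float))
    spectra = cm.validate_spectrum(reference_spectra, "reference_spectra")
    if xyz.shape[0] != spectra.shape[0]:
        raise ValueError("corrected_xyz and reference_spectra must be patch-aligned")
    v = build_color_basis(xyz / 100.0)  # (n, 7)
    if xyz.shape[0] < v.shape[1]:
        warnings.warn(
            f"{xyz.shape[0]} samples < {v.shape[1]} colour-basis terms: "
            "rank-deficient fit, minimum-norm solution",
            stacklevel=2,
        )
    scores = basis.scores(spectra)  # (n, k)
    m = scores.T @ np.linalg.pinv(v.T, rcond=rcond)
    model = ReconstructionModel(basis=basis, M=m)

    if illuminant is not None:
        cmf = cmf if cmf is not None else cm.cie_1931_cmf()
        recon = reconstruct_spectrum(model, xyz)
        white = cm.illuminant_white(illuminant, cmf)
        lab_rec = cm.xyz_to_lab(cm.spectrum_to_xyz(recon, illuminant, cmf), white)
        lab_ref = cm.xyz_to_lab(cm.spectrum_to_xyz(spectra, illuminant, cmf), white)
        model.training_fidelity = {
            "mean_de00": float(np.mean(cm.delta_e_2000(lab_rec, lab_ref))),
            "mean_de76": float(np.mean(cm.delta_e_76(lab_rec, lab_ref))),
            "mean_rmse": float(np.mean(np.sqrt(np.mean((recon - spectra) ** 2, axis=1)))),
        }
    return model


def reconstruct_spectrum(model: ReconstructionModel, xyz) -> np.ndarray:
    """Analog spectrum mean + EV·(M·V_Color) for one or many XYZ triples.

    Negative values are clipped to zero (physical nonnegativity); values
    above 1 are left untouched so calibration drift stays visible.
    """
    arr = np.asarray(xyz, dtype=float)
    squeeze = arr.ndim == 1
    v = build_color_basis(np.atleast_2d(arr) / model.scale)
    spectra = model.basis.inverse(v @ model.M.T)
    if model.clip_negative:
        spectra = np.clip(spectra, 0.0, None)
    return spectra[0] if squeeze else spectra


@dataclass
class HyperCube:
    """An H×W×401 stack of per-pixel spectra on the shared wavelength grid."""

    spectra: np.ndarray
    wavelengths: np.ndarray = field(default_factory=cm.wavelength_grid)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra)
        if self.spectra.ndim != 3 or self.spectra.shape[2] != cm.N_WAVELENGTHS:
            raise ValueError(f"spectra must be (H, W, {cm.N_WAVELENGTHS}), got {self.spectra.shape}")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("cube contains non-finite values")

    @property
    def height(self) -> int:
        return self.spectra.shape[0]

    @property
    def width(self) -> int:
        return self.spectra.shape[1]

    # -- NPZ round trip (bit exact for float32) --
    def save_npz(self, path) -> None:
        np.savez_compressed(
            path,
            spectra=self.spectra.astype(np.float32),
            wavelengths=self.wavelengths,
            meta=json.dumps(self.meta),
        )

    @classmethod
    def load_npz(cls, path) -> "HyperCube":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                spectra=z["spectra"],
                wavelengths=z["wavelengths"],
                meta=json.loads(str(z["meta"])),
            )

    # -- ENVI band-sequential (ASCII .hdr + float32 .raw) --
    def save_envi(self, header_path) -> None:
        header_path = Path(header_path)
        raw_path = header_path.with_suffix(".raw")
        data = np.ascontiguousarray(
            np.moveaxis(self.spectra.astype("<f4"), 2, 0)
        )  # BSQ: band, line, sample
        data.tofile(raw_path)
        wl = ", ".join(f"{w:.1f}" for w in self.wavelengths)
        header_path.write_text(
            "ENVI\n"
            f"samples = {self.width}\n"
            f"lines = {self.height}\n"
            f"bands = {self.spectra.shape[2]}\n"
            "header offset = 0\n"
            "file type = ENVI Standard\n"
            "data type = 4\n"
            "interleave = bsq\n"
            "byte order = 0\n"
            "wavelength units = Nanometers\n"
            f"wavelength = {{ {wl} }}\n"
        )

    @classmethod
    def load_envi(cls, header_path) -> "HyperCube":
        header_path = Path(header_path)
        fields = {}
        text = header_path.read_text()
        for line in text.splitlines():
            if "=" in line and not line.strip().startswith("wavelength ="):
                key, _, val = line.partition("=")
                fields[key.strip()] = val.strip()
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        wl_block = text.split("wavelength = {", 1)[1].split("}", 1)[0]
        wavelengths = np.array([float(t) for t in wl_block.split(",")])
        data = np.fromfile(header_path.with_suffix(".raw"), dtype="<f4")
        cube = np.moveaxis(data.reshape(bands, lines, samples), 0, 2)
        return cls(spectra=cube, wavelengths=wavelengths)


def reconstruct_cube(
    model: ReconstructionModel,
    image,
    correction: cal.CorrectionModel,
    source_white: cm.WhitePoint | None = None,
    *,
    cache: bool = True,
    paper_matrix: bool = False,
) -> HyperCube:
    """Per-pixel sRGB -> corrected XYZ -> spectrum over an 8-bit RGB image.

    With ``cache=True`` each unique 24-bit colour is reconstructed once and
    broadcast, which is bitwise identical to the per-pixel path.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"image must be H x W x 3, got shape {img.shape}")
    h, w, _ = img.shape
    flat = img.reshape(-1, 3)

    def colors_to_raw(colors):
        xyz = cm.srgb_to_xyz(colors, source_white, paper_matrix=paper_matrix)
        corrected = cal.apply_correction(correction, xyz)
        v = build_color_basis(corrected / model.scale)
        # fixed-order products: bitwise identical whether or not colours
        # are deduplicated first
        return model.basis.inverse(np.einsum("ij,kj->ik", v, model.M))

    if cache:
        uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
        raw = colors_to_raw(uniq)[inverse]
    else:
        raw = colors_to_raw(flat)
    n_clipped = int(np.count_nonzero(raw < 0.0))
    if model.clip_negative:
        raw = np.clip(raw, 0.0, None)
    cube = raw.reshape(h, w, cm.N_WAVELENGTHS)
    return HyperCube(spectra=cube, meta={"n_negative_clipped": n_clipped})


@dataclass
class CalibratedPipeline:
    """Correction + reconstruction models fitted on one calibration target."""

    correction: cal.CorrectionModel
    reconstruction: ReconstructionModel
    source_white: cm.WhitePoint
    illuminant: np.ndarray

    def reconstruct_image(self, image, **kwargs) -> HyperCube:
        return reconstruct_cube(
            self.reconstruction, image, self.correction, self.source_white, **kwargs
        )

    def reconstruct_xyz(self, camera_xyz) -> np.ndarray:
        corrected = cal.apply_correction(self.correction, camera_xyz)
        return reconstruct_spectrum(self.reconstruction, corrected)


def fit_pipeline(
    target: cal.CalibrationTarget,
    cmf: cm.CMFTable | None = None,
    n_components: int = 12,
    *,
    centered: bool = False,
    paper_matrix: bool = False,
) -> CalibratedPipeline:
    """Fit the full camera-to-spectrum pipeline on a calibration target.

    Camera XYZ comes from the patch mean RGBs; reference XYZ from the patch
    spectra under the target's illuminant.  C is fitted first, the PCA
    basis and M on top of the corrected XYZ.  The spectral basis is
    uncentred by default: the colour polynomial carries no constant term,
    so uncentred scores (purely linear in the spectra) are the
    formulation the regression can represent exactly; ``centered=True``
    switches to mean-centred PCA with the mean added back.
    """
    cmf = cmf if cmf is not None else cm.cie_1931_cmf()
    camera_xyz = cm.srgb_to_xyz(target.rgb8, target.source_white, paper_matrix=paper_matrix)
    reference_xyz = cm.spectrum_to_xyz(target.reference_spectra, target.illuminant, cmf)
    correction = cal.fit_correction(camera_xyz, reference_xyz, white=target.source_white)
    corrected = cal.apply_correction(correction, camera_xyz)
    basis = fit_spectral_basis(
        target.reference_spectra, n_components=n_components, uncentered=not centered
    )
    recon = fit_reconstruction(
        basis, corrected, target.reference_spectra, illuminant=target.illuminant, cmf=cmf
    )
    return CalibratedPipeline(
        correction=correction,
        reconstruction=recon,
        source_white=target.source_white,
        illuminant=target.illuminant,
    )
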