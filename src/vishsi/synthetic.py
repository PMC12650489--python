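"""Synthetic stand-ins for the study hardware: checker spectra, a camera
forward model, and stained-cell scenes with ground-truth spectra.

Everything here is seeded and bit-reproducible, and writes to the same
formats the real pipeline reads, so synthetic and real runs share one code
path.  The camera model follows a plain ISP chain: band integration of the
scene spectrum against sensitivity x illuminant, per-channel white
normalisation (auto white balance), optional extra gains, sRGB gamma
encoding, dark-current offset, additive Gaussian read noise in 8-bit
counts, and quantisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import colorimetry as cm
from .calibration import CalibrationPatch, CalibrationTarget
from .reconstruction import HyperCube

__all__ = [
    "gaussian_bump",
    "blackbody_spd",
    "halogen_illuminant",
    "default_sensitivities",
    "CameraModel",
    "default_camera",
    "generate_checker_spectra",
    "simulate_camera",
    "make_calibration_target",
    "CellSpec",
    "CellSceneSpec",
    "default_cell_templates",
    "SceneRender",
    "generate_cell_image",
]


def gaussian_bump(center: float, width: float, amplitude: float = 1.0) -> np.ndarray:
    """A smooth Gaussian reflectance bump on the wavelength grid."""
    wl = cm.wavelength_grid()
    return amplitude * np.exp(-0.5 * ((wl - center) / width) ** 2)


def blackbody_spd(temperature: float) -> np.ndarray:
    """Planckian radiator spectrum, normalised to 1 at 560 nm."""
    c2 = 1.4388e-2  # m K
    lam = cm.wavelength_grid() * 1e-9
    spd = lam**-5 / np.expm1(c2 / (lam * temperature))
    return spd / np.interp(560.0, cm.wavelength_grid(), spd)


def halogen_illuminant() -> np.ndarray:
    """Halogen-lamp-like illuminant: a 3200 K blackbody."""
    return blackbody_spd(3200.0)


def default_sensitivities() -> np.ndarray:
    """Bayer-like RGB channel responses: Gaussians at 610/540/460 nm, SD 30."""
    return np.stack(
        [gaussian_bump(c, 30.0) for c in (610.0, 540.0, 460.0)]
    )


@dataclass
class CameraModel:
    """Parametric forward model of an 8-bit RGB (or k-band) camera."""

    sensitivities: np.ndarray = field(default_factory=default_sensitivities)  # (k, 401)
    illuminant: np.ndarray = None
    white_balance_gains: np.ndarray = None  # (k,), on top of auto white normalisation
    gamma: str = "srgb"  # "srgb" or "linear"
    dark_offset: float = 0.0  # 8-bit counts
    noise_sd: float = 0.0  # 8-bit counts, additive Gaussian post-gamma
    seed: int = 0

    def __post_init__(self):
        self.sensitivities = np.atleast_2d(
            cm.validate_spectrum(self.sensitivities, "sensitivities")
        )
        if np.any(self.sensitivities < 0):
            raise ValueError("sensitivities must be nonnegative")
        if not np.any(self.sensitivities.sum(axis=1) > 0):
            raise ValueError("all-zero sensitivities")
        if self.illuminant is None:
            self.illuminant = cm.d65_illuminant()
        self.illuminant = cm.validate_spectrum(self.illuminant, "illuminant")
        k = self.sensitivities.shape[0]
        if self.white_balance_gains is None:
            self.white_balance_gains = np.ones(k)
        self.white_balance_gains = np.asarray(self.white_balance_gains, dtype=float)
        if np.any(self.white_balance_gains <= 0):
            raise ValueError("white balance gains must be positive")

    @property
    def n_bands(self) -> int:
        return self.sensitivities.shape[0]

    def source_white(self, cmf: cm.CMFTable | None = None) -> cm.WhitePoint:
        cmf = cmf if cmf is not None else cm.cie_1931_cmf()
        return cm.illuminant_white(self.illuminant, cmf)


def default_camera(seed: int = 0, *, dark_offset: float = 0.0, noise_sd: float = 0.0) -> CameraModel:
    return CameraModel(dark_offset=dark_offset, noise_sd=noise_sd, seed=seed)


def simulate_camera(spectra, camera: CameraModel, rng: np.random.Generator | None = None) -> np.ndarray:
    """Render reflectance/transmittance spectra to 8-bit camera triples.

    Chain: band integration -> per-channel normalisation so the perfect
    reflector hits full scale -> white-balance gains -> gamma encode ->
    x255 -> + dark offset + Gaussian noise -> clip, quantise.  Pass an
    ``rng`` to draw noise from an external stream; otherwise the camera's
    own seed is used (fresh generator per call, so same input -> same
    output).
    """
    arr = np.atleast_2d(cm.validate_spectrum(spectra, "spectra"))
    sens = camera.sensitivities * camera.illuminant  # (k, 401)
    white = sens.sum(axis=1)
    if np.any(white <= 0):
        raise ValueError("a channel has zero response under the illuminant")
    linear = arr @ sens.T / white * camera.white_balance_gains
    linear = np.clip(linear, 0.0, 1.0)
    if camera.gamma == "srgb":
        encoded = cm.gamma_encode(linear)
    elif camera.gamma == "linear":
        encoded = linear
    else:
        raise ValueError(f"unknown gamma mode {camera.gamma!r}")
    counts = encoded * 255.0 + camera.dark_offset
    if camera.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(camera.seed)
        counts = counts + rng.normal(0.0, camera.noise_sd, counts.shape)
    out = np.round(np.clip(counts, 0.0, 255.0)).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# Colour-checker spectra
# ---------------------------------------------------------------------------

# Dye-like primary bumps (center nm, width nm): broad Gaussians that are
# normalized to a partition of unity below, mimicking how compensating
# filters mix a small set of dyes.
_PRIMARY_BUMPS = ((650.0, 55.0), (550.0, 45.0), (455.0, 45.0))  # R, G, B

# Hue-family mixture weights over the (R, G, B) primaries.
_HUE_WEIGHTS = {
    "red": (0.85, 0.08, 0.05),
    "green": (0.10, 0.80, 0.08),
    "blue": (0.06, 0.10, 0.85),
    "magenta": (0.75, 0.08, 0.75),
    "yellow": (0.85, 0.70, 0.06),
    "cyan": (0.06, 0.70, 0.80),
}


def checker_primaries() -> np.ndarray:
    """The three smooth primary transmittance curves, (3, 401), summing to 1."""
    g = np.stack([gaussian_bump(c, w) for c, w in _PRIMARY_BUMPS])
    return g / g.sum(axis=0)


def generate_checker_spectra(n: int = 24, seed: int = 0) -> np.ndarray:
    """Smooth colour-checker-like reflectance spectra, (n, 401) in [0.02, 0.98].

    Each patch is a nonnegative mixture of three broad dye-like primary
    bumps (Gaussians at 650/550/455 nm, widths >= 45 nm, normalised to a
    partition of unity) — the dye-mixture structure of compensating
    filters, which makes the family exactly rank 3.  The first n-6 patches
    cycle through six hue families (red, green, blue, magenta, yellow,
    cyan) with seeded +/-15% jitter on the mixture weights; the last six
    are an exactly wavelength-constant gray ramp with strictly increasing
    levels — the gradation block used to assess camera nonlinearity.
    """
    if n < 7:
        raise ValueError(f"need at least 7 patches (6 hues + gray), got {n}")
    rng = np.random.default_rng(seed)
    primaries = checker_primaries()
    families = list(_HUE_WEIGHTS)
    spectra = np.empty((n, cm.N_WAVELENGTHS))
    n_chromatic = n - 6
    for i in range(n_chromatic):
        w = np.array(_HUE_WEIGHTS[families[i % len(families)]])
        w = w * rng.uniform(0.85, 1.15, size=3)
        # mixture values stay inside [min(w), max(w)] subset [0.02, 0.98]
        spectra[i] = w @ primaries
    levels = np.linspace(0.05, 0.90, 6)
    for j, level in enumerate(levels):
        spectra[n_chromatic + j] = level  # equal-weight mixture: exactly flat
    return spectra


def generate_low_rank_spectra(
    n: int = 24,
    seed: int = 0,
    centers=(420.0, 480.0, 540.0, 600.0, 660.0),
    width: float = 40.0,
    amplitude: float = 0.35,
    noise_sd: float = 1e-4,
) -> np.ndarray:
    """Near-low-rank smooth reflectance set: mixtures of fixed Gaussian bumps.

    Each spectrum is a nonnegative mixture (weights uniform on [0,1]) of
    ``len(centers)`` Gaussian basis curves plus small additive noise,
    clipped to [0,1].  The basis peaks at ``amplitude`` so that mixtures
    stay below 1 and the clip never truncates the low-rank structure: the
    set's variance is concentrated in the first ``len(centers)``
    principal components up to the noise floor.
    """
    rng = np.random.default_rng(seed)
    basis = np.stack([gaussian_bump(c, width, amplitude) for c in centers])
    weights = rng.uniform(0.0, 1.0, (n, len(centers)))
    spectra = weights @ basis
    spectra = spectra + rng.normal(0.0, noise_sd, spectra.shape)
    return np.clip(spectra, 0.0, 1.0)


def make_calibration_target(
    n: int = 24,
    seed: int = 0,
    camera: CameraModel | None = None,
    cmf: cm.CMFTable | None = None,
) -> CalibrationTarget:
    """A full synthetic calibration session: spectra + simulated patch RGBs."""
    camera = camera if camera is not None else default_camera()
    spectra = generate_checker_spectra(n, seed)
    rgb = simulate_camera(spectra, camera)
    patches = [
        CalibrationPatch(patch_id=f"patch_{i + 1:02d}", mean_rgb8=rgb[i], reference_spectrum=spectra[i])
        for i in range(n)
    ]
    return CalibrationTarget(
        patches=patches,
        illuminant=camera.illuminant,
        source_white=camera.source_white(cmf),
    )


# ---------------------------------------------------------------------------
# Stained-cell scenes
# ---------------------------------------------------------------------------

@dataclass
class CellSpec:
    center: tuple  # (row, col)
    nucleus_radius: float
    cytoplasm_radius: float
    label: str  # normal | non_normal | malignant

    def __post_init__(self):
        if not 0 < self.nucleus_radius < self.cytoplasm_radius:
            raise ValueError("need 0 < nucleus_radius < cytoplasm_radius")
        if self.label not in ("normal", "non_normal", "malignant"):
            raise ValueError(f"unknown label {self.label!r}")


def default_cell_templates() -> dict:
    """Class/compartment transmittance templates for Giemsa-stained cells.

    Built to satisfy the observed spectral orderings: the malignant nucleus
    sits strictly below the normal nucleus across 520-600 nm
    (hyperchromasia absorbs there), and within every class the nucleus sits
    below its cytoplasm across 450-550 nm (nucleic-acid absorption of
    blue-green light).
    """
    base = 0.80 + 0.10 * gaussian_bump(700.0, 120.0)  # bright, mildly red-tilted
    nuc_dip = gaussian_bump(500.0, 55.0)   # 450-550 nm nucleic-acid band
    chr_dip = gaussian_bump(560.0, 45.0)   # 520-600 nm chromatin band
    templates = {
        ("normal", "cytoplasm"): base - 0.06 * nuc_dip,
        ("normal", "nucleus"): base - 0.22 * nuc_dip - 0.05 * chr_dip,
        ("non_normal", "cytoplasm"): base - 0.08 * nuc_dip - 0.04 * chr_dip,
        ("non_normal", "nucleus"): base - 0.26 * nuc_dip - 0.16 * chr_dip,
        ("malignant", "cytoplasm"): base - 0.10 * nuc_dip - 0.10 * chr_dip,
        ("malignant", "nucleus"): base - 0.30 * nuc_dip - 0.34 * chr_dip,
    }
    return {k: np.clip(v, 0.0, 1.0) for k, v in templates.items()}


@dataclass
class CellSceneSpec:
    """Layout + spectral templates of a synthetic stained-cell field."""

    height: int = 96
    width: int = 96
    cells: list = field(default_factory=list)  # list[CellSpec]
    templates: dict = field(default_factory=default_cell_templates)
    background: np.ndarray = None
    perturbation_sd: float = 0.01  # per-cell smooth amplitude jitter
    seed: int = 0

    def __post_init__(self):
        if self.background is None:
            self.background = np.full(cm.N_WAVELENGTHS, 0.93)
        self.background = cm.validate_spectrum(self.background, "background")

    @classmethod
    def demo(cls, n_per_class: int = 2, seed: int = 0) -> "CellSceneSpec":
        """A small non-overlapping grid of cells, n per class."""
        labels = ["normal", "non_normal", "malignant"]
        cells = []
        n_total = 3 * n_per_class
        cols = int(np.ceil(np.sqrt(n_total)))
        rows = int(np.ceil(n_total / cols))
        pitch = 30
        h, w = rows * pitch + 6, cols * pitch + 6
        i = 0
        for lab in labels:
            for _ in range(n_per_class):
                r, c = divmod(i, cols)
                cells.append(
                    CellSpec(
                        center=(3 + pitch // 2 + r * pitch, 3 + pitch // 2 + c * pitch),
                        nucleus_radius=6.0,
                        cytoplasm_radius=11.0,
                        label=lab,
                    )
                )
                i += 1
        return cls(height=h, width=w, cells=cells, seed=seed)


@dataclass
class SceneRender:
    image: np.ndarray        # (H, W, 3) uint8
    truth_cube: HyperCube    # ground-truth per-pixel spectra
    label_map: np.ndarray    # (H, W) int: -1 background, else cell index
    compartment_map: np.ndarray  # (H, W) int: 0 bg, 1 cytoplasm, 2 nucleus
    roi_annotations: list    # dicts: cell_id,label,compartment,row,col,size


def generate_cell_image(scene: CellSceneSpec, camera: CameraModel, roi_size: int = 10) -> SceneRender:
    """Paint ground-truth spectra for a cell field and render it through the camera.

    Each cell gets a small seeded smooth perturbation of its class template
    (shared by nucleus and cytoplasm); ROI annotations are nucleus-centred
    ``roi_size`` x ``roi_size`` windows.  Overlapping cells trigger a
    warning, not an error.
    """
    import warnings

    h, w = scene.height, scene.width
    rr, cc = np.mgrid[0:h, 0:w]
    truth = np.broadcast_to(scene.background, (h, w, cm.N_WAVELENGTHS)).copy()
    label_map = np.full((h, w), -1, dtype=int)
    compartment_map = np.zeros((h, w), dtype=int)
    rng = np.random.default_rng(scene.seed)
    annotations = []

    painted = np.zeros((h, w), dtype=bool)
    for idx, cell in enumerate(scene.cells):
        r0, c0 = cell.center
        if not (0 <= r0 < h and 0 <= c0 < w):
            raise ValueError(f"cell {idx} centre {cell.center} outside the {h}x{w} image")
        dist = np.hypot(rr - r0, cc - c0)
        cyto = dist <= cell.cytoplasm_radius
        nuc = dist <= cell.nucleus_radius
        if np.any(painted & cyto):
            warnings.warn(f"cell {idx} overlaps a previously placed cell", stacklevel=2)
        painted |= cyto
        # Smooth per-cell perturbation: one wide bump with seeded amplitude.
        bump = gaussian_bump(rng.uniform(450.0, 650.0), 80.0)
        perturb = rng.normal(0.0, scene.perturbation_sd) * bump
        for compartment, mask, code in (("cytoplasm", cyto & ~nuc, 1), ("nucleus", nuc, 2)):
            spec = np.clip(scene.templates[(cell.label, compartment)] + perturb, 0.0, 1.0)
            truth[mask] = spec
        label_map[cyto] = idx
        compartment_map[cyto & ~nuc] = 1
        compartment_map[nuc] = 2
        annotations.append(
            {
                "cell_id": f"cell_{idx:03d}",
                "label": cell.label,
                "compartment": "nucleus",
                "row": int(r0 - roi_size // 2),
                "col": int(c0 - roi_size // 2),
                "size": roi_size,
            }
        )

    flat = truth.reshape(-1, cm.N_WAVELENGTHS)
    noise_rng = np.random.default_rng(camera.seed)
    rgb = simulate_camera(flat, camera, rng=noise_rng).reshape(h, w, 3)
    cube = HyperCube(spectra=truth, meta={"synthetic": True, "seed": scene.seed})
    return SceneRender(
        image=rgb,
        truth_cube=cube,
        label_map=label_map,
        compartment_map=compartment_map,
        roi_annotations=annotations,
    )
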