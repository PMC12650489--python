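"""Readers/writers and run configuration.

All tabular interchange is plain CSV on the strict 380-780 nm / 1 nm grid;
models are JSON; images go through imageio (PNG/TIFF losslessly, JPEG with
a logged warning since compression perturbs the reconstructed spectra).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import colorimetry as cm
from .calibration import CalibrationPatch, CalibrationTarget

log = logging.getLogger("vishsi")

__all__ = [
    "read_spectra_csv",
    "write_spectra_csv",
    "read_calibration_target",
    "write_calibration_target",
    "read_annotations_csv",
    "write_annotations_csv",
    "read_filter_array_csv",
    "write_filter_array_csv",
    "read_image",
    "write_image",
    "RunConfig",
    "provenance_record",
]


def _check_grid(wl: np.ndarray, path) -> None:
    expected = cm.wavelength_grid()
    if len(wl) != cm.N_WAVELENGTHS or not np.array_equal(np.asarray(wl, dtype=float), expected):
        wl = np.asarray(wl, dtype=float)
        bad = next(
            (f"{w:g}" for w, e in zip(wl, expected) if w != e),
            f"{len(wl)} rows (need {cm.N_WAVELENGTHS})",
        )
        raise ValueError(f"{path}: wavelength grid must be 380..780 step 1; first mismatch: {bad}")


def read_spectra_csv(path) -> tuple[list[str], np.ndarray]:
    """CSV with wavelength_nm + one column per spectrum -> (labels, (n, 401))."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be wavelength_nm, got {df.columns[0]!r}")
    _check_grid(df["wavelength_nm"].to_numpy(), path)
    values = df.iloc[:, 1:]
    arr = values.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        r, c = np.argwhere(~np.isfinite(arr))[0]
        raise ValueError(f"{path}: non-numeric cell at row {r + 2}, column {values.columns[c]!r}")
    return list(values.columns), arr.T.copy()


def write_spectra_csv(path, spectra, labels=None) -> None:
    arr = np.atleast_2d(cm.validate_spectrum(spectra, "spectra"))
    if labels is None:
        labels = [f"spectrum_{i + 1}" for i in range(arr.shape[0])]
    df = pd.DataFrame({"wavelength_nm": cm.wavelength_grid().astype(int)})
    for name, col in zip(labels, arr):
        df[name] = col
    df.to_csv(path, index=False, float_format="%.17g")


def read_calibration_target(rgb_csv, spectra_csv, illuminant_csv, cmf=None) -> CalibrationTarget:
    """Assemble a calibration target from its three CSV files.

    ``rgb_csv`` needs patch_id, R, G, B columns; ``spectra_csv`` one column
    per patch (column order = patch order); ``illuminant_csv`` a single
    spectrum column.
    """
    rgb = pd.read_csv(rgb_csv)
    for col in ("patch_id", "R", "G", "B"):
        if col not in rgb.columns:
            raise ValueError(f"{rgb_csv}: missing column {col!r}")
    _, spectra = read_spectra_csv(spectra_csv)
    if spectra.shape[0] != len(rgb):
        raise ValueError(
            f"{spectra_csv} has {spectra.shape[0]} spectra but {rgb_csv} has {len(rgb)} patches"
        )
    _, illum = read_spectra_csv(illuminant_csv)
    cmf = cmf if cmf is not None else cm.cie_1931_cmf()
    patches = [
        CalibrationPatch(
            patch_id=str(row.patch_id),
            mean_rgb8=np.array([row.R, row.G, row.B], dtype=float),
            reference_spectrum=spectra[i],
        )
        for i, row in enumerate(rgb.itertuples())
    ]
    return CalibrationTarget(
        patches=patches,
        illuminant=illum[0],
        source_white=cm.illuminant_white(illum[0], cmf),
    )


def write_calibration_target(target: CalibrationTarget, rgb_csv, spectra_csv, illuminant_csv) -> None:
    pd.DataFrame(
        {
            "patch_id": [p.patch_id for p in target.patches],
            "R": target.rgb8[:, 0].astype(int),
            "G": target.rgb8[:, 1].astype(int),
            "B": target.rgb8[:, 2].astype(int),
        }
    ).to_csv(rgb_csv, index=False)
    write_spectra_csv(spectra_csv, target.reference_spectra, [p.patch_id for p in target.patches])
    write_spectra_csv(illuminant_csv, target.illuminant, ["illuminant"])


def read_annotations_csv(path) -> list[dict]:
    df = pd.read_csv(path)
    required = {"cell_id", "label", "compartment", "row", "col", "size"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return df.to_dict(orient="records")


def write_annotations_csv(path, annotations) -> None:
    pd.DataFrame(annotations).to_csv(path, index=False)


def read_filter_array_csv(path, name=None, provenance="rgb"):
    from .metrics import FilterArraySpec

    labels, bands = read_spectra_csv(path)
    return FilterArraySpec(name or Path(path).stem, bands, provenance)


def write_filter_array_csv(path, filters) -> None:
    write_spectra_csv(
        path,
        filters.band_transmittances,
        [f"band_{i + 1}" for i in range(filters.n_bands)],
    )


def read_image(path) -> np.ndarray:
    """Load an 8-bit RGB image (PNG/TIFF/JPEG); alpha dropped if present."""
    import imageio.v3 as iio

    suffix = Path(path).suffix.lower()
    if suffix in (".jpg", ".jpeg"):
        log.warning("%s: JPEG compression perturbs reconstructed spectra", path)
    img = iio.imread(path)
    if img.ndim == 2:
        raise ValueError(f"{path}: grayscale image; need 3 RGB channels")
    if img.shape[2] == 4:
        img = img[..., :3]
    if img.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got dtype {img.dtype}")
    return img


def write_image(path, image) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


class ColorimetryOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    paper_matrix: bool = False
    adaptation: str = "vonkries_xyz"


class CalibrationOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_components: int = 12
    pinv_tolerance: float = 1e-10
    n_patches: int = 24


class RunConfig(BaseModel):
    """Validated experiment configuration (YAML/JSON; unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    output_dir: str = "vishsi_out"
    target_rgb_csv: str | None = None
    target_spectra_csv: str | None = None
    illuminant_csv: str | None = None
    image_path: str | None = None
    annotations_csv: str | None = None
    colorimetry: ColorimetryOptions = Field(default_factory=ColorimetryOptions)
    calibration: CalibrationOptions = Field(default_factory=CalibrationOptions)
    clip_negative: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def provenance_record(config: RunConfig | None = None, seed: int | None = None) -> dict:
    """Config hash, seed and library versions, embedded next to every output."""
    import sklearn

    rec = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scikit_learn": sklearn.__version__,
    }
    if config is not None:
        rec["config_hash"] = config.config_hash()
        rec["seed"] = config.seed
    if seed is not None:
        rec["seed"] = seed
    return rec
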