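"""Camera colorimetric correction against spectrometer-derived XYZ.

The camera's XYZ (from 8-bit sRGB) differs from the spectrometer's XYZ
through four error sources: nonlinear sensor response, dark current,
colour-filter inaccuracy and colour shift.  They are corrected jointly by a
single linear regression on a 20-term polynomial expansion V of the camera
XYZ:

    V = [X³ Y³ Z³ X²Y X²Z Y²Z XY² XZ² YZ² XYZ X² Y² Z² XY XZ YZ X Y Z 1]ᵀ
    C = XYZ_ref · pinv(V)          (C is 3×20)
    XYZ_corrected = C · V

The cubic block models the nonlinear response, the constant term absorbs
dark current, and the cross terms model filter inaccuracy / colour shift.
XYZ values are rescaled from 0–100 to 0–1 before the expansion so the cubic
monomials stay well conditioned; fit metrics are reported on that [0,1]
scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import colorimetry as cm

__all__ = [
    "VARIABLE_BASIS_NAMES",
    "CalibrationPatch",
    "CalibrationTarget",
    "CorrectionModel",
    "build_variable_matrix",
    "fit_correction",
    "apply_correction",
    "assess_nonlinearity",
]

# Ordered 20-term basis. The constant term models dark current.
VARIABLE_BASIS_NAMES = (
    "X3", "Y3", "Z3",
    "X2Y", "X2Z", "Y2Z", "XY2", "XZ2", "YZ2", "XYZ",
    "X2", "Y2", "Z2",
    "XY", "XZ", "YZ",
    "X", "Y", "Z",
    "1",
)


@dataclass
class CalibrationPatch:
    patch_id: str
    mean_rgb8: np.ndarray          # three values in 0..255
    reference_spectrum: np.ndarray  # 401 reflectances


@dataclass
class CalibrationTarget:
    """A colour-checker session: patches + the light source they were shot under."""

    patches: list[CalibrationPatch]
    illuminant: np.ndarray
    source_white: cm.WhitePoint

    def __post_init__(self):
        ids = [p.patch_id for p in self.patches]
        if len(set(ids)) != len(ids):
            raise ValueError("patch_ids must be unique")
        if len(self.patches) < 20:
            raise ValueError(f"need at least 20 patches, got {len(self.patches)}")
        self.illuminant = cm.validate_spectrum(self.illuminant, "illuminant")

    @property
    def rgb8(self) -> np.ndarray:
        return np.stack([p.mean_rgb8 for p in self.patches]).astype(float)

    @property
    def reference_spectra(self) -> np.ndarray:
        return np.stack([p.reference_spectrum for p in self.patches])

    def gray_ramp_indices(self) -> np.ndarray:
        """The last six patches form the gray gradation ramp."""
        return np.arange(len(self.patches) - 6, len(self.patches))


def build_variable_matrix(xyz) -> np.ndarray:
    """Expand XYZ (on the [0,1] scale) into the ordered 20-term basis.

    Accepts a 3-vector or (n, 3) array; returns (20,) or (n, 20).
    """
    arr = np.asarray(xyz, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("XYZ input contains non-finite values")
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) XYZ, got shape {arr.shape}")
    X, Y, Z = arr[:, 0], arr[:, 1], arr[:, 2]
    cols = [
        X**3, Y**3, Z**3,
        X**2 * Y, X**2 * Z, Y**2 * Z, X * Y**2, X * Z**2, Y * Z**2, X * Y * Z,
        X**2, Y**2, Z**2,
        X * Y, X * Z, Y * Z,
        X, Y, Z,
        np.ones_like(X),
    ]
    v = np.stack(cols, axis=1)
    return v[0] if squeeze else v


@dataclass
class CorrectionModel:
    """Fitted 3×20 correction matrix with its basis definition and fit metrics."""

    C: np.ndarray
    basis_spec: tuple = VARIABLE_BASIS_NAMES
    fit_rmse: float = float("nan")      # on the [0,1] XYZ scale
    fit_delta_e00: float = float("nan")
    scale: float = 100.0                # inputs/outputs are 0-100; V built on /scale

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (3, len(self.basis_spec)):
            raise ValueError(f"C must be 3x{len(self.basis_spec)}, got {self.C.shape}")

    @property
    def dark_current_estimate(self) -> np.ndarray:
        """Learned coefficients of the constant basis term ([0,1] XYZ scale)."""
        return self.C[:, list(self.basis_spec).index("1")]

    def to_json(self, path) -> None:
        payload = {
            "C_row_major": self.C.ravel().tolist(),
            "basis_spec": list(self.basis_spec),
            "scale": self.scale,
            "fit_rmse": self.fit_rmse,
            "fit_delta_e00": self.fit_delta_e00,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "CorrectionModel":
        payload = json.loads(Path(path).read_text())
        basis = tuple(payload["basis_spec"])
        return cls(
            C=np.array(payload["C_row_major"]).reshape(3, len(basis)),
            basis_spec=basis,
            fit_rmse=payload["fit_rmse"],
            fit_delta_e00=payload["fit_delta_e00"],
            scale=payload["scale"],
        )


def fit_correction(
    camera_xyz,
    reference_xyz,
    white: cm.WhitePoint | None = None,
    rcond: float = 1e-10,
) -> CorrectionModel:
    """Solve C = XYZ_ref · pinv(V) on patch-aligned camera/reference XYZ.

    Inputs are on the 0-100 scale; the regression runs on the [0,1]
    rescale.  ``white`` (default: the sRGB D65 specification white) is the
    reference against which the ΔE00 fit metric is evaluated.
    """
    cam = np.atleast_2d(np.asarray(camera_xyz, dtype=float))
    ref = np.atleast_2d(np.asarray(reference_xyz, dtype=float))
    if cam.shape != ref.shape:
        raise ValueError(f"camera/reference shapes differ: {cam.shape} vs {ref.shape}")
    n = cam.shape[0]
    v = build_variable_matrix(cam / 100.0)  # (n, 20)
    if n < v.shape[1]:
        warnings.warn(
            f"{n} samples < {v.shape[1]} basis terms: rank-deficient fit, "
            "returning the minimum-norm solution",
            stacklevel=2,
        )
    # C = ref01 (3, n) @ pinv(V (20, n)); singular values < rcond*sigma_max dropped.
    c = (ref.T / 100.0) @ np.linalg.pinv(v.T, rcond=rcond)
    model = CorrectionModel(C=c)
    corrected = apply_correction(model, cam)
    resid = (corrected - ref) / 100.0
    model.fit_rmse = float(np.sqrt(np.mean(resid**2)))
    wp = white if white is not None else cm.d65_specification_white()
    model.fit_delta_e00 = float(
        np.mean(cm.delta_e_2000(cm.xyz_to_lab(corrected, wp), cm.xyz_to_lab(ref, wp)))
    )
    return model


def apply_correction(model: CorrectionModel, xyz) -> np.ndarray:
    """XYZ_corrected = C · V(xyz); in and out on the 0-100 scale."""
    arr = np.asarray(xyz, dtype=float)
    v = build_variable_matrix(arr / model.scale)
    return model.scale * v @ model.C.T


def assess_nonlinearity(camera_gray_Y, reference_gray_Y) -> dict:
    """Cubic OLS of reference luminance on camera luminance (gray ramp).

    The spectrometer responds linearly, so curvature in this fit is the
    camera's nonlinear response; returns the cubic coefficients (highest
    power first) and the coefficient of determination.
    """
    x = np.asarray(camera_gray_Y, dtype=float)
    y = np.asarray(reference_gray_Y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("camera and reference luminances must be equal-length 1-D")
    if np.ptp(x) == 0:
        raise ValueError("camera luminances are constant; cubic fit is degenerate")
    coeffs = np.polyfit(x, y, 3)
    pred = np.polyval(coeffs, x)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return {"coefficients": coeffs, "r_squared": r2}
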