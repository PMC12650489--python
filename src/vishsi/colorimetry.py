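"""CIE 1931 colorimetry shared by every pipeline stage.

All spectral quantities live on a fixed visible-light grid, 380-780 nm
sampled every 1 nm (401 points).  Tristimulus values use the 0-100
convention in which the Y of the measuring illuminant is 100.  The module
provides the ground-truth transforms the calibration and reconstruction
stages are built on:

* sRGB gamma decoding / encoding (IEC 61966-2-1 piecewise curve),
* 8-bit sRGB -> XYZ with diagonal (von Kries in XYZ) chromatic adaptation
  from the sRGB D65 specification white to a measured source white,
* spectrum -> XYZ integration against the 2-degree standard observer with
  the brightness normalisation k that pins the illuminant's Y at 100,
* XYZ -> CIELAB, and the CIE76 / CIEDE2000 colour differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources

import numpy as np

__all__ = [
    "WL_START",
    "WL_STOP",
    "N_WAVELENGTHS",
    "wavelength_grid",
    "validate_spectrum",
    "CMFTable",
    "WhitePoint",
    "Tristimulus",
    "TristimulusOrigin",
    "LabColor",
    "SRGB_TO_XYZ_STANDARD",
    "SRGB_TO_XYZ_PAPER",
    "gamma_expand",
    "gamma_encode",
    "linear_rgb_to_xyz",
    "srgb_to_xyz",
    "spectrum_to_xyz",
    "illuminant_white",
    "xyz_to_lab",
    "delta_e_76",
    "delta_e_2000",
    "cie_1931_cmf",
    "d65_illuminant",
    "d65_specification_white",
]

WL_START = 380
WL_STOP = 780
N_WAVELENGTHS = 401


def wavelength_grid() -> np.ndarray:
    """The shared 380..780 nm, 1 nm wavelength grid (401 points)."""
    return np.arange(WL_START, WL_STOP + 1, dtype=float)


def validate_spectrum(values, name: str = "spectrum") -> np.ndarray:
    """Coerce to float array and check the 401-sample grid contract."""
    arr = np.asarray(values, dtype=float)
    if arr.shape[-1] != N_WAVELENGTHS:
        raise ValueError(
            f"{name} must have {N_WAVELENGTHS} samples on the 380-780 nm 1 nm "
            f"grid, got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


class TristimulusOrigin(str, Enum):
    CAMERA = "camera"
    SPECTRUM = "spectrum"
    CORRECTED = "corrected"


@dataclass(frozen=True)
class Tristimulus:
    """An (X, Y, Z) triple on the 0-100 scale with a provenance tag."""

    X: float
    Y: float
    Z: float
    origin: TristimulusOrigin = TristimulusOrigin.SPECTRUM

    def to_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z], dtype=float)

    @classmethod
    def from_array(cls, xyz, origin=TristimulusOrigin.SPECTRUM) -> "Tristimulus":
        x, y, z = np.asarray(xyz, dtype=float).reshape(3)
        return cls(float(x), float(y), float(z), TristimulusOrigin(origin))


@dataclass(frozen=True)
class LabColor:
    L: float
    a: float
    b: float

    def to_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class WhitePoint:
    """Reference white on the 0-100 scale; Yw is 100 by construction."""

    Xw: float
    Yw: float
    Zw: float
    role: str = "measured_source"  # or "d65_specification"

    def __post_init__(self):
        if min(self.Xw, self.Yw, self.Zw) <= 0:
            raise ValueError("white point components must be positive")
        if abs(self.Yw - 100.0) > 0.5:
            raise ValueError(f"white point Yw must be ~100, got {self.Yw}")

    def to_array(self) -> np.ndarray:
        return np.array([self.Xw, self.Yw, self.Zw], dtype=float)


@dataclass(frozen=True)
class CMFTable:
    """Colour matching functions x̄, ȳ, z̄ of the 2° standard observer."""

    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self):
        for name in ("xbar", "ybar", "zbar"):
            arr = validate_spectrum(getattr(self, name), name)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
            object.__setattr__(self, name, arr)

    def stack(self) -> np.ndarray:
        """(3, 401) array in x̄, ȳ, z̄ order."""
        return np.stack([self.xbar, self.ybar, self.zbar])


# IEC 61966-2-1 linear-RGB -> XYZ matrix (D65 white).
SRGB_TO_XYZ_STANDARD = np.array(
    [
        [0.4124, 0.3576, 0.1805],
        [0.2126, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9505],
    ]
)

# Variant with first element 0.4104, offered for strict reproduction of
# sources that print that value; it breaks the D65 white identity slightly.
SRGB_TO_XYZ_PAPER = SRGB_TO_XYZ_STANDARD.copy()
SRGB_TO_XYZ_PAPER[0, 0] = 0.4104

# Bradford cone-response matrix, optional chromatic-adaptation mode.
_BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)


def d65_specification_white(paper_matrix: bool = False) -> WhitePoint:
    """The sRGB D65 specification white implied by the conversion matrix.

    Defined as 100x the matrix row sums so that RGB=(255,255,255) maps to
    the specification white exactly and the chromatic adaptation of a
    D65-white source is the identity.
    """
    t = SRGB_TO_XYZ_PAPER if paper_matrix else SRGB_TO_XYZ_STANDARD
    x, y, z = 100.0 * t.sum(axis=1)
    return WhitePoint(x, y, z, role="d65_specification")


def gamma_expand(encoded) -> np.ndarray | float:
    """sRGB electro-optical transfer: encoded [0,1] -> linear [0,1].

    Piecewise: n/12.92 for n <= 0.04045, else ((n+0.055)/1.055)^2.4.
    """
    arr = np.asarray(encoded, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        bad = arr[~(np.isfinite(arr) & (arr >= 0) & (arr <= 1))]
        raise ValueError(f"encoded values must lie in [0, 1]; offending value(s) {bad.ravel()[:5]}")
    out = np.where(arr > 0.04045, ((arr + 0.055) / 1.055) ** 2.4, arr / 12.92)
    return float(out) if np.isscalar(encoded) else out


def gamma_encode(linear) -> np.ndarray | float:
    """Inverse of :func:`gamma_expand` (the sRGB OETF)."""
    arr = np.asarray(linear, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        bad = arr[~(np.isfinite(arr) & (arr >= 0) & (arr <= 1))]
        raise ValueError(f"linear values must lie in [0, 1]; offending value(s) {bad.ravel()[:5]}")
    out = np.where(arr > 0.0031308, 1.055 * arr ** (1 / 2.4) - 0.055, 12.92 * arr)
    return float(out) if np.isscalar(linear) else out


def linear_rgb_to_xyz(rgb_linear, paper_matrix: bool = False) -> np.ndarray:
    """Linear RGB in [0,1] -> XYZ on the 0-100 scale (no adaptation)."""
    t = SRGB_TO_XYZ_PAPER if paper_matrix else SRGB_TO_XYZ_STANDARD
    rgb = np.asarray(rgb_linear, dtype=float)
    return 100.0 * rgb @ t.T


def _adaptation_matrix(source_white: WhitePoint, spec_white: WhitePoint, mode: str) -> np.ndarray:
    sw = source_white.to_array()
    cw = spec_white.to_array()
    if mode == "vonkries_xyz":
        return np.diag(sw / cw)
    if mode == "bradford":
        rho_s = _BRADFORD @ sw
        rho_c = _BRADFORD @ cw
        return np.linalg.inv(_BRADFORD) @ np.diag(rho_s / rho_c) @ _BRADFORD
    raise ValueError(f"unknown adaptation mode {mode!r}")


def srgb_to_xyz(
    rgb8,
    source_white: WhitePoint | None = None,
    *,
    paper_matrix: bool = False,
    adaptation: str = "vonkries_xyz",
) -> np.ndarray:
    """8-bit sRGB -> camera XYZ (0-100) under the measuring light source.

    The 0-255 channels are rescaled to [0,1], gamma expanded, pushed through
    the sRGB matrix, scaled x100 and finally adapted from the sRGB D65
    specification white to ``source_white`` by a diagonal XYZ scaling
    (``adaptation="bradford"`` swaps in the Bradford transform).

    Accepts a single triple or any (..., 3) array; returns matching shape.
    """
    rgb = np.asarray(rgb8, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) RGB input, got shape {rgb.shape}")
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError("8-bit RGB channels must lie in 0..255")
    xyz = linear_rgb_to_xyz(gamma_expand(rgb / 255.0), paper_matrix=paper_matrix)
    spec_white = d65_specification_white(paper_matrix=paper_matrix)
    if source_white is not None:
        ma = _adaptation_matrix(source_white, spec_white, adaptation)
        xyz = xyz @ ma.T
    return xyz


def spectrum_to_xyz(reflectance, illuminant, cmf: CMFTable) -> np.ndarray:
    """Reflectance (or transmittance) spectrum -> XYZ under an illuminant.

    X = k * sum(S R x̄), etc., with k = 100 / sum(S ȳ) so that a perfect
    reflector has Y = 100.  Integrals are rectangle-rule sums on the 1 nm
    grid.  ``reflectance`` may be (401,) or (n, 401).
    """
    refl = validate_spectrum(reflectance, "reflectance")
    illum = validate_spectrum(illuminant, "illuminant")
    denom = float(illum @ cmf.ybar)
    if denom <= 0:
        raise ZeroDivisionError("illuminant has zero luminance: k is undefined")
    k = 100.0 / denom
    weighted = cmf.stack() * illum  # (3, 401)
    return k * refl @ weighted.T


def illuminant_white(illuminant, cmf: CMFTable) -> WhitePoint:
    """White point of an illuminant: XYZ of the perfect reflector under it."""
    x, y, z = spectrum_to_xyz(np.ones(N_WAVELENGTHS), illuminant, cmf)
    return WhitePoint(x, y, z, role="measured_source")


def _lab_f(n: np.ndarray) -> np.ndarray:
    # Branch threshold 0.008856 = (6/29)^3; offset 0.137931 = 16/116.
    return np.where(n > 0.008856, np.cbrt(n), 7.787 * n + 0.137931)


def xyz_to_lab(xyz, white: WhitePoint) -> np.ndarray:
    """XYZ (0-100) -> CIELAB under the given reference white.

    L* = 116 f(Y/Yn) - 16, a* = 500 (f(X/Xn) - f(Y/Yn)),
    b* = 200 (f(Y/Yn) - f(Z/Zn)).
    """
    arr = np.asarray(xyz, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) XYZ input, got shape {arr.shape}")
    f = _lab_f(arr / white.to_array())
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    return np.stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)], axis=-1)


def delta_e_76(lab1, lab2) -> np.ndarray | float:
    """CIE76 colour difference: Euclidean distance in Lab."""
    d = np.asarray(lab1, dtype=float) - np.asarray(lab2, dtype=float)
    out = np.sqrt(np.sum(d * d, axis=-1))
    return float(out) if out.ndim == 0 else out


def delta_e_2000(lab1, lab2, kL: float = 1.0, kC: float = 1.0, kH: float = 1.0):
    """CIEDE2000 colour difference (Sharma et al. formulation).

    Includes the a*-axis rescaling (G), weighting functions S_L/S_C/S_H and
    the blue-region rotation term R_T; parametric factors default to 1.
    """
    l1 = np.asarray(lab1, dtype=float)
    l2 = np.asarray(lab2, dtype=float)
    L1, a1, b1 = l1[..., 0], l1[..., 1], l1[..., 2]
    L2, a2, b2 = l2[..., 0], l2[..., 1], l2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0, 0.0, h1p)
    h2p = np.where(C2p == 0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p

    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        C1p * C2p == 0,
        hsum,
        np.where(
            habs <= 180.0,
            0.5 * hsum,
            np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
        ),
    )

    T = (
        1.0
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    out = np.sqrt(
        (dLp / (kL * SL)) ** 2
        + (dCp / (kC * SC)) ** 2
        + (dHp / (kH * SH)) ** 2
        + RT * (dCp / (kC * SC)) * (dHp / (kH * SH))
    )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Packaged observer / illuminant tables
# ---------------------------------------------------------------------------

def _read_packaged_csv(name: str) -> np.ndarray:
    with resources.files("vishsi.data").joinpath(name).open("r") as fh:
        data = np.loadtxt(fh, delimiter=",", skiprows=1)
    wl = data[:, 0]
    expected = wavelength_grid()
    if data.shape[0] != N_WAVELENGTHS or not np.allclose(wl, expected):
        bad = wl[0] if data.shape[0] and wl[0] != expected[0] else wl
        raise ValueError(f"packaged table {name} is not on the 380-780/1 nm grid (starts {bad})")
    return data[:, 1:]


_CMF_CACHE: CMFTable | None = None
_D65_CACHE: np.ndarray | None = None


def cie_1931_cmf() -> CMFTable:
    """The packaged CIE 1931 2° standard-observer table at 1 nm.

    See ``vishsi/data/PROVENANCE.md`` for the source of the table.
    """
    global _CMF_CACHE
    if _CMF_CACHE is None:
        cols = _read_packaged_csv("cmf_cie1931_2deg.csv")
        _CMF_CACHE = CMFTable(cols[:, 0], cols[:, 1], cols[:, 2])
    return _CMF_CACHE


def d65_illuminant() -> np.ndarray:
    """Packaged daylight illuminant whose white point matches D65.

    A synthetic smooth daylight curve (see data provenance note); its XYZ
    under the packaged observer equals the D65 white to numerical precision.
    """
    global _D65_CACHE
    if _D65_CACHE is None:
        _D65_CACHE = _read_packaged_csv("illuminant_d65_synthetic.csv")[:, 0]
    return _D65_CACHE
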