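"""Regenerate the packaged colorimetric tables in src/vishsi/data/.

Run from the repository root:  python scripts/build_tables.py

Both tables are fully determined by published closed forms, so the CSVs can
be rebuilt bit-identically at any time; provenance details live in
src/vishsi/data/PROVENANCE.md.
"""

from pathlib import Path

import numpy as np

WL = np.arange(380.0, 781.0)
OUT = Path(__file__).resolve().parent.parent / "src" / "vishsi" / "data"

# D65 chromaticity white on the 0-100 scale (X/Y and Z/Y ratios are used).
D65_WHITE = np.array([95.047, 100.0, 108.883])


def _lobe(x, mu, tau_l, tau_r):
    """Piecewise Gaussian with separate left/right inverse widths."""
    tau = np.where(x < mu, tau_l, tau_r)
    return np.exp(-0.5 * (tau * (x - mu)) ** 2)


def analytic_cmf(wl):
    """Multi-lobe Gaussian fit to the CIE 1931 2-degree observer.

    Coefficients from Wyman, Sloan & Shirley, "Simple Analytic
    Approximations to the CIE XYZ Color Matching Functions", JCGT 2(2),
    2013 (multi-lobe fit). Values clipped at 0 to keep the observer
    nonnegative where the fit dips marginally below zero.
    """
    xbar = (
        1.056 * _lobe(wl, 599.8, 0.0264, 0.0323)
        + 0.362 * _lobe(wl, 442.0, 0.0624, 0.0374)
        - 0.065 * _lobe(wl, 501.1, 0.0490, 0.0382)
    )
    ybar = 0.821 * _lobe(wl, 568.8, 0.0213, 0.0247) + 0.286 * _lobe(wl, 530.9, 0.0613, 0.0322)
    zbar = 1.217 * _lobe(wl, 437.0, 0.0845, 0.0278) + 0.681 * _lobe(wl, 459.0, 0.0385, 0.0725)
    return np.clip(np.stack([xbar, ybar, zbar], axis=1), 0.0, None)


def planck_spd(wl_nm, temperature):
    """Blackbody spectral radiance, normalised to 1 at 560 nm."""
    c2 = 1.4388e-2  # m K
    lam = wl_nm * 1e-9
    spd = lam**-5 / np.expm1(c2 / (lam * temperature))
    return spd / np.interp(560.0, wl_nm, spd)


def synthetic_d65(wl, cmf):
    """Smooth daylight-like curve whose white point is exactly D65.

    Start from a 6504 K Planckian radiator and add a small smooth
    correction in the span of the observer curves so that the chromaticity
    of the perfect reflector matches the D65 white exactly.
    """
    s0 = planck_spd(wl, 6504.0)
    xbar, ybar, zbar = cmf.T
    tx, ty, tz = D65_WHITE

    def u(s):
        return np.array([s @ xbar, s @ ybar, s @ zbar])

    # Constraints: 100*U1 - tx*U2 = 0 and 100*U3 - tz*U2 = 0 for
    # S = s0 + alpha*xbar + beta*zbar (linear in alpha, beta).
    def resid(s):
        ux, uy, uz = u(s)
        return np.array([100.0 * ux - tx * uy, 100.0 * uz - tz * uy])

    a = np.column_stack([resid(xbar), resid(zbar)])
    alpha, beta = np.linalg.solve(a, -resid(s0))
    spd = s0 + alpha * xbar + beta * zbar
    if spd.min() < 0:
        raise RuntimeError("synthetic daylight went negative; correction too large")
    return spd / np.interp(560.0, wl, spd)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cmf = analytic_cmf(WL)
    with open(OUT / "cmf_cie1931_2deg.csv", "w") as fh:
        fh.write("wavelength_nm,xbar,ybar,zbar\n")
        for wl, (x, y, z) in zip(WL, cmf):
            fh.write(f"{wl:.0f},{x:.8f},{y:.8f},{z:.8f}\n")

    d65 = synthetic_d65(WL, cmf)
    with open(OUT / "illuminant_d65_synthetic.csv", "w") as fh:
        fh.write("wavelength_nm,relative_power\n")
        for wl, v in zip(WL, d65):
            fh.write(f"{wl:.0f},{v:.8f}\n")

    ux = cmf[:, 0] @ d65
    uy = cmf[:, 1] @ d65
    uz = cmf[:, 2] @ d65
    print("white point:", 100 * ux / uy, 100.0, 100 * uz / uy)
    print("ybar peak at", WL[np.argmax(cmf[:, 1])], "nm")


if __name__ == "__main__":
    main()
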