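# Methods

This note documents the models, numerical choices and known limits of
`vishsi`. Everything quantitative below is computed by the test suite or
`scripts/acceptance.py`; nothing is asserted that the code does not measure.

## Colorimetry

All spectral data live on a fixed 380–780 nm grid at 1 nm (401 samples);
integrals are rectangle-rule sums with dλ = 1 nm, matching the sampling of
the data the pipeline consumes (no higher-order quadrature is warranted at
1 nm resolution). Tristimulus values use the 0–100 convention: the
brightness constant k = 100/∫S(λ)ȳ(λ)dλ pins the measuring illuminant's Y
at 100, so a perfect reflector always has Y = 100 regardless of the lamp.

The sRGB decode follows IEC 61966-2-1 (linear segment below 0.04045,
exponent 2.4 above; both branches agree to <1e-6 at the threshold). The
default linear-RGB→XYZ matrix is the standard IEC matrix (first element
0.4124); a `paper_matrix=True` switch substitutes 0.4104 in that position
for strict reproduction of sources that print that variant, at the cost of
breaking the D65 white identity by ~0.2 in X. The D65 specification white
is defined as 100× the matrix row sums, so RGB=(255,255,255) maps to the
specification white *exactly* and chromatic adaptation of a D65 source is
the identity. Adaptation is the diagonal von Kries scaling in XYZ, as is
conventional for this calibration style; a Bradford mode is provided but
off by default.

CIELAB uses the two-branch f with threshold 0.008856 and offset 16/116;
CIEDE2000 implements the Sharma et al. formulation with kL = kC = kH = 1
(no parametric factors are given for the microscopy use case, and 1 is the
reference condition). The implementation reproduces the published
worked-example pairs to 1e-4 and matches scikit-image's independent
implementation to 1e-4 over random Lab pairs (both checked in the suite).

**Observer and illuminant tables.** The packaged CIE 1931 2° observer is
the multi-lobe piecewise-Gaussian analytic fit of Wyman, Sloan & Shirley
(JCGT 2013), sampled at 1 nm and clipped at zero; its ȳ peaks at 554 nm.
The packaged daylight illuminant is a *synthetic* curve — a 6504 K
Planckian radiator plus a small correction in the span of the observer
functions, solved so the perfect-reflector white point is exactly
(95.047, 100, 108.883). Both are regenerated bit-identically by
`scripts/build_tables.py`; see `src/vishsi/data/PROVENANCE.md`. Because
reference XYZ, the camera simulation and all fidelity metrics share this
observer, every result in the package is self-consistent in it; absolute
agreement with instruments calibrated to the measured CIE tables is
limited by the ~1% fit error of the analytic observer.

## Camera correction

The 20-term basis V is ordered [X³ Y³ Z³ X²Y X²Z Y²Z XY² XZ² YZ² XYZ X² Y²
Z² XY XZ YZ X Y Z 1]. The cubic block absorbs the sensor's nonlinear
response, the constant term absorbs dark current (its fitted coefficient
column is exposed as `dark_current_estimate`), and the degree-2 cross terms
absorb colour-filter inaccuracy and colour shift. XYZ is rescaled from
0–100 to [0,1] before building V: cubic monomials on the 0–100 scale span
six orders of magnitude and wreck the conditioning of the pseudoinverse.
All fit metrics (RMSE) are reported on that [0,1] scale. The pseudoinverse
truncates singular values below 1e-10·σ_max — deterministic across
platforms and loose enough to keep the minimum-norm solution stable when
fewer than 20 independent samples are supplied (a rank warning is raised).

Camera nonlinearity is assessed on the six-step gray ramp (last six
patches) by cubic OLS of spectrometer luminance on camera luminance; R² is
computed from the residual and total sums of squares and lies in [0,1] by
construction of the intercept-bearing fit.

## Spectral reconstruction

The reference spectra are compressed to 12 principal components. For the
**score regression the PCA is uncentred by default** (plain truncated SVD,
zero mean vector). The reason is structural: V_Color = [XYZ XY XZ YZ X Y Z]
contains no constant term. Mean-centred scores are an *affine* function of
the corrected XYZ — the subtracted mean contributes a constant offset — and
a regression without a constant term cannot represent them: on exact
rank-3 training data the centred formulation leaves a mean ΔE00 of ~3,
while the uncentred formulation (S = EV·M·V_Color, with no mean term to
add back) is exact up to quantisation. A `centered=True` switch retains
the mean-centred variant for users who add their own offset handling. Six-
and arbitrary-k-component modes are available; training spectral RMSE is
provably nonincreasing in the component count (tested 1→12).

Reconstructed spectra are clipped at zero (physical nonnegativity) with
the clipped count logged per cube; values above 1 are *not* clipped, so
transmittance >1 remains visible as a calibration-drift flag. Cube
reconstruction deduplicates 24-bit colours by default; the score→spectrum
products use fixed-order summation (einsum) so cached and uncached paths
are bitwise identical.

Whether the score regression should use all 24 patches or hold some out is
an open choice; all 24 are used, matching a bench calibration where the
checker is the only reference available, and the reported training
fidelity is therefore an in-sample figure.

## Fidelity metrics and filter arrays

SAM is arccos of cosine similarity, clamped before arccos; it is
scale-invariant and confined to [0, π/2] for nonnegative spectra. The
filter-array harness measures what a band layout is worth to *this*
pipeline: training spectra are imaged through the candidate bands (linear
integration against band×illuminant, per-band white normalisation,
optional 8-bit quantisation and seeded noise), a PCA basis and score
regression are fitted on the band signals, and held-out test spectra are
reconstructed and scored by SAM against truth. Three-band arrays use the
same 7-term colour polynomial as the XYZ pipeline; for k > 3 bands the
regression is linear in the k signals plus a constant — a degree-2
expansion of 24 bands (≈300 terms) would dwarf any desk-scale training
set. Published per-array figures from specific hardware are not
reproducible here because the test spectra and measured filter
transmittances behind them are not available; the harness instead supports
relative comparisons (e.g. a magenta/blue-weighted 24-band set versus RGB)
on stated spectral families, where SAM magnitudes of order 0.003–0.13 rad
arise. SAM values are reported in radians throughout.

## Synthetic generators

The generators define the test-bench conditions and are bit-reproducible
from (seed, parameters).

**Checker spectra.** Real colour-compensating filters are dye mixtures, so
the generator models each patch as a nonnegative mixture of three broad
dye-like primary bumps — Gaussians at 650/550/455 nm (widths 55/45/45 nm)
normalised to a partition of unity. Six hue families (red, green, blue,
magenta, yellow, cyan) are mixture-weight archetypes with seeded ±15%
weight jitter; the last six patches are equal-weight mixtures, hence
*exactly* wavelength-constant grays with strictly increasing levels
(0.05→0.90), serving as the nonlinearity gradation block. The partition
structure makes the family exactly rank 3, values stay in [0.02, 0.98]
without clipping. This low intrinsic dimension is deliberate and matters:
three camera measurements can only ever determine a three-parameter
spectral family, and the dye-mixture model is the realistic mechanism that
makes checker calibration informative at all. Spectral families of higher
intrinsic dimension contain metamers, and reconstruction error on them is
dominated by the information bottleneck, not by pipeline defects.

**Camera.** Bayer-like Gaussian sensitivities (peaks 610/540/460 nm, SD
30 nm — the measured response of the original sensor being unavailable),
daylight or 3200 K halogen-like illuminant, per-channel white
normalisation (auto white balance) so the perfect reflector hits full
scale, optional extra gains, sRGB gamma encoding, dark offset in 8-bit
counts, additive Gaussian read noise post-gamma (the simplest model
consistent with an ISP output; Poisson shot noise is out of scope), then
clipping and quantisation to 0–255. Defaults for the noisy bench: dark
offset 2 counts, noise 0.5 counts.

**Cell scenes.** Cells are disks (nucleus inside cytoplasm) painted with
class/compartment transmittance templates constructed to satisfy the
observed orderings — the malignant nucleus lies strictly below the normal
nucleus across 520–600 nm, and within each class the nucleus lies below
its cytoplasm across 450–550 nm — plus one smooth seeded perturbation per
cell (SD 0.01 in amplitude). Scenes default to 8 cells per class (24
cells), each annotated with a nucleus-centred 10×10 ROI. The renderer
emits the ground-truth cube alongside the camera image, so cytology code
paths can be tested against truth and against reconstruction separately.
What these scenes do **not** model: cell overlap and clumping, optical
blur and depth of field, staining batch variation, debris/background
texture. Passing tests therefore demonstrate correctness of the spectral
feature machinery, not clinical performance on real slides.

**Low-rank reflectance fixture.** For PCA-compaction measurements: 24
nonnegative mixtures (weights uniform on [0,1]) of five Gaussian basis
curves (centers 420–660 nm, SD 40 nm) peaking at 0.35, plus additive noise
of SD 1e-4, clipped to [0,1]. The 0.35 amplitude keeps mixtures below 1 so
the clip never truncates the rank-5 structure; with it the first six
principal components carry >99.999% of the variance, as the acceptance
script verifies.

## Problem sizes and runtime

All fixtures run at bench scale by design: 24 calibration patches, 24
cells, images up to ~100×100 pixels, ten noise replicates for averaged
fidelity figures. The full test suite completes in a few seconds on one
CPU; the acceptance script in under a minute.

## Known limitations

- The analytic observer and synthetic daylight bound absolute colorimetric
  accuracy (~1%); swap in measured CSV tables for instrument-grade work.
- Reconstruction fidelity on spectral families with intrinsic dimension
  greater than ~3 is limited by the tristimulus bottleneck, not by the
  regression; the reported ΔE figures apply to checker-like (dye-mixture)
  scenes.
- The correction model is per-session: no transfer across illuminants or
  cameras is attempted.
- The nearest-centroid assignment is a convenience for sanity checks, not
  a validated classifier; score-space separation is reported descriptively
  (centroids + silhouette index) without inferential statistics.
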