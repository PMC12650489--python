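# Data provenance

Both tables are generated by `scripts/build_tables.py` from published
closed forms and can be rebuilt bit-identically.

## cmf_cie1931_2deg.csv

CIE 1931 2° standard-observer colour matching functions x̄, ȳ, z̄ on the
380–780 nm, 1 nm grid, computed from the multi-lobe piecewise-Gaussian
analytic fit of Wyman, Sloan & Shirley, *Simple Analytic Approximations to
the CIE XYZ Color Matching Functions*, Journal of Computer Graphics
Techniques 2(2), 2013. The fit agrees with the measured observer to within
about 1% of peak per function; values are clipped at 0 where the x̄ fit
dips marginally negative. The pipeline is self-consistent in this
observer: reference XYZ, camera simulation and reconstruction metrics all
use the same table.

## illuminant_d65_synthetic.csv

A **synthetic** smooth daylight-like illuminant (not the CIE D65 SPD
table): a 6504 K Planckian radiator plus a small correction in the span of
the observer curves, solved so that the white point of the perfect
reflector under this table's observer is exactly (95.047, 100, 108.883) —
the D65 chromaticity. Normalised to 1 at 560 nm. It stands in for a
measured lamp spectrum wherever a daylight-like source is needed; any
measured source spectrum on the same grid can be supplied instead.
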