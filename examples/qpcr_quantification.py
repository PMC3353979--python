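"""qPCR copy-number quantification via a standard curve.

A dilution series of known template amounts calibrates Ct against
log10(copies); the slope gives the amplification efficiency
E = 10^(-1/slope) - 1, and unknown extracts are read off the inverted curve.
"""

from paleosweep import SyntheticSpec, fit_standard_curve, quantify_extract
from paleosweep.synthetic_data import gen_dilution_series

# the high-concentration design: 1.4e4 / 1.4e5 / 1.4e6 copies/ul, 4 replicates
spec = SyntheticSpec(seed=5, qpcr_efficiency=1.02, qpcr_ct_sd=0.1)
series = gen_dilution_series(spec)
curve = fit_standard_curve(series)

print(f"dilution points: {[float(c) for c in sorted(series['copies_per_ul'].unique())]}")
print(f"slope     : {curve.slope:8.4f} Ct per log10(copies)")
print(f"efficiency: {curve.efficiency * 100:8.1f}%  (true: 102%)")
print(f"r^2       : {curve.r_squared:8.4f}")

for ct in (28.0, 33.0):
    print(f"unknown extract at Ct {ct:.1f}: "
          f"{quantify_extract(ct, curve):,.0f} copies/ul")
print()
print("Reading: efficiency near 100% with r^2 ~ 0.99 matches a well-behaved"
      "\nassay; extracts quantified this way decide whether enough template"
      "\nsurvives for credible genotyping.")
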