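"""Contamination screening and replicate concordance.

Because rs497116 is monomorphic in Europeans, mitochondrial HVR-I haplotypes
individualize each sample and everyone who handled it; any sample whose
haplotype matches an investigator's is flagged.  Independently, a genotype
is only authenticated when two independent assays agree.
"""

from paleosweep import SyntheticSpec, contamination_screen, genotype_concordance
from paleosweep.synthetic_data import gen_haplotype_survey

# a survey with contamination deliberately planted in 15% of samples
spec = SyntheticSpec(seed=11, contamination_rate=0.15)
samples, researchers, truth = gen_haplotype_survey(spec, researcher_pool_size=8,
                                                   n_samples=40)
report = contamination_screen(samples, researchers)
print(f"samples screened: {len(samples)}, researchers: {len(researchers)}")
print(f"planted contaminations: {len(truth)}, flagged: {len(report.matches)}")
print(f"flags match planted truth exactly: {sorted(report.matches) == sorted(truth)}")
print(f"screen verdict: {'PASS' if report.passed else 'CONTAMINATION DETECTED'}")

print()
for calls in (["TT", "TT"], ["TT", "missing"], ["CT", "TT"]):
    res = genotype_concordance(calls)
    print(f"calls {calls!r:24s} -> {res.status}"
          + (f" ({res.genotype})" if res.genotype else ""))
print()
print("Reading: exact-haplotype matching recovers every planted contaminant"
      "\nand nothing else; the concordance rule accepts a genotype only on"
      "\nindependent agreement, the standard aDNA authentication criterion.")
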