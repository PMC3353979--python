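"""Can neutral drift explain near-fixation of the T allele in Europe?

Forward Wright-Fisher replicates on the scaled Out-of-Africa model: a single
derived copy arises early in Africa; replicates are kept only if the
present-day African frequency lands in the hunter-gatherer range [0.3, 0.5];
among those, we ask how often Europe ends at >= 0.95.

(Small replicate numbers here for a quick demonstration; the analysis-scale
run uses >= 2,000 accepted replicates — see scripts/acceptance.py.)
"""

from paleosweep import (
    NEUTRAL_SCHEME,
    estimate_conditional_probability,
    expected_frequency_at_time,
    load_packaged_model,
    run_conditional_experiment,
)
from paleosweep.wf_engine import compile_model

cm = compile_model(load_packaged_model())
reps = run_conditional_experiment(
    cm, NEUTRAL_SCHEME, n_accepted_target=300, seed=42, batch_size=50_000
)
est = estimate_conditional_probability(cm, NEUTRAL_SCHEME, replicates=reps)
e7k = expected_frequency_at_time(cm, NEUTRAL_SCHEME, replicates=reps)

print(f"raw replicates run:        {est.n_raw:,}")
print(f"accepted (AFR in 0.3-0.5): {est.n_accepted}")
print(f"P(EUR >= 0.95 | accepted): {est.p_hat:.4f}  "
      f"95% CI [{est.ci95[0]:.4f}, {est.ci95[1]:.4f}]")
print(f"mean EUR frequency ~7,000 years BP: {e7k['mean']:.3f}  "
      f"95% CI [{e7k['ci95'][0]:.3f}, {e7k['ci95'][1]:.3f}]")
print()
print("Reading: the conditional probability is a few percent (< 0.05), so a"
      "\npurely neutral history is rejected; yet Europe already held ~0.4 at"
      "\nthe dawn of its Neolithic, which is where the two-step scenario"
      "\n(selection on standing variation) starts.")
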