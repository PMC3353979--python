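# Methods

## The question and the estimators

The package quantifies three lines of computational evidence about the
derived (inactive) T allele at *CASP12* rs497116:

1. how fast deterministic selection can move its frequency,
2. how probable its near-fixation in Europe is under explicit demographic
   histories, conditional on what Africa looks like today, and
3. what an all-T sample of prehistoric individuals implies about its
   frequency at their time.

Around these sit the ancient-DNA authentication computations that make the
genotype data credible, and seeded generators that stand in for the
(undeposited) specimens.

## Deterministic selection dynamics

A single biallelic locus under constant viability selection in an
effectively infinite population follows

p′ = p(p·w_AA + q·w_Aa)/w̄, w̄ = p²·w_AA + 2pq·w_Aa + q²·w_aa.

Three viability parameterizations are first-class, because the sweep-time
conclusions depend on them:

| tag | w_AA | w_Aa | w_aa | per-copy advantage (small s) |
|---|---|---|---|---|
| `viability` | 1 | 1 − hs | 1 − s | ≈ hs→(1−h)s, frequency-dependent |
| `additive` | 1 | 1 − s/2 | 1 − s | s/2 |
| `genic` | 1 | 1/(1+s) | 1/(1+s)² | s |

`generations_to_reach` uses closed comparison (first generation with
p ≥ target) since the recursion never hits interior targets exactly;
the convergence guard defaults to 10,000 generations and a "not reached"
result is an explicit `None`, not an error.

**A documented tension.** With s = 0.01 and h = 0.11 the viability
recursion takes 457 generations for 0.4 → 0.8 and ~2,550 for 0.4 → 0.99 —
not the ~200 and <250 generations originally claimed for these transitions.
The genic scheme gives 181 and 503. The implementation reproduces the
recursion faithfully and reports all parameterizations side by side; the
analysis report flags the discrepancy rather than forcing the published
figures. The additive case is verified against its closed form
t = (2/s)·ln(p₂q₁/p₁q₂) to within 5%.

## The scaled demographic model

The packaged model is a three-population Out-of-Africa history rescaled to
an ancestral diploid size N₀ = 500, which preserves the compound parameters
(2Ns, per-generation migration fractions after rescaling, t/2N) while
making forward simulation cheap. Times are in units of 2N₀ generations from
simulation start; t_end = 0.607 (607 generations). The event list: Africa
0.1× at t = 0, 10× at 0.004, 1.68202× at 0.005 (→ 841); Europe splits off
at 0.211074 with a 0.170737565× bottleneck (→ 144); Asia splits from
Europe at 0.534772 (0.724763218× and 0.162342748× bottlenecks, exponential
growth at rates 33.98 and 62.27 per unit scaled time); African migration
shuts off at 0.54805.

**Migration convention.** The model's printed migration values decode as
M = 2·N_recipient(t)·m with a *symmetric* per-generation fraction m — e.g.
6.133603671/(2×841.01) = 1.047236559/(2×143.59) = 3.6465×10⁻³ in the first
epoch, and the 0.534772 epoch collapses the same way to three symmetric
rates. This `2N_recipient` convention is the package default; `4Nm`
(fixed-N₀ scaling) and `fraction` (direct per-generation fractions) are
selectable in the model YAML for sensitivity work. The choice matters: the
fixed-N₀ reading weakens Africa↔Europe coupling ~7-fold and inflates the
neutral conditional probability from ~0.03 to ~0.16.

κ = 14.62 (the real:scaled size ratio) and the 25-year generation time are
presentation-only: they convert scaled times to years (the out-of-Africa
split lands near 145 ka) and never enter the dynamics. The European
frequency is additionally recorded at t_end − 0.0175, the model's
~7,000-years-BP time point.

## The Wright–Fisher engine

Each generation applies, in a fixed order: (1) deterministic migration
mixing of population frequencies (infinite migrant-pool expectation),
(2) the selection recursion, (3) one binomial draw of next-generation
allele counts at next-generation sizes. Splits copy the parent's
post-selection frequency into the daughter, whose founding counts are drawn
binomially at the founding (bottleneck) size — founder sampling is part of
the bottleneck. The locus starts monomorphic; a single derived copy is
injected at a uniform scaled time in [0.001, 0.003] (while Africa holds 50
individuals, so the entering frequency is 1/100).

The batched runner vectorizes replicates per generation and retires
globally-lost and globally-fixed replicates every 16 generations, which
keeps cost dominated by the short pre-absorption phase. Validation against
diffusion theory (both at 10⁵ replicates, constant N = 500): neutral
new-mutant fixation 1.07×10⁻³ vs 1/(2N) = 10⁻³; genic s = 0.01 fixation
0.0200 vs (1−e^(−2s))/(1−e^(−4Ns)) = 0.0198; both inside 99% intervals.
The neutral one-generation martingale E[p′|p] = p holds within 3 SE.

## Conditional experiments

Rejection sampling: replicates run to t_end; those whose final African
frequency falls in [0.3, 0.5] are accepted (lost replicates count as raw
failures); batches continue until the accepted target is met
(default 2,000, binomial CI half-width ≈ 0.006 at p ≈ 0.02–0.03; the
acceptance script uses 6,000). Acceptance and success are evaluated on
population frequencies by default; a sampled-frequency variant (binomial
draws of 100 chromosomes, matching the original survey design) is
available. The ~7,000-years-BP mean is taken over accepted replicates, with
the unconditional mean over all surviving replicates reported alongside.

At analysis scale the estimates are: neutral P(EUR ≥ 0.95 | window)
≈ 0.031 ± 0.001, selected (additive s = 0.01 from origin) ≈ 0.019 ± 0.001,
mean European frequency at ~7 ka ≈ 0.37. Both probabilities sit well below
the 0.05 rejection line — the operative inference — and within ~0.01 of the
originally reported 0.021/0.024, a residual consistent with the remaining
interpretation freedom in the original tooling (selection flag semantics,
sampled vs population frequencies) and its unreported Monte-Carlo error.
The "additive s = 0.01" selected scenario maps to the h = ½ viability
scheme; the genic and dominant readings were measured too and move the
estimate by ≲ 0.007.

The two-step scenario needs no simulator: it hands the ~0.4 standing
frequency to the deterministic recursion under the assumption that
post-Neolithic European sizes make drift negligible.

## The monomorphic-sample bound

For k independent copies all showing one allele, the exact one-sided lower
bound at level α solves p^k = α (the all-successes Clopper–Pearson corner),
so p_min = α^(1/k). k defaults to the number of *individuals* (one
confirmed copy each) — conservative against allelic dropout, which can make
a heterozygote look homozygous; the chromosome-counting variant (k = 2n) is
exposed. k = 17, α = 0.05 gives 0.8384 (reported as "0.83", a truncation);
k = 34 gives 0.9157.

## Ancient-DNA authentication

*Damage profiling* deduplicates clone sequences within a sample ("unique
clones"), aligns each to the consensus (direct base comparison at equal
length; otherwise end-anchored global alignment scoring substitutions above
gap pairs), and tallies events as A>G, G>A, C>T, T>C, single-base insA/insG,
or other. Clones matching the consensus at fewer than half their bases are
excluded with a warning. Per-sample totals divide by all samples profiled
(the mean over damaged-only samples is reported alongside). *Contamination
screening* flags exact variant-set identity between sample and investigator
HVR-I haplotypes (positions 15,998–16,400); haplotype sharing among samples
is a note, not a flag. *Concordance* authenticates a genotype only when ≥ 2
non-missing independent calls agree. *qPCR*: ordinary least squares of Ct
on log₁₀(copies); efficiency E = 10^(−1/slope) − 1; quantification inverts
the fitted curve.

## Synthetic data: what it does and does not emulate

Generators draw from the printed study conditions: the six-site layout of
the 24 genotyped individuals; per-type damage rates per sample
(mtDNA ~100 bp: A>G 1.8, G>A 2.2, insA 1.5, insG 0.04, C>T 0.2, T>C 0.08;
CASP12 ~80 bp: A>G 1.2, G>A 0.6), allocated to 10 clones/sample as Poisson
counts with mean rate/10 (the study reports only means; Poisson is the
maximum-entropy choice, and a deterministic-count mode exists for exact
tests); per-allele, per-assay dropout (default 0.1, a mid-range value for
degraded teeth); investigator contamination as whole-haplotype replacement
at a configurable rate (default 0 — none was found); dilution series from
Ct = intercept − log₁₀(copies)/log₁₀(1+E) + N(0, sd).

Consensus fragments are random-composition synthetic sequences — the true
amplicon sequences are not reproduced and composition only affects event
eligibility. Deduplication can merge identically-damaged clones, giving the
profiler a small (≈1–2%) downward bias at the study rates; recovery tests
use a 3-SE band that absorbs it. Not emulated: position-dependent
deamination (damage concentrates at fragment ends in real aDNA), realistic
HVR-I phylogenetic structure, assay-level PCR artifacts. Passing recovery
tests therefore demonstrates the estimators' correctness on data satisfying
their own assumptions, not robustness to every real-world failure mode.

## Numerical and design choices

- All randomness flows from one master seed through `numpy` `SeedSequence`
  spawning (per-batch child streams; named streams per generator); every
  result object carries its seed, and reports carry a config hash.
- Frequencies are clipped to [0, 1] after migration+selection before the
  binomial draw; counts are integer throughout; sizes are rounded to ≥ 2.
- Generation indices discretize scaled times by half-up rounding; a
  daughter population inherits its parent's size *before* same-time events
  (split first, then bottleneck multipliers, growth, migration).
- Ties in the clone-majority check fail (a site is authenticated only by a
  strict majority).
- Problem sizes used by the shipped runs — 2,000–6,000 accepted replicates,
  10⁵-replicate fixation checks, 200–400 synthetic clone-set samples —
  were chosen so that Monte-Carlo error is small against each quantity's
  decision threshold while a full run stays in the minutes range on a
  laptop core.

## Known limitations

- Single locus, no recombination or background mutation (θ = 0 in the
  source model); selection from standing variation is handled only via the
  deterministic two-step construction, mirroring the original analysis.
- The demographic model is a point estimate; no parameter uncertainty is
  propagated into the conditional probabilities.
- The frequency bound treats individuals as unrelated; kinship within a
  burial site would reduce the effective k.
- The damage profiler's alignment tolerates isolated short indels, not
  heavily degenerate clones (those are excluded, with a record).
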