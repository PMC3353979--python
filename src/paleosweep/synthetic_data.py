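"""Seeded generators for every tabular/sequence input the analysis consumes.

These stand in for prehistoric specimens: no sequencing data is deposited
for the original samples, so each downstream computation is exercised on
synthetic inputs whose *generating parameters are the printed study
conditions* — the excavation-site layout of the 24 genotyped individuals,
the per-type post-mortem damage rates recovered from cloned PCR products,
the qPCR dilution-series design, and mitochondrial haplotype surveys with
(optionally) planted investigator contamination.  Every generator is
deterministic under a fixed seed.

Damage-event counts per clone are Poisson with mean rate/n_clones (the study
reports only per-sample means; Poisson is the maximum-entropy count model
and makes per-sample totals Poisson at the per-type rate).  A
``deterministic`` count model that plants exactly ``round(rate)`` events per
sample is available for exact-count tests.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adna_qc import HVR1_END, HVR1_START, CloneSet, Haplotype
from .sample_stats import AncientGenotypeTable

__all__ = [
    "SyntheticSpec",
    "TABLE1_LAYOUT",
    "CASP12_DAMAGE_RATES",
    "MTDNA_DAMAGE_RATES",
    "gen_genotype_table",
    "gen_clone_sets",
    "gen_haplotype_survey",
    "gen_dilution_series",
]

#: site layout of the 24 genotyped individuals (site, period, c14 date, N)
TABLE1_LAYOUT = (
    ("La Pasiega (Cantabria)", "Magdalenian", None, 1),
    ("La Chora (Cantabria)", "Magdalenian", None, 1),
    ("Erralla (Gipuzkoa)", "Magdalenian", 12319, 1),
    ("Marizulo (Gipuzkoa)", "Neolithic", 5285, 1),
    ("SJAPL (Araba)", "Late-Neolithic", 5070, 17),
    ("Longar (Navarre)", "Neolithic-Calcolithic", 4445, 3),
)

#: mean damage events per sample in unique clones, by type
CASP12_DAMAGE_RATES = {"A>G": 1.2, "G>A": 0.6}
MTDNA_DAMAGE_RATES = {
    "A>G": 1.8, "G>A": 2.2, "insA": 1.5, "insG": 0.04, "C>T": 0.2, "T>C": 0.08,
}

#: cloned-fragment lengths (bp): the 91-bp CASP12 amplicon trims to ~80 bp
#: of clonable sequence; HVR-I fragments are ~100 bp
FRAGMENT_LENGTHS = {"casp12": 80, "mtdna_hvr1": 100}


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study; defaults are the printed conditions."""

    seed: int = 0
    n_samples: int = 24
    site_layout: tuple = TABLE1_LAYOUT
    genotype_distribution: dict = field(
        default_factory=lambda: {"CC": 0.0, "CT": 0.0, "TT": 1.0}
    )
    dropout_rate: float = 0.1
    n_assays: int = 2
    damage_rates: dict = field(
        default_factory=lambda: {
            "casp12": dict(CASP12_DAMAGE_RATES),
            "mtdna_hvr1": dict(MTDNA_DAMAGE_RATES),
        }
    )
    clones_per_sample: int = 10
    fragment_lengths: dict = field(default_factory=lambda: dict(FRAGMENT_LENGTHS))
    damage_count_model: str = "poisson"  # or "deterministic"
    contamination_rate: float = 0.0
    qpcr_efficiency: float = 1.02
    qpcr_intercept: float = 40.0
    qpcr_ct_sd: float = 0.1
    qpcr_points: tuple = (1.4e4, 1.4e5, 1.4e6)
    qpcr_replicates: int = 4

    def __post_init__(self) -> None:
        probs = self.genotype_distribution
        if abs(sum(probs.values()) - 1.0) > 1e-9 or min(probs.values()) < 0:
            raise SpecError(f"genotype distribution {probs} is not a distribution")
        for r in (self.dropout_rate, self.contamination_rate):
            if not (0.0 <= r <= 1.0):
                raise SpecError(f"probability {r} outside [0, 1]")
        for locus, rates in self.damage_rates.items():
            if any(v < 0 for v in rates.values()):
                raise SpecError(f"negative damage rate for locus {locus!r}")
        if self.damage_count_model not in ("poisson", "deterministic"):
            raise SpecError(f"unknown count model {self.damage_count_model!r}")
        if self.n_samples < 1 or self.clones_per_sample < 1:
            raise SpecError("n_samples and clones_per_sample must be >= 1")

    def rng(self, *stream) -> np.random.Generator:
        """A child generator for a named stream, derived from the seed."""
        key = [self.seed] + [zlib.crc32(str(s).encode()) for s in stream]
        return np.random.default_rng(np.random.SeedSequence(key))


# ---------------------------------------------------------------------------
# genotype tables


def _sample_layout(spec: SyntheticSpec) -> list[tuple[str, str, object]]:
    rows = []
    for site, period, c14, n in spec.site_layout:
        rows.extend((site, period, c14) for _ in range(n))
    if len(rows) != spec.n_samples:
        # layout mirrors Table 1 by default; a custom n_samples needs a
        # matching custom layout
        raise SpecError(
            f"site layout holds {len(rows)} samples but n_samples={spec.n_samples}"
        )
    return rows


def gen_genotype_table(spec: SyntheticSpec) -> AncientGenotypeTable:
    """Draw true genotypes, then per-assay calls with per-allele dropout.

    Each assay observes each of the two allele copies independently with
    probability ``1 - dropout_rate``; a heterozygote with one dropped allele
    is miscalled homozygous, and a call with both copies dropped is missing.
    The consensus genotype is the first authenticated-style call (two assays
    agreeing), else the first non-missing call, else missing.
    """
    rng = spec.rng("genotypes")
    layout = _sample_layout(spec)
    genos = list(spec.genotype_distribution)
    probs = np.array([spec.genotype_distribution[g] for g in genos])
    rows = []
    site_counter: dict[str, int] = {}
    for site, period, c14 in layout:
        site_counter[site] = site_counter.get(site, 0) + 1
        short = site.split(" (")[0].replace(" ", "")
        sample_id = f"{short}_{site_counter[site]:02d}"
        true_geno = genos[rng.choice(len(genos), p=probs)]
        calls = [_assay_call(true_geno, spec.dropout_rate, rng)
                 for _ in range(spec.n_assays)]
        called = [c for c in calls if c != "missing"]
        consensus = called[0] if called else "missing"
        for c in called[1:]:
            if c != consensus:  # discordant assays: leave the call missing
                consensus = "missing"
                break
        rows.append(
            dict(sample=sample_id, site=site, period=period,
                 c14_bp=c14, genotype=consensus, replicates=",".join(calls))
        )
    return AncientGenotypeTable(pd.DataFrame(rows))


def _assay_call(genotype: str, dropout: float, rng: np.random.Generator) -> str:
    seen = [a for a in genotype if rng.random() >= dropout]
    if not seen:
        return "missing"
    alleles = sorted(set(seen))
    if len(alleles) == 1:
        return alleles[0] * 2
    return "".join(alleles)


# ---------------------------------------------------------------------------
# clone sets with planted damage


_SUB_TYPES = {"A>G": ("A", "G"), "G>A": ("G", "A"), "C>T": ("C", "T"), "T>C": ("T", "C")}
_INS_TYPES = {"insA": "A", "insG": "G"}


def _random_fragment(length: int, rng: np.random.Generator) -> str:
    # roughly uniform composition guarantees eligible bases for every type
    return "".join(rng.choice(list("ACGT"), size=length))


def gen_clone_sets(spec: SyntheticSpec, locus: str = "mtdna_hvr1",
                   n_samples: int | None = None) -> list[CloneSet]:
    """Per sample: a consensus fragment and clones carrying damage events.

    Event counts per clone and type are Poisson with mean rate/n_clones, so
    per-sample totals have mean equal to the per-type rate; positions are
    uniform over eligible bases (insertions: uniform over gaps).
    """
    if locus not in spec.damage_rates:
        raise SpecError(f"no damage rates configured for locus {locus!r}")
    rates = spec.damage_rates[locus]
    unknown = set(rates) - set(_SUB_TYPES) - set(_INS_TYPES)
    if unknown:
        raise SpecError(f"unsupported damage type(s) {sorted(unknown)}")
    rng = spec.rng("clones", locus)
    n_samples = spec.n_samples if n_samples is None else n_samples
    length = spec.fragment_lengths[locus]
    out = []
    for i in range(n_samples):
        consensus = _random_fragment(length, rng)
        for t, rate in rates.items():
            if rate > 0 and t in _SUB_TYPES:
                src = _SUB_TYPES[t][0]
                if src not in consensus:
                    raise SpecError(
                        f"rate for {t} > 0 but fragment has no {src} base"
                    )
        clones = [
            _damaged_clone(consensus, rates, spec, rng)
            for _ in range(spec.clones_per_sample)
        ]
        out.append(CloneSet(f"synth_{i:04d}", consensus, clones, locus=locus))
    return out


def _damaged_clone(consensus: str, rates: dict, spec: SyntheticSpec,
                   rng: np.random.Generator) -> str:
    seq = list(consensus)
    deterministic = spec.damage_count_model == "deterministic"
    insertions = []
    for t, rate in rates.items():
        per_clone = rate / spec.clones_per_sample
        k = int(round(per_clone)) if deterministic else rng.poisson(per_clone)
        if k == 0:
            continue
        if t in _SUB_TYPES:
            src, dst = _SUB_TYPES[t]
            eligible = [i for i, b in enumerate(seq) if b == src]
            for i in rng.choice(eligible, size=min(k, len(eligible)), replace=False):
                seq[i] = dst
        else:
            base = _INS_TYPES[t]
            insertions.extend(
                (int(pos), base) for pos in rng.integers(0, len(seq) + 1, size=k)
            )
    for pos, base in sorted(insertions, reverse=True):
        seq.insert(pos, base)
    return "".join(seq)


# ---------------------------------------------------------------------------
# haplotype surveys


def gen_haplotype_survey(
    spec: SyntheticSpec, researcher_pool_size: int = 8, n_samples: int | None = None
) -> tuple[list[Haplotype], list[Haplotype], list[tuple[str, str]]]:
    """Distinct researcher haplotypes, sample haplotypes from a diverse pool,
    and the planted-contamination truth list (sample id, researcher id)."""
    rng = spec.rng("haplotypes")
    n_samples = spec.n_samples if n_samples is None else n_samples
    n_needed = researcher_pool_size + n_samples
    positions = np.arange(HVR1_START, HVR1_END + 1)
    if n_needed > 4000:
        raise SpecError("haplotype pool too small for requested distinctness")
    ref_base = {
        int(p): "ACGT"[rng.integers(4)] for p in positions
    }
    pool: list[frozenset] = []
    seen = set()
    while len(pool) < n_needed:
        k = int(rng.integers(2, 7))
        pos = rng.choice(positions, size=k, replace=False)
        variants = frozenset(
            (int(p), ref_base[int(p)],
             rng.choice([b for b in "ACGT" if b != ref_base[int(p)]]))
            for p in pos
        )
        if variants not in seen:
            seen.add(variants)
            pool.append(variants)
    researchers = [
        Haplotype(f"researcher_{i:02d}", pool[i]) for i in range(researcher_pool_size)
    ]
    samples = []
    truth = []
    for j in range(n_samples):
        sid = f"sample_{j:03d}"
        if rng.random() < spec.contamination_rate:
            r = researchers[rng.integers(len(researchers))]
            samples.append(Haplotype(sid, r.variants))
            truth.append((sid, r.id))
        else:
            samples.append(Haplotype(sid, pool[researcher_pool_size + j]))
    return samples, researchers, truth


# ---------------------------------------------------------------------------
# qPCR dilution series


def gen_dilution_series(spec: SyntheticSpec) -> pd.DataFrame:
    """A dilution series (copies_per_ul, ct, replicate) at a set true
    efficiency: Ct = intercept − log10(copies)/log10(1+E) + N(0, sd)."""
    if spec.qpcr_efficiency <= 0:
        raise SpecError("amplification efficiency must be > 0")
    if any(c <= 0 for c in spec.qpcr_points):
        raise SpecError("copy numbers must be positive")
    rng = spec.rng("qpcr")
    slope = -1.0 / np.log10(1.0 + spec.qpcr_efficiency)
    rows = []
    for copies in spec.qpcr_points:
        for rep in range(1, spec.qpcr_replicates + 1):
            ct = spec.qpcr_intercept + slope * np.log10(copies)
            if spec.qpcr_ct_sd > 0:
                ct += rng.normal(0.0, spec.qpcr_ct_sd)
            rows.append(dict(copies_per_ul=copies, ct=round(float(ct), 6),
                             replicate=rep))
    return pd.DataFrame(rows)


def dilution_series_csv(spec: SyntheticSpec) -> str:
    """CSV text of :func:`gen_dilution_series` (byte-stable under a seed)."""
    df = gen_dilution_series(spec)
    return df.to_csv(index=False, float_format="%.6f")
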