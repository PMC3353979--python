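"""Ancient-DNA authentication computations.

Four independent lines of evidence are quantified, mirroring standard aDNA
practice on cloned PCR products, mitochondrial haplotypes and qPCR assays:

* **damage profiling** — clones of a PCR product are compared against the
  directly-sequenced consensus; substitutions and single-base insertions in
  *unique* (deduplicated) clone sequences are tallied by type.  Moderate
  counts dominated by A→G / G→A (and C→T/T→C deamination-driven classes)
  indicate post-mortem template damage rather than exogenous contamination.
* **contamination screening** — each sample's HVR-I variant set is compared
  for identity against the haplotypes of everyone who handled the material.
* **replicate concordance** — per-sample genotype calls from independent
  extractions/laboratories are authenticated only if at least two
  non-missing calls agree.
* **qPCR quantitation** — a standard curve Ct = a·log10(copies) + b fit by
  least squares; amplification efficiency E = 10^(−1/slope) − 1; unknown
  extracts are quantified by inverting the curve.

Clone sets are read and written as FASTA with the consensus record first
(ids ``<sample>|consensus`` and ``<sample>|clone<N>``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

__all__ = [
    "Haplotype",
    "CloneSet",
    "DamageProfile",
    "StandardCurve",
    "DAMAGE_TYPES",
    "damage_profile",
    "contamination_screen",
    "genotype_concordance",
    "clone_majority_check",
    "fit_standard_curve",
    "quantify_extract",
    "read_clone_sets",
    "write_clone_sets",
]

HVR1_START, HVR1_END = 15_998, 16_400

DAMAGE_TYPES = ("A>G", "G>A", "C>T", "T>C", "insA", "insG", "other")


# ---------------------------------------------------------------------------
# haplotypes and contamination


@dataclass(frozen=True)
class Haplotype:
    """An HVR-I haplotype as a set of variants against the reference."""

    id: str
    variants: frozenset  # of (position, ref_base, observed)

    def __post_init__(self) -> None:
        seen = set()
        for pos, ref, alt in sorted(self.variants):
            if not (HVR1_START <= pos <= HVR1_END):
                raise ValueError(
                    f"{self.id}: position {pos} outside HVR-I "
                    f"[{HVR1_START}, {HVR1_END}]"
                )
            if pos in seen:
                raise ValueError(f"{self.id}: duplicate variant position {pos}")
            if not ref or not alt:
                raise ValueError(f"{self.id}: malformed variant {(pos, ref, alt)}")
            seen.add(pos)


@dataclass
class ContaminationReport:
    matches: list          # (sample_id, researcher_id) identical haplotypes
    shared_sample_haplotypes: list  # (sample_id, sample_id) notes, not flags

    @property
    def passed(self) -> bool:
        return not self.matches


def contamination_screen(
    sample_haplotypes: list[Haplotype], researcher_haplotypes: list[Haplotype]
) -> ContaminationReport:
    """Flag every sample whose variant set is identical to an investigator's.

    Haplotype sharing *among samples* is reported as a note only; it is
    expected in a population sample and does not indicate contamination.
    """
    matches = [
        (s.id, r.id)
        for s in sample_haplotypes
        for r in researcher_haplotypes
        if s.variants == r.variants
    ]
    shared = []
    for i, a in enumerate(sample_haplotypes):
        for b in sample_haplotypes[i + 1 :]:
            if a.variants == b.variants:
                shared.append((a.id, b.id))
    return ContaminationReport(matches=matches, shared_sample_haplotypes=shared)


# ---------------------------------------------------------------------------
# clone sets and damage profiling


@dataclass
class CloneSet:
    """Consensus (direct PCR product) sequence plus its cloned sequences."""

    sample_id: str
    consensus: str
    clones: list[str]
    locus: str = "mtdna_hvr1"

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        self.clones = [c.upper() for c in self.clones]
        if not self.consensus:
            raise ValueError(f"{self.sample_id}: empty consensus")
        if not self.clones:
            raise ValueError(f"{self.sample_id}: clone set without clones")
        if len(self.clones) < 10:
            warnings.warn(
                f"{self.sample_id}: only {len(self.clones)} clones "
                "(protocol expects >= 10)",
                stacklevel=2,
            )

    @property
    def unique_clones(self) -> list[str]:
        """Deduplicated clone sequences, first occurrence order."""
        return list(dict.fromkeys(self.clones))


def _aligner() -> PairwiseAligner:
    # substitutions preferred over gap pairs; single short indels tolerated
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = -1.0
    a.open_gap_score = -3.0
    a.extend_gap_score = -2.0
    return a


def _classify_events(consensus: str, clone: str) -> dict[str, int] | None:
    """Damage events in one clone relative to the consensus, by type.

    Returns ``None`` when the clone cannot be sensibly aligned (less than
    half of its bases match the consensus).
    """
    counts = dict.fromkeys(DAMAGE_TYPES, 0)
    if clone == consensus:
        return counts
    if len(clone) == len(consensus):
        pairs = zip(consensus, clone)
        aligned = list(pairs)
    else:
        aln = _aligner().align(consensus, clone)[0]
        a, b = str(aln[0]), str(aln[1])
        aligned = list(zip(a, b))
    n_match = sum(1 for c, d in aligned if c == d and c != "-")
    if n_match < 0.5 * len(clone):
        return None
    for c_base, k_base in aligned:
        if c_base == k_base:
            continue
        if c_base == "-":  # base present in clone only: insertion
            key = {"A": "insA", "G": "insG"}.get(k_base, "other")
        elif k_base == "-":  # deletion
            key = "other"
        else:
            key = f"{c_base}>{k_base}"
            if key not in counts:
                key = "other"
        counts[key] += 1
    return counts


@dataclass
class DamageProfile:
    """Per-substitution-type damage means across samples."""

    per_type_means: dict
    per_sample_totals: list
    n_samples: int
    mean_total: float
    mean_total_damaged_only: float | None
    excluded_clones: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(sum(self.per_type_means.values()) - self.mean_total) > 1e-9:
            raise ValueError("per-type means must sum to the total mean")


def damage_profile(clonesets: list[CloneSet]) -> DamageProfile:
    """Tally damage events by type in unique clones, per sample, then average.

    Means divide by *all* samples profiled; the mean over only samples that
    show at least one event is reported alongside.  Unalignable clones are
    excluded with a warning and listed in ``excluded_clones``.
    """
    if not clonesets:
        raise ValueError("at least one clone set is required")
    type_totals = dict.fromkeys(DAMAGE_TYPES, 0)
    sample_totals = []
    excluded = []
    for cs in clonesets:
        total = 0
        for i, clone in enumerate(cs.unique_clones):
            counts = _classify_events(cs.consensus, clone)
            if counts is None:
                excluded.append((cs.sample_id, i))
                warnings.warn(
                    f"{cs.sample_id}: clone {i} unalignable to consensus; excluded",
                    stacklevel=2,
                )
                continue
            for k, v in counts.items():
                type_totals[k] += v
            total += sum(counts.values())
        sample_totals.append(total)
    n = len(clonesets)
    damaged = [t for t in sample_totals if t > 0]
    return DamageProfile(
        per_type_means={k: v / n for k, v in type_totals.items()},
        per_sample_totals=sample_totals,
        n_samples=n,
        mean_total=sum(type_totals.values()) / n,
        mean_total_damaged_only=(sum(damaged) / len(damaged)) if damaged else None,
        excluded_clones=excluded,
    )


@dataclass(frozen=True)
class MajorityCheck:
    passed: bool
    majority_fraction: float
    consensus_base: str
    tie: bool = False


def clone_majority_check(cloneset: CloneSet, site_position: int) -> MajorityCheck:
    """Does a strict majority of clones carry the consensus base at a site?

    ``site_position`` is a 0-based index into the consensus sequence; clone
    bases are read through the alignment, so indels elsewhere do not shift
    the site.
    """
    if len(cloneset.clones) < 3:
        raise ValueError("majority check needs >= 3 clones")
    if not (0 <= site_position < len(cloneset.consensus)):
        raise ValueError(f"site {site_position} outside consensus")
    ref_base = cloneset.consensus[site_position]
    agree = 0
    for clone in cloneset.clones:
        agree += _base_at(cloneset.consensus, clone, site_position) == ref_base
    frac = agree / len(cloneset.clones)
    tie = agree * 2 == len(cloneset.clones)
    return MajorityCheck(
        passed=frac > 0.5, majority_fraction=frac, consensus_base=ref_base, tie=tie
    )


def _base_at(consensus: str, clone: str, pos: int) -> str:
    if len(clone) == len(consensus):
        return clone[pos]
    aln = _aligner().align(consensus, clone)[0]
    a, b = str(aln[0]), str(aln[1])
    i = -1
    for c_base, k_base in zip(a, b):
        if c_base != "-":
            i += 1
            if i == pos:
                return k_base
    return "-"


# ---------------------------------------------------------------------------
# replicate concordance


@dataclass(frozen=True)
class ConcordanceResult:
    status: str                  # authenticated | discordant | unconfirmed
    genotype: str | None = None  # set when authenticated


def genotype_concordance(per_assay_calls: list[str]) -> ConcordanceResult:
    """Authentication rule for repeated genotype calls of one sample.

    ``authenticated`` requires at least two non-missing calls, all equal;
    any two differing non-missing calls are ``discordant``; a single
    non-missing call is ``unconfirmed``.  Order-invariant.
    """
    if not per_assay_calls:
        raise ValueError("at least one call is required")
    calls = [c for c in per_assay_calls if c and c.lower() != "missing"]
    if not calls:
        return ConcordanceResult("unconfirmed")
    if len(set(calls)) > 1:
        return ConcordanceResult("discordant")
    if len(calls) == 1:
        return ConcordanceResult("unconfirmed")
    return ConcordanceResult("authenticated", genotype=calls[0])


# ---------------------------------------------------------------------------
# qPCR standard curves


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares Ct-vs-log10(copies) calibration."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float

    def __post_init__(self) -> None:
        expected = 10.0 ** (-1.0 / self.slope) - 1.0
        if not math.isclose(self.efficiency, expected, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("efficiency inconsistent with slope")

    def predict_ct(self, copies: float) -> float:
        return self.slope * math.log10(copies) + self.intercept


def fit_standard_curve(series) -> StandardCurve:
    """Fit a standard curve from (copies_per_ul, ct) dilution points.

    ``series`` is an iterable of pairs or a DataFrame with columns
    ``copies_per_ul`` and ``ct``; replicate measurements are simply extra
    points.  At least 3 distinct concentrations are required (the standard
    3-point design runs 4 replicates per point).
    """
    if hasattr(series, "columns"):
        copies = np.asarray(series["copies_per_ul"], dtype=float)
        ct = np.asarray(series["ct"], dtype=float)
    else:
        arr = np.asarray(list(series), dtype=float)
        copies, ct = arr[:, 0], arr[:, 1]
    if np.any(copies <= 0):
        raise ValueError("copy numbers must be positive")
    if len(np.unique(copies)) < 3:
        raise ValueError("need >= 3 distinct concentrations to fit a curve")
    x = np.log10(copies)
    res = stats.linregress(x, ct)
    if res.slope == 0:
        raise ValueError("degenerate fit: zero slope")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency=float(10.0 ** (-1.0 / res.slope) - 1.0),
    )


def quantify_extract(ct: float, curve: StandardCurve) -> float:
    """Copies/µl for an observed Ct: the inverse of the standard curve."""
    if curve.slope == 0:
        raise ValueError("degenerate curve: zero slope")
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


# ---------------------------------------------------------------------------
# FASTA I/O for clone sets


def write_clone_sets(clonesets: list[CloneSet], path: str | Path) -> None:
    records = []
    for cs in clonesets:
        records.append(
            SeqRecord(Seq(cs.consensus), id=f"{cs.sample_id}|consensus", description="")
        )
        for i, clone in enumerate(cs.clones, start=1):
            records.append(
                SeqRecord(Seq(clone), id=f"{cs.sample_id}|clone{i}", description="")
            )
    SeqIO.write(records, str(path), "fasta")


def read_clone_sets(path: str | Path, locus: str = "mtdna_hvr1") -> list[CloneSet]:
    by_sample: dict[str, dict] = {}
    order = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sample, _, kind = rec.id.partition("|")
        entry = by_sample.setdefault(sample, {"consensus": None, "clones": []})
        if sample not in order:
            order.append(sample)
        if kind == "consensus":
            entry["consensus"] = str(rec.seq)
        else:
            entry["clones"].append(str(rec.seq))
    out = []
    for sample in order:
        entry = by_sample[sample]
        if entry["consensus"] is None:
            raise ValueError(f"sample {sample!r} has no consensus record")
        out.append(
            CloneSet(sample, entry["consensus"], entry["clones"], locus=locus)
        )
    return out
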