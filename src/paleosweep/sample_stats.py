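"""Ancient-sample genotype bookkeeping and the monomorphic-sample bound.

The central statistic: if every one of ``k`` independently observed allele
copies in a sample carries the same allele, the smallest population frequency
``p`` under which that observation has probability at least ``alpha`` solves
``p^k = alpha``, i.e. ``p_min = alpha**(1/k)`` — the exact (Clopper-Pearson
style) one-sided lower bound for an all-successes binomial sample.  For the
best-represented burial site (17 individuals, all homozygous for the
inactive allele, counted conservatively as one independent allele each
because of possible allelic dropout) this gives p_min ≈ 0.8384 at α = 0.05.

Genotype tables are tab-separated with columns
``sample  site  period  c14_bp  genotype  replicates`` (``replicates`` is a
comma-joined list of per-assay calls; ``c14_bp`` may be empty).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AncientGenotypeTable",
    "FrequencyBound",
    "min_compatible_frequency",
    "summarize_genotype_table",
    "observed_allele_frequency",
    "load_packaged_table",
]

GENOTYPES = ("CC", "CT", "TT")
MISSING = "missing"

_COLUMNS = ["sample", "site", "period", "c14_bp", "genotype", "replicates"]


@dataclass(frozen=True)
class FrequencyBound:
    """Lower bound on an allele frequency from a monomorphic sample."""

    k: int
    alpha: float
    p_min: float

    def __post_init__(self) -> None:
        if abs(self.p_min**self.k - self.alpha) > 1e-12:
            raise ValueError("p_min**k must equal alpha")


def min_compatible_frequency(k: int, alpha: float = 0.05) -> FrequencyBound:
    """Smallest allele frequency compatible (at level ``alpha``) with
    observing the same allele in all ``k`` independent copies."""
    if k < 1:
        raise ValueError(f"k={k} must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha={alpha} must be in (0, 1)")
    return FrequencyBound(k=k, alpha=alpha, p_min=alpha ** (1.0 / k))


class TableValidationError(ValueError):
    pass


@dataclass
class AncientGenotypeTable:
    """Per-individual genotypes of prehistoric samples at rs497116."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in _COLUMNS if c not in self.df.columns]
        if missing_cols:
            raise TableValidationError(f"table missing column(s) {missing_cols}")
        dup = self.df["sample"][self.df["sample"].duplicated()]
        if not dup.empty:
            raise TableValidationError(f"duplicate sample ids: {sorted(set(dup))}")
        bad = set(self.df["genotype"]) - set(GENOTYPES) - {MISSING}
        if bad:
            raise TableValidationError(f"unknown genotype value(s) {sorted(bad)}")
        # a consensus genotype must be among its own replicate calls
        for _, row in self.df.iterrows():
            calls = self.replicate_calls(row)
            if row["genotype"] != MISSING and calls and row["genotype"] not in calls:
                raise TableValidationError(
                    f"sample {row['sample']}: genotype {row['genotype']} "
                    f"inconsistent with replicate calls {calls}"
                )

    @staticmethod
    def replicate_calls(row) -> list[str]:
        raw = row.get("replicates")
        if pd.isna(raw) or not str(raw).strip():
            return []
        return [c.strip() for c in str(raw).split(",")]

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AncientGenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"replicates": str})
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def load_packaged_table(name: str = "ancient_genotypes") -> AncientGenotypeTable:
    """The packaged table of the 24 genotyped prehistoric individuals."""
    with resources.as_file(
        resources.files("paleosweep.data").joinpath(f"{name}.tsv")
    ) as p:
        return AncientGenotypeTable.from_tsv(p)


def summarize_genotype_table(table: AncientGenotypeTable) -> dict:
    """Counts per site, per cultural period, and per genotype."""
    df = table.df
    per_site = df.groupby("site").size().to_dict()
    per_period = df.groupby("period").size().to_dict()
    genotype_counts = df.groupby("genotype").size().to_dict()
    summary = {
        "total": int(len(df)),
        "per_site": {k: int(v) for k, v in per_site.items()},
        "per_period": {k: int(v) for k, v in per_period.items()},
        "genotype_counts": {k: int(v) for k, v in genotype_counts.items()},
    }
    assert sum(summary["per_site"].values()) == summary["total"]
    assert sum(summary["per_period"].values()) == summary["total"]
    return summary


def observed_allele_frequency(table: AncientGenotypeTable, allele: str = "T") -> dict:
    """Observed frequency of ``allele`` among non-missing genotypes.

    Reports both counting conventions: ``chromosomes`` (2 copies per
    individual; a heterozygote contributes one copy of each allele) and the
    dropout-conservative ``individuals`` convention (one confirmed copy per
    individual: an individual counts toward the allele if it shows it at
    all), which is the convention behind the k=17 frequency bound.
    """
    if allele not in ("C", "T"):
        raise ValueError(f"allele must be 'C' or 'T', got {allele!r}")
    geno = table.df["genotype"]
    called = geno[geno != MISSING]
    if called.empty:
        raise ValueError("all genotypes missing: observed frequency undefined")
    copies = called.map(lambda g: g.count(allele)).sum()
    n_chrom = 2 * len(called)
    carriers = int((called.str.contains(allele)).sum())
    return {
        "allele": allele,
        "n_individuals": int(len(called)),
        "allele_copies": int(copies),
        "frequency": copies / n_chrom,
        "carrier_individuals": carriers,
        "carrier_frequency": carriers / len(called),
    }
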