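"""Deterministic single-locus selection dynamics.

Implements the classical one-generation viability-selection recursion for a
biallelic locus in an effectively infinite population,

    p' = p (p w_AA + q w_Aa) / w̄,    w̄ = p² w_AA + 2pq w_Aa + q² w_aa,

where A is the derived, advantageous allele, and the solvers built on top of
it (trajectory iteration and time-to-frequency).  Three parameterizations of
the genotype viabilities are supported so that the sensitivity of sweep
timings to the fitness model can be examined:

``viability``
    w_AA = 1, w_Aa = 1 - h s, w_aa = 1 - s (h = heterozygous effect).
``genic``
    multiplicative per-allele-copy fitness 1 and 1 + s, i.e. viabilities
    proportional to (1+s)², (1+s), 1.
``additive``
    the viability scheme pinned at h = 1/2 (w_Aa exactly midway).

For weak selection the additive model admits the closed-form sweep time
t ≈ (2/s) ln(p₂q₁ / p₁q₂), and the genic model t ≈ (1/s) ln(p₂q₁ / p₁q₂);
both are exposed for cross-checking the recursion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FitnessScheme",
    "Trajectory",
    "step_frequency",
    "simulate_trajectory",
    "generations_to_reach",
    "additive_sweep_time",
    "genic_sweep_time",
]

_SCHEMES = ("viability", "genic", "additive")


@dataclass(frozen=True)
class FitnessScheme:
    """Selection parameters and the genotype viabilities they induce.

    Parameters
    ----------
    s : float
        Selection coefficient against the ancestral homozygote, ``0 <= s < 1``.
    h : float
        Heterozygous effect in ``[0, 1]`` (0: derived allele fully dominant
        in fitness; 1: fully recessive advantage).  Ignored by the ``genic``
        and ``additive`` parameterizations.
    parameterization : str
        One of ``viability`` (default), ``genic``, ``additive``.
    """

    s: float = 0.0
    h: float = 0.5
    parameterization: str = "viability"

    def __post_init__(self) -> None:
        if not (0.0 <= self.s < 1.0):
            raise ValueError(f"selection coefficient s={self.s!r} must be in [0, 1)")
        if not (0.0 <= self.h <= 1.0):
            raise ValueError(f"heterozygous effect h={self.h!r} must be in [0, 1]")
        if self.parameterization not in _SCHEMES:
            raise ValueError(
                f"unknown parameterization {self.parameterization!r}; "
                f"expected one of {_SCHEMES}"
            )

    @property
    def viabilities(self) -> tuple[float, float, float]:
        """(w_AA, w_Aa, w_aa), normalized so that w_AA = 1."""
        s = self.s
        if self.parameterization == "genic":
            return 1.0, 1.0 / (1.0 + s), 1.0 / (1.0 + s) ** 2
        h = 0.5 if self.parameterization == "additive" else self.h
        return 1.0, 1.0 - h * s, 1.0 - s

    @property
    def neutral(self) -> bool:
        return self.s == 0.0


@dataclass(frozen=True)
class Trajectory:
    """A deterministic allele-frequency trajectory, one entry per generation."""

    generations: np.ndarray
    frequencies: np.ndarray
    scheme: FitnessScheme
    p0: float = field(default=0.0)

    def __post_init__(self) -> None:
        g = np.asarray(self.generations, dtype=int)
        f = np.asarray(self.frequencies, dtype=float)
        if g.shape != f.shape:
            raise ValueError("generations and frequencies must have equal length")
        if f.size and not math.isclose(f[0], self.p0, abs_tol=1e-12):
            raise ValueError("frequencies[0] must equal p0")
        object.__setattr__(self, "generations", g)
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return len(self.generations)

    @property
    def final_frequency(self) -> float:
        return float(self.frequencies[-1])


def step_frequency(p, scheme: FitnessScheme):
    """One generation of viability selection.

    Accepts a scalar or ndarray of frequencies; scalars are range-checked,
    arrays are assumed valid (the Wright-Fisher engine feeds clipped values).
    """
    w_AA, w_Aa, w_aa = scheme.viabilities
    if np.isscalar(p) or isinstance(p, float):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"allele frequency p={p!r} outside [0, 1]")
        q = 1.0 - p
        marginal = p * (p * w_AA + q * w_Aa)
        wbar = p * p * w_AA + 2.0 * p * q * w_Aa + q * q * w_aa
        return marginal / wbar if wbar > 0.0 else p
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    marginal = p * (p * w_AA + q * w_Aa)
    wbar = p * p * w_AA + 2.0 * p * q * w_Aa + q * q * w_aa
    with np.errstate(invalid="ignore"):
        out = np.where(wbar > 0.0, marginal / np.where(wbar > 0.0, wbar, 1.0), p)
    return out


def simulate_trajectory(p0: float, scheme: FitnessScheme, n_generations: int) -> Trajectory:
    """Iterate the recursion for ``n_generations`` generations from ``p0``."""
    if n_generations < 0:
        raise ValueError("n_generations must be >= 0")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError(f"initial frequency p0={p0!r} outside [0, 1]")
    freqs = np.empty(n_generations + 1, dtype=float)
    freqs[0] = p = p0
    for t in range(1, n_generations + 1):
        p = step_frequency(p, scheme)
        freqs[t] = p
    return Trajectory(np.arange(n_generations + 1), freqs, scheme, p0=p0)


def generations_to_reach(
    p0: float,
    target: float,
    scheme: FitnessScheme,
    max_generations: int = 10_000,
) -> int | None:
    """Smallest generation t at which the trajectory first satisfies p_t >= target.

    Returns ``None`` if the target is not attained within ``max_generations``
    (e.g. under neutrality, or for targets unreachable from a boundary).
    The comparison is closed (>=): the deterministic recursion approaches but
    never exactly hits interior targets.
    """
    for x, name in ((p0, "p0"), (target, "target")):
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"{name}={x!r} outside [0, 1]")
    if max_generations < 0:
        raise ValueError("max_generations must be >= 0")
    p = p0
    if p >= target:
        return 0
    if scheme.neutral or p0 in (0.0, 1.0):
        return None  # fixed point: the target can never be reached
    for t in range(1, max_generations + 1):
        p = step_frequency(p, scheme)
        if p >= target:
            return t
    return None


def additive_sweep_time(p1: float, p2: float, s: float) -> float:
    """Closed-form weak-selection sweep time for the additive (h=1/2) model:
    t = (2/s) ln(p₂ q₁ / p₁ q₂)."""
    _check_interior(p1, p2, s)
    return (2.0 / s) * math.log((p2 * (1 - p1)) / (p1 * (1 - p2)))

def genic_sweep_time(p1: float, p2: float, s: float) -> float:
    """Closed-form sweep time for genic (per-copy) selection:
    t = (1/s) ln(p₂ q₁ / p₁ q₂)."""
    _check_interior(p1, p2, s)
    return (1.0 / s) * math.log((p2 * (1 - p1)) / (p1 * (1 - p2)))


def _check_interior(p1: float, p2: float, s: float) -> None:
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("closed forms require interior frequencies")
    if s <= 0.0:
        raise ValueError("closed forms require s > 0")
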