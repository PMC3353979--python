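"""Seeded single-locus forward Wright-Fisher simulator.

Each generation applies, in a fixed documented order: (1) deterministic
migration mixing of population frequencies from the migrant-pool expectation,
(2) the viability-selection transform, (3) a binomial resampling of allele
counts at next-generation population sizes.  Population splits copy the
parent's post-selection frequency into the daughter, whose founding counts
are drawn binomially at the founding size (founder sampling is part of the
bottleneck).  The locus starts monomorphic ancestral; a single derived copy
is injected at a configurable scaled time.

Two surfaces are provided: an explicit per-replicate API
(:class:`LocusState`, :func:`inject_mutation`, :func:`advance_generation`,
:func:`simulate_replicate`) that mirrors the model definition, and a batched
runner (:func:`simulate_batch`) that vectorizes many replicates for the
rejection-sampling experiments.  Both consume the same compiled per-generation
schedules, and a replicate is reproducible from its seed on either path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import (
    DemographicModel,
    migration_schedule,
    scaled_to_generations,
    size_schedule,
)
from .selection_dynamics import FitnessScheme, step_frequency

__all__ = [
    "LocusState",
    "ReplicateResult",
    "BatchResult",
    "CompiledModel",
    "compile_model",
    "inject_mutation",
    "advance_generation",
    "simulate_replicate",
    "simulate_batch",
]

FATE_LOST = "lost"
FATE_SEGREGATING = "segregating"
FATE_FIXED = "fixed_global"


class StateError(RuntimeError):
    """The locus state was driven into an inconsistent configuration."""


@dataclass
class CompiledModel:
    """Per-generation schedules derived once from a :class:`DemographicModel`."""

    model: DemographicModel
    sizes: np.ndarray        # (G+1, P) diploid sizes, 0 before founding
    migration: np.ndarray    # (G+1, P, P) per-generation fractions
    splits: list             # (generation, parent_index, daughter_index)
    n_generations: int

    def pop_index(self, label: str) -> int:
        return self.model.populations.index(label)


def compile_model(model: DemographicModel) -> CompiledModel:
    sizes = size_schedule(model)
    mig = migration_schedule(model)
    splits = []
    idx = {p: j for j, p in enumerate(model.populations)}
    for ev in model.events:
        if ev.kind == "split":
            splits.append(
                (scaled_to_generations(model, ev.time), idx[ev.pop], idx[ev.daughter])
            )
    return CompiledModel(model, sizes, mig, splits, model.n_generations)


# ---------------------------------------------------------------------------
# per-replicate API


@dataclass
class LocusState:
    """Allele counts per population at one generation of one replicate."""

    compiled: CompiledModel
    counts: np.ndarray
    generation: int
    rng: np.random.Generator
    mutation_injected: bool = False

    @property
    def sizes(self) -> np.ndarray:
        return self.compiled.sizes[self.generation]

    @property
    def frequencies(self) -> np.ndarray:
        n = 2 * self.sizes
        return np.where(n > 0, self.counts / np.maximum(n, 1), 0.0)

    def check(self) -> None:
        n = 2 * self.sizes
        if np.any(self.counts < 0) or np.any(self.counts > n):
            raise StateError(
                f"allele counts {self.counts} outside [0, 2N]={n} "
                f"at generation {self.generation}"
            )


def initial_state(compiled: CompiledModel, seed: int | np.random.Generator) -> LocusState:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.zeros(len(compiled.model.populations), dtype=np.int64)
    return LocusState(compiled, counts, 0, rng)


def inject_mutation(state: LocusState, pop: str, t: float) -> LocusState:
    """Place a single derived copy in ``pop`` at scaled time ``t`` (in place)."""
    cm = state.compiled
    g = scaled_to_generations(cm.model, t)
    if g != state.generation:
        raise ValueError(
            f"injection time t={t} is generation {g}, state is at {state.generation}"
        )
    j = cm.pop_index(pop)
    if cm.sizes[g, j] <= 0:
        raise ValueError(f"population {pop!r} does not exist at t={t}")
    if state.mutation_injected or state.counts.any():
        raise StateError("locus is no longer monomorphic ancestral")
    state.counts[j] = 1
    state.mutation_injected = True
    return state


def advance_generation(
    state: LocusState, scheme: FitnessScheme | None = None
) -> LocusState:
    """One migration→selection→drift step (in place); splits found daughters."""
    cm = state.compiled
    g = state.generation
    if g >= cm.n_generations:
        raise StateError("simulation already at its final generation")
    scheme = scheme or FitnessScheme(0.0)
    state.check()
    p = state.frequencies
    p = _migrate(p, cm.migration[g], cm.sizes[g])
    p = np.clip(step_frequency(p, scheme), 0.0, 1.0)
    for g_split, parent, daughter in cm.splits:
        if g_split == g + 1:
            p[daughter] = p[parent]
    n_next = 2 * cm.sizes[g + 1]
    state.counts = state.rng.binomial(n_next, np.where(n_next > 0, p, 0.0))
    state.generation = g + 1
    return state


def _migrate(p: np.ndarray, m: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Expected post-migration frequencies from the migrant-pool mixture."""
    exists = sizes > 0
    m_eff = m * exists[None, :] * exists[:, None]
    return p * (1.0 - m_eff.sum(axis=1)) + m_eff @ p


@dataclass(frozen=True)
class ReplicateResult:
    """Summary of one forward replicate."""

    final_frequencies: dict
    frequency_at_records: dict
    mutation_origin_time: float
    fate: str
    seed: int
    accepted: bool | None = None


def simulate_replicate(
    model: DemographicModel | CompiledModel,
    scheme: FitnessScheme,
    origin_window: tuple[float, float],
    seed: int,
    origin_pop: str | None = None,
) -> ReplicateResult:
    """Run one replicate: inject a derived copy at a uniform scaled time in
    ``origin_window`` (in ``origin_pop``, default the root population), then
    advance to t_end, recording frequencies at the model's record times."""
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    lo, hi = origin_window
    if not (0.0 <= lo <= hi <= cm.model.t_end):
        raise ValueError(f"origin window {origin_window} outside [0, t_end]")
    res = simulate_batch(cm, scheme, origin_window, n_replicates=1, seed=seed,
                         origin_pop=origin_pop)
    pops = cm.model.populations
    return ReplicateResult(
        final_frequencies={p: float(res.final_freq[0, j]) for j, p in enumerate(pops)},
        frequency_at_records={
            k: float(v[0]) for k, v in res.record_freq.items()
        },
        mutation_origin_time=float(res.origin_time[0]),
        fate=res.fates()[0],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# batched runner


@dataclass
class BatchResult:
    """Vectorized replicate summaries (row per replicate)."""

    populations: tuple[str, ...]
    final_freq: np.ndarray          # (B, P)
    record_freq: dict               # name -> (B,) frequency in record pop
    origin_time: np.ndarray         # (B,) scaled times
    fate_code: np.ndarray           # (B,) 0 lost / 1 segregating / 2 fixed

    def fates(self) -> np.ndarray:
        return np.array([FATE_LOST, FATE_SEGREGATING, FATE_FIXED])[self.fate_code]

    def __len__(self) -> int:
        return len(self.origin_time)


def simulate_batch(
    model: DemographicModel | CompiledModel,
    scheme: FitnessScheme,
    origin_window: tuple[float, float],
    n_replicates: int,
    seed: int | np.random.Generator,
    origin_pop: str | None = None,
    record_pop: str = "EUR",
    compact_every: int = 16,
) -> BatchResult:
    """Run ``n_replicates`` independent replicates, vectorized per generation.

    Replicates whose derived allele is globally lost (or globally fixed once
    all populations exist) are finalized early and removed from the active
    set, which keeps the cost dominated by the short pre-absorption phase.
    """
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pops = cm.model.populations
    P = len(pops)
    G = cm.n_generations
    j_origin = cm.pop_index(origin_pop or cm.model.root_population)
    record_gens = {
        name: scaled_to_generations(cm.model, t)
        for name, t in cm.model.record_times.items()
    }
    j_record = cm.pop_index(record_pop) if record_pop in pops else j_origin
    last_split_gen = max((g for g, _, _ in cm.splits), default=0)

    B = int(n_replicates)
    t_mut = rng.uniform(origin_window[0], origin_window[1], size=B)
    g_mut = np.floor(t_mut * cm.model.ploidy * cm.model.N0 + 0.5).astype(np.int64)

    final_freq = np.zeros((B, P), dtype=float)
    record_freq = {name: np.zeros(B, dtype=float) for name in record_gens}
    fate_code = np.zeros(B, dtype=np.int8)

    counts = np.zeros((B, P), dtype=np.int64)
    active = np.arange(B)
    g_mut_active = g_mut.copy()

    for g in range(G):
        inject = g_mut_active == g
        if inject.any():
            counts[inject, j_origin] = 1

        n_now = 2 * cm.sizes[g]
        exists = n_now > 0
        p = np.zeros_like(counts, dtype=float)
        p[:, exists] = counts[:, exists] / n_now[exists]

        p = _migrate_batch(p, cm.migration[g], cm.sizes[g])
        p = np.clip(step_frequency(p, scheme), 0.0, 1.0)
        for g_split, parent, daughter in cm.splits:
            if g_split == g + 1:
                p[:, daughter] = p[:, parent]
        n_next = 2 * cm.sizes[g + 1]
        counts = rng.binomial(n_next[None, :], np.where(n_next > 0, p, 0.0))

        if g + 1 in record_gens.values():
            f_rec = counts[:, j_record] / max(1, n_next[j_record])
            for name, g_rec in record_gens.items():
                if g_rec == g + 1:
                    record_freq[name][active] = f_rec

        if (g + 1) % compact_every == 0 and g + 1 < G:
            keep = _compact(
                cm, counts, active, g + 1, g_mut_active, n_next,
                final_freq, record_freq, fate_code, record_gens, last_split_gen,
            )
            if keep is not None:
                counts = counts[keep]
                active = active[keep]
                g_mut_active = g_mut_active[keep]
                if active.size == 0:
                    break

    if active.size:
        n_end = 2 * cm.sizes[G]
        exists = n_end > 0
        f = np.zeros_like(counts, dtype=float)
        f[:, exists] = counts[:, exists] / n_end[exists]
        final_freq[active] = f
        lost = (counts[:, exists].sum(axis=1) == 0)
        fixed = np.all(counts[:, exists] == n_end[exists], axis=1)
        fate_code[active[lost]] = 0
        fate_code[active[fixed]] = 2
        fate_code[active[~lost & ~fixed]] = 1

    return BatchResult(pops, final_freq, record_freq, t_mut, fate_code)


def _migrate_batch(p: np.ndarray, m: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    exists = sizes > 0
    m_eff = m * (exists[None, :] & exists[:, None])
    return p * (1.0 - m_eff.sum(axis=1))[None, :] + p @ m_eff.T


def _compact(
    cm, counts, active, g, g_mut_active, n_now,
    final_freq, record_freq, fate_code, record_gens, last_split_gen,
):
    """Finalize globally-lost and globally-fixed replicates; return keep mask
    (or None if nothing can be retired)."""
    exists = n_now > 0
    injected = g_mut_active <= g
    lost = injected & (counts[:, exists].sum(axis=1) == 0)
    # global fixation is only final once every population has been founded
    if g >= last_split_gen:
        fixed = np.all(counts[:, exists] == n_now[exists], axis=1)
    else:
        fixed = np.all(counts[:, exists] == n_now[exists], axis=1) & injected
        # a fixed ancestor propagates fixation through future splits, so this
        # is final even before all daughters exist
    retire = lost | fixed
    if not retire.any():
        return None
    idx_lost = active[lost]
    idx_fixed = active[fixed]
    fate_code[idx_lost] = 0
    fate_code[idx_fixed] = 2
    # frequencies: lost -> 0 everywhere (default); fixed -> 1 everywhere
    final_freq[idx_fixed] = 1.0
    for name, g_rec in record_gens.items():
        if g_rec > g:  # not yet recorded for these replicates
            record_freq[name][idx_fixed] = 1.0
    return ~retire
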