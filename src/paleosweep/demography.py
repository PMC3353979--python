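"""Scaled demographic timeline for the three-population Out-of-Africa model.

The model is a forward-time event list over named diploid populations.  Times
are *scaled*: one unit equals ``2 N0`` generations, where ``N0`` is the scaled
ancestral diploid size (500 in the packaged model, chosen to keep compound
parameters 2Ns, 4Nm and t/2N at their real-scale values while making forward
simulation cheap).  Event kinds:

``size_change``
    multiply the population's current size by ``value``;
``growth_rate_change``
    set the exponential growth rate to ``value`` per unit scaled time,
    N(t) = N(t_event) · exp(value · (t − t_event));
``split``
    found ``daughter`` from ``pop`` (the daughter starts at the parent's
    current size; an accompanying size_change usually bottlenecks it);
``migration_change``
    set the rate at which ``pop`` receives migrants from ``source``.  Under
    the default ``4Nm`` convention the stored value is M = 4·N0·m, with m the
    per-generation fraction of ``pop`` replaced by migrants from ``source``;
    the ``fraction`` convention stores m directly.

The packaged fixture ``ooa_scaled`` transcribes the African size history
(0.1× at t=0, 10× at 0.004, 1.68202× at 0.005), the African→European split at
t=0.211074 with a 0.170737565× bottleneck, the European→Asian split at
t=0.534772 with 0.724763218×/0.162342748× bottlenecks and exponential growth
(33.98, 62.27), the full time-varying migration matrix, and the end of
simulation at t=0.607, with the European frequency additionally recorded at
t = 0.607 − 0.0175 (≈7,000 years before present under κ=14.62 scaling and
25-year generations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "DemographicEvent",
    "DemographicModel",
    "load_model",
    "load_packaged_model",
    "constant_size_model",
    "scaled_to_generations",
    "population_size_at",
]

EVENT_KINDS = ("split", "size_change", "growth_rate_change", "migration_change")

# events at the same scaled time apply in this order (split founds the
# daughter at the parent's pre-bottleneck size)
_KIND_ORDER = {k: i for i, k in enumerate(EVENT_KINDS)}

MIGRATION_CONVENTIONS = ("2N_recipient", "4Nm", "fraction")


class ModelValidationError(ValueError):
    """A demographic configuration violates the model contract."""


@dataclass(frozen=True)
class DemographicEvent:
    time: float
    kind: str
    pop: str
    value: float | None = None
    daughter: str | None = None   # split only
    source: str | None = None     # migration_change only: origin of migrants

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ModelValidationError(f"event time {self.time} < 0 ({self})")
        if self.kind not in EVENT_KINDS:
            raise ModelValidationError(f"unknown event kind {self.kind!r}")
        if self.kind == "size_change" and (self.value is None or self.value <= 0):
            raise ModelValidationError(f"size multiplier must be > 0 ({self})")
        if self.kind == "migration_change":
            if self.source is None:
                raise ModelValidationError(f"migration_change needs a source ({self})")
            if self.value is None or self.value < 0:
                raise ModelValidationError(f"migration rate must be >= 0 ({self})")
        if self.kind == "split" and not self.daughter:
            raise ModelValidationError(f"split needs a daughter label ({self})")
        if self.kind == "growth_rate_change" and self.value is None:
            raise ModelValidationError(f"growth_rate_change needs a value ({self})")


@dataclass(frozen=True)
class DemographicModel:
    """A validated, time-sorted demographic timeline over named populations."""

    N0: int
    t_end: float
    populations: tuple[str, ...]
    events: tuple[DemographicEvent, ...] = ()
    root_population: str | None = None
    record_times: dict = field(default_factory=dict)
    migration_convention: str = "4Nm"
    kappa: float = 14.62
    generation_time_years: float = 25.0
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.N0 < 2:
            raise ModelValidationError(f"N0={self.N0} must be >= 2")
        if self.t_end <= 0:
            raise ModelValidationError(f"t_end={self.t_end} must be > 0")
        if self.migration_convention not in MIGRATION_CONVENTIONS:
            raise ModelValidationError(
                f"migration_convention must be one of {MIGRATION_CONVENTIONS}"
            )
        if not self.populations:
            raise ModelValidationError("at least one population is required")
        root = self.root_population or self.populations[0]
        object.__setattr__(self, "root_population", root)
        events = tuple(
            sorted(self.events, key=lambda e: (e.time, _KIND_ORDER[e.kind]))
        )
        object.__setattr__(self, "events", events)
        self._validate(events)

    def _validate(self, events: tuple[DemographicEvent, ...]) -> None:
        founded = {self.root_population: 0.0}
        for ev in events:
            if ev.time > self.t_end:
                raise ModelValidationError(
                    f"event at t={ev.time} occurs after t_end={self.t_end} ({ev})"
                )
            for label in filter(None, (ev.pop, ev.source, ev.daughter)):
                if label not in self.populations:
                    raise ModelValidationError(f"unknown population {label!r} ({ev})")
            if ev.pop not in founded or founded[ev.pop] > ev.time:
                raise ModelValidationError(
                    f"event on population {ev.pop!r} before it exists ({ev})"
                )
            if ev.kind == "split":
                if ev.daughter in founded:
                    raise ModelValidationError(
                        f"daughter {ev.daughter!r} already exists ({ev})"
                    )
                founded[ev.daughter] = ev.time
            if ev.kind == "migration_change" and ev.source not in founded:
                raise ModelValidationError(
                    f"migration from unfounded population {ev.source!r} ({ev})"
                )
        for rt in self.record_times.values():
            if not (0.0 <= rt <= self.t_end):
                raise ModelValidationError(f"record time {rt} outside [0, t_end]")

    # -- time bookkeeping -------------------------------------------------

    @property
    def n_generations(self) -> int:
        return scaled_to_generations(self, self.t_end)

    def founding_time(self, pop: str) -> float:
        """Scaled time at which ``pop`` comes into existence."""
        if pop == self.root_population:
            return 0.0
        for ev in self.events:
            if ev.kind == "split" and ev.daughter == pop:
                return ev.time
        raise ModelValidationError(f"population {pop!r} is never founded")

    def split_parent(self, pop: str) -> str | None:
        for ev in self.events:
            if ev.kind == "split" and ev.daughter == pop:
                return ev.pop
        return None

    def migration_fraction(self, value: float, recipient: str | None = None,
                           t: float | None = None) -> float:
        """Convert a stored migration value to a per-generation fraction.

        Under the ``2N_recipient`` convention (the packaged default) the
        stored value is 2·N_i(t)·m with N_i the recipient's diploid size at
        the epoch start; this is the reading under which the model's printed
        rates collapse to a symmetric per-generation migration matrix.
        ``4Nm`` uses the fixed ancestral size (value = 4·N0·m); ``fraction``
        stores m directly.
        """
        if self.migration_convention == "2N_recipient":
            if recipient is None or t is None:
                raise ValueError("2N_recipient convention needs recipient and time")
            return value / (2.0 * _size_lineage(self, recipient, t))
        if self.migration_convention == "4Nm":
            return value / (4.0 * self.N0)
        return value

    def scaled_time_to_years_bp(self, t: float) -> float:
        """Years before present for a scaled time point (presentation only).

        Scaled dynamics are unaffected by κ; it enters only here, converting
        scaled generations back to real ones before applying generation time
        (e.g. the 0.211074 split lands at ≈145,000 years BP with κ=14.62 and
        25-year generations).
        """
        scaled_gens = (self.t_end - t) * self.ploidy * self.N0
        return scaled_gens * self.kappa * self.generation_time_years

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        events = []
        for ev in self.events:
            d = {"time": ev.time, "kind": ev.kind, "pop": ev.pop}
            if ev.value is not None:
                d["value"] = ev.value
            if ev.daughter is not None:
                d["daughter"] = ev.daughter
            if ev.source is not None:
                d["source"] = ev.source
            events.append(d)
        return {
            "N0": self.N0,
            "t_end": self.t_end,
            "populations": list(self.populations),
            "root_population": self.root_population,
            "record_times": dict(self.record_times),
            "migration_convention": self.migration_convention,
            "kappa": self.kappa,
            "generation_time_years": self.generation_time_years,
            "events": events,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_model(config: dict | str | Path) -> DemographicModel:
    """Build a validated :class:`DemographicModel` from a mapping or YAML file."""
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ModelValidationError("demographic config must be a mapping")
    missing = [k for k in ("N0", "t_end", "populations") if k not in config]
    if missing:
        raise ModelValidationError(f"config missing required field(s): {missing}")
    events = []
    for entry in config.get("events", []):
        try:
            events.append(DemographicEvent(**entry))
        except TypeError as exc:
            raise ModelValidationError(f"malformed event {entry!r}: {exc}") from exc
    return DemographicModel(
        N0=int(config["N0"]),
        t_end=float(config["t_end"]),
        populations=tuple(config["populations"]),
        events=tuple(events),
        root_population=config.get("root_population"),
        record_times=dict(config.get("record_times", {})),
        migration_convention=config.get("migration_convention", "4Nm"),
        kappa=float(config.get("kappa", 14.62)),
        generation_time_years=float(config.get("generation_time_years", 25.0)),
    )


def load_packaged_model(name: str = "ooa_scaled") -> DemographicModel:
    """Load a model shipped with the package (default: the scaled OoA model)."""
    text = resources.files("paleosweep.data").joinpath(f"{name}.yaml").read_text()
    return load_model(yaml.safe_load(text))


def constant_size_model(N: int, n_generations: int, label: str = "POP") -> DemographicModel:
    """A single constant-size population running for ``n_generations``."""
    return DemographicModel(
        N0=N, t_end=n_generations / (2.0 * N), populations=(label,)
    )


def scaled_to_generations(model: DemographicModel, t: float) -> int:
    """Discrete generation index for scaled time t (half-up rounding)."""
    if not (0.0 <= t <= model.t_end + 1e-12):
        raise ValueError(f"scaled time {t} outside [0, {model.t_end}]")
    return int(math.floor(t * model.ploidy * model.N0 + 0.5))


def population_size_at(model: DemographicModel, pop: str, t: float) -> int:
    """Diploid size of ``pop`` at scaled time ``t`` (events at exactly ``t``
    included), applying size multipliers and exponential growth; >= 2."""
    if pop not in model.populations:
        raise ValueError(f"unknown population {pop!r}")
    t0 = model.founding_time(pop)
    if t < t0 - 1e-12:
        raise ValueError(f"population {pop!r} not yet founded at t={t}")

    size = _size_lineage(model, pop, t)
    return max(2, int(round(size)))


def _size_lineage(
    model: DemographicModel, pop: str, t: float, include_at_t: bool = True
) -> float:
    """Continuous size of ``pop`` at time t, following the parent lineage back
    through splits for the founding size.

    A daughter inherits the parent's size *before* any same-time events (the
    split happens first; bottleneck multipliers then act on each branch), so
    the parent lineage is evaluated with ``include_at_t=False``.
    """
    t0 = model.founding_time(pop)
    parent = model.split_parent(pop)
    size = (
        float(model.N0)
        if parent is None
        else _size_lineage(model, parent, t0, include_at_t=False)
    )
    growth_rate = 0.0
    t_anchor = t0
    for ev in model.events:
        if ev.pop != pop or ev.time < t0 or ev.time > t:
            continue
        if not include_at_t and ev.time == t:
            continue
        # advance growth up to the event, then apply it
        size *= math.exp(growth_rate * (ev.time - t_anchor))
        t_anchor = ev.time
        if ev.kind == "size_change":
            size *= ev.value
        elif ev.kind == "growth_rate_change":
            growth_rate = ev.value
    size *= math.exp(growth_rate * (t - t_anchor))
    return size


def size_schedule(model: DemographicModel) -> np.ndarray:
    """Per-generation diploid sizes, shape (n_generations+1, n_pops);
    0 where a population does not yet exist."""
    G = model.n_generations
    P = len(model.populations)
    sizes = np.zeros((G + 1, P), dtype=np.int64)
    for j, pop in enumerate(model.populations):
        try:
            g0 = scaled_to_generations(model, model.founding_time(pop))
        except ModelValidationError:
            continue  # never founded in this model
        t_found = model.founding_time(pop)
        for g in range(g0, G + 1):
            # the founding generation's discretized time may fall just short
            # of the exact split time; clamp so the population exists there
            t = max(g / (model.ploidy * model.N0), t_found)
            sizes[g, j] = population_size_at(model, pop, min(t, model.t_end))
    return sizes


def migration_schedule(model: DemographicModel) -> np.ndarray:
    """Per-generation migration fractions m[g, i, j]: fraction of population i
    replaced, in the step leaving generation g, by migrants from population j."""
    G = model.n_generations
    P = len(model.populations)
    idx = {p: j for j, p in enumerate(model.populations)}
    m = np.zeros((G + 1, P, P), dtype=float)
    changes = [ev for ev in model.events if ev.kind == "migration_change"]
    for ev in changes:
        g0 = scaled_to_generations(model, ev.time)
        m[g0:, idx[ev.pop], idx[ev.source]] = model.migration_fraction(
            ev.value, recipient=ev.pop, t=ev.time
        )
    return m
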