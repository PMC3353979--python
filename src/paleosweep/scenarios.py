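"""The three simulation experiments around the derived CASP12 allele.

1.  *Neutral conditional probability*: among neutral replicates whose
    present-day African frequency falls in an acceptance window (default
    [0.3, 0.5], the range seen in African hunter-gatherers), the fraction
    whose present-day European frequency reaches a success threshold
    (default 0.95).  A small value rejects purely neutral evolution.
2.  *Selected-since-origin probability*: the same conditional estimate with
    the allele under additive selection (s = 0.01, scaled 2N0s = 10) from its
    origin.  A small value rejects constant selection predating the Neolithic.
3.  *Two-step Neolithic scenario*: the forward simulation supplies the
    expected European frequency at ~7,000 years before present under
    neutrality (~0.4); the deterministic recursion then asks how many
    generations of Neolithic-onset selection are needed to carry that
    standing frequency to near-fixation.

Replicates are drawn in vectorized batches until the accepted-replicate
target is met; each batch consumes a child seed spawned deterministically
from the master seed, so estimates are reproducible end to end.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest

from .demography import DemographicModel
from .selection_dynamics import (
    FitnessScheme,
    Trajectory,
    generations_to_reach,
    simulate_trajectory,
)
from .wf_engine import CompiledModel, compile_model, simulate_batch

__all__ = [
    "ConditionalEstimate",
    "ExperimentReplicates",
    "run_conditional_experiment",
    "estimate_conditional_probability",
    "expected_frequency_at_time",
    "two_step_neolithic",
    "NEUTRAL_SCHEME",
    "SELECTED_SCHEME",
    "ORIGIN_WINDOW",
    "ACCEPTANCE_WINDOW",
    "SUCCESS_THRESHOLD",
]

#: study defaults: the allele arises in Africa early in the scaled timeline
ORIGIN_WINDOW = (0.001, 0.003)
#: present-day African frequency window used for rejection sampling
ACCEPTANCE_WINDOW = (0.3, 0.5)
#: "practically fixed in Europe" success criterion
SUCCESS_THRESHOLD = 0.95

NEUTRAL_SCHEME = FitnessScheme(0.0)
#: additive selection s = 1% (scaled 2*N0*s = 10 at N0 = 500) since origin
SELECTED_SCHEME = FitnessScheme(0.01, parameterization="additive")


class AcceptanceExhausted(RuntimeError):
    """The raw-replicate cap was reached before enough replicates were accepted."""


@dataclass(frozen=True)
class ConditionalEstimate:
    """A conditional probability estimate from rejection sampling."""

    n_raw: int
    n_accepted: int
    k_success: int
    p_hat: float
    ci95: tuple[float, float]
    scenario: str
    seed: int
    runtime_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.k_success <= self.n_accepted <= self.n_raw):
            raise ValueError("inconsistent replicate counts")


@dataclass
class ExperimentReplicates:
    """Accepted-replicate arrays shared by the conditional estimators."""

    n_raw: int
    afr_final: np.ndarray
    eur_final: np.ndarray
    record_freq: dict           # record name -> (n_accepted,) frequencies
    seed: int
    scenario: str
    sampled_chromosomes: int | None = None
    runtime_s: float = 0.0
    #: record name -> (sum, n) over *all* surviving (segregating) replicates,
    #: accepted or not; the unconditional counterpart of ``record_freq``
    survivor_record_sums: dict = field(default_factory=dict)

    @property
    def n_accepted(self) -> int:
        return len(self.afr_final)

    def survivor_record_mean(self, name: str) -> float | None:
        s, n = self.survivor_record_sums.get(name, (0.0, 0))
        return s / n if n else None


def run_conditional_experiment(
    model: DemographicModel | CompiledModel,
    scheme: FitnessScheme,
    acceptance_window: tuple[float, float] = ACCEPTANCE_WINDOW,
    n_accepted_target: int = 2000,
    seed: int = 0,
    origin_window: tuple[float, float] = ORIGIN_WINDOW,
    accept_pop: str = "AFR",
    success_pop: str = "EUR",
    batch_size: int = 50_000,
    raw_cap: int = 5_000_000,
    sampled_chromosomes: int | None = None,
    scenario: str = "",
) -> ExperimentReplicates:
    """Run batches of replicates until ``n_accepted_target`` pass the
    acceptance window on ``accept_pop``'s final frequency.

    With ``sampled_chromosomes`` set (the survey design drew 100 chromosomes
    per population), acceptance and success are evaluated on binomial sample
    frequencies rather than population frequencies.
    """
    lo, hi = acceptance_window
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"acceptance window {acceptance_window} outside [0, 1]")
    if n_accepted_target < 1:
        raise ValueError("n_accepted_target must be >= 1")
    cm = model if isinstance(model, CompiledModel) else compile_model(model)
    ss = np.random.SeedSequence(seed)
    sample_rng = np.random.default_rng(ss.spawn(1)[0])
    j_acc = cm.pop_index(accept_pop)
    j_suc = cm.pop_index(success_pop)

    t0 = time.perf_counter()
    n_raw = 0
    acc_afr: list[np.ndarray] = []
    acc_eur: list[np.ndarray] = []
    acc_rec: dict[str, list[np.ndarray]] = {k: [] for k in cm.model.record_times}
    surv_sums = {k: (0.0, 0) for k in cm.model.record_times}
    n_accepted = 0
    batch_index = 0
    while n_accepted < n_accepted_target:
        if n_raw >= raw_cap:
            raise AcceptanceExhausted(
                f"raw cap {raw_cap} reached with {n_accepted}/{n_accepted_target} "
                f"accepted replicates (acceptance rate "
                f"{n_accepted / max(1, n_raw):.2e})"
            )
        child = np.random.default_rng(ss.spawn(1)[0])
        batch_index += 1
        res = simulate_batch(
            cm, scheme, origin_window, n_replicates=batch_size, seed=child,
            record_pop=success_pop,
        )
        n_raw += len(res)
        f_acc = res.final_freq[:, j_acc]
        f_suc = res.final_freq[:, j_suc]
        if sampled_chromosomes:
            n_chr = sampled_chromosomes
            f_acc = sample_rng.binomial(n_chr, f_acc) / n_chr
            f_suc = sample_rng.binomial(n_chr, f_suc) / n_chr
        keep = (f_acc >= lo) & (f_acc <= hi)
        acc_afr.append(f_acc[keep])
        acc_eur.append(f_suc[keep])
        surviving = res.fate_code != 0
        for name in acc_rec:
            acc_rec[name].append(res.record_freq[name][keep])
            s, n = surv_sums[name]
            surv_sums[name] = (
                s + float(res.record_freq[name][surviving].sum()),
                n + int(surviving.sum()),
            )
        n_accepted += int(keep.sum())

    cat = lambda xs: np.concatenate(xs) if xs else np.empty(0)
    out = ExperimentReplicates(
        n_raw=n_raw,
        afr_final=cat(acc_afr),
        eur_final=cat(acc_eur),
        record_freq={k: cat(v) for k, v in acc_rec.items()},
        seed=seed,
        scenario=scenario or ("neutral" if scheme.neutral else "selected"),
        sampled_chromosomes=sampled_chromosomes,
        runtime_s=time.perf_counter() - t0,
        survivor_record_sums=surv_sums,
    )
    return out


def estimate_conditional_probability(
    model: DemographicModel | CompiledModel,
    scheme: FitnessScheme,
    acceptance_window: tuple[float, float] = ACCEPTANCE_WINDOW,
    success_threshold: float = SUCCESS_THRESHOLD,
    n_accepted_target: int = 2000,
    seed: int = 0,
    replicates: ExperimentReplicates | None = None,
    **kwargs,
) -> ConditionalEstimate:
    """P(success-population final frequency >= threshold | acceptance window).

    A pre-run :class:`ExperimentReplicates` may be supplied to evaluate
    several thresholds on one shared replicate set.
    """
    if not (0.0 <= success_threshold <= 1.0):
        raise ValueError("success threshold outside [0, 1]")
    if replicates is None:
        replicates = run_conditional_experiment(
            model, scheme, acceptance_window, n_accepted_target, seed, **kwargs
        )
    n_acc = replicates.n_accepted
    k = int(np.sum(replicates.eur_final >= success_threshold))
    ci = binomtest(k, n_acc).proportion_ci(confidence_level=0.95, method="exact")
    return ConditionalEstimate(
        n_raw=replicates.n_raw,
        n_accepted=n_acc,
        k_success=k,
        p_hat=k / n_acc,
        ci95=(float(ci.low), float(ci.high)),
        scenario=replicates.scenario,
        seed=replicates.seed,
        runtime_s=replicates.runtime_s,
    )


def expected_frequency_at_time(
    model: DemographicModel | CompiledModel,
    scheme: FitnessScheme,
    record_label: str = "eur_7kybp",
    acceptance_window: tuple[float, float] = ACCEPTANCE_WINDOW,
    n_accepted_target: int = 2000,
    seed: int = 0,
    replicates: ExperimentReplicates | None = None,
    n_bootstrap: int = 2000,
    **kwargs,
) -> dict:
    """Mean frequency at a model record time over accepted replicates, with a
    bootstrap 95% CI.

    The mean over *all* surviving (non-lost) replicates, without the
    acceptance conditioning, is reported alongside under
    ``mean_all_survivors`` for comparison.
    """
    if replicates is None:
        replicates = run_conditional_experiment(
            model, scheme, acceptance_window, n_accepted_target, seed, **kwargs
        )
    if record_label not in replicates.record_freq:
        raise KeyError(f"model has no record time {record_label!r}")
    f = replicates.record_freq[record_label]
    rng = np.random.default_rng(np.random.SeedSequence([replicates.seed, 7_000]))
    boots = rng.choice(f, size=(n_bootstrap, len(f)), replace=True).mean(axis=1)
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return {
        "mean": float(f.mean()),
        "ci95": (float(lo), float(hi)),
        "n_accepted": replicates.n_accepted,
        "mean_all_survivors": replicates.survivor_record_mean(record_label),
        "record": record_label,
        "seed": replicates.seed,
    }


def two_step_neolithic(
    p_start: float = 0.4,
    scheme_post: FitnessScheme = FitnessScheme(0.01, h=0.11),
    target: float = 0.99,
    max_generations: int = 10_000,
) -> tuple[int | None, Trajectory]:
    """Step two of the standing-variation workaround: deterministic selection
    from the pre-Neolithic standing frequency to near-fixation, assuming
    post-Neolithic population sizes large enough for drift to be negligible."""
    gens = generations_to_reach(p_start, target, scheme_post, max_generations)
    horizon = gens if gens is not None else max_generations
    traj = simulate_trajectory(p_start, scheme_post, horizon)
    return gens, traj
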