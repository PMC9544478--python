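"""Forward-in-time fate of a recessive TE insertion under episodic drought.

Single-locus Wright–Fisher model with partial selfing and hard selection.
A population of diploids at carrying capacity ``K`` starts with one
heterozygous carrier of a transposon insertion polymorphism (TIP), i.e. an
initial allele frequency of ``1/(2K)``.  The insertion is fully recessive
(dominance ``h = 0``): homozygous carriers have fitness ``1 + s_plus``
during scheduled drought generations and ``1 + s_minus`` otherwise, all
other genotypes have fitness 1.

Hard selection couples population size to mean fitness: the number of
offspring produced into the next generation is ``min(K, round(K * wbar))``
where ``wbar`` is the parental mean fitness.  Each offspring draws its
first parent with probability proportional to fitness; with probability
``selfing_rate`` it is produced by selfing, otherwise a second parent is
drawn independently (with replacement, so self-pairing by chance is
possible).  One Mendelian allele is transmitted per parent.

Because offspring are exchangeable, a generation reduces to a single
multinomial draw over the three offspring genotypes; the same offspring
distribution also defines the exact Markov chain used as a validation
oracle at small ``K`` (:func:`exact_chain_distribution`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "DroughtSchedule",
    "PopulationState",
    "ReplicateResult",
    "build_drought_schedule",
    "genotype_fitness",
    "initialize_population",
    "next_generation",
    "run_replicate",
    "run_replicates",
    "run_grid",
    "exact_chain_distribution",
    "DEFAULT_S_PLUS_GRID",
    "DEFAULT_S_MINUS_GRID",
    "DEFAULT_N_EVENTS_GRID",
    "DEFAULT_EVENT_LENGTH_GRID",
]

#: Selection-coefficient grids of the default scenario sweep.
DEFAULT_S_PLUS_GRID = (0.5, 1.0, 2.0, 5.0)
DEFAULT_S_MINUS_GRID = (-0.1, -0.2, -0.5, -0.9)
DEFAULT_N_EVENTS_GRID = (1, 2, 3, 4)
DEFAULT_EVENT_LENGTH_GRID = (2, 3, 4)

WT_HOM = "wt_hom"
HET = "het"
TE_HOM = "te_hom"
DROUGHT = "drought"
NORMAL = "normal"


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulation scenario.

    Parameters
    ----------
    carrying_capacity
        Maximum population size ``K`` (default 100 diploids).
    selfing_rate
        Probability that an offspring is produced by self-fertilisation
        (default 0.99, the rate of *Arabidopsis thaliana*).
    generations
        Number of generations ``G`` to simulate (default 50).
    s_plus
        Selection coefficient of the insertion homozygote during drought.
    s_minus
        Selection coefficient of the insertion homozygote under normal
        conditions (negative in all scenarios of interest).
    dominance
        Dominance coefficient ``h`` of the insertion allele; 0 means fully
        recessive (the only value used in the scenario sweep).
    replicates
        Default number of replicate simulations per scenario.
    seed
        Root RNG seed; replicate streams are spawned from it.
    """

    carrying_capacity: int = 100
    selfing_rate: float = 0.99
    generations: int = 50
    s_plus: float = 0.0
    s_minus: float = 0.0
    dominance: float = 0.0
    replicates: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.carrying_capacity < 1:
            raise ValueError("carrying_capacity must be >= 1")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must lie in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for name, s in (("s_plus", self.s_plus), ("s_minus", self.s_minus)):
            if 1.0 + s < 0.0:
                raise ValueError(
                    f"{name}={s} gives negative homozygote fitness (requires s >= -1)"
                )


@dataclass(frozen=True)
class DroughtSchedule:
    """Set of generations (1-based) during which drought selection acts."""

    drought_generations: frozenset[int]
    n_events: int
    event_length: int

    def is_drought(self, generation: int) -> bool:
        return generation in self.drought_generations


#: A schedule with no drought at all (pure s_minus regime).
NO_DROUGHT = DroughtSchedule(frozenset(), 0, 0)


def build_drought_schedule(
    generations: int, n_events: int, event_length: int
) -> DroughtSchedule:
    """Place ``n_events`` drought blocks of ``event_length`` generations at
    regular intervals over a horizon of ``generations``.

    Event ``e`` (1-based) starts at generation ``round(e*G/(n_events+1))``,
    which spaces the events symmetrically with head and tail room.  Blocks
    must fall within ``1..G`` and be disjoint.
    """
    if n_events < 1 or event_length < 1:
        raise ValueError("n_events and event_length must be >= 1")
    if n_events * event_length > generations:
        raise ValueError("drought events do not fit into the simulated horizon")
    blocks: list[range] = []
    for e in range(1, n_events + 1):
        start = round(e * generations / (n_events + 1))
        start = max(start, 1)
        block = range(start, start + event_length)
        if block[-1] > generations:
            raise ValueError(
                f"event {e} (generations {block[0]}..{block[-1]}) exceeds horizon G={generations}"
            )
        if blocks and block[0] <= blocks[-1][-1]:
            raise ValueError(
                f"event {e} starting at generation {block[0]} overlaps the previous event"
            )
        blocks.append(block)
    gens = frozenset(itertools.chain.from_iterable(blocks))
    return DroughtSchedule(gens, n_events, event_length)


@dataclass(frozen=True)
class PopulationState:
    """Genotype counts of one generation."""

    generation: int
    n_wt_hom: int
    n_het: int
    n_te_hom: int

    @property
    def pop_size(self) -> int:
        return self.n_wt_hom + self.n_het + self.n_te_hom

    @property
    def allele_frequency(self) -> float:
        """Frequency of the insertion allele; 0.0 for an extinct population."""
        n = self.pop_size
        if n == 0:
            return 0.0
        return (self.n_het + 2 * self.n_te_hom) / (2 * n)

    @property
    def extinct(self) -> bool:
        return self.pop_size == 0


@dataclass
class ReplicateResult:
    """Outcome of a single replicate simulation."""

    final_frequency: float
    persisted: bool
    fixed: bool
    extinct_population: bool
    trajectory: pd.DataFrame | None = None


def genotype_fitness(genotype: str, condition: str, params: SimParams) -> float:
    """Fitness of a genotype under the given condition.

    Wild-type homozygotes have fitness 1; heterozygotes ``1 + h*s``;
    insertion homozygotes ``1 + s`` with ``s = s_plus`` during drought and
    ``s = s_minus`` otherwise.
    """
    if condition == DROUGHT:
        s = params.s_plus
    elif condition == NORMAL:
        s = params.s_minus
    else:
        raise ValueError(f"unknown condition {condition!r}")
    if genotype == WT_HOM:
        return 1.0
    if genotype == HET:
        w = 1.0 + params.dominance * s
    elif genotype == TE_HOM:
        w = 1.0 + s
    else:
        raise ValueError(f"unknown genotype {genotype!r}")
    if w < 0.0:
        raise ValueError(f"negative fitness {w} for {genotype} under {condition}")
    return w


def initialize_population(params: SimParams) -> PopulationState:
    """Founding population: one heterozygous carrier among ``K`` plants,
    i.e. a single insertion-bearing genome copy out of ``2K``."""
    k = params.carrying_capacity
    return PopulationState(generation=0, n_wt_hom=k - 1, n_het=1, n_te_hom=0)


def _offspring_distribution(
    state: PopulationState, condition: str, params: SimParams
) -> tuple[int, tuple[float, float, float]]:
    """Next population size and the genotype distribution of one offspring.

    Returns ``(n_next, (p_wt, p_het, p_te))``.  Offspring are i.i.d. given
    the parental state, so genotype counts in the next generation are
    multinomial with these probabilities.
    """
    w_wt = genotype_fitness(WT_HOM, condition, params)
    w_het = genotype_fitness(HET, condition, params)
    w_te = genotype_fitness(TE_HOM, condition, params)
    n = state.pop_size
    total_w = state.n_wt_hom * w_wt + state.n_het * w_het + state.n_te_hom * w_te
    wbar = total_w / n
    n_next = min(params.carrying_capacity, round(params.carrying_capacity * wbar))
    if n_next <= 0:
        return 0, (0.0, 0.0, 0.0)
    if total_w == 0.0:
        return 0, (0.0, 0.0, 0.0)
    # fitness-weighted probability of picking each parental genotype
    q_wt = state.n_wt_hom * w_wt / total_w
    q_het = state.n_het * w_het / total_w
    q_te = state.n_te_hom * w_te / total_w
    # selfing component: Mendelian segregation within one parent
    self_wt = q_wt + 0.25 * q_het
    self_het = 0.5 * q_het
    self_te = q_te + 0.25 * q_het
    # outcrossing component: each gamete carries the insertion with prob a
    a = 0.5 * q_het + q_te
    out_wt = (1.0 - a) ** 2
    out_het = 2.0 * a * (1.0 - a)
    out_te = a * a
    sigma = params.selfing_rate
    p = (
        sigma * self_wt + (1.0 - sigma) * out_wt,
        sigma * self_het + (1.0 - sigma) * out_het,
        sigma * self_te + (1.0 - sigma) * out_te,
    )
    return n_next, p


def next_generation(
    state: PopulationState,
    condition: str,
    params: SimParams,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance the population by one generation of hard selection,
    partially selfed reproduction and Mendelian transmission."""
    if state.pop_size < 1:
        raise ValueError("cannot reproduce an extinct population")
    n_next, p = _offspring_distribution(state, condition, params)
    g = state.generation + 1
    if n_next == 0:
        return PopulationState(g, 0, 0, 0)
    counts = rng.multinomial(n_next, p)
    return PopulationState(g, int(counts[0]), int(counts[1]), int(counts[2]))


def _deterministic_tail_extinct(
    params: SimParams, schedule: DroughtSchedule, start_gen: int
) -> bool:
    """Whether a population fixed for the insertion dies out in the remaining
    generations.  Once monomorphic, mean fitness depends only on the
    condition, so the hard-selection size update is deterministic."""
    k = params.carrying_capacity
    for g in range(start_gen, params.generations + 1):
        s = params.s_plus if schedule.is_drought(g) else params.s_minus
        if min(k, round(k * (1.0 + s))) <= 0:
            return True
    return False


def run_replicate(
    params: SimParams,
    schedule: DroughtSchedule,
    rng: np.random.Generator,
    record_trajectory: bool = False,
) -> ReplicateResult:
    """Simulate one replicate for ``params.generations`` generations.

    Drought fitness applies to reproduction *into* each scheduled
    generation.  Once the insertion allele is lost or fixed its frequency
    can no longer change, so the stochastic loop stops early unless a
    trajectory is requested; a fixed population may still go extinct
    deterministically under strongly negative ``s_minus``.
    """
    state = initialize_population(params)
    rows = []
    final_freq: float | None = None
    extinct = False
    for g in range(1, params.generations + 1):
        condition = DROUGHT if schedule.is_drought(g) else NORMAL
        state = next_generation(state, condition, params, rng)
        if record_trajectory:
            rows.append(
                (g, state.allele_frequency, state.pop_size, condition == DROUGHT)
            )
        if state.extinct:
            extinct = True
            final_freq = 0.0
            break
        freq = state.allele_frequency
        if not record_trajectory and freq in (0.0, 1.0):
            final_freq = freq
            if freq == 1.0:
                extinct = _deterministic_tail_extinct(params, schedule, g + 1)
                if extinct:
                    final_freq = 0.0
            break
    if final_freq is None:
        final_freq = state.allele_frequency
    persisted = (not extinct) and final_freq > 0.0
    fixed = (not extinct) and final_freq == 1.0
    trajectory = None
    if record_trajectory:
        trajectory = pd.DataFrame(
            rows, columns=["generation", "frequency", "pop_size", "drought"]
        )
    return ReplicateResult(
        final_frequency=final_freq if not extinct else 0.0,
        persisted=persisted,
        fixed=fixed,
        extinct_population=extinct,
        trajectory=trajectory,
    )


def run_replicates(
    params: SimParams,
    schedule: DroughtSchedule,
    n_replicates: int,
    seed: int | np.random.SeedSequence | None = None,
) -> list[ReplicateResult]:
    """Run ``n_replicates`` independent replicates, one spawned RNG stream
    each, so results are reproducible and order-independent."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = root.spawn(n_replicates)
    return [
        run_replicate(params, schedule, np.random.Generator(np.random.PCG64(c)))
        for c in children
    ]


def summarize_replicates(results: Sequence[ReplicateResult]) -> dict[str, float]:
    freqs = np.array([r.final_frequency for r in results])
    return {
        "replicates": len(results),
        "persistence_prob": float(np.mean([r.persisted for r in results])),
        "mean_final_freq": float(freqs.mean()),
        "fixation_prob": float(np.mean([r.fixed for r in results])),
        "extinction_prob": float(np.mean([r.extinct_population for r in results])),
    }


def run_grid(
    s_plus_values: Iterable[float] = DEFAULT_S_PLUS_GRID,
    s_minus_values: Iterable[float] = DEFAULT_S_MINUS_GRID,
    n_events_values: Iterable[int] = DEFAULT_N_EVENTS_GRID,
    event_length_values: Iterable[int] = DEFAULT_EVENT_LENGTH_GRID,
    replicates: int = 1000,
    seed: int | None = None,
    carrying_capacity: int = 100,
    selfing_rate: float = 0.99,
    generations: int = 50,
) -> pd.DataFrame:
    """Sweep the scenario grid (default 4 x 4 x 4 x 3 = 192 combinations,
    1000 replicates each) and summarise each cell.

    Returns a DataFrame with columns ``s_plus, s_minus, n_events,
    event_length, replicates, persistence_prob, mean_final_freq,
    fixation_prob``.  A fixed seed gives a bit-identical summary: one child
    RNG stream is spawned per grid cell and per replicate.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    combos = list(
        itertools.product(
            s_plus_values, s_minus_values, n_events_values, event_length_values
        )
    )
    if not combos:
        raise ValueError("empty parameter grid")
    root = np.random.SeedSequence(seed)
    cell_seeds = root.spawn(len(combos))
    rows = []
    for (s_plus, s_minus, n_events, event_length), cell_seed in zip(
        combos, cell_seeds
    ):
        params = SimParams(
            carrying_capacity=carrying_capacity,
            selfing_rate=selfing_rate,
            generations=generations,
            s_plus=s_plus,
            s_minus=s_minus,
        )
        schedule = build_drought_schedule(generations, n_events, event_length)
        results = run_replicates(params, schedule, replicates, cell_seed)
        summary = summarize_replicates(results)
        rows.append(
            {
                "s_plus": s_plus,
                "s_minus": s_minus,
                "n_events": n_events,
                "event_length": event_length,
                "replicates": replicates,
                "persistence_prob": summary["persistence_prob"],
                "mean_final_freq": summary["mean_final_freq"],
                "fixation_prob": summary["fixation_prob"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Exact Markov-chain oracle (small K)
# ---------------------------------------------------------------------------

_MAX_ORACLE_K = 6


def _enumerate_states(k: int) -> list[tuple[int, int, int]]:
    """All genotype-count compositions with total size 0..K (extinct first)."""
    states = [(0, 0, 0)]
    for n in range(1, k + 1):
        for n_wt in range(n + 1):
            for n_het in range(n - n_wt + 1):
                states.append((n_wt, n_het, n - n_wt - n_het))
    return states


def _multinomial_pmf(counts: tuple[int, int, int], p: tuple[float, ...]) -> float:
    n = sum(counts)
    coef = math.factorial(n)
    prob = 1.0
    for c, pi in zip(counts, p):
        coef //= math.factorial(c)
        if c > 0:
            if pi == 0.0:
                return 0.0
            prob *= pi**c
    return coef * prob


def exact_chain_distribution(
    params: SimParams, schedule: DroughtSchedule
) -> dict[tuple[int, int, int], float]:
    """Exact distribution over genotype-count states after ``G`` generations,
    by transition-matrix multiplication with the same reproduction rules as
    the stochastic simulator.  Tractable only for small ``K``; serves as an
    independent validation oracle for the Monte-Carlo engine.
    """
    k = params.carrying_capacity
    if k > _MAX_ORACLE_K:
        raise ValueError(
            f"exact chain enumeration supports K <= {_MAX_ORACLE_K}, got {k}"
        )
    states = _enumerate_states(k)
    index = {s: i for i, s in enumerate(states)}
    n_states = len(states)

    def transition_matrix(condition: str) -> np.ndarray:
        t = np.zeros((n_states, n_states))
        t[0, 0] = 1.0  # extinction is absorbing
        for s, i in index.items():
            if i == 0:
                continue
            st = PopulationState(0, *s)
            n_next, p = _offspring_distribution(st, condition, params)
            if n_next == 0:
                t[i, 0] = 1.0
                continue
            for dest in states:
                if sum(dest) != n_next:
                    continue
                t[i, index[dest]] = _multinomial_pmf(dest, p)
        return t

    t_normal = transition_matrix(NORMAL)
    t_drought = transition_matrix(DROUGHT)
    dist = np.zeros(n_states)
    init = initialize_population(params)
    dist[index[(init.n_wt_hom, init.n_het, init.n_te_hom)]] = 1.0
    for g in range(1, params.generations + 1):
        t = t_drought if schedule.is_drought(g) else t_normal
        dist = dist @ t
    return {s: float(dist[i]) for s, i in index.items()}
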