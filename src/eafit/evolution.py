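"""Interactive evolutionary loop for frequency-map fitting.

The search is a small-budget hybrid of a genetic algorithm and an evolution
strategy, sized for a listener who can only sit through ~13 speech tests in
one session: 4 randomly initialized parent maps, then 3 generations of 3
children each, bred by 2-tournament selection (with replacement), per-locus
uniform crossover of upper band edges, and Gaussian mutation (probability
0.2 per band, sigma = 0.1 x band width), with every candidate repaired onto
the device grid.  Survivor selection is elitist: the breeding pool for each
generation is the 4 highest-scoring maps among *all* maps generated so far,
so the pool for generation 2 is drawn from 7 candidates, for generation 3
from 10, and the final winner from all 13.  Fitness is a word recognition
score in noise out of ten, supplied by a callback — a human listener at the
audiometer or the simulated listener of :mod:`eafit.fitness`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from .fmap_core import (
    ConstraintError,
    DeviceProfile,
    ExplorationDomain,
    FrequencyMap,
    chain_and_repair,
    make_exploration_domain,
)

__all__ = [
    "EvolutionConfig",
    "SessionAborted",
    "SessionState",
    "StateError",
    "crossover",
    "init_parents",
    "make_generation",
    "mutate",
    "run_session",
    "tournament_select",
]


class StateError(RuntimeError):
    """An operation was called on a session in the wrong state."""


class SessionAborted(RuntimeError):
    """Raised by a fitness callback when the listener stops the session."""


@dataclass(frozen=True)
class EvolutionConfig:
    """Tunables of the search; defaults are the published protocol.

    ``mutation_sigma_frac`` scales the Gaussian step by the band width of the
    chained candidate ("current") or of the device default ("default").
    ``tournament_win_prob`` is the probability that the better-scoring of the
    drawn pair wins (1.0 = deterministic tournament).
    """

    n_parents: int = 4
    children_per_generation: int = 3
    n_generations: int = 3
    mutation_prob: float = 0.2
    mutation_sigma_frac: float = 0.1
    domain_expansion: float = 1.2
    tournament_size: int = 2
    rng_seed: int = 0
    tournament_win_prob: float = 1.0
    crossover_mix: float = 0.5
    sigma_reference: str = "current"  # or "default"

    def __post_init__(self):
        if min(self.n_parents, self.children_per_generation,
               self.n_generations, self.tournament_size) < 1:
            raise ValueError("population counts must be >= 1")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must lie in [0, 1]")
        if self.mutation_sigma_frac <= 0:
            raise ValueError("mutation_sigma_frac must be > 0")
        if self.sigma_reference not in ("current", "default"):
            raise ValueError("sigma_reference must be 'current' or 'default'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "EvolutionConfig":
        return cls(**d)


def _stream(seed: int, op: int) -> np.random.Generator:
    # one independent child stream per logical operation -> resumable sessions
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(op,)))


def _score_value(result) -> float:
    """Accept a bare number or anything exposing ``score_out_of_ten``."""
    if result is None:
        raise StateError("fitness callback returned no score")
    v = getattr(result, "score_out_of_ten", result)
    return float(v)


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def init_parents(
    domain: ExplorationDomain,
    profile: DeviceProfile,
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> list[FrequencyMap]:
    """Random initial population, uniform within the feasible box.

    Upper edges are sampled apex-to-base, each uniformly on the part of its
    exploration interval still feasible given the predecessor (the band must
    keep its minimum width), then repaired onto the device grid.
    """
    parents = []
    for j in range(config.n_parents):
        prev = profile.global_f_min
        vec = []
        for e, (lo, hi) in zip(domain.electrodes, domain.intervals):
            lower = max(prev + profile.min_band_width_hz, lo)
            if lower > hi:
                raise ConstraintError(
                    f"infeasible exploration domain at electrode {e}", electrode=e
                )
            v = rng.uniform(lower, hi)
            vec.append(v)
            prev = v
        fmap = chain_and_repair(
            vec, profile, domain, id=f"P{j + 1}", origin="parent", generation=0
        )
        fmap.creation_index = j
        parents.append(fmap)
    return parents


def tournament_select(
    pool: Sequence[FrequencyMap],
    rng: np.random.Generator,
    config: EvolutionConfig,
) -> FrequencyMap:
    """Pick one breeding parent: best of ``tournament_size`` drawn with replacement.

    Score ties among the drawn candidates are broken uniformly at random.
    With ``tournament_win_prob`` < 1 the best-of-draw wins only with that
    probability (otherwise a uniformly chosen non-best candidate is returned).
    """
    if not pool:
        raise StateError("tournament pool is empty")
    for ind in pool:
        if ind.score is None:
            raise StateError(f"unscored individual in tournament pool: {ind.id}")
    idx = rng.integers(0, len(pool), size=config.tournament_size)
    drawn = [pool[i] for i in idx]
    best_score = max(d.score for d in drawn)
    winners = [d for d in drawn if d.score == best_score]
    losers = [d for d in drawn if d.score != best_score]
    if losers and config.tournament_win_prob < 1.0:
        if rng.random() >= config.tournament_win_prob:
            return losers[int(rng.integers(0, len(losers)))]
    return winners[int(rng.integers(0, len(winners)))]


def crossover(
    parent_a: FrequencyMap,
    parent_b: FrequencyMap,
    rng: np.random.Generator,
    mix: float = 0.5,
) -> list[float]:
    """Per-locus uniform crossover of upper band edges.

    Each electrode's upper edge is copied verbatim from parent a with
    probability ``mix``, else from parent b; edges are never averaged.  The
    returned raw vector may be non-monotone — repair happens downstream.
    """
    if parent_a.electrodes != parent_b.electrodes:
        raise StateError("crossover parents live on different electrode sets")
    a = parent_a.f_high
    b = parent_b.f_high
    take_a = rng.random(len(a)) < mix
    return [a[i] if take_a[i] else b[i] for i in range(len(a))]


def mutate(
    f_high_vector: Sequence[float],
    domain: ExplorationDomain,
    profile: DeviceProfile,
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> list[float]:
    """Gaussian mutation of upper edges, clamped to the exploration domain.

    Each band independently mutates with probability ``mutation_prob``; the
    step is N(0, (sigma_frac x band width)^2) where the width is that of the
    chained, repaired candidate (lower edges follow upper edges by chaining,
    so perturbing the upper edge alone spans the whole search space without
    creating overlaps).
    """
    if len(f_high_vector) != len(domain.electrodes):
        raise StateError("mutation vector length does not match active electrodes")
    if config.sigma_reference == "default":
        widths = profile.active_default_map().widths
    else:
        widths = chain_and_repair(f_high_vector, profile, domain).widths
    out = []
    for v, w, (lo, hi) in zip(f_high_vector, widths, domain.intervals):
        v = float(v)
        if rng.random() < config.mutation_prob:
            v = v + rng.normal(0.0, config.mutation_sigma_frac * w)
        out.append(min(max(v, lo), hi))
    return out


# ---------------------------------------------------------------------------
# Session bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class SessionState:
    """Event-sourced record of one fitting session.

    Individuals are labeled P1..P4 then C1..C9 in creation order.  Randomness
    is drawn from per-operation substreams of ``config.rng_seed`` (operation
    0 initializes the parents; operation k >= 1 creates child k), so a session
    resumed from its event log continues bit-identically.
    """

    profile: DeviceProfile
    config: EvolutionConfig
    domain: ExplorationDomain
    individuals: list[FrequencyMap] = field(default_factory=list)
    survivor_ids: list[str] = field(default_factory=list)
    generation: int = 0  # completed breeding generations
    events: list[dict] = field(default_factory=list)

    # -- construction --------------------------------------------------------
    @classmethod
    def start(cls, profile: DeviceProfile, config: EvolutionConfig) -> "SessionState":
        domain = make_exploration_domain(profile, expansion=config.domain_expansion)
        state = cls(profile=profile, config=config, domain=domain)
        state.events.append(
            {"kind": "init", "seed": config.rng_seed,
             "profile": profile.to_dict(), "config": config.to_dict()}
        )
        parents = init_parents(domain, profile, config, _stream(config.rng_seed, 0))
        for p in parents:
            state.individuals.append(p)
            state.events.append(_propose_event(p))
        return state

    # -- queries -------------------------------------------------------------
    @property
    def n_children(self) -> int:
        return len(self.individuals) - self.config.n_parents

    @property
    def evaluated_count(self) -> int:
        return sum(1 for i in self.individuals if i.score is not None)

    @property
    def complete(self) -> bool:
        total = (self.config.n_parents
                 + self.config.n_generations * self.config.children_per_generation)
        return len(self.individuals) == total and not self.pending()

    def pending(self) -> list[FrequencyMap]:
        return [i for i in self.individuals if i.score is None]

    def get(self, map_id: str) -> FrequencyMap:
        for i in self.individuals:
            if i.id == map_id:
                return i
        raise KeyError(f"no individual with id {map_id!r}")

    def scored(self) -> list[FrequencyMap]:
        return [i for i in self.individuals if i.score is not None]

    # -- transitions ---------------------------------------------------------
    def record_score(self, map_id: str, score) -> None:
        ind = self.get(map_id)
        if ind.score is not None:
            raise StateError(f"{map_id} already scored")
        ind.score = _score_value(score)
        self.events.append({"kind": "score", "id": map_id, "score": ind.score})

    def _recompute_survivors(self) -> None:
        """Elitist pool: top ``n_parents`` by score over all generated maps.

        Ties at the pool boundary break toward the earlier generation, then
        the earlier creation index (stable sort on creation order).
        """
        ranked = sorted(
            self.scored(), key=lambda i: (-i.score, i.generation, i.creation_index)
        )
        pool = ranked[: self.config.n_parents]
        self.survivor_ids = [i.id for i in pool]
        self.events.append(
            {"kind": "survivors", "pool": list(self.survivor_ids),
             "source_size": len(self.scored())}
        )

    def next_child(self) -> FrequencyMap:
        """Breed, repair and propose the next child (unscored).

        Requires every earlier individual to be scored.  At a generation
        boundary the survivor pool is first recomputed from all individuals.
        """
        if self.pending():
            raise StateError("score all pending maps before breeding the next child")
        if self.complete:
            raise StateError("session already produced all generations")
        k = self.n_children  # 0-based index of the child about to be created
        if k % self.config.children_per_generation == 0:
            self._recompute_survivors()
        pool = [self.get(i) for i in self.survivor_ids]
        rng = _stream(self.config.rng_seed, k + 1)
        pa = tournament_select(pool, rng, self.config)
        pb = tournament_select(pool, rng, self.config)
        vec = crossover(pa, pb, rng, mix=self.config.crossover_mix)
        vec = mutate(vec, self.domain, self.profile, self.config, rng)
        gen = k // self.config.children_per_generation + 1
        child = chain_and_repair(
            vec, self.profile, self.domain,
            id=f"C{k + 1}", origin="child", generation=gen,
        )
        child.creation_index = self.config.n_parents + k
        self.individuals.append(child)
        self.generation = gen
        self.events.append(_propose_event(child, parents=[pa.id, pb.id]))
        return child

    # -- final selection -----------------------------------------------------
    def best_candidates(self) -> list[FrequencyMap]:
        """All scored maps sharing the maximum score (possibly several)."""
        scored = self.scored()
        if not scored:
            raise StateError("no scored individuals yet")
        top = max(i.score for i in scored)
        return [i for i in scored if i.score == top]

    def select_best(self, policy: str = "latest") -> FrequencyMap:
        """Final winner among the top scorers.

        ``latest`` (batch default) takes the most recently generated of the
        tied maps, standing in for the listener's sound-quality preference;
        ``earliest`` takes the first.  Interactive front ends should present
        :meth:`best_candidates` and let the listener choose.
        """
        cands = self.best_candidates()
        if policy == "latest":
            best = max(cands, key=lambda i: i.creation_index)
        elif policy == "earliest":
            best = min(cands, key=lambda i: i.creation_index)
        else:
            raise ValueError(f"unknown tie-break policy: {policy!r}")
        self.events.append(
            {"kind": "select_best", "id": best.id, "tied": [c.id for c in cands]}
        )
        return best

    def transcript(self) -> list[tuple[str, float | None]]:
        return [(i.id, i.score) for i in self.individuals]


def _propose_event(fmap: FrequencyMap, parents: list[str] | None = None) -> dict:
    ev = {"kind": "propose", "id": fmap.id, "origin": fmap.origin,
          "generation": fmap.generation, "creation_index": fmap.creation_index,
          "electrodes": list(fmap.electrodes),
          "bands": [[lo, hi] for lo, hi in fmap.bands]}
    if parents:
        ev["parents"] = parents
    return ev


def make_generation(state: SessionState, fitness: Callable) -> SessionState:
    """Breed and evaluate one full generation of children in place.

    Children are created and scored one at a time (selection, crossover,
    mutation, repair, then the fitness callback), as in a live fitting
    session.  Raises :class:`StateError` if maps are still unscored.
    """
    for _ in range(state.config.children_per_generation):
        child = state.next_child()
        state.record_score(child.id, fitness(child))
    return state


def run_session(
    profile: DeviceProfile,
    config: EvolutionConfig,
    fitness: Callable,
    tie_break: str = "latest",
) -> tuple[FrequencyMap, SessionState]:
    """Run a complete fitting session; return (best map, full state).

    ``fitness`` maps a :class:`FrequencyMap` to a word recognition score out
    of ten (a number or a :class:`~eafit.fitness.WRSResult`).  If the
    callback raises :class:`SessionAborted` the session stops where it is
    (mirroring listeners who abandon mid-protocol) and the best map among
    those already scored is returned with the partial state.
    """
    state = SessionState.start(profile, config)
    try:
        for p in list(state.individuals):
            state.record_score(p.id, fitness(p))
        while not state.complete:
            child = state.next_child()
            state.record_score(child.id, fitness(child))
    except SessionAborted:
        state.events.append({"kind": "abort", "evaluated": state.evaluated_count})
    best = state.select_best(policy=tie_break)
    return best, state
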