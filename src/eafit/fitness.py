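"""Fitness oracles: word-recognition scoring by human or simulated listener.

In the clinic, every candidate map is evaluated by a speech-in-noise test: a
fresh list of 10 monosyllabic words at the listener's fixed signal-to-noise
ratio, scored as words correct out of ten (initial and final evaluations use
20-word lists, still reported out of ten, hence half-point scores).  That
human oracle is :func:`interactive_fitness`.

For automated testing, :class:`SimulatedListener` stands in for the human: a
synthetic construct (no such data exist in print) whose recognition
probability decays logistically with the weighted octave distance between a
candidate map's per-electrode center frequencies and a hidden ideal map.
Apical (low-frequency) electrodes carry geometrically larger weights, so the
simulated optimum — like bimodal listeners in practice — is most sensitive to
low-frequency allocation.  Scores are Binomial(n_words, p) draws, or
round(n_words * p) in noise-free mode.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .evolution import (
    EvolutionConfig,
    SessionAborted,
    StateError,
    init_parents,
    run_session,
)
from .fmap_core import (
    DeviceProfile,
    FrequencyMap,
    load_profile,
    make_exploration_domain,
)

__all__ = [
    "WRSResult",
    "SimulatedListener",
    "interactive_fitness",
    "mismatch",
    "recovery_experiment",
    "simulate_wrs",
]

VALID_SNR_DB = (-10, -7, -5, 0, 5, 10)


@dataclass(frozen=True)
class WRSResult:
    """One word-recognition-score measurement in noise.

    ``n_words`` is 10 for intermediate (per-map) tests and 20 for the initial
    and final evaluations; all scores are reported out of ten, so a 20-word
    test yields half-point granularity.  ``snr_db`` is carried as metadata
    (each listener keeps one fixed SNR throughout).
    """

    score: float
    n_words: int = 10
    snr_db: float | None = None

    def __post_init__(self):
        if not 0 <= self.score <= self.n_words:
            raise ValueError(f"score {self.score} outside [0, {self.n_words}]")

    @property
    def score_out_of_ten(self) -> float:
        return 10.0 * self.score / self.n_words


def _geometric_weights(n: int, decay: float = 0.7) -> tuple[float, ...]:
    w = np.asarray([decay**i for i in range(n)], dtype=float)
    return tuple(w / w.sum())


@dataclass
class SimulatedListener:
    """Synthetic bimodal listener with a hidden ideal frequency map.

    Recognition probability is ``p = 1 / (1 + exp(-(a - b * d)))`` where
    ``d`` is the apically-weighted octave distance between the candidate's
    and the ideal's center frequencies.  With the defaults (a=4, b=25 per
    octave, apical decay 0.7) the ideal map scores ~10/10 noise-free while
    random in-domain maps land in the clinical mid-range; the steep slope
    reflects that the 1.2x exploration domain only spans fractions of an
    octave.
    """

    ideal_map: FrequencyMap
    apical_weights: tuple[float, ...] = ()
    slope_a: float = 4.0
    slope_b: float = 25.0
    noise_mode: str = "binomial"  # or "noise_free"
    snr_db: float = 0.0
    rng_seed: int = 0
    _rng: np.random.Generator | None = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.ideal_map.electrodes)
        if not self.apical_weights:
            self.apical_weights = _geometric_weights(n)
        if len(self.apical_weights) != n:
            raise ValueError("one apical weight per active electrode required")
        w = np.asarray(self.apical_weights, dtype=float)
        if (w < 0).any() or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("apical weights must be non-negative and sum to 1")
        if self.slope_b <= 0:
            raise ValueError("slope_b must be > 0")
        if self.noise_mode not in ("binomial", "noise_free"):
            raise ValueError(f"unknown noise mode: {self.noise_mode!r}")
        if self._rng is None:
            self._rng = np.random.default_rng(self.rng_seed)

    # -- construction --------------------------------------------------------
    @classmethod
    def random(
        cls,
        profile: DeviceProfile,
        seed: int,
        *,
        decay: float = 0.7,
        slope_a: float = 4.0,
        slope_b: float = 25.0,
        noise_mode: str = "binomial",
        domain_expansion: float = 1.2,
    ) -> "SimulatedListener":
        """Listener whose hidden ideal map is drawn uniformly in the domain."""
        domain = make_exploration_domain(profile, expansion=domain_expansion)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                           spawn_key=(0xEA,)))
        cfg = EvolutionConfig(n_parents=1, rng_seed=seed)
        ideal = init_parents(domain, profile, cfg, rng)[0]
        ideal.id = "ideal"
        return cls(
            ideal_map=ideal,
            apical_weights=_geometric_weights(len(ideal.electrodes), decay),
            slope_a=slope_a,
            slope_b=slope_b,
            noise_mode=noise_mode,
            rng_seed=seed,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulatedListener":
        d = json.loads(Path(path).read_text())
        return cls(
            ideal_map=FrequencyMap.from_dict(d["ideal_map"]),
            apical_weights=tuple(d.get("apical_weights", ())),
            slope_a=float(d.get("slope_a", 4.0)),
            slope_b=float(d.get("slope_b", 25.0)),
            noise_mode=d.get("noise_mode", "binomial"),
            snr_db=float(d.get("snr_db", 0.0)),
            rng_seed=int(d.get("rng_seed", 0)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "ideal_map": self.ideal_map.to_dict(),
            "apical_weights": list(self.apical_weights),
            "slope_a": self.slope_a,
            "slope_b": self.slope_b,
            "noise_mode": self.noise_mode,
            "snr_db": self.snr_db,
            "rng_seed": self.rng_seed,
        }, indent=1))

    # -- psychometrics -------------------------------------------------------
    def mismatch(self, fmap: FrequencyMap) -> float:
        return mismatch(self, fmap)

    def recognition_probability(self, fmap: FrequencyMap) -> float:
        d = self.mismatch(fmap)
        return 1.0 / (1.0 + math.exp(-(self.slope_a - self.slope_b * d)))

    def score(self, fmap: FrequencyMap, n_words: int = 10,
              rng: np.random.Generator | None = None) -> WRSResult:
        return simulate_wrs(self, fmap, n_words, rng)

    def fitness(self, n_words: int = 10) -> Callable[[FrequencyMap], WRSResult]:
        """Fitness callback for :func:`eafit.evolution.run_session`."""
        return lambda fmap: self.score(fmap, n_words=n_words)


def mismatch(listener: SimulatedListener, fmap: FrequencyMap) -> float:
    """Apically-weighted octave distance between map and hidden ideal.

    ``sum_i w_i * |log2 Fc_i(map) - log2 Fc_i(ideal)|`` over active
    electrodes; symmetric, zero iff the center frequencies coincide.
    """
    if fmap.electrodes != listener.ideal_map.electrodes:
        raise StateError("candidate and ideal maps live on different electrode sets")
    fc = np.asarray(fmap.center_frequencies())
    fi = np.asarray(listener.ideal_map.center_frequencies())
    w = np.asarray(listener.apical_weights)
    return float(np.sum(w * np.abs(np.log2(fc) - np.log2(fi))))


def simulate_wrs(
    listener: SimulatedListener,
    fmap: FrequencyMap,
    n_words: int = 10,
    rng: np.random.Generator | None = None,
) -> WRSResult:
    """Simulated word-recognition score for one candidate map.

    Binomial mode draws ``score ~ Binomial(n_words, p)``; noise-free mode
    returns ``round(n_words * p)`` — useful for deterministic property tests.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    p = listener.recognition_probability(fmap)
    if listener.noise_mode == "noise_free":
        score = round(n_words * p)
    else:
        gen = rng if rng is not None else listener._rng
        score = int(gen.binomial(n_words, p))
    return WRSResult(score=score, n_words=n_words, snr_db=listener.snr_db)


def interactive_fitness(
    input_stream=None,
    output_stream=None,
    n_words: int = 10,
    snr_db: float | None = None,
) -> Callable[[FrequencyMap], WRSResult]:
    """Fitness callback that asks a human for each map's score.

    Prints the candidate's band table, then prompts for an integer between 0
    and ``n_words``; invalid entries re-prompt, end-of-input raises
    :class:`SessionAborted` so the session can be serialized and resumed.
    No feedback about previous maps or scores is given to the listener.
    """
    import sys

    fin = input_stream if input_stream is not None else sys.stdin
    fout = output_stream if output_stream is not None else sys.stderr

    def ask(fmap: FrequencyMap) -> WRSResult:
        fout.write(f"\nCandidate map {fmap.id} (generation {fmap.generation}):\n")
        fout.write("  electrode   f_low (Hz)   f_high (Hz)\n")
        for e, (lo, hi) in zip(fmap.electrodes, fmap.bands):
            fout.write(f"  {e:9d}   {lo:10.0f}   {hi:11.0f}\n")
        while True:
            fout.write(f"Words correct for {fmap.id} (0-{n_words}): ")
            fout.flush()
            line = fin.readline()
            if line == "":
                fout.write("\n[input closed - session aborted, state is resumable]\n")
                raise SessionAborted(f"input closed while scoring {fmap.id}")
            try:
                v = int(line.strip())
            except ValueError:
                fout.write(f"  please enter an integer 0-{n_words}\n")
                continue
            if not 0 <= v <= n_words:
                fout.write(f"  score must be between 0 and {n_words}\n")
                continue
            return WRSResult(score=v, n_words=n_words, snr_db=snr_db)

    return ask


def recovery_experiment(
    profile: DeviceProfile | str = "medel12",
    n_seeds: int = 200,
    n_words: int = 10,
    noise_mode: str = "binomial",
    base_seed: int = 0,
    config: EvolutionConfig | None = None,
    listener_kwargs: dict | None = None,
):
    """Paired optimization-gain simulation over many seeded sessions.

    For each seed a fresh simulated listener (new hidden ideal map) is drawn
    and a full fitting session is run.  Per seed the best-of-session measured
    score is compared with the best among the four random parents, and the
    hidden mismatch of the finally selected map with the mismatch of the best
    parent — the quantity the optimizer is actually supposed to reduce.

    Returns a pandas DataFrame with one row per seed and columns
    ``best_parent_wrs, best_session_wrs, parent_mismatch, selected_mismatch``.
    """
    import pandas as pd

    if isinstance(profile, str):
        profile = load_profile(profile)
    cfg = config or EvolutionConfig()
    rows = []
    for k in range(n_seeds):
        seed = base_seed + k
        listener = SimulatedListener.random(
            profile, seed=seed, noise_mode=noise_mode, **(listener_kwargs or {})
        )
        session_cfg = EvolutionConfig(**{**cfg.to_dict(), "rng_seed": seed})
        best, state = run_session(profile, session_cfg,
                                  listener.fitness(n_words=n_words))
        parents = [i for i in state.individuals if i.origin == "parent"]
        best_parent = max(parents, key=lambda i: i.score)
        rows.append({
            "seed": seed,
            "best_parent_wrs": best_parent.score,
            "best_session_wrs": best.score,
            "parent_mismatch": listener.mismatch(best_parent),
            "selected_mismatch": listener.mismatch(best),
        })
    return pd.DataFrame(rows)
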