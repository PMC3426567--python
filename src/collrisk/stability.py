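"""Persistence of homogeneous behavioral populations under mutation-selection.

A population is initialized with Z copies of an unconditional genome that
realizes a focal behavior (e.g. the 'fair rational' 0000022222), then
evolved under the usual Wright-Fisher dynamics.  Persistence time is the
first generation at which fewer than Z/2 individuals still realize the
focal behavior — the natural point at which another behavior can take
over.  Every behavior is eventually lost to mutation, selection and drift;
stable behaviors just take much longer.

Focal membership is judged on *realized* behavior, not genome identity:
threshold loci drift neutrally in unconditional genomes, so genome
equality would undercount.  An individual's realized behavior is read from
the first game it played that generation; the rare individual sampled into
no game is counted as still-focal (it was not observed to deviate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import analysis
from .evolution import EvoConfig, PopulationState, _generation_games, wright_fisher_step
from .game_core import GameConfig, StrategyGenome

__all__ = [
    "FIVE_BEHAVIORS",
    "StabilityResult",
    "behavior_to_strategy",
    "measure_persistence",
    "results_to_dataframe",
]

# the five canonical ten-round focal behaviors of the stability assays
FIVE_BEHAVIORS: dict[str, tuple[int, ...]] = {
    "defector": (0,) * 10,
    "altruist": (2,) * 10,
    "fair_rational": (0, 0, 0, 0, 0, 2, 2, 2, 2, 2),
    "fair_naive": (1,) * 10,
    "reverse_fair_rational": (2, 2, 2, 2, 2, 0, 0, 0, 0, 0),
}


@dataclass(frozen=True)
class StabilityResult:
    """Persistence of one focal behavior in one replicate.

    ``censored`` flags replicates that still held a focal majority when
    the generation cap was reached.
    """

    behavior: str
    persistence_time: int
    seed: int
    censored: bool


def behavior_to_strategy(behavior: Sequence[int], threshold: float = 0.5) -> StrategyGenome:
    """Unconditional genome realizing ``behavior`` in any group.

    Both contribution levels equal the behavior's round value, so the
    threshold never matters; it is set to 0.5 by convention.
    """
    b = np.asarray(behavior, dtype=np.int64)
    return StrategyGenome(np.full(len(b), threshold), b.copy(), b.copy())


def measure_persistence(
    behavior: Sequence[int],
    game: GameConfig,
    evo: EvoConfig,
    replicates: int = 1,
    cap: int = 10_000,
) -> list[StabilityResult]:
    """Persistence times of a homogeneous focal population, one per replicate.

    Replicate k runs on its own generator seeded ``evo.seed + k``.  Each
    replicate starts from Z identical unconditional genomes, evolves, and
    records the first generation (1-based) at which fewer than Z/2
    individuals realized the focal behavior; right-censored at ``cap``.
    """
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    b = tuple(int(x) for x in behavior)
    if len(b) != game.rounds:
        raise ValueError("behavior length must equal the number of rounds")
    if max(b) > game.contribution_cap:
        raise ValueError("behavior exceeds the per-round contribution cap")
    base = game.contribution_cap + 1
    focal_code = int(analysis.encode_behaviors(np.array([b]), base)[0])
    label = analysis.behavior_to_string(b)
    seed_genome = behavior_to_strategy(b)
    z = evo.population_size
    results = []
    for rep in range(replicates):
        rng = np.random.default_rng(evo.seed + rep)
        thr = np.tile(seed_genome.thresholds, (z, 1))
        ab = np.tile(seed_genome.above, (z, 1))
        be = np.tile(seed_genome.below, (z, 1))
        persistence, censored = cap, True
        for gen in range(1, cap + 1):
            mean_payoffs, batch = _generation_games(thr, ab, be, game, evo, rng)
            groups = batch["groups"]
            codes = analysis.encode_behaviors(
                batch["contributions"].reshape(-1, game.rounds), base
            )
            flat_players = groups.ravel()
            uniq, first_idx = np.unique(flat_players, return_index=True)
            ind_codes = np.full(z, focal_code, dtype=np.int64)  # unplayed stay focal
            ind_codes[uniq] = codes[first_idx]
            if int(np.count_nonzero(ind_codes == focal_code)) < z / 2:
                persistence, censored = gen, False
                break
            pop = PopulationState(thr, ab, be, mean_payoffs, gen)
            nxt = wright_fisher_step(pop, evo, rng, c_max=game.contribution_cap)
            thr, ab, be = nxt.thresholds, nxt.above, nxt.below
        results.append(StabilityResult(label, persistence, evo.seed + rep, censored))
    return results


def results_to_dataframe(results: Sequence[StabilityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "behavior": r.behavior,
                "persistence_time": r.persistence_time,
                "seed": r.seed,
                "censored": r.censored,
            }
            for r in results
        ]
    )
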