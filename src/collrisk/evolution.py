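"""Wright-Fisher mutation-selection dynamics over strategy populations.

Each generation, G games are played among groups of M individuals sampled
uniformly (without replacement within a game) from a well-mixed population
of size Z.  An individual's payoff is the mean over the games it played;
payoff maps to fitness exponentially, f = exp(w * payoff), where w is the
intensity of selection.  The next generation is drawn by the Wright-Fisher
process (Z offspring, parent probability proportional to fitness) and each
offspring locus mutates independently with probability mu: thresholds
receive Gaussian noise (SD sigma, clamped to [0, 1]), contribution levels
are resampled uniformly from {0..c_max}.

The engine keeps the whole population as flat numpy arrays; the
StrategyGenome objects of :mod:`collrisk.game_core` are materialized only
on demand through :attr:`PopulationState.genomes`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import analysis
from .game_core import (
    ConfigurationError,
    GameConfig,
    StrategyGenome,
    _play_batch,
    _play_batch_sequential,
)

__all__ = [
    "EvoConfig",
    "PopulationState",
    "EvolutionResult",
    "initialize_population",
    "fitness",
    "play_generation",
    "wright_fisher_step",
    "mutate",
    "run_evolution",
]


@dataclass(frozen=True)
class EvoConfig:
    """Population-level parameters of the mutation-selection process.

    ``games_per_generation`` defaults to the population size, so each
    individual plays M games per generation on average.  Long-run
    statistics exclude the first ``burn_in`` generations.
    """

    population_size: int = 100
    games_per_generation: int | None = None
    selection_intensity: float = 0.4
    error_prob: float = 0.01
    threshold_noise_sd: float = 0.15
    generations: int = 3000
    burn_in: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ValueError("population_size must be at least 1")
        g = (
            self.population_size
            if self.games_per_generation is None
            else int(self.games_per_generation)
        )
        if g < 0:
            raise ValueError("games_per_generation must be non-negative")
        if self.selection_intensity < 0:
            raise ValueError("selection_intensity must be non-negative")
        if not 0.0 <= self.error_prob <= 1.0:
            raise ValueError("error_prob must lie in [0, 1]")
        if self.threshold_noise_sd <= 0:
            raise ValueError("threshold_noise_sd must be positive")
        if self.generations < 1:
            raise ValueError("generations must be at least 1")
        if not 0 <= self.burn_in < self.generations:
            raise ValueError("burn_in must lie in [0, generations)")
        object.__setattr__(self, "games_per_generation", g)


@dataclass
class PopulationState:
    """Z genomes as flat arrays plus the per-generation mean payoffs."""

    thresholds: np.ndarray  # (Z, R) float in [0, 1]
    above: np.ndarray       # (Z, R) int
    below: np.ndarray       # (Z, R) int
    payoffs: np.ndarray     # (Z,) mean payoff over games played this generation
    generation: int = 0

    @property
    def size(self) -> int:
        return len(self.thresholds)

    @property
    def genomes(self) -> list[StrategyGenome]:
        return [
            StrategyGenome(self.thresholds[i], self.above[i], self.below[i])
            for i in range(self.size)
        ]

    @classmethod
    def from_genomes(cls, genomes: Sequence[StrategyGenome], generation: int = 0):
        thr = np.stack([g.thresholds for g in genomes])
        ab = np.stack([g.above for g in genomes])
        be = np.stack([g.below for g in genomes])
        return cls(thr, ab, be, np.zeros(len(genomes)), generation)


def initialize_population(
    evo: EvoConfig, game: GameConfig, rng: np.random.Generator
) -> PopulationState:
    """Random initial population: actions uniform on {0..c_max}, thresholds
    uniform on [0, 1]."""
    z, r = evo.population_size, game.rounds
    cap = game.contribution_cap
    return PopulationState(
        thresholds=rng.random((z, r)),
        above=rng.integers(0, cap + 1, (z, r)),
        below=rng.integers(0, cap + 1, (z, r)),
        payoffs=np.zeros(z),
    )


def fitness(payoff, w: float):
    """Exponential payoff-to-fitness map, f = exp(w * payoff).

    Strictly increasing in payoff, always positive, and equal to 1 under
    neutral selection (w = 0).
    """
    if w < 0:
        raise ValueError("selection intensity must be non-negative")
    out = np.exp(w * np.asarray(payoff, dtype=float))
    return float(out) if np.isscalar(payoff) else out


# ---------------------------------------------------------------------------
# one generation of play
# ---------------------------------------------------------------------------


def _sample_groups(z: int, g: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """(g, m) player indices; within a game players are distinct."""
    if m > z:
        raise ConfigurationError("population smaller than the group size")
    if g == 0:
        return np.empty((0, m), dtype=np.int64)
    if m == z:
        return np.tile(np.arange(z, dtype=np.int64), (g, 1))
    r = rng.random((g, z))
    return np.argpartition(r, m, axis=1)[:, :m].astype(np.int64)


def _generation_games(
    thr: np.ndarray,
    above: np.ndarray,
    below: np.ndarray,
    game: GameConfig,
    evo: EvoConfig,
    rng: np.random.Generator,
):
    """Play one generation's games; returns (mean payoffs per individual,
    batch dict with an extra 'groups' key)."""
    z = len(thr)
    groups = _sample_groups(z, evo.games_per_generation, game.group_size, rng)
    kernel = _play_batch_sequential if game.mode == "sequential" else _play_batch
    if len(groups) == 0:
        batch = {
            "contributions": np.zeros((0, game.group_size, game.rounds), np.int64),
            "target_met": np.zeros(0, bool),
            "payoffs": np.zeros((0, game.group_size)),
            "totals": np.zeros((0, game.group_size), np.int64),
        }
    else:
        batch = kernel(thr[groups], above[groups], below[groups], game, rng)
    batch["groups"] = groups
    sums = np.zeros(z)
    counts = np.zeros(z, dtype=np.int64)
    if len(groups):
        np.add.at(sums, groups.ravel(), batch["payoffs"].ravel())
        np.add.at(counts, groups.ravel(), 1)
    played = counts > 0
    mean_payoffs = np.zeros(z)
    if played.any():
        mean_payoffs[played] = sums[played] / counts[played]
        # individuals sampled into no game inherit the population mean
        # (neutral), so they are neither favored nor purged spuriously
        mean_payoffs[~played] = mean_payoffs[played].mean()
    return mean_payoffs, batch


def play_generation(
    pop: PopulationState, game: GameConfig, evo: EvoConfig, rng: np.random.Generator
) -> PopulationState:
    """Sample groups, play all games, fill per-individual mean payoffs."""
    if pop.size < game.group_size:
        raise ConfigurationError("population smaller than the group size")
    mean_payoffs, _ = _generation_games(
        pop.thresholds, pop.above, pop.below, game, evo, rng
    )
    return PopulationState(
        pop.thresholds, pop.above, pop.below, mean_payoffs, pop.generation
    )


# ---------------------------------------------------------------------------
# reproduction
# ---------------------------------------------------------------------------


def _mutate_arrays(thr, above, below, evo: EvoConfig, c_max: int, rng):
    """Per-locus inheritance errors on copies of the given arrays."""
    mu, sigma = evo.error_prob, evo.threshold_noise_sd
    thr = thr.copy()
    above = above.copy()
    below = below.copy()
    if mu > 0:
        m = rng.random(thr.shape) < mu
        if m.any():
            thr[m] = np.clip(thr[m] + rng.normal(0.0, sigma, int(m.sum())), 0.0, 1.0)
        for arr in (above, below):
            m = rng.random(arr.shape) < mu
            if m.any():
                arr[m] = rng.integers(0, c_max + 1, int(m.sum()))
    return thr, above, below


def mutate(
    genome: StrategyGenome,
    evo: EvoConfig,
    rng: np.random.Generator,
    *,
    c_max: int = 2,
) -> StrategyGenome:
    """Apply inheritance errors to one genome.

    Each of the 3R loci mutates independently with probability
    ``evo.error_prob``: thresholds get Gaussian noise (SD
    ``evo.threshold_noise_sd``) clamped to [0, 1]; contribution loci are
    resampled uniformly from {0..c_max} (possibly redrawing the same
    value).
    """
    thr, ab, be = _mutate_arrays(
        genome.thresholds[None, :], genome.above[None, :], genome.below[None, :],
        evo, c_max, rng,
    )
    return StrategyGenome(thr[0], ab[0], be[0])


def wright_fisher_step(
    pop: PopulationState,
    evo: EvoConfig,
    rng: np.random.Generator,
    *,
    c_max: int = 2,
) -> PopulationState:
    """Draw the next generation: Z offspring, parents weighted by fitness,
    then per-locus mutation of every offspring."""
    w = evo.selection_intensity
    logf = w * pop.payoffs
    weights = np.exp(logf - logf.max())  # shift-invariant, avoids overflow
    probs = weights / weights.sum()
    parents = rng.choice(pop.size, size=pop.size, p=probs)
    thr, ab, be = _mutate_arrays(
        pop.thresholds[parents], pop.above[parents], pop.below[parents],
        evo, c_max, rng,
    )
    return PopulationState(thr, ab, be, np.zeros(pop.size), pop.generation + 1)


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------


@dataclass
class EvolutionResult:
    """Trajectory of one evolutionary run.

    ``summaries`` holds one row per generation; ``behavior_counts`` tallies
    realized behaviors (encoded base c_max+1) over all post-burn-in
    player-games.
    """

    summaries: pd.DataFrame
    behavior_counts: Counter
    game: GameConfig
    evo: EvoConfig
    final_population: PopulationState

    def post_burn_in(self) -> pd.DataFrame:
        return self.summaries[self.summaries["generation"] >= self.evo.burn_in]

    def long_run_means(self) -> pd.Series:
        """Post-burn-in mean of every summary column."""
        return self.post_burn_in().drop(columns=["generation"]).mean()

    def modal_behavior(self) -> tuple[tuple[int, ...], float]:
        return analysis.modal_from_counts(
            self.behavior_counts, self.game.rounds, self.game.contribution_cap + 1
        )


def run_evolution(
    game: GameConfig,
    evo: EvoConfig,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    collect_behaviors: bool = True,
    progress: bool = False,
) -> EvolutionResult:
    """Initialize, then iterate play -> summarize -> Wright-Fisher step.

    Deterministic given the seed (``evo.seed`` unless overridden).  Emits
    one :class:`~collrisk.analysis.GenerationSummary` row per generation;
    behavior tallies start after ``evo.burn_in`` generations.
    """
    if rng is None:
        rng = np.random.default_rng(evo.seed if seed is None else seed)
    if evo.population_size < game.group_size:
        raise ConfigurationError("population smaller than the group size")
    pop0 = initialize_population(evo, game, rng)
    thr_pop, above_pop, below_pop = pop0.thresholds, pop0.above, pop0.below
    base = game.contribution_cap + 1
    counts: Counter = Counter()
    rows = []
    for gen in range(evo.generations):
        mean_payoffs, batch = _generation_games(
            thr_pop, above_pop, below_pop, game, evo, rng
        )
        summary = analysis.summarize_arrays(
            batch["contributions"],
            batch["target_met"],
            batch["payoffs"],
            game,
            generation=gen,
            mean_payoff=float(mean_payoffs.mean()),
        )
        rows.append(summary.to_dict())
        if collect_behaviors and gen >= evo.burn_in and batch["contributions"].size:
            codes = analysis.encode_behaviors(
                batch["contributions"].reshape(-1, game.rounds), base
            )
            uniq, n = np.unique(codes, return_counts=True)
            counts.update(dict(zip(uniq.tolist(), n.tolist())))
        if progress and gen % 200 == 0:
            print(f"generation {gen}: payoff={summary.mean_payoff:.2f} "
                  f"success={summary.success_fraction:.2f}")
        pop = PopulationState(thr_pop, above_pop, below_pop, mean_payoffs, gen)
        nxt = wright_fisher_step(pop, evo, rng, c_max=game.contribution_cap)
        thr_pop, above_pop, below_pop = nxt.thresholds, nxt.above, nxt.below
    final = PopulationState(thr_pop, above_pop, below_pop, np.zeros(len(thr_pop)),
                            evo.generations)
    return EvolutionResult(pd.DataFrame(rows), counts, game, evo, final)
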