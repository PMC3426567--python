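"""Model variants: interest, target noise, cap sweeps, sequential play.

These are perturbations of the baseline collective-risk game that probe
the timing of contributions: interest on the common account makes early
units worth more, target noise blurs the success criterion, varying the
per-round cap changes how late contributions can start, and the
sequential variant gives each of M players a single move in a fixed
random order instead of M simultaneous moves per round.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import analysis
from .game_core import (
    ConfigurationError,
    GameConfig,
    GameRecord,
    StrategyGenome,
    _play_batch_sequential,
    _stack_strategies,
    apply_interest,
    sample_target,
)

__all__ = [
    "SequentialConfig",
    "apply_interest",
    "sample_target",
    "play_sequential",
    "cap_sweep",
    "latest_start_round",
]


@dataclass(frozen=True)
class SequentialConfig(GameConfig):
    """Game config for the sequential variant.

    Exactly one player moves per round (so R == M), the move order is a
    fresh uniform permutation per game, and the per-move action range
    defaults to the whole endowment [0, E] — with a single move each, a
    small per-round cap would make the target arithmetically unreachable.
    """

    mode: str = "sequential"

    def __post_init__(self) -> None:
        if self.mode != "sequential":
            raise ConfigurationError("SequentialConfig is always sequential")
        super().__post_init__()


def play_sequential(
    strategies: Sequence[StrategyGenome],
    config: GameConfig,
    rng: np.random.Generator,
) -> GameRecord:
    """Play one sequential game; the mover of round r applies its round-r
    rule against the current pool, investing up to its whole endowment."""
    if config.mode != "sequential":
        raise ConfigurationError("config.mode must be 'sequential'")
    thr, ab, be = _stack_strategies(strategies, config)
    batch = _play_batch_sequential(thr, ab, be, config, rng)
    return GameRecord(
        contributions=batch["contributions"][0],
        pool_trajectory=batch["pool_trajectory"][0],
        realized_target=float(batch["realized_target"][0]),
        target_met=bool(batch["target_met"][0]),
        totals=batch["totals"][0],
        payoffs=batch["payoffs"][0],
    )


def latest_start_round(rounds: int, c_max: int, fair_share: int) -> int:
    """First contributing round of the latest-possible fair-share schedule.

    Contributing the fair share at the maximum rate needs
    ``ceil(fair_share / c_max)`` rounds, so the latest start is
    ``R - ceil(fair_share / c_max) + 1``.
    """
    return rounds - math.ceil(fair_share / c_max) + 1


def cap_sweep(
    game: GameConfig,
    evo,
    caps: Sequence[int],
    replicates: int = 1,
) -> pd.DataFrame:
    """Evolve the game under different per-round contribution caps.

    The endowment is held fixed while the cap varies, so small caps force
    early starts and large caps allow very late ones.  For each cap the
    modal post-burn-in behavior, its first contributing round and the
    long-run success fraction are reported (behavior tallies pooled over
    replicates; replicate k reseeded as ``evo.seed + k``).
    """
    from .evolution import run_evolution  # deferred: avoids an import cycle

    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    if any(c < 1 for c in caps):
        raise ValueError("caps must be at least 1")
    rows = []
    for cap in caps:
        g = replace(game, contribution_cap=int(cap))
        counts: Counter = Counter()
        success = []
        totals = []
        for rep in range(replicates):
            e = replace(evo, seed=evo.seed + rep)
            result = run_evolution(g, e)
            counts.update(result.behavior_counts)
            means = result.long_run_means()
            success.append(means["success_fraction"])
            totals.append(means["mean_total_contribution"])
        modal, freq = analysis.modal_from_counts(counts, g.rounds, g.contribution_cap + 1)
        nonzero = np.nonzero(np.asarray(modal))[0]
        first_round = int(nonzero[0]) + 1 if len(nonzero) else 0
        rows.append(
            {
                "contribution_cap": int(cap),
                "modal_behavior": analysis.behavior_to_string(modal),
                "modal_freq": freq,
                "first_contribution_round": first_round,
                "success_fraction": float(np.mean(success)),
                "mean_total_contribution": float(np.mean(totals)),
            }
        )
    return pd.DataFrame(rows)
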