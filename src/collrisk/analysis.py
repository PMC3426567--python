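"""Behavioral statistics of realized game play.

'Behavior' is the realized sequence of a player's per-round contributions
in one game — distinct from the strategy that generated it, since a
threshold-conditional strategy can realize different behaviors against
different co-players.  Behaviors are tallied per player-game.

Total contributions fall in four categories relative to the endowment E:
zero (c = 0), under (0 < c < E/2), fair (c = E/2, the equal split of the
target) and over (c > E/2).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .game_core import GameConfig, GameRecord

__all__ = [
    "CATEGORIES",
    "GenerationSummary",
    "classify_total",
    "count_fair_share_behaviors",
    "half_split",
    "dominant_behavior",
    "summarize_generation",
    "risk_sweep",
    "behavior_to_string",
    "parse_behavior",
    "encode_behaviors",
    "decode_behavior",
    "modal_from_counts",
]

CATEGORIES = ("zero", "under", "fair", "over")


def classify_total(total: int, endowment: int) -> str:
    """Category of a player's total contribution relative to the endowment."""
    if not 0 <= total <= endowment:
        raise ValueError("total must lie in [0, endowment]")
    if total == 0:
        return "zero"
    if 2 * total == endowment:
        return "fair"
    if 2 * total < endowment:
        return "under"
    return "over"


def _classify_totals(totals: np.ndarray, endowment: int) -> dict[str, float]:
    """Vectorised category frequencies over a flat array of totals."""
    n = totals.size
    if n == 0:
        raise ValueError("no totals to classify")
    doubled = 2 * totals
    zero = int(np.count_nonzero(totals == 0))
    fair = int(np.count_nonzero((doubled == endowment) & (totals > 0)))
    under = int(np.count_nonzero((doubled < endowment) & (totals > 0)))
    over = int(np.count_nonzero(doubled > endowment))
    return {
        "frac_zero": zero / n,
        "frac_under": under / n,
        "frac_fair": fair / n,
        "frac_over": over / n,
    }


def count_fair_share_behaviors(rounds: int, c_max: int, fair_share: int) -> int:
    """Number of length-R sequences over {0..c_max} summing to ``fair_share``.

    Dynamic programme over rounds: ``ways[s]`` is the number of prefixes
    summing to s.  For the classic four-round game with contributions in
    {0, 1, 2} there are 19 ways to contribute a fair share of 4.
    """
    if rounds < 1 or c_max < 1:
        raise ValueError("rounds and c_max must be at least 1")
    if fair_share < 0:
        return 0
    ways = np.zeros(fair_share + 1, dtype=np.int64)
    ways[0] = 1
    for _ in range(rounds):
        nxt = np.zeros_like(ways)
        for a in range(min(c_max, fair_share) + 1):
            nxt[a:] += ways[: fair_share + 1 - a]
        ways = nxt
    return int(ways[fair_share])


def half_split(behavior: Sequence[int]) -> float:
    """Fraction of a behavior's total contributed in the second half.

    For odd round counts the first half is rounds 1..floor(R/2).  A
    non-contributing behavior maps to 0 by convention.
    """
    b = np.asarray(behavior, dtype=np.int64)
    total = int(b.sum())
    if total == 0:
        return 0.0
    return float(b[len(b) // 2 :].sum() / total)


# -- behavior encoding -------------------------------------------------------


def encode_behaviors(contributions: np.ndarray, base: int) -> np.ndarray:
    """Pack per-round contribution rows into integer codes, base ``c_max+1``.

    Codes order lexicographically like the sequences themselves, so the
    smallest code is the lexicographically smallest behavior.
    """
    r = contributions.shape[-1]
    powers = base ** np.arange(r - 1, -1, -1, dtype=np.int64)
    return contributions.astype(np.int64) @ powers


def decode_behavior(code: int, rounds: int, base: int) -> tuple[int, ...]:
    out = []
    for _ in range(rounds):
        out.append(int(code % base))
        code //= base
    return tuple(reversed(out))


def behavior_to_string(behavior: Sequence[int]) -> str:
    """Serialize a behavior as a digit string, e.g. ``"0000022222"``."""
    if max(behavior, default=0) > 9:
        return "-".join(str(int(x)) for x in behavior)
    return "".join(str(int(x)) for x in behavior)


def parse_behavior(text: str) -> tuple[int, ...]:
    if "-" in text:
        return tuple(int(x) for x in text.split("-"))
    return tuple(int(ch) for ch in text)


def modal_from_counts(counts: Counter, rounds: int, base: int) -> tuple[tuple[int, ...], float]:
    """Modal behavior and its frequency from a code -> count tally."""
    if not counts:
        raise ValueError("empty behavior tally")
    total = sum(counts.values())
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return decode_behavior(best[0], rounds, base), best[1] / total


def dominant_behavior(records: Iterable[GameRecord]) -> tuple[tuple[int, ...], float]:
    """Modal realized behavior over all player-games, with its frequency.

    Ties are broken toward the lexicographically smallest sequence.
    """
    counts: Counter = Counter()
    rounds = None
    for rec in records:
        rounds = rec.contributions.shape[1]
        for row in rec.contributions:
            counts[tuple(int(x) for x in row)] += 1
    if rounds is None:
        raise ValueError("empty record collection")
    total = sum(counts.values())
    best = max(counts.items(), key=lambda kv: (kv[1], tuple(-x for x in kv[0])))
    return best[0], best[1] / total


# -- generation summaries ----------------------------------------------------


@dataclass(frozen=True)
class GenerationSummary:
    """Per-generation aggregates over all player-games.

    ``mean_total_contribution`` is in units per player; ``first_half`` and
    ``second_half`` are mean units per player contributed in each half of
    the game; ``half_split`` is the aggregate second-half share of all
    contributions (0 when nothing was contributed).
    """

    generation: int
    mean_payoff: float
    mean_total_contribution: float
    success_fraction: float
    first_half: float
    second_half: float
    half_split: float
    frac_zero: float
    frac_under: float
    frac_fair: float
    frac_over: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_arrays(
    contributions: np.ndarray,
    target_met: np.ndarray,
    payoffs: np.ndarray,
    game: GameConfig,
    generation: int = 0,
    mean_payoff: float | None = None,
) -> GenerationSummary:
    """Summary from batch arrays (n_games, M, R) / (n_games,) / (n_games, M).

    ``mean_payoff`` defaults to the mean over player-games; the evolution
    engine passes the population mean (which includes the fill-in payoff
    of individuals that played no game) instead.
    """
    if contributions.size == 0:
        raise ValueError("no games to summarize")
    r = contributions.shape[-1]
    totals = contributions.sum(axis=-1)
    cats = _classify_totals(totals.ravel(), game.endowment)
    first = contributions[..., : r // 2].sum()
    second = contributions[..., r // 2 :].sum()
    grand = first + second
    n_players = totals.size
    return GenerationSummary(
        generation=generation,
        mean_payoff=float(payoffs.mean() if mean_payoff is None else mean_payoff),
        mean_total_contribution=float(totals.mean()),
        success_fraction=float(np.mean(target_met)),
        first_half=float(first / n_players),
        second_half=float(second / n_players),
        half_split=float(second / grand) if grand > 0 else 0.0,
        **cats,
    )


def summarize_generation(
    records: Sequence[GameRecord], game: GameConfig, generation: int = 0
) -> GenerationSummary:
    """Summary over an explicit collection of game records."""
    if len(records) == 0:
        raise ValueError("no games to summarize")
    contrib = np.stack([rec.contributions for rec in records])
    met = np.array([rec.target_met for rec in records])
    payoffs = np.stack([rec.payoffs for rec in records])
    return summarize_arrays(contrib, met, payoffs, game, generation)


def risk_sweep(
    game: GameConfig,
    evo,
    p_grid: Sequence[float],
    replicates: int = 1,
) -> pd.DataFrame:
    """Long-run summary statistics across a grid of risk probabilities.

    For each risk level, runs ``replicates`` independent evolutionary
    realizations (replicate k reseeded as ``evo.seed + k``), averages the
    per-generation summaries over post-burn-in generations and replicates,
    and reports the modal post-burn-in behavior.  One output row per p.
    """
    from .evolution import run_evolution  # deferred: avoids an import cycle

    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    rows = []
    base = game.contribution_cap + 1
    for p in p_grid:
        g = replace(game, risk_prob=float(p))
        counts: Counter = Counter()
        frames = []
        for rep in range(replicates):
            e = replace(evo, seed=evo.seed + rep)
            result = run_evolution(g, e)
            frames.append(result.post_burn_in().drop(columns=["generation"]))
            counts.update(result.behavior_counts)
        means = pd.concat(frames).mean()
        modal, freq = modal_from_counts(counts, game.rounds, base)
        row = {"risk_prob": float(p)}
        row.update(means.to_dict())
        row["mean_total_frac"] = row["mean_total_contribution"] / g.endowment
        row["mean_payoff_frac"] = row["mean_payoff"] / g.endowment
        row["modal_behavior"] = behavior_to_string(modal)
        row["modal_freq"] = freq
        rows.append(row)
    return pd.DataFrame(rows)
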