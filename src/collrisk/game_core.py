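"""Single collective-risk games: strategies, payoffs and risk curves.

A collective-risk dilemma is a multi-round group game in which ``M``
players each start with an endowment ``E`` and may invest a few units per
round into a common pool.  If the pool misses a collective target ``T`` by
the last round, every player loses their uninvested savings with
probability ``p``; if the target is met, everyone keeps what they did not
invest.  Strategies are *threshold-conditional*: in every round a player
compares the current pool with a round-specific threshold (expressed as a
fraction of the target) and plays one of two contribution levels depending
on whether the pool is at-or-above or below it.

This module is deliberately free of any evolutionary machinery; it only
knows how to play games.  The vectorised kernels (:func:`_play_batch`,
:func:`_play_batch_sequential`) evaluate many games at once and are shared
with the evolution engine; :func:`play_game` is the single-game wrapper.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "StrategyGenome",
    "GameConfig",
    "GameRecord",
    "decide_contribution",
    "play_game",
    "expected_payoff",
    "effective_risk",
    "apply_interest",
    "sample_target",
    "load_strategies",
    "save_strategies",
]


class ConfigurationError(ValueError):
    """Strategies and game settings are mutually inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrategyGenome:
    """Heritable rule set: one (threshold, above, below) triple per round.

    ``thresholds[r]`` is a fraction of the collective target; when the
    common pool at the start of round ``r`` is at least
    ``thresholds[r] * target`` the player invests ``above[r]`` units,
    otherwise ``below[r]`` units.

    Parameters
    ----------
    thresholds
        Length-R array of fractions in [0, 1].
    above, below
        Length-R arrays of non-negative integer contribution levels.
    """

    thresholds: np.ndarray
    above: np.ndarray
    below: np.ndarray

    def __post_init__(self) -> None:
        thr = np.asarray(self.thresholds, dtype=float).copy()
        ab = np.asarray(self.above, dtype=np.int64).copy()
        be = np.asarray(self.below, dtype=np.int64).copy()
        if thr.ndim != 1 or ab.ndim != 1 or be.ndim != 1:
            raise ValueError("rule arrays must be one-dimensional")
        if not (len(thr) == len(ab) == len(be)):
            raise ValueError("thresholds, above and below must have equal length")
        if len(thr) < 1:
            raise ValueError("a strategy needs at least one round")
        if np.any((thr < 0.0) | (thr > 1.0)):
            raise ValueError("thresholds must lie in the closed interval [0, 1]")
        if np.any(ab < 0) or np.any(be < 0):
            raise ValueError("contribution levels must be non-negative integers")
        for arr in (thr, ab, be):
            arr.setflags(write=False)
        object.__setattr__(self, "thresholds", thr)
        object.__setattr__(self, "above", ab)
        object.__setattr__(self, "below", be)

    @property
    def rounds(self) -> int:
        return len(self.thresholds)

    @property
    def rules(self) -> list[tuple[float, int, int]]:
        """The per-round (threshold, above, below) triples."""
        return [
            (float(t), int(a), int(b))
            for t, a, b in zip(self.thresholds, self.above, self.below)
        ]

    @classmethod
    def from_rules(cls, rules: Iterable[Sequence[float]]) -> "StrategyGenome":
        rules = [tuple(r) for r in rules]
        if any(len(r) != 3 for r in rules):
            raise ValueError("each rule must be a (threshold, above, below) triple")
        thr = [r[0] for r in rules]
        ab = [r[1] for r in rules]
        be = [r[2] for r in rules]
        return cls(np.array(thr, float), np.array(ab, np.int64), np.array(be, np.int64))

    def to_dict(self) -> dict:
        return {"rounds": self.rounds, "rules": [list(r) for r in self.rules]}

    @classmethod
    def from_dict(cls, d: dict) -> "StrategyGenome":
        genome = cls.from_rules(d["rules"])
        if "rounds" in d and int(d["rounds"]) != genome.rounds:
            raise ValueError("declared round count does not match the rule list")
        return genome


@dataclass(frozen=True)
class GameConfig:
    """Game-level parameters of one collective-risk dilemma.

    Defaults mirror the standard six-player, ten-round game with per-round
    contributions in {0, 1, 2}: endowment ``E = 2R`` and target
    ``T = M*E/2`` (each player's fair share is half the endowment).
    ``contribution_cap`` defaults to 2 in simultaneous mode and to the full
    endowment in sequential mode, where each player moves exactly once.
    """

    risk_prob: float
    group_size: int = 6
    rounds: int = 10
    contribution_cap: int | None = None
    endowment: int | None = None
    target: int | None = None
    risk_curve: str = "step"
    interest_rate: float = 0.0
    target_noise_sd: float = 0.0
    mode: str = "simultaneous"
    sample_loss: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("simultaneous", "sequential"):
            raise ConfigurationError(f"unknown game mode: {self.mode!r}")
        if self.risk_curve not in ("step", "linear"):
            raise ConfigurationError(f"unknown risk curve: {self.risk_curve!r}")
        if self.group_size < 2:
            raise ValueError("group_size must be at least 2")
        if self.rounds < 1:
            raise ValueError("rounds must be at least 1")
        endowment = 2 * self.rounds if self.endowment is None else int(self.endowment)
        if endowment < 1:
            raise ValueError("endowment must be positive")
        cap = self.contribution_cap
        if cap is None:
            cap = endowment if self.mode == "sequential" else 2
        cap = int(cap)
        if cap < 1:
            raise ValueError("contribution_cap must be at least 1")
        target = (
            self.group_size * endowment // 2 if self.target is None else int(self.target)
        )
        if target < 1:
            raise ValueError("target must be positive")
        if target > self.group_size * endowment:
            raise ValueError("target exceeds the group's total endowment")
        if not 0.0 <= self.risk_prob <= 1.0:
            raise ValueError("risk_prob must lie in [0, 1]")
        if self.interest_rate < 0.0:
            raise ValueError("interest_rate must be non-negative")
        if self.target_noise_sd < 0.0:
            raise ValueError("target_noise_sd must be non-negative")
        if self.mode == "sequential" and self.rounds != self.group_size:
            raise ConfigurationError(
                "sequential games need exactly one round per player (R == M)"
            )
        object.__setattr__(self, "endowment", endowment)
        object.__setattr__(self, "contribution_cap", cap)
        object.__setattr__(self, "target", target)

    @property
    def fair_share(self) -> int:
        """Half the endowment: each player's equal split of the target."""
        return self.endowment // 2


@dataclass(frozen=True)
class GameRecord:
    """Realized outcome of one game.

    ``contributions`` is the M x R table of per-round deposits,
    ``pool_trajectory`` the pool after each round (index 0 is the empty
    pool; interest, if any, is included), ``realized_target`` the target
    actually compared against (equals the nominal target unless target
    noise is on), and ``payoffs`` the per-player expected payoffs.
    """

    contributions: np.ndarray
    pool_trajectory: np.ndarray
    realized_target: float
    target_met: bool
    totals: np.ndarray
    payoffs: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        """One row per player: id, per-round contributions, total, payoff."""
        m, r = self.contributions.shape
        df = pd.DataFrame(
            self.contributions, columns=[f"round_{i + 1}" for i in range(r)]
        )
        df.insert(0, "player", np.arange(m))
        df["total"] = self.totals
        df["payoff"] = self.payoffs
        return df

    def to_json_dict(self) -> dict:
        return {
            "contributions": self.contributions.tolist(),
            "pool_trajectory": self.pool_trajectory.tolist(),
            "realized_target": float(self.realized_target),
            "target_met": bool(self.target_met),
            "totals": self.totals.tolist(),
            "payoffs": self.payoffs.tolist(),
        }


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def effective_risk(total_pool, target, p: float, curve: str = "step"):
    """Probability of losing the uninvested savings, given the final pool.

    The ``step`` curve is the classical all-or-nothing rule: full risk
    ``p`` below the target, zero at or above it.  The ``linear`` curve
    lets partial contributions partially mitigate the risk,
    ``p * max(0, 1 - pool/target)``.  Accepts scalars or arrays.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    pool = np.asarray(total_pool, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if curve == "step":
        risk = np.where(pool < tgt, p, 0.0)
    elif curve == "linear":
        with np.errstate(divide="ignore", invalid="ignore"):
            shortfall = np.where(tgt > 0, 1.0 - pool / np.where(tgt > 0, tgt, 1.0), 0.0)
        risk = p * np.clip(shortfall, 0.0, 1.0)
    else:
        raise ConfigurationError(f"unknown risk curve: {curve!r}")
    if np.isscalar(total_pool) and np.isscalar(target):
        return float(risk)
    return risk


def expected_payoff(endowment: int, total_contrib: int, target_met: bool, risk: float) -> float:
    """Expected payoff of a player who invested ``total_contrib`` units.

    ``E - c`` when the target was met, ``(1 - risk) * (E - c)`` when it was
    missed; ``risk`` is the effective loss probability from the risk curve.
    """
    if not 0 <= total_contrib <= endowment:
        raise ValueError("total contribution must lie in [0, endowment]")
    if not 0.0 <= risk <= 1.0:
        raise ValueError("risk must lie in [0, 1]")
    kept = float(endowment - total_contrib)
    return kept if target_met else (1.0 - risk) * kept


def apply_interest(pool: float, rate: float) -> float:
    """Grow the common pool by one interest period: ``pool * (1 + rate)``.

    Interest accrues at the start of rounds 2..R, so a deposit made in
    round r is worth ``(1 + rate)**(R - r)`` units in the final pool and
    the last round's deposit accrues nothing.
    """
    if rate < 0.0:
        raise ValueError("interest rate must be non-negative")
    return pool * (1.0 + rate)


def sample_target(target: float, sd: float, rng: np.random.Generator | None = None) -> float:
    """Draw the realized target: Normal(T, sd) truncated below at zero.

    Drawn once per game and used only in the final success check; players'
    thresholds always scale with the announced (nominal) target.
    """
    if sd < 0.0:
        raise ValueError("target noise SD must be non-negative")
    if sd == 0.0:
        return float(target)
    if rng is None:
        raise ValueError("a random generator is required when sd > 0")
    return float(max(0.0, rng.normal(target, sd)))


def decide_contribution(
    strategy: StrategyGenome,
    round_index: int,
    pool: float,
    config: GameConfig,
    spent_so_far: int = 0,
) -> int:
    """Contribution of one player in round ``round_index`` (1-based).

    Plays the rule's ``above`` action when the pool is at-or-above
    ``threshold * target`` (the boundary counts as above), else ``below``;
    the result is clipped to the player's remaining endowment.
    """
    if strategy.rounds != config.rounds:
        raise ConfigurationError(
            f"strategy has {strategy.rounds} rounds, game expects {config.rounds}"
        )
    if not 1 <= round_index <= config.rounds:
        raise IndexError(f"round_index {round_index} outside 1..{config.rounds}")
    if pool < 0:
        raise ValueError("pool must be non-negative")
    if not 0 <= spent_so_far <= config.endowment:
        raise ValueError("spent_so_far must lie in [0, endowment]")
    r = round_index - 1
    action = int(strategy.above[r]) if pool >= strategy.thresholds[r] * config.target else int(
        strategy.below[r]
    )
    if action > config.contribution_cap:
        raise ConfigurationError(
            f"action {action} exceeds the per-round cap {config.contribution_cap}"
        )
    return min(action, config.endowment - spent_so_far)


# ---------------------------------------------------------------------------
# vectorised game kernels
# ---------------------------------------------------------------------------


def _check_kernel_rng(cfg: GameConfig, rng) -> None:
    if rng is None and (cfg.target_noise_sd > 0 or cfg.sample_loss):
        raise ValueError("a random generator is required for this configuration")


def _realized_targets(cfg: GameConfig, n: int, rng) -> np.ndarray:
    if cfg.target_noise_sd > 0:
        return np.maximum(0.0, rng.normal(cfg.target, cfg.target_noise_sd, n))
    return np.full(n, float(cfg.target))


def _finish_batch(cfg: GameConfig, pool, spent, contrib, traj, realized, rng):
    met = pool >= realized - 1e-9
    risk = effective_risk(pool, realized, cfg.risk_prob, cfg.risk_curve)
    risk = np.where(met, 0.0, risk)
    kept = (cfg.endowment - spent).astype(float)
    if cfg.sample_loss:
        lost = rng.random(len(pool)) < risk
        payoffs = kept * (~lost)[:, None]
    else:
        payoffs = kept * (1.0 - risk)[:, None]
    return {
        "contributions": contrib,
        "pool_trajectory": traj,
        "realized_target": realized,
        "target_met": met,
        "totals": spent,
        "payoffs": payoffs,
    }


def _play_batch(thr: np.ndarray, above: np.ndarray, below: np.ndarray,
                cfg: GameConfig, rng=None) -> dict:
    """Play ``n`` simultaneous-mode games at once.

    ``thr``, ``above``, ``below`` have shape (n, M, R).  Returns arrays:
    contributions (n, M, R), pool_trajectory (n, R+1), realized_target (n,),
    target_met (n,), totals (n, M), payoffs (n, M).
    """
    _check_kernel_rng(cfg, rng)
    n, m, r_total = thr.shape
    scaled = thr * cfg.target
    pool = np.zeros(n)
    traj = np.zeros((n, r_total + 1))
    spent = np.zeros((n, m), dtype=np.int64)
    contrib = np.zeros((n, m, r_total), dtype=np.int64)
    realized = _realized_targets(cfg, n, rng)
    growth = 1.0 + cfg.interest_rate
    for r in range(r_total):
        if r > 0 and cfg.interest_rate > 0:
            pool = pool * growth
        act = np.where(pool[:, None] >= scaled[:, :, r], above[:, :, r], below[:, :, r])
        np.minimum(act, cfg.endowment - spent, out=act)
        contrib[:, :, r] = act
        spent += act
        pool = pool + act.sum(axis=1)
        traj[:, r + 1] = pool
    return _finish_batch(cfg, pool, spent, contrib, traj, realized, rng)


def _play_batch_sequential(thr: np.ndarray, above: np.ndarray, below: np.ndarray,
                           cfg: GameConfig, rng) -> dict:
    """Play ``n`` sequential-mode games (one mover per round, R == M).

    Move order is a fresh uniform permutation per game; the round-r mover
    applies its round-r rule with actions in [0, E].
    """
    if rng is None:
        raise ValueError("sequential games sample a move order and need a generator")
    n, m, r_total = thr.shape
    if r_total != m:
        raise ConfigurationError("sequential games need R == M")
    orders = np.argsort(rng.random((n, m)), axis=1)
    scaled = thr * cfg.target
    pool = np.zeros(n)
    traj = np.zeros((n, r_total + 1))
    spent = np.zeros((n, m), dtype=np.int64)
    contrib = np.zeros((n, m, r_total), dtype=np.int64)
    realized = _realized_targets(cfg, n, rng)
    rows = np.arange(n)
    growth = 1.0 + cfg.interest_rate
    for r in range(r_total):
        if r > 0 and cfg.interest_rate > 0:
            pool = pool * growth
        mover = orders[:, r]
        act = np.where(
            pool >= scaled[rows, mover, r], above[rows, mover, r], below[rows, mover, r]
        )
        np.minimum(act, cfg.endowment - spent[rows, mover], out=act)
        contrib[rows, mover, r] = act
        spent[rows, mover] += act
        pool = pool + act
        traj[:, r + 1] = pool
    return _finish_batch(cfg, pool, spent, contrib, traj, realized, rng)


def _stack_strategies(strategies: Sequence[StrategyGenome], config: GameConfig):
    if len(strategies) != config.group_size:
        raise ConfigurationError(
            f"expected {config.group_size} strategies, got {len(strategies)}"
        )
    for s in strategies:
        if s.rounds != config.rounds:
            raise ConfigurationError(
                f"strategy has {s.rounds} rounds, game expects {config.rounds}"
            )
        if int(s.above.max()) > config.contribution_cap or int(s.below.max()) > config.contribution_cap:
            raise ConfigurationError("strategy action exceeds the per-round cap")
    thr = np.stack([s.thresholds for s in strategies])[None, :, :]
    ab = np.stack([s.above for s in strategies])[None, :, :]
    be = np.stack([s.below for s in strategies])[None, :, :]
    return thr, ab, be


def play_game(
    strategies: Sequence[StrategyGenome],
    config: GameConfig,
    rng: np.random.Generator | None = None,
) -> GameRecord:
    """Play one game among ``config.group_size`` players.

    In simultaneous mode all players decide against the pool at the start
    of each round; in sequential mode a random permutation assigns one
    mover per round.  ``rng`` is required only when something is sampled
    (target noise, loss sampling, sequential move order).
    """
    thr, ab, be = _stack_strategies(strategies, config)
    if config.mode == "sequential":
        batch = _play_batch_sequential(thr, ab, be, config, rng)
    else:
        batch = _play_batch(thr, ab, be, config, rng)
    return GameRecord(
        contributions=batch["contributions"][0],
        pool_trajectory=batch["pool_trajectory"][0],
        realized_target=float(batch["realized_target"][0]),
        target_met=bool(batch["target_met"][0]),
        totals=batch["totals"][0],
        payoffs=batch["payoffs"][0],
    )


# ---------------------------------------------------------------------------
# strategy / population files
# ---------------------------------------------------------------------------


def save_strategies(strategies: Sequence[StrategyGenome], path) -> None:
    """Write a population file: a JSON array of {rounds, rules} records."""
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in strategies], fh, indent=1)


def load_strategies(path) -> list[StrategyGenome]:
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    return [StrategyGenome.from_dict(d) for d in data]
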