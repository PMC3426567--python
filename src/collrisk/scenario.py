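"""Scenario files, run metadata and canned fixtures.

A scenario is the full description of one experiment: a ``game`` block
(GameConfig fields) plus an ``evolution`` block (EvoConfig fields), with
optional ``replicates`` and ``output_dir``.  Scenarios round-trip
losslessly through YAML or JSON, and every run directory written by the
CLI contains a metadata file from which the scenario can be rebuilt
exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .evolution import EvoConfig, PopulationState, initialize_population
from .game_core import ConfigurationError, GameConfig, GameRecord, StrategyGenome, play_game
from .stability import FIVE_BEHAVIORS, behavior_to_strategy

__all__ = ["Scenario", "load_scenario", "save_scenario", "make_fixtures"]

_GAME_FIELDS = {f.name for f in dataclasses.fields(GameConfig)}
_EVO_FIELDS = {f.name for f in dataclasses.fields(EvoConfig)}


@dataclass(frozen=True)
class Scenario:
    """One reproducible experiment: game rules + evolutionary parameters."""

    game: GameConfig
    evolution: EvoConfig = field(default_factory=EvoConfig)
    replicates: int = 1
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")

    def to_dict(self) -> dict:
        d = {
            "game": dataclasses.asdict(self.game),
            "evolution": dataclasses.asdict(self.evolution),
            "replicates": self.replicates,
        }
        if self.output_dir is not None:
            d["output_dir"] = self.output_dir
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        if not isinstance(data, dict):
            raise ValueError("scenario must be a mapping")
        unknown = set(data) - {"game", "evolution", "replicates", "output_dir"}
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        game_d = dict(data.get("game", {}))
        evo_d = dict(data.get("evolution", {}))
        bad = set(game_d) - _GAME_FIELDS
        if bad:
            raise ValueError(f"unknown game keys: {sorted(bad)}")
        bad = set(evo_d) - _EVO_FIELDS
        if bad:
            raise ValueError(f"unknown evolution keys: {sorted(bad)}")
        if "risk_prob" not in game_d:
            raise ValueError("game.risk_prob is required")
        try:
            game = GameConfig(**game_d)
            evo = EvoConfig(**evo_d)
        except (ValueError, ConfigurationError) as exc:
            raise ValueError(f"invalid scenario: {exc}") from exc
        return cls(
            game=game,
            evolution=evo,
            replicates=int(data.get("replicates", 1)),
            output_dir=data.get("output_dir"),
        )


def load_scenario(path) -> Scenario:
    """Read and validate a YAML or JSON scenario file.

    A minimal file needs only ``game: {risk_prob: ...}``; every other
    field takes its documented default and is recorded explicitly when the
    scenario is serialized again.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if isinstance(data, dict) and "game" not in data and "risk_prob" in data:
        data = {"game": data}  # convenience: a bare game block
    return Scenario.from_dict(data)


def save_scenario(scenario: Scenario, path) -> None:
    path = Path(path)
    d = scenario.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=1))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(kind: str, seed: int = 0, population_size: int = 100):
    """Deterministic canned objects used across the test suite.

    ``five_behaviors``
        The five canonical unconditional ten-round genomes: defector
        (all 0), altruist (all 2), fair rational (0000022222), fair naive
        (1111111111) and the reverse fair rational (2222200000).
    ``random_population``
        A reproducible random PopulationState for the standard game.
    ``mixed_known_composition``
        A list of GameRecords whose category tallies are known by
        construction, plus the expected tally dict.
    """
    if kind == "five_behaviors":
        return {name: behavior_to_strategy(b) for name, b in FIVE_BEHAVIORS.items()}
    if kind == "random_population":
        rng = np.random.default_rng(seed)
        game = GameConfig(risk_prob=0.9)
        evo = EvoConfig(population_size=population_size)
        return initialize_population(evo, game, rng)
    if kind == "mixed_known_composition":
        game = GameConfig(risk_prob=0.5)
        m = game.group_size
        genomes = {name: behavior_to_strategy(b) for name, b in FIVE_BEHAVIORS.items()}
        under = behavior_to_strategy((1,) + (0,) * 9)  # total 1: 'under'
        # homogeneous games -> every player-game lands in a known category
        plan = [
            ("defector", 3),       # 3*M zero
            ("fair_rational", 2),  # 2*M fair
            ("altruist", 1),       # 1*M over
        ]
        records: list[GameRecord] = []
        for name, n_games in plan:
            for _ in range(n_games):
                records.append(play_game([genomes[name]] * m, game))
        records.append(play_game([under] * m, game))  # 1*M under
        expected = {
            "frac_zero": 3 * m / (7 * m),
            "frac_fair": 2 * m / (7 * m),
            "frac_over": 1 * m / (7 * m),
            "frac_under": 1 * m / (7 * m),
        }
        return records, expected
    raise ValueError(f"unknown fixture kind: {kind!r}")
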