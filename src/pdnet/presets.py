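"""Canned experiment configurations mirroring the study's figure setups.

Each preset is a list of labelled treatments; ``run_preset`` executes them
with independently spawned child seeds and returns a tidy table with one
row per ensemble.

* ``fig2``   — N=18, f=1.5: the four punishment x diversity treatments.
* ``fig3``   — N=18, f in {2.5, 1.1} x punishment on/off, no diversity.
* ``fig4``   — N=18, f in {1.1, 1.5, 2.4} x diversity on/off, no punishment.
* ``fig5``   — same sweep with costly punishment (6/6/6 start).
* ``fig6``   — 25x25 periodic lattice, k=4, 313 defectors / 312 cooperators:
               control (fixed neighborhoods) and experimental (players
               permuted over sites every round).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import GameConfig, Strategy
from .ensembles import TreatmentConfig, run_ensemble
from .networks import NetworkConfig, Topology

__all__ = ["PRESETS", "preset_treatments", "run_preset", "lattice_treatment"]


def _random_treatment(
    f: float,
    punishment: bool,
    diversity: bool,
    n_players: int = 18,
    n_games: int = 100,
    max_rounds: int = 1000,
) -> TreatmentConfig:
    net = NetworkConfig(
        topology=Topology.RANDOM,
        n_players=n_players,
        multiplying_factor=f,
        diversity=diversity,
    )
    game = GameConfig(
        network=net, punishment_enabled=punishment, max_rounds=max_rounds
    )
    return TreatmentConfig(game=game, n_games=n_games)


def lattice_treatment(
    diversity: bool,
    side: int = 25,
    n_games: int = 100,
    max_rounds: int = 1000,
    lattice_diversity_mode: str = "regular",
) -> TreatmentConfig:
    """The square-lattice replication: 313 defectors / 312 cooperators, k=4."""
    n = side * side
    net = NetworkConfig(
        topology=Topology.LATTICE,
        n_players=n,
        multiplying_factor=None,
        lattice_side=side,
        diversity=diversity,
        lattice_diversity_mode=lattice_diversity_mode,
    )
    comp = {Strategy.DEFECT: (n + 1) // 2, Strategy.COOPERATE: n // 2}
    game = GameConfig(
        network=net,
        punishment_enabled=False,
        max_rounds=max_rounds,
        initial_composition=comp,
    )
    return TreatmentConfig(game=game, n_games=n_games)


def preset_treatments(
    name: str, n_games: int = 100
) -> list[tuple[dict, TreatmentConfig]]:
    """Labelled treatments of one preset; labels become table columns."""
    if name == "fig2":
        return [
            (
                {"f": 1.5, "punishment": p, "diversity": d},
                _random_treatment(1.5, p, d, n_games=n_games),
            )
            for p in (False, True)
            for d in (False, True)
        ]
    if name == "fig3":
        return [
            (
                {"f": f, "punishment": p, "diversity": False},
                _random_treatment(f, p, False, n_games=n_games),
            )
            for f in (2.5, 1.1)
            for p in (False, True)
        ]
    if name in ("fig4", "fig5"):
        punishment = name == "fig5"
        return [
            (
                {"f": f, "punishment": punishment, "diversity": d},
                _random_treatment(f, punishment, d, n_games=n_games),
            )
            for f in (1.1, 1.5, 2.4)
            for d in (False, True)
        ]
    if name == "fig6":
        return [
            (
                {"lattice": "25x25", "punishment": False, "diversity": d},
                lattice_treatment(d, n_games=n_games),
            )
            for d in (False, True)
        ]
    raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


PRESETS = ("fig2", "fig3", "fig4", "fig5", "fig6")


def run_preset(name: str, master_seed: int, n_games: int = 100) -> pd.DataFrame:
    """Run every ensemble of a preset; one tidy row per ensemble."""
    treatments = preset_treatments(name, n_games=n_games)
    seeds = np.random.SeedSequence(master_seed).generate_state(len(treatments))
    rows = []
    for (label, treatment), seed in zip(treatments, seeds):
        res = run_ensemble(treatment, int(seed % 2**31))
        rows.append(res.to_row(**label, seed=int(seed % 2**31)))
    return pd.DataFrame(rows)
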