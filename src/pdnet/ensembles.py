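"""Ensembles of games and the summary statistics reported over them.

A treatment is one combination of the punishment and diversity switches on
top of a base game configuration; an ensemble runs ``n_games`` independent
games of that treatment.  Each game receives its own child seed spawned
from the master seed, so ensembles are reproducible and games independent.

Summary statistics:

* outcome tallies and probabilities (cooperation / defection / punishment
  fixation, or the equilibrium "No Preference" state at the round cap);
* mean average payoff — each game's mean per-player per-round payoff,
  averaged over games (the paper-style "average payoff"; the mean final
  cumulative payoff per player is also carried for comparison);
* the majority-defection fraction — the proportion of games in which more
  than half the players spent strictly more rounds defecting than
  cooperating;
* equilibrium compositions of the games that end without fixation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .engine import GameConfig, GameResult, Outcome, run_game
from .networks import Topology, f_range
from .payoffs import Strategy

__all__ = [
    "TreatmentConfig",
    "EnsembleResult",
    "run_ensemble",
    "majority_defection_fraction",
    "mean_average_payoff",
    "classify_equilibrium",
    "sweep_f",
]


@dataclass
class TreatmentConfig:
    """An ensemble specification: a base game repeated ``n_games`` times."""

    game: GameConfig = field(default_factory=GameConfig)
    n_games: int = 100
    # "large majority" threshold for the majority-defection statistic
    majority_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_games < 1:
            raise ValueError("n_games must be >= 1")


@dataclass
class EnsembleResult:
    outcome_counts: dict[Outcome, int]
    outcome_probabilities: dict[Outcome, float]
    mean_average_payoff: float
    mean_cumulative_payoff: float
    majority_defection_fraction: float
    equilibrium_compositions: list[dict[Strategy, int]]
    results: list[GameResult]
    master_seed: int | None = None

    @property
    def n_games(self) -> int:
        return len(self.results)

    def to_row(self, **extra) -> dict:
        """Flat dict for one tidy results-table row."""
        row = dict(extra)
        row["n_games"] = self.n_games
        for o in Outcome:
            row[f"count_{o.value}"] = self.outcome_counts[o]
        for o in Outcome:
            row[f"p_{o.value}"] = self.outcome_probabilities[o]
        row["mean_average_payoff"] = self.mean_average_payoff
        row["mean_cumulative_payoff"] = self.mean_cumulative_payoff
        row["majority_defection_fraction"] = self.majority_defection_fraction
        return row


def _majority_defecting(result: GameResult, threshold: float) -> bool:
    """Did more than ``threshold`` of players defect more rounds than cooperate?

    A game that is unanimous at round 0 plays no rounds; it contributes its
    single starting composition, so an all-defector start counts as
    majority-defecting.
    """
    if result.rounds_elapsed == 0:
        defected_more = result.final_strategies == int(Strategy.DEFECT)
    else:
        defected_more = result.defect_round_counts > result.cooperate_round_counts
    return float(defected_more.mean()) > threshold


def majority_defection_fraction(
    results: list[GameResult], threshold: float = 0.5
) -> float:
    """Proportion of games whose player-majority defected more than it cooperated."""
    if not results:
        raise ValueError("majority_defection_fraction requires at least one game")
    flags = [_majority_defecting(r, threshold) for r in results]
    return float(np.mean(flags))


def mean_average_payoff(results: list[GameResult]) -> float:
    """Mean over games of each game's mean per-player per-round payoff."""
    if not results:
        raise ValueError("mean_average_payoff requires at least one game")
    return float(np.mean([r.mean_payoff_per_player_round for r in results]))


def classify_equilibrium(result: GameResult) -> str:
    """Label the surviving-strategy set of a No Preference game.

    Returns ``"C_AND_D"`` (cooperators and defectors coexist), ``"D_AND_P"``
    (defectors and punishers), or ``"OTHER"``.
    """
    if result.outcome is not Outcome.NO_PREFERENCE:
        raise ValueError("classify_equilibrium applies only to NO_PREFERENCE games")
    survivors = frozenset(
        s for s, c in result.final_composition.items() if c > 0
    )
    if survivors == {Strategy.COOPERATE, Strategy.DEFECT}:
        return "C_AND_D"
    if survivors == {Strategy.DEFECT, Strategy.PUNISH}:
        return "D_AND_P"
    return "OTHER"


def run_ensemble(
    treatment: TreatmentConfig, master_seed: int
) -> EnsembleResult:
    """Run ``n_games`` independent seeded games and aggregate the statistics."""
    children = np.random.SeedSequence(master_seed).spawn(treatment.n_games)
    results = [
        run_game(treatment.game, np.random.default_rng(child)) for child in children
    ]
    counts = {o: 0 for o in Outcome}
    for r in results:
        counts[r.outcome] += 1
    n = treatment.n_games
    probs = {o: c / n for o, c in counts.items()}
    eq_comps = [
        r.final_composition for r in results if r.outcome is Outcome.NO_PREFERENCE
    ]
    return EnsembleResult(
        outcome_counts=counts,
        outcome_probabilities=probs,
        mean_average_payoff=mean_average_payoff(results),
        mean_cumulative_payoff=float(
            np.mean([r.mean_cumulative_payoff for r in results])
        ),
        majority_defection_fraction=majority_defection_fraction(
            results, treatment.majority_threshold
        ),
        equilibrium_compositions=eq_comps,
        results=results,
        master_seed=master_seed,
    )


def sweep_f(
    base: TreatmentConfig, f_values: list[float], master_seed: int
) -> pd.DataFrame:
    """Run one ensemble per f value; returns a tidy table, one row per ensemble.

    Seeds are spawned per f so adding values to the sweep does not perturb
    other rows.
    """
    net = base.game.network
    if net.topology is not Topology.RANDOM:
        raise ValueError("sweep_f applies to RANDOM topology")
    lo, hi = f_range(net.n_players)
    rows = []
    seeds = np.random.SeedSequence(master_seed).generate_state(len(f_values)) % 2**31
    for f, seed in zip(f_values, seeds):
        if not lo <= f <= hi:
            raise ValueError(
                f"f={f} outside feasible range [{lo:.6g}, {hi:.6g}] "
                f"for N={net.n_players}"
            )
        game = replace(base.game, network=replace(net, multiplying_factor=f))
        res = run_ensemble(replace(base, game=game), int(seed))
        rows.append(
            res.to_row(
                f=f,
                punishment=base.game.punishment_enabled,
                diversity=net.diversity,
            )
        )
    return pd.DataFrame(rows)
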