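"""Single-game engine: repeated rounds, synchronous imitate-the-best updates.

One game proceeds in rounds.  In a round every player plays a pairwise
Prisoner's Dilemma with each of its current neighbors and adds the sum of
the pairwise payoffs to its running total.  Before each round after the
first, all players update simultaneously: each considers the payoff its
current neighbors have accumulated over the game so far and adopts the
strategy of the highest-payoff neighbor if — and only if — that payoff
strictly exceeds its own, with ties among equally-maximal neighbors broken
uniformly at random.  A game ends when all players hold the same strategy
(fixation) or after ``max_rounds`` rounds with two or more strategies
surviving, the equilibrium / "No Preference" state.

Imitation compares cumulative payoffs by default (``imitation_payoff=
"cumulative"``); a per-round-reset mode is kept for sensitivity analysis.
The cumulative comparison is what produces the model's characteristic
standoffs — defectors whose haul stalls once their victims are gone facing
cooperator clusters that keep accruing — and with it the reported
equilibrium states (thriving cooperators alongside defectors without
punishment; low-payoff defectors alongside lower-payoff punishers with
it).  Under per-round resets defection fixates almost surely in every
treatment and none of those states can occur.

When diversity is on, the interaction structure is re-randomized at the
start of each round, so imitation compares the previous round's payoffs
within the *new* neighborhoods before the new round is played.  This
ordering matters: payoffs earned in one neighborhood travel with the
player into the next, which is what lets a well-placed cooperator be
imitated by defectors it meets after rewiring.  (If instead each round's
imitation used the same graph the payoffs were earned on, a defector on a
k-regular structure could never see a cooperator whose payoff strictly
beats its own, and cooperation could never spread under diversity.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import networkx as nx
import numpy as np
import pandas as pd

from .networks import NetworkConfig, Topology, neighbor_table, _random_connected_edges
from .payoffs import PayoffParams, Strategy, payoff_array

__all__ = [
    "Outcome",
    "GameConfig",
    "GameState",
    "GameResult",
    "equal_composition",
    "play_round",
    "imitation_update",
    "run_game",
]


class Outcome(str, Enum):
    COOP_FIXATION = "COOP_FIXATION"
    DEFECT_FIXATION = "DEFECT_FIXATION"
    PUNISH_FIXATION = "PUNISH_FIXATION"
    NO_PREFERENCE = "NO_PREFERENCE"


_FIXATION = {
    Strategy.COOPERATE: Outcome.COOP_FIXATION,
    Strategy.DEFECT: Outcome.DEFECT_FIXATION,
    Strategy.PUNISH: Outcome.PUNISH_FIXATION,
}


def equal_composition(
    n_players: int, punishment_enabled: bool
) -> dict[Strategy, int]:
    """Split N players as evenly as possible over the admissible strategies.

    With punishment: equal thirds (6/6/6 at N=18); without: equal halves
    (9/9 at N=18).  Any remainder goes to defectors first, then cooperators
    (so N=625 without punishment gives 313 defectors / 312 cooperators).
    """
    kinds = (
        [Strategy.DEFECT, Strategy.COOPERATE, Strategy.PUNISH]
        if punishment_enabled
        else [Strategy.DEFECT, Strategy.COOPERATE]
    )
    base, rem = divmod(n_players, len(kinds))
    comp = {s: base + (1 if i < rem else 0) for i, s in enumerate(kinds)}
    return comp


@dataclass
class GameConfig:
    """Full specification of one game."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    params: PayoffParams = field(default_factory=PayoffParams)
    punishment_enabled: bool = True
    max_rounds: int = 1000
    initial_composition: dict[Strategy, int] | None = None
    # cumulative: imitation compares payoffs accumulated over the game;
    # "round" resets the comparison each round (sensitivity mode)
    imitation_payoff: str = "cumulative"

    def __post_init__(self) -> None:
        if self.initial_composition is None:
            self.initial_composition = equal_composition(
                self.network.n_players, self.punishment_enabled
            )
        comp = {Strategy(k): int(v) for k, v in self.initial_composition.items()}
        if any(v < 0 for v in comp.values()):
            raise ValueError("strategy counts must be non-negative")
        total = sum(comp.values())
        if total != self.network.n_players:
            raise ValueError(
                f"initial composition sums to {total}, expected "
                f"{self.network.n_players} players"
            )
        if not self.punishment_enabled and comp.get(Strategy.PUNISH, 0) > 0:
            raise ValueError("punishers require punishment_enabled=True")
        if self.imitation_payoff not in ("round", "cumulative"):
            raise ValueError("imitation_payoff must be 'round' or 'cumulative'")
        self.initial_composition = comp


@dataclass
class GameState:
    """Mutable per-round state of a running game."""

    strategies: np.ndarray  # int8 per player
    round_index: int = 0
    round_payoffs: np.ndarray | None = None
    strategy_round_counts: np.ndarray | None = None  # (N, 3) rounds spent per type

    def composition(self) -> dict[Strategy, int]:
        vals, counts = np.unique(self.strategies, return_counts=True)
        comp = {s: 0 for s in Strategy}
        comp.update({Strategy(int(v)): int(c) for v, c in zip(vals, counts)})
        return comp


@dataclass
class GameResult:
    """Terminal record of one game."""

    outcome: Outcome
    rounds_elapsed: int
    final_composition: dict[Strategy, int]
    mean_payoff_per_player_round: float
    strategy_round_counts: np.ndarray  # (N, 3)
    final_strategies: np.ndarray
    mean_round_payoffs: np.ndarray  # per-round mean payoff across players
    n_players: int

    @property
    def mean_cumulative_payoff(self) -> float:
        """Mean over players of total payoff accumulated over the whole game."""
        return float(self.mean_round_payoffs.sum())

    @property
    def defect_round_counts(self) -> np.ndarray:
        return self.strategy_round_counts[:, Strategy.DEFECT]

    @property
    def cooperate_round_counts(self) -> np.ndarray:
        return self.strategy_round_counts[:, Strategy.COOPERATE]

    def to_json(self) -> dict:
        return {
            "outcome": self.outcome.value,
            "rounds_elapsed": self.rounds_elapsed,
            "final_composition": {
                s.letter: int(c) for s, c in self.final_composition.items()
            },
            "mean_payoff_per_player_round": self.mean_payoff_per_player_round,
            "mean_cumulative_payoff": self.mean_cumulative_payoff,
            "n_players": self.n_players,
        }


def _strategies_array(strategies) -> np.ndarray:
    arr = np.asarray([int(Strategy(s)) for s in strategies], dtype=np.int8)
    return arr


def _round_payoffs(
    s: np.ndarray, nbr: np.ndarray, valid: np.ndarray, matrix: np.ndarray
) -> np.ndarray:
    pay = matrix[s[:, None], s[nbr]]
    pay[~valid] = 0.0
    return pay.sum(axis=1)


def _imitate(
    s: np.ndarray,
    payoffs: np.ndarray,
    nbr: np.ndarray,
    valid: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    p_nb = payoffs[nbr].copy()
    p_nb[~valid] = -np.inf
    best = p_nb.max(axis=1)
    switch = best > payoffs  # strict: equal-payoff neighbors never trigger a switch
    new = s.copy()
    if not switch.any():
        return new
    keys = rng.random(nbr.shape)
    keys[p_nb != best[:, None]] = -1.0
    choice = keys.argmax(axis=1)
    idx = np.flatnonzero(switch)
    new[idx] = s[nbr[idx, choice[idx]]]
    return new


def play_round(
    strategies, graph: nx.Graph, params: PayoffParams | None = None
) -> np.ndarray:
    """One round of pairwise games: each node's payoff summed over its neighbors."""
    s = _strategies_array(strategies)
    nbr, valid = neighbor_table(graph, len(s))
    return _round_payoffs(s, nbr, valid, payoff_array(params))


def imitation_update(
    strategies,
    round_payoffs,
    graph: nx.Graph,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Synchronous imitate-the-best update given this round's payoffs."""
    s = _strategies_array(strategies)
    rng = np.random.default_rng(rng)
    nbr, valid = neighbor_table(graph, len(s))
    return _imitate(s, np.asarray(round_payoffs, dtype=float), nbr, valid, rng)


def _initial_strategies(
    comp: dict[Strategy, int], rng: np.random.Generator
) -> np.ndarray:
    s = np.concatenate(
        [np.full(c, int(k), dtype=np.int8) for k, c in comp.items()]
    )
    rng.shuffle(s)
    return s


def run_game(
    config: GameConfig,
    rng: np.random.Generator | int | None = None,
    trajectory_path=None,
) -> GameResult:
    """Run one game to fixation or the round cap.

    Deterministic given the config and an integer seed (or seeded
    Generator).  ``trajectory_path`` optionally writes a per-round CSV with
    columns round, node, strategy, payoff.
    """
    rng = np.random.default_rng(rng)
    net = config.network
    n = net.n_players
    matrix = payoff_array(config.params)
    cumulative = config.imitation_payoff == "cumulative"

    strategies = _initial_strategies(config.initial_composition, rng)
    counts = np.zeros((n, 3), dtype=np.int64)
    mean_round_pay: list[float] = []
    cum_pay = np.zeros(n)
    traj_rows: list[tuple] = [] if trajectory_path is not None else None

    lattice = net.topology is Topology.LATTICE
    permute = lattice and net.diversity and net.lattice_diversity_mode == "permute"
    nbr = valid = None
    if lattice and not (net.diversity and net.lattice_diversity_mode == "regular"):
        nbr, valid = neighbor_table(net.build(), n)
    elif not lattice and not net.diversity:
        nbr, valid = neighbor_table(_random_connected_edges(n, net.n_edges, rng), n)

    rounds = 0
    idx = np.arange(n)
    s2p = idx
    prev_pay: np.ndarray | None = None  # player-indexed payoffs of the last round
    while rounds < config.max_rounds and not (strategies == strategies[0]).all():
        # (re)build this round's interaction structure
        if net.diversity:
            if permute:
                s2p = rng.permutation(n)  # entry v: the player occupying site v
            elif lattice:  # fresh random 4-regular graph
                seed = int(rng.integers(0, 2**31 - 1))
                g = nx.random_regular_graph(net.neighbors_k, n, seed=seed)
                nbr, valid = neighbor_table(g, n)
            else:
                nbr, valid = neighbor_table(
                    _random_connected_edges(n, net.n_edges, rng), n
                )

        # synchronous imitate-the-best on this round's neighborhoods,
        # comparing the payoffs everyone earned in the previous round
        if prev_pay is not None:
            imit_pay = cum_pay if cumulative else prev_pay
            if permute:
                new_site_s = _imitate(
                    strategies[s2p], imit_pay[s2p], nbr, valid, rng
                )
                strategies = strategies.copy()
                strategies[s2p] = new_site_s
            else:
                strategies = _imitate(strategies, imit_pay, nbr, valid, rng)
            if (strategies == strategies[0]).all():
                break

        site_s = strategies[s2p] if permute else strategies
        pay = _round_payoffs(site_s, nbr, valid, matrix)  # site-indexed
        if permute:
            prev_pay = np.empty(n)
            prev_pay[s2p] = pay
        else:
            prev_pay = pay
        counts[idx, strategies] += 1
        mean_round_pay.append(float(pay.mean()))
        if cumulative:
            cum_pay += prev_pay
        if traj_rows is not None:
            traj_rows.extend(
                (rounds, int(i), Strategy(int(strategies[i])).letter, float(prev_pay[i]))
                for i in range(n)
            )
        rounds += 1

    state = GameState(strategies, rounds, None, counts)
    comp = state.composition()
    survivors = [s for s, c in comp.items() if c > 0]
    if len(survivors) == 1:
        outcome = _FIXATION[survivors[0]]
    else:
        outcome = Outcome.NO_PREFERENCE
    mean_round_pay = np.asarray(mean_round_pay)
    mean_ppr = float(mean_round_pay.mean()) if rounds > 0 else 0.0

    if traj_rows is not None:
        pd.DataFrame(
            traj_rows, columns=["round", "node", "strategy", "payoff"]
        ).to_csv(trajectory_path, index=False)

    return GameResult(
        outcome=outcome,
        rounds_elapsed=rounds,
        final_composition=comp,
        mean_payoff_per_player_round=mean_ppr,
        strategy_round_counts=counts,
        final_strategies=strategies,
        mean_round_payoffs=mean_round_pay,
        n_players=n,
    )
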