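"""Game engine: round payoffs, synchronous imitation, termination, determinism."""

import itertools
from collections import Counter

import networkx as nx
import numpy as np
import pytest

from pdnet import (
    GameConfig,
    NetworkConfig,
    Outcome,
    PayoffParams,
    Strategy,
    Topology,
    equal_composition,
    imitation_update,
    pairwise_payoff,
    play_round,
    run_game,
)

C, D, P = Strategy.COOPERATE, Strategy.DEFECT, Strategy.PUNISH


def path_graph(n):
    return nx.path_graph(n)


def test_play_round_path_CDC():
    pay = play_round([C, D, C], path_graph(3))
    assert pay.tolist() == [-2, 8, -2]


def test_play_round_complete_cooperators():
    pay = play_round([C, C, C], nx.complete_graph(3))
    assert pay.tolist() == [4, 4, 4]


def test_play_round_all_defectors_zero():
    pay = play_round([D] * 5, nx.cycle_graph(5))
    assert pay.tolist() == [0] * 5


def test_imitation_update_path_CDC_all_defect():
    new = imitation_update([C, D, C], [-2, 8, -2], path_graph(3), 0)
    assert new.tolist() == [D, D, D]


def test_imitation_update_unanimous_unchanged():
    new = imitation_update([D, D, D], [5.0, 1.0, 3.0], path_graph(3), 0)
    assert new.tolist() == [D, D, D]


def test_imitation_update_equal_payoffs_never_switch():
    """Strict inequality: an equal-payoff neighbor does not trigger imitation."""
    new = imitation_update([C, D], [4.0, 4.0], path_graph(2), 0)
    assert new.tolist() == [C, D]


def test_imitation_tie_break_uniform():
    """A node facing two equally-maximal neighbors of different strategies
    adopts each with probability 1/2 (binomial 3-sigma check, 10^4 trials)."""
    star = nx.Graph([(0, 1), (0, 2)])
    rng = np.random.default_rng(7)
    picks = Counter()
    for _ in range(10_000):
        new = imitation_update([D, C, P], [0.0, 5.0, 5.0], star, rng)
        picks[Strategy(int(new[0]))] += 1
    assert set(picks) == {C, P}
    # 3 sigma around 5000 for p=1/2
    assert abs(picks[C] - 5000) <= 3 * 50


def complete_config(n_c, n_d, f=8.5, **kw):
    net = NetworkConfig(n_players=n_c + n_d, multiplying_factor=f)
    return GameConfig(
        network=net,
        punishment_enabled=False,
        initial_composition={C: n_c, D: n_d},
        **kw,
    )


def test_unanimous_start_terminates_at_round_zero():
    cfg = complete_config(18, 0)
    res = run_game(cfg, 0)
    assert res.outcome is Outcome.COOP_FIXATION
    assert res.rounds_elapsed == 0
    assert res.final_composition[C] == 18
    assert res.mean_payoff_per_player_round == 0.0


def test_one_mutant_defector_fixates_in_one_sweep():
    """On the complete 18-player graph every cooperator sees the lone
    defector's payoff of 68 beat its own 30 and switches at the first update."""
    for seed in range(20):
        res = run_game(complete_config(17, 1), seed)
        assert res.outcome is Outcome.DEFECT_FIXATION
        assert res.rounds_elapsed == 1


def test_seed_determinism():
    net = NetworkConfig(n_players=18, multiplying_factor=1.5, diversity=True)
    cfg = GameConfig(network=net, punishment_enabled=True, max_rounds=200)
    a = run_game(cfg, 123)
    b = run_game(cfg, 123)
    assert a.outcome == b.outcome
    assert a.rounds_elapsed == b.rounds_elapsed
    assert np.array_equal(a.final_strategies, b.final_strategies)
    assert np.array_equal(a.strategy_round_counts, b.strategy_round_counts)
    assert np.array_equal(a.mean_round_payoffs, b.mean_round_payoffs)


def test_player_count_conserved_and_strategies_admissible():
    cfg = GameConfig(
        network=NetworkConfig(n_players=18, multiplying_factor=1.1),
        punishment_enabled=True,
        max_rounds=100,
    )
    res = run_game(cfg, 5)
    assert sum(res.final_composition.values()) == 18
    assert set(np.unique(res.final_strategies)) <= {0, 1, 2}
    # tallies count exactly one strategy per player per played round
    assert res.strategy_round_counts.sum() == 18 * res.rounds_elapsed


def test_unanimity_is_absorbing():
    """Once every player holds one strategy, further play changes nothing."""
    res = run_game(complete_config(17, 1), 3)
    s = res.final_strategies
    g = nx.complete_graph(18)
    pay = play_round(s, g)
    after = imitation_update(s, pay, g, 0)
    assert np.array_equal(after, s)


def test_trajectory_dump(tmp_path):
    import pandas as pd

    cfg = complete_config(17, 1)
    path = tmp_path / "traj.csv"
    res = run_game(cfg, 0, trajectory_path=path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["round", "node", "strategy", "payoff"]
    assert len(df) == 18 * res.rounds_elapsed
    assert set(df["strategy"]) <= {"C", "D", "P"}


def test_game_config_validation():
    with pytest.raises(ValueError, match="sums to"):
        GameConfig(
            network=NetworkConfig(n_players=18, multiplying_factor=1.5),
            initial_composition={C: 5, D: 5},
        )
    with pytest.raises(ValueError, match="punishers"):
        GameConfig(
            network=NetworkConfig(n_players=18, multiplying_factor=1.5),
            punishment_enabled=False,
            initial_composition={C: 8, D: 8, P: 2},
        )
    assert equal_composition(18, True) == {D: 6, C: 6, P: 6}
    assert equal_composition(18, False) == {D: 9, C: 9}
    assert equal_composition(625, False) == {D: 313, C: 312}


# ---------------------------------------------------------------------------
# Exhaustive-enumeration oracle: for a 4-player game over 3 rounds, the
# engine's distribution of final states must match probability-weighted
# enumeration of every spanning tree, every initial arrangement, and every
# tie-break resolution.
# ---------------------------------------------------------------------------


def _oracle_distribution(n, composition, max_rounds, params):
    """Probability of each final strategy tuple, enumerated exactly.

    Mirrors the engine's control flow (play round 1; then imitate on
    cumulative payoffs / play until fixation or the cap) but computes
    payoffs by direct pairwise sums and enumerates tie-breaks exactly.
    """
    from pdnet.networks import _random_tree_edges  # enumerate via Pruefer space

    dist: Counter = Counter()

    def payoffs(s, nbrs):
        return [
            sum(pairwise_payoff(Strategy(s[i]), Strategy(s[j]), params) for j in nbrs[i])
            for i in range(n)
        ]

    def imitation_options(s, cum, nbrs):
        """Per node: list of (strategy, probability) after one update."""
        opts = []
        for i in range(n):
            best = max(cum[j] for j in nbrs[i])
            if best > cum[i]:
                arg = [j for j in nbrs[i] if cum[j] == best]
                cnt = Counter(s[j] for j in arg)
                opts.append([(sig, k / len(arg)) for sig, k in cnt.items()])
            else:
                opts.append([(s[i], 1.0)])
        return opts

    def step(s, cum, rounds, weight, nbrs, played_first):
        if len(set(s)) == 1 or rounds >= max_rounds:
            dist[s] += weight
            return
        if played_first:
            for combo in itertools.product(*imitation_options(s, cum, nbrs)):
                w = weight
                new_s = []
                for sig, p in combo:
                    w *= p
                    new_s.append(sig)
                new_s = tuple(new_s)
                if len(set(new_s)) == 1:
                    dist[new_s] += w
                    continue
                pay = payoffs(new_s, nbrs)
                step(new_s, tuple(c + p for c, p in zip(cum, pay)), rounds + 1, w, nbrs, True)
        else:
            pay = payoffs(s, nbrs)
            step(s, tuple(pay), rounds + 1, weight, nbrs, True)

    # all labelled trees on n nodes via their Pruefer sequences
    trees = [
        _random_tree_edges(n, _FixedSeq(seq))
        for seq in itertools.product(range(n), repeat=n - 2)
    ]
    pool = [int(k) for k, c in composition.items() for _ in range(c)]
    arrangements = set(itertools.permutations(pool))
    w0 = 1.0 / (len(trees) * len(arrangements))
    for edges in trees:
        nbrs = [[] for _ in range(n)]
        for u, v in edges:
            nbrs[u].append(v)
            nbrs[v].append(u)
        for s0 in arrangements:
            step(tuple(s0), (0.0,) * n, 0, w0, nbrs, False)
    return dist


class _FixedSeq:
    """Stands in for a Generator so _random_tree_edges decodes a given sequence."""

    def __init__(self, seq):
        self.seq = np.array(seq)

    def integers(self, lo, hi, size):
        assert size == len(self.seq)
        return self.seq


def test_engine_matches_exhaustive_enumeration():
    """Distribution of final states of a 4-player, 3-round game equals the
    exhaustively enumerated tie-break/tree/arrangement distribution."""
    params = PayoffParams()
    comp = {C: 2, D: 1, P: 1}
    oracle = _oracle_distribution(4, comp, 3, params)
    assert abs(sum(oracle.values()) - 1.0) < 1e-9

    cfg = GameConfig(
        network=NetworkConfig(n_players=4, multiplying_factor=0.75),
        punishment_enabled=True,
        max_rounds=3,
        initial_composition=comp,
    )
    n_runs = 4000
    empirical: Counter = Counter()
    for seed in range(n_runs):
        res = run_game(cfg, seed)
        empirical[tuple(int(x) for x in res.final_strategies)] += 1

    states = set(oracle) | set(empirical)
    tv = 0.5 * sum(
        abs(oracle.get(s, 0.0) - empirical.get(s, 0) / n_runs) for s in states
    )
    assert tv < 0.06, f"total variation {tv:.3f}"
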