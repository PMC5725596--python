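"""One repeated game on a random 18-player network.

Builds a random connected graph with density of connectivity D_c = 18 x
1.5 = 27 edges, starts with 6 cooperators, 6 defectors, and 6 punishers,
and runs up to 1000 rounds of pairwise games with synchronous
imitate-the-best updates.  Prints the terminal outcome: which strategy (if
any) swept the network, how long it took, and the average payoff earned.
"""

from pdnet import GameConfig, NetworkConfig, run_game

config = GameConfig(
    network=NetworkConfig(n_players=18, multiplying_factor=1.5),
    punishment_enabled=True,
)
result = run_game(config, rng=42)

print("outcome:           ", result.outcome.value)
print("rounds played:     ", result.rounds_elapsed)
print("final composition: ", {s.letter: c for s, c in result.final_composition.items()})
print(f"mean payoff per player-round: {result.mean_payoff_per_player_round:.3f}")
print("A NO_PREFERENCE outcome means two or more strategies still coexisted")
print("when the 1000-round cap was reached; otherwise one strategy fixed.")
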