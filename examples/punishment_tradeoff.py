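"""Costly punishment disfavors defection but lowers the average payoff.

Runs two 100-game ensembles at f=2.5 (N=18), with and without costly
punishers in the initial population, and compares the probability that
defection ends up the sole strategy and the mean per-player per-round
payoff.  Punishment turns most defection sweeps into defector-punisher
standoffs — at the price of everyone earning less.
"""

from pdnet import GameConfig, NetworkConfig, Outcome, TreatmentConfig, run_ensemble

for punishment in (False, True):
    game = GameConfig(
        network=NetworkConfig(n_players=18, multiplying_factor=2.5),
        punishment_enabled=punishment,
    )
    res = run_ensemble(TreatmentConfig(game=game, n_games=100), master_seed=1)
    print(
        f"punishment={'on ' if punishment else 'off'}: "
        f"P(defection fixes)={res.outcome_probabilities[Outcome.DEFECT_FIXATION]:.2f}  "
        f"P(no preference)={res.outcome_probabilities[Outcome.NO_PREFERENCE]:.2f}  "
        f"mean payoff={res.mean_average_payoff:+.2f}"
    )
print("Lower defection probability with punishment, but a lower (negative)")
print("average payoff: punishing is costly for everyone.")
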