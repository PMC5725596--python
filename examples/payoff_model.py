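"""The pairwise payoff matrix and the complete-graph expected values.

Prints the actor-row payoff matrix with and without costly punishment and
the expected per-round payoffs of cooperators and defectors on a fully
connected 18-player network, illustrating why a single mutant defector is
enough to take over: its expected payoff (68) is more than double any
cooperator's (30), so under imitate-the-best every cooperator copies it.
"""

from pdnet import (
    expected_value_cooperator,
    expected_value_defector,
    payoff_matrix,
)

print("Payoff matrix (actor rows), default parameters b=3, c=1, d=1, alpha=1, beta=4:")
print(payoff_matrix())
print("\nWithout costly punishment (cooperate/defect submatrix):")
print(payoff_matrix(punishment_enabled=False))

print("\nComplete 18-player graph, 17 cooperators + 1 mutant defector:")
print("  cooperator expected payoff:", expected_value_cooperator(17, 1))
print("  defector expected payoff:  ", expected_value_defector(17, 1))
print("The defector earns more than twice any cooperator, so every")
print("cooperator imitates it and defection fixes in a single update.")
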