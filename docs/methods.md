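# Methods

## Model definition

A population of `N` players occupies the nodes of an undirected, simple,
connected graph.  Each player holds one of three pure strategies:
cooperate (C), defect (D), or costly punishment (P).  A *game* is a
sequence of rounds; in each round every player plays one pairwise
Prisoner's Dilemma with each of its current neighbors and receives the sum
of the pairwise payoffs.  The pairwise payoff to the actor is the sum of
what its own move earns it and what the partner's move does to it, built
from five constants (all in dimensionless payoff units):

| constant | meaning | default |
|----------|---------|---------|
| `b` | benefit a cooperator confers on its partner | 3 |
| `c` | cost of cooperating, per interaction | 1 |
| `d` | defection gain (partner loses the same amount) | 1 |
| `alpha` | cost of punishing, per interaction | 1 |
| `beta` | loss inflicted on a punished partner | 4 |

giving the actor-row matrix `[[b−c, −d−c, −β−c], [b+d, 0, −β+d],
[b−α, −d−α, −β−α]]` = `[[2, −2, −5], [4, 0, −3], [2, −2, −5]]`.
Punishers are unconditional: the matrix as defined inflicts `β` on every
partner, cooperators included.  Whether that is behaviorally intended is
ambiguous, but it is what the symmetric construction implies, and we
implement it exactly; a "punish defectors only" variant is deliberately
not offered.  When punishment is disabled the strategy space is restricted
to the C/D submatrix and no punisher may appear in any state.

## Update rule

Strategy dynamics are synchronous **imitate-the-best** with a strict
threshold: before each round after the first, every player simultaneously
examines the payoffs of its current neighbors and adopts the strategy of
the maximum-payoff neighbor if and only if that payoff strictly exceeds
its own.  Ties among equally-maximal neighbors are broken uniformly at
random (a deterministic rule would bias the lattice's symmetries); an
equal-payoff neighbor never causes a switch.  Unanimity is absorbing.

Two design points deserve emphasis because the model's qualitative
behavior hinges on them:

**Imitation compares cumulative payoffs.**  The payoff a player carries
into the comparison is its total accumulated over the game so far, not the
last round's haul (a per-round-reset mode is retained as
`imitation_payoff="round"` for sensitivity analysis).  The cumulative
comparison is what produces the model's characteristic standoffs: once a
defector's cooperator neighbors are gone its total stalls (D–D pays 0),
while a surviving cooperator cluster keeps accruing `b−c` per internal
edge per round — so equilibria of defectors coexisting with *thriving*
cooperators, and of low-payoff defectors facing even-lower-payoff
punishers, can persist to the round cap.  Under per-round resets these
states cannot exist and defection fixes in essentially every treatment on
every topology: on a k-regular graph a defector adjacent to a cooperator
caps that cooperator's round payoff at `(k−1)(b−c) − (d+c)`, which never
strictly exceeds the defector's own gain from that same cooperator, so a
defector can never adopt cooperation at all.  The cumulative rule is
therefore the substantive model; the reset rule is a falsifiable
alternative the test suite does not use.

**Payoffs travel with players under diversity.**  When diversity is on,
the interaction structure is re-randomized at the *start* of each round,
and the imitation step compares previously-earned payoffs within the new
neighborhoods.  A cooperator that accumulated wealth in one neighborhood
is then visible — and imitable — to defectors it meets after rewiring.
This ordering, rather than imitating on the same graph the payoffs were
earned on, is what allows diversity to convert stalled mixed states into
cooperation sweeps.

## Networks

* **Random topology.**  The density of connectivity is `D_c = N·f`,
  rounded half-away-from-zero to an edge count, feasible in
  `[N−1, N(N−1)/2]`, i.e. `f ∈ [(N−1)/N, (N−1)/2]`.  Graphs are sampled
  as a uniform random labelled spanning tree (random Prüfer sequence)
  plus uniformly chosen additional non-edges: connected, simple, exact
  edge count, randomized degree sequence.  Any connected sampler with an
  exact edge count would satisfy the model's definition; this one is
  simple and easy to test.
* **Square lattice.**  `side²` players with von Neumann neighborhoods.
  Periodic boundaries (default) keep every degree exactly 4; the open
  lattice is retained for sensitivity analysis, and a 2×2 torus is
  rejected because its wrap-around edges would collapse into multi-edges.
* **Diversity.**  Random topology: a fresh random connected graph with
  the same edge count each round.  Lattice: the default mechanism draws a
  fresh random 4-regular graph each round, keeping `k = 4` while
  re-randomizing all connections; a player-to-site permutation over the
  fixed lattice (structure fixed, occupants shuffled) is available as
  `lattice_diversity_mode="permute"`.  The two mechanisms give similar
  results — the permutation mode runs a few percentage points lower on
  the majority-defection statistic — and the regular-graph mechanism is
  the default because exchanging *connections* rather than *locations* is
  the more literal reading of per-round heterogeneity with constant k.

## Games, ensembles, and statistics

A game starts from a uniformly random placement of a fixed strategy
composition — equal thirds with punishment (6/6/6 at N = 18), equal halves
without (9/9); remainders go to defectors first, so the 625-player lattice
starts 313 D / 312 C.  A game ends at unanimity (fixation of C, D, or P)
or after `max_rounds = 1000` rounds in the equilibrium / "No Preference"
state.  An initial unanimous state terminates at round 0 before any
interaction.  1000 rounds is past the point where further rounds change
outcomes at these sizes; runtime is dominated by No Preference games that
run to the cap.

Ensembles run `n_games` (default 100) independent games; each game's
generator is spawned from the master seed via `numpy` seed sequences, so
every ensemble is exactly reproducible and games are independent.
Reported statistics:

* **Outcome probabilities** — fraction of games ending in each fixation
  class or No Preference.
* **Mean average payoff** — each game's mean per-player per-round payoff,
  averaged over games.  The averaging window is an interpretation (a
  game-end cumulative mean is also carried as
  `mean_cumulative_payoff`); per-player-per-round is the headline number
  because it is comparable across games of different lengths.
* **Majority-defection fraction** — a player is majority-defecting if it
  spent strictly more rounds holding D than C; a game counts if more than
  half its players are (the "large majority" threshold is a config knob,
  default 0.5); the statistic is the fraction of such games.  A game
  unanimous at round 0 contributes its single starting composition.
* **Equilibrium composition** — No Preference games are labelled
  `C_AND_D`, `D_AND_P`, or `OTHER` by their surviving strategy set; only
  the final composition is classified, not intermediate oscillations.

## Numerical and degenerate-input choices

Payoffs are float64 throughout (integers under the defaults).  The engine
evaluates rounds vectorized over a padded neighbor table; the public
`play_round` / `imitation_update` accept any `networkx` graph.  Degenerate
inputs are rejected with explicit messages: infeasible `f` (with the valid
range), composition/player-count mismatches, punishers without punishment,
`N < 2` graphs.  Determinism: one game is a pure function of its
configuration and seed.

## What the tests show — and what they do not

The suite verifies the payoff algebra exactly, checks the closed-form
complete-graph expected values against brute-force neighbor sums, matches
the engine's small-game trajectory distribution against exhaustive
enumeration of every spanning tree, initial arrangement, and tie-break
resolution (4 players, 3 rounds, total-variation < 0.06 at 4000 runs), and
reproduces the replication statistics at 100 games and the directional
punishment × diversity × connectivity interactions at binomial 3σ.
Problem sizes (100-game ensembles; 10,000 games for the rare-cooperation
bound) mirror the study conditions.  All of this characterizes the model,
not the world: the agents are memoryless pure-strategy imitators, payoffs
are noiseless, and the networks are synthetic; conclusions about human or
biological cooperation require the model's assumptions to hold there.

## Known limitations

* No asynchronous or payoff-proportional (Fermi) updating; no mutation or
  exploration noise; no mixed or reactive strategies.
* `mean_average_payoff` for a game unanimous at round 0 is defined as 0
  (no rounds were played).
* Fresh random 4-regular graphs are sampled without conditioning on
  connectivity; at 625 nodes disconnection is vanishingly rare and a rare
  disconnected round is harmless to the dynamics.
* The cumulative-payoff and travel-with-players conventions above are
  modelling choices for an under-determined verbal specification; the
  alternative conventions are implemented behind flags so their (very
  different) behavior can be examined directly.
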