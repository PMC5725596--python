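# pdnet — repeated Prisoner's Dilemma games on networks

`pdnet` is an agent-based simulator for studying how **costly punishment**,
**diversity** (per-round re-randomization of who interacts with whom), and
the **density of connectivity** of an interaction network jointly shape the
evolution of cooperation.  It is aimed at researchers in evolutionary game
theory and network science who want a small, fully reproducible model of
strategy dynamics on graphs with controllable treatments.

## The model

Players are nodes of a connected graph; each of the `N` players holds one
of three strategies — cooperate (C), defect (D), or costly punishment (P).
Every round, each player plays a pairwise Prisoner's Dilemma with each of
its neighbors.  Cooperating pays a cost *c* = 1 so the partner gains
*b* = 3; defecting gains *d* = 1 at an equal cost to the partner; punishing
pays *α* = 1 so the partner loses *β* = 4.  The resulting actor-row payoff
matrix is

|       | C  | D  | P  |
|-------|----|----|----|
| **C** | b−c = 2 | −d−c = −2 | −β−c = −5 |
| **D** | b+d = 4 | 0         | −β+d = −3 |
| **P** | b−α = 2 | −d−α = −2 | −β−α = −5 |

Strategies evolve by synchronous **imitate-the-best**: before each round,
every player looks at the payoff each current neighbor has accumulated
over the game and copies the strategy of the richest neighbor, provided
that payoff strictly exceeds its own (ties among equally-rich neighbors
break uniformly at random).  A game ends when one strategy fixes, or after
1000 rounds in the equilibrium / "No Preference" state with two or more
strategies still coexisting.

The interaction graph is controlled by the **density of connectivity**
`D_c = N·f`: the total number of edges, set through the multiplying factor
`f`, feasible between `(N−1)/N` (spanning tree) and `(N−1)/2` (complete
graph).  With **diversity** on, the graph is re-randomized every round.
A 25×25 periodic square lattice with k = 4 neighbors is provided for the
spatial-structure replication experiment.

On a complete graph the expected per-round payoffs are
`E[C] = (N_c−1)(b−c) + N_d(−d−c)` and `E[D] = N_c(b+d)`; since `E[D] >
2·E[C]` even for a single mutant defector, one defector suffices to sweep
a fully connected population — the baseline against which punishment,
diversity, and sparsity are measured.

## Worked example

The square-lattice replication: 625 players (313 defectors / 312
cooperators), fixed neighborhoods (control) versus per-round rewiring
(experimental):

```bash
$ python examples/lattice_replication.py 20
control (fixed lattice) : majority-defection 100% | cooperation fixes 0% | No Preference games 1 (surviving cooperators: [5])
experimental (diversity): majority-defection 100% | cooperation fixes 55% | No Preference games 0
```

In every control game — and nearly every experimental one — most players
spend more rounds defecting than cooperating: locally, defection rules.
Yet globally, rewiring the network every round lets cooperation emerge as
the *sole surviving strategy* in about half the experimental games, while
control games either fix on defection or stall with a handful of surviving
cooperators in clusters.  Other examples in `examples/` show the payoff
algebra, a single game, the punishment/payoff trade-off, and the
connectivity × diversity sweep.

The same experiments are scriptable from the shell:

```bash
pdnet run --n-players 18 --f 1.5 --games 100 --punishment on --diversity off --seed 42 --out out/
pdnet reproduce fig6 --seed 1 --out out/   # presets: fig2 fig3 fig4 fig5 fig6
```

Each run writes a tidy `results.csv` (one row per ensemble) and a
`manifest.json` with the resolved configuration and seeds; identical seeds
reproduce byte-identical CSVs.

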