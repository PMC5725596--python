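"""Interaction-graph construction.

Two topologies are supported:

* ``RANDOM`` — a connected simple graph on N nodes whose edge count is the
  density of connectivity ``D_c = round(N * f)``, where ``f`` is the
  multiplying factor.  Connectivity pins ``f`` to the feasible range
  ``(N-1)/N <= f <= (N-1)/2`` (spanning tree up to complete graph).  The
  sampler draws a uniform random labelled spanning tree (via a random
  Pruefer sequence) and then adds the remaining edges uniformly at random
  without replacement from the non-edges, so degree sequences vary across
  draws while the edge count is exact.
* ``LATTICE`` — a square lattice with von Neumann (k=4) neighborhoods.
  Periodic boundaries (a torus) keep every degree exactly 4; the open
  lattice is retained for sensitivity analysis.

"Diversity" re-randomizes who interacts with whom every round: a fresh
random connected graph with the same edge count (RANDOM), or — keeping
the degree fixed at k=4 — a fresh random 4-regular graph (LATTICE
default).  A uniform permutation of players over the fixed lattice sites
(structure fixed, occupants shuffled) is available as an alternative
lattice mechanism.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "Topology",
    "NetworkConfig",
    "f_range",
    "edge_count",
    "random_connected_graph",
    "square_lattice",
    "rewire_for_diversity",
    "write_edge_list",
]


class Topology(str, Enum):
    RANDOM = "random"
    LATTICE = "lattice"


def f_range(n_players: int) -> tuple[float, float]:
    """Feasible range of the multiplying factor f for a connected graph.

    The least density of connectivity is the spanning tree (N-1 edges,
    f = (N-1)/N); the highest is the complete graph (N(N-1)/2 edges,
    f = (N-1)/2).
    """
    if n_players < 2:
        raise ValueError("f_range requires at least 2 players")
    n = n_players
    return (n - 1) / n, (n - 1) / 2


def edge_count(n_players: int, f: float) -> int:
    """Density of connectivity D_c = N*f, rounded half-away-from-zero.

    Raises if the rounded count falls outside [N-1, C(N,2)].
    """
    if n_players < 2:
        raise ValueError("edge_count requires at least 2 players")
    m = math.floor(n_players * f + 0.5)
    lo, hi = n_players - 1, n_players * (n_players - 1) // 2
    if not lo <= m <= hi:
        fmin, fmax = f_range(n_players)
        raise ValueError(
            f"f={f} infeasible for N={n_players}: need "
            f"{fmin:.6g} <= f <= {fmax:.6g} (edge count in [{lo}, {hi}])"
        )
    return m


def _random_tree_edges(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random labelled tree on n nodes, decoded from a Pruefer sequence."""
    if n == 2:
        return np.array([[0, 1]])
    prufer = rng.integers(0, n, size=n - 2)
    degree = np.ones(n, dtype=np.int64)
    for v in prufer:
        degree[v] += 1
    leaves = [int(v) for v in range(n) if degree[v] == 1]
    heapq.heapify(leaves)
    edges = np.empty((n - 1, 2), dtype=np.int64)
    for i, v in enumerate(prufer):
        leaf = heapq.heappop(leaves)
        edges[i] = (leaf, v)
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, int(v))
    u = heapq.heappop(leaves)
    w = heapq.heappop(leaves)
    edges[n - 2] = (u, w)
    return edges


def _random_connected_edges(
    n: int, n_edges: int, rng: np.random.Generator
) -> np.ndarray:
    """Edge array of a random connected simple graph with exactly n_edges edges."""
    max_edges = n * (n - 1) // 2
    if not n - 1 <= n_edges <= max_edges:
        raise ValueError(
            f"n_edges={n_edges} infeasible for n={n}: need {n - 1} <= m <= {max_edges}"
        )
    tree = _random_tree_edges(n, rng)
    extra = n_edges - (n - 1)
    if extra == 0:
        return tree
    # pair id for (i, j), i < j, in lexicographic order
    iu, ju = np.triu_indices(n, k=1)
    lo = np.minimum(tree[:, 0], tree[:, 1])
    hi = np.maximum(tree[:, 0], tree[:, 1])
    tree_ids = lo * n + hi
    all_ids = iu * n + ju
    candidates = np.flatnonzero(~np.isin(all_ids, tree_ids))
    pick = rng.choice(candidates, size=extra, replace=False)
    extra_edges = np.column_stack([iu[pick], ju[pick]])
    return np.concatenate([tree, extra_edges])


def random_connected_graph(
    n_players: int, n_edges: int, rng: np.random.Generator | int | None = None
) -> nx.Graph:
    """Connected simple graph on ``n_players`` nodes with exactly ``n_edges`` edges.

    Uniform spanning tree plus uniformly chosen extra non-edges; node labels
    are 0..N-1.
    """
    rng = np.random.default_rng(rng)
    edges = _random_connected_edges(n_players, n_edges, rng)
    g = nx.Graph()
    g.add_nodes_from(range(n_players))
    g.add_edges_from(map(tuple, edges.tolist()))
    return g


def square_lattice(side: int, periodic: bool = True) -> nx.Graph:
    """Square lattice with von Neumann neighborhoods, nodes relabelled 0..side^2-1.

    Periodic boundaries require side >= 3 (on a 2x2 torus the wrap-around
    edges collapse into multi-edges); the open lattice allows side >= 2.
    """
    if side < 2:
        raise ValueError("square_lattice requires side >= 2")
    if periodic and side < 3:
        raise ValueError("periodic square_lattice requires side >= 3")
    g = nx.grid_2d_graph(side, side, periodic=periodic)
    mapping = {(r, c): r * side + c for r, c in g.nodes}
    return nx.relabel_nodes(g, mapping)


@dataclass
class NetworkConfig:
    """Topology specification for one game.

    For RANDOM topology ``n_players`` and ``multiplying_factor`` (f) fix the
    edge count; for LATTICE, ``lattice_side`` fixes ``n_players = side**2``
    with k=4 neighbors.  ``diversity`` re-randomizes the interaction
    structure every round.
    """

    topology: Topology = Topology.RANDOM
    n_players: int = 18
    multiplying_factor: float | None = 1.5
    lattice_side: int | None = None
    neighbors_k: int = 4
    periodic: bool = True
    diversity: bool = False
    lattice_diversity_mode: str = "regular"  # or "permute"

    def __post_init__(self) -> None:
        self.topology = Topology(self.topology)
        if self.topology is Topology.RANDOM:
            if self.multiplying_factor is None:
                raise ValueError("RANDOM topology requires a multiplying factor f")
            edge_count(self.n_players, self.multiplying_factor)  # validates range
        else:
            if self.lattice_side is None:
                self.lattice_side = int(round(math.sqrt(self.n_players)))
            if self.lattice_side**2 != self.n_players:
                raise ValueError(
                    f"LATTICE requires n_players = lattice_side**2, got "
                    f"{self.n_players} != {self.lattice_side}**2"
                )
            if self.neighbors_k != 4:
                raise ValueError("LATTICE supports only k=4 (von Neumann) neighborhoods")
            if self.lattice_diversity_mode not in ("permute", "regular"):
                raise ValueError("lattice_diversity_mode must be 'permute' or 'regular'")

    @property
    def n_edges(self) -> int:
        if self.topology is Topology.RANDOM:
            return edge_count(self.n_players, self.multiplying_factor)
        side = self.lattice_side
        return 2 * side * side if self.periodic else 2 * side * (side - 1)

    def build(self, rng: np.random.Generator | int | None = None) -> nx.Graph:
        """Instantiate one interaction graph."""
        if self.topology is Topology.RANDOM:
            return random_connected_graph(self.n_players, self.n_edges, rng)
        return square_lattice(self.lattice_side, periodic=self.periodic)


def rewire_for_diversity(
    config: NetworkConfig, rng: np.random.Generator | int | None = None
) -> nx.Graph | np.ndarray:
    """One round's diversity re-randomization.

    RANDOM topology: a fresh random connected graph with the same edge count.
    LATTICE topology (default "regular" mode): a fresh random 4-regular
    graph, preserving the degree k=4 while re-randomizing all connections.
    In "permute" mode a uniform permutation of players over lattice sites
    is returned instead — entry ``v`` is the player occupying site ``v``
    this round; the lattice itself stays fixed.
    """
    if not config.diversity:
        raise ValueError("rewire_for_diversity requires the diversity flag")
    rng = np.random.default_rng(rng)
    if config.topology is Topology.RANDOM:
        return random_connected_graph(config.n_players, config.n_edges, rng)
    if config.lattice_diversity_mode == "regular":
        seed = int(rng.integers(0, 2**31 - 1))
        g = nx.random_regular_graph(config.neighbors_k, config.n_players, seed=seed)
        return g
    return rng.permutation(config.n_players)


def write_edge_list(graph: nx.Graph, path) -> None:
    """Write a graph as a two-column text edge list (0-based node ids)."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u} {v}\n")


def neighbor_table(
    graph_or_edges: nx.Graph | Iterable[tuple[int, int]] | np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Padded neighbor-index table for vectorized round evaluation.

    Returns ``(nbr, valid)`` where ``nbr`` is an (n, max_degree) int array of
    neighbor ids (padded with 0) and ``valid`` the boolean mask of real
    entries.
    """
    if isinstance(graph_or_edges, nx.Graph):
        edges = np.array(graph_or_edges.edges, dtype=np.int64).reshape(-1, 2)
    else:
        edges = np.asarray(graph_or_edges, dtype=np.int64).reshape(-1, 2)
    deg = np.zeros(n, dtype=np.int64)
    np.add.at(deg, edges[:, 0], 1)
    np.add.at(deg, edges[:, 1], 1)
    width = max(int(deg.max(initial=0)), 1)
    nbr = np.zeros((n, width), dtype=np.int64)
    fill = np.zeros(n, dtype=np.int64)
    for u, v in edges:
        nbr[u, fill[u]] = v
        fill[u] += 1
        nbr[v, fill[v]] = u
        fill[v] += 1
    valid = np.arange(width)[None, :] < deg[:, None]
    return nbr, valid
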