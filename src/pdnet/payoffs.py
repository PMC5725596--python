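"""Pairwise payoff model for the three-strategy Prisoner's Dilemma.

The game has three agent types: cooperators (C) pay a cost ``c`` so that
their partner gains a benefit ``b``; defectors (D) gain ``d`` at a cost of
``d`` to their partner; costly punishers (P) pay ``alpha`` so that their
partner loses ``beta``.  Each pairwise interaction sums what the actor's
own move earns with what the partner's move does to the actor, giving the
actor-row payoff matrix::

            partner: C       D        P
    actor C        b - c   -d - c   -beta - c
    actor D        b + d      0     -beta + d
    actor P      b - alpha  -d - alpha  -beta - alpha

With the default unit payoffs (b=3, c=1, d=1, alpha=1, beta=4) the matrix
is [[2, -2, -5], [4, 0, -3], [2, -2, -5]].

Note the matrix is stored actor-row: ``pairwise_payoff(D, C)`` is +4, the
defector's take when exploiting a cooperator — never transpose it.
Punishers are unconditional: they inflict ``beta`` on every partner,
cooperators included (the symmetric matrix above, implemented as printed;
a "punish defectors only" rule is deliberately not offered).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "Strategy",
    "PayoffParams",
    "pairwise_payoff",
    "payoff_matrix",
    "payoff_array",
    "expected_value_cooperator",
    "expected_value_defector",
]


class Strategy(IntEnum):
    """The three admissible agent types."""

    COOPERATE = 0
    DEFECT = 1
    PUNISH = 2

    @property
    def letter(self) -> str:
        return {0: "C", 1: "D", 2: "P"}[int(self)]


_LETTERS = ["C", "D", "P"]


@dataclass(frozen=True)
class PayoffParams:
    """The five payoff constants, in dimensionless payoff units.

    b     benefit a cooperator confers on its partner
    c     cost of cooperating
    d     defection gain (and the partner's equal loss)
    alpha cost of punishing
    beta  loss inflicted on the punished partner
    """

    b: float = 3.0
    c: float = 1.0
    d: float = 1.0
    alpha: float = 1.0
    beta: float = 4.0

    def __post_init__(self) -> None:
        for name in ("b", "c", "d", "alpha", "beta"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"payoff constant {name!r} must be finite, got {v}")


def _as_strategy(value: object) -> Strategy:
    try:
        return Strategy(value)
    except ValueError:
        raise ValueError(
            f"invalid strategy {value!r}; must be one of "
            f"{[s.name for s in Strategy]}"
        ) from None


def payoff_array(params: PayoffParams | None = None) -> np.ndarray:
    """3x3 actor-row payoff matrix as a float array indexed by Strategy value."""
    p = params or PayoffParams()
    return np.array(
        [
            [p.b - p.c, -p.d - p.c, -p.beta - p.c],
            [p.b + p.d, 0.0, -p.beta + p.d],
            [p.b - p.alpha, -p.d - p.alpha, -p.beta - p.alpha],
        ]
    )


def pairwise_payoff(
    actor: Strategy, partner: Strategy, params: PayoffParams | None = None
) -> float:
    """Payoff the *actor* receives from one interaction with *partner*."""
    a = _as_strategy(actor)
    b = _as_strategy(partner)
    return float(payoff_array(params)[a, b])


def payoff_matrix(
    params: PayoffParams | None = None, punishment_enabled: bool = True
) -> pd.DataFrame:
    """Actor-row payoff matrix as a labelled DataFrame.

    With ``punishment_enabled=False`` the punisher type is inadmissible and
    only the 2x2 cooperate/defect submatrix is returned.
    """
    arr = payoff_array(params)
    k = 3 if punishment_enabled else 2
    labels = _LETTERS[:k]
    return pd.DataFrame(arr[:k, :k], index=labels, columns=labels)


def expected_value_cooperator(
    n_cooperators: int, n_defectors: int, params: PayoffParams | None = None
) -> float:
    """Per-round payoff of one cooperator in a complete C/D population.

    On the complete graph every cooperator meets the other ``Nc - 1``
    cooperators and all ``Nd`` defectors, so its round payoff is
    ``(Nc - 1)(b - c) + Nd(-d - c)`` — with default payoffs,
    ``2 Nc - 2 - 2 Nd``.
    """
    if n_cooperators < 1:
        raise ValueError("expected_value_cooperator requires at least one cooperator")
    if n_defectors < 0:
        raise ValueError("n_defectors must be non-negative")
    p = params or PayoffParams()
    return (n_cooperators - 1) * (p.b - p.c) + n_defectors * (-p.d - p.c)


def expected_value_defector(
    n_cooperators: int, n_defectors: int, params: PayoffParams | None = None
) -> float:
    """Per-round payoff of one defector in a complete C/D population.

    ``(Nd - 1) * 0 + Nc (b + d)`` — with default payoffs, ``4 Nc``.  Because
    this exceeds twice the cooperator's expected value even for a single
    mutant defector, one defector suffices to take over a fully connected
    population under imitate-the-best dynamics.
    """
    if n_defectors < 1:
        raise ValueError("expected_value_defector requires at least one defector")
    if n_cooperators < 0:
        raise ValueError("n_cooperators must be non-negative")
    p = params or PayoffParams()
    return n_cooperators * (p.b + p.d)
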