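"""Hierarchy formation and round-robin session scheduling.

A session group has ``group_size`` players.  In the earned-hierarchy
treatments players are ranked by descending skill score (abstract stand-ins
for the ranking tasks); in the random-hierarchy treatments ranks are a
uniform permutation; the control has no ranks.  Every player then meets every
other player exactly once over ``group_size - 1`` rounds (a 1-factorization
built with the circle method).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Hierarchy",
    "Schedule",
    "form_hierarchy_earned",
    "form_hierarchy_random",
    "round_robin_schedule",
]


@dataclass(frozen=True)
class Hierarchy:
    """Bijection player index -> rank (1 = top); ``ranks`` is None when origin is 'none'."""

    ranks: Optional[tuple[int, ...]]
    origin: str  # earned | random | none

    def __post_init__(self) -> None:
        if self.origin not in ("earned", "random", "none"):
            raise ValueError(f"unknown hierarchy origin {self.origin!r}")
        if self.origin == "none":
            if self.ranks is not None:
                raise ValueError("origin 'none' implies no ranks")
        else:
            n = len(self.ranks)
            if sorted(self.ranks) != list(range(1, n + 1)):
                raise ValueError("ranks must be a permutation of 1..n")

    def rank_of(self, player: int) -> int:
        return self.ranks[player]


@dataclass(frozen=True)
class Schedule:
    """``rounds[r]`` is a perfect matching: tuples of player-index pairs."""

    rounds: tuple[tuple[tuple[int, int], ...], ...]


def form_hierarchy_earned(
    skill_scores: Sequence[float], rng: np.random.Generator
) -> Hierarchy:
    """Rank players by descending skill score; ties broken by the seeded RNG."""
    scores = np.asarray(skill_scores, dtype=float)
    if scores.ndim != 1 or scores.size < 2:
        raise ValueError("need one numeric score per player (at least two players)")
    # random tie-break: jitter the sort key by a random permutation index
    tiebreak = rng.permutation(scores.size)
    order = np.lexsort((tiebreak, -scores))  # primary: descending score
    ranks = np.empty(scores.size, dtype=int)
    ranks[order] = np.arange(1, scores.size + 1)
    return Hierarchy(ranks=tuple(int(r) for r in ranks), origin="earned")


def form_hierarchy_random(group_size: int, rng: np.random.Generator) -> Hierarchy:
    """Uniform random ranking, as in the arbitrary-hierarchy treatments."""
    if group_size < 2:
        raise ValueError("group_size must be at least 2")
    ranks = rng.permutation(group_size) + 1
    return Hierarchy(ranks=tuple(int(r) for r in ranks), origin="random")


def round_robin_schedule(group_size: int) -> Schedule:
    """Circle-method 1-factorization: n-1 rounds, each pair met exactly once.

    Player ``n-1`` is the fixed pivot; the others rotate around the circle.
    """
    n = group_size
    if n < 2 or n % 2 != 0:
        raise ValueError(f"group_size must be even and >= 2, got {n}")
    others = list(range(n - 1))
    rounds = []
    for _ in range(n - 1):
        pairing = [(others[0], n - 1)]
        for i in range(1, n // 2):
            a, b = others[i], others[n - 1 - i]
            pairing.append((min(a, b), max(a, b)))
        rounds.append(tuple(pairing))
        others = [others[-1]] + others[:-1]
    return Schedule(rounds=tuple(rounds))
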