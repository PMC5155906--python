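"""Subgame-perfect equilibrium of the two-stage game by backward induction.

The splitting phase is an ultimatum game with a lottery outside option: a
responder who rejects receives the whole pot with probability ``p_low``, so
their expected rejection value is ``p_low * pot`` and (with risk neutrality
and acceptance at indifference on the integer grid) the equilibrium offer is
the smallest integer at or above it — 4k on the 40-unit pot when
``p_low = k/10``.  Plugging the resulting continuation values back into the
contribution stage and enumerating best responses on the 21x21 integer grid
closes the model: the pure-strategy Nash profiles of the contribution stage
are the exactly-at-threshold profiles where neither player contributes more
than their continuation value, plus (when neither continuation value exceeds
the endowment) the all-out failure profile (0, 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

from .game_core import GameConfig, Treatment, get_treatment, lottery_probability

__all__ = [
    "SPEResult",
    "spe_split",
    "continuation_values",
    "contribution_equilibria",
    "default_selection_rule",
    "spe_full_game",
]


@dataclass(frozen=True)
class SPEResult:
    """Backward-induction solution for one treatment/rank-difference state."""

    p_low: float
    offer_star: int
    accept_star: int
    cont_high: int
    cont_low: int
    contribution_eq_set: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    selected_contribution: Optional[tuple[int, int]] = None


def spe_split(p_low: float, pot: int = 40) -> tuple[int, int]:
    """Equilibrium (offer, acceptance threshold) of the splitting subgame.

    The responder's expected value of rejecting is ``p_low * pot``; the
    minimum acceptable integer offer is its ceiling, and the proposer offers
    exactly that amount.
    """
    if not 0.0 <= p_low <= 1.0:
        raise ValueError(f"p_low must be in [0, 1], got {p_low}")
    accept_star = math.ceil(p_low * pot - 1e-12)
    return accept_star, accept_star


def continuation_values(
    treatment: "Treatment | str",
    d: Optional[int] = None,
    config: GameConfig = GameConfig(),
) -> tuple[int, int]:
    """Splitting-phase continuation values (high, low) entering the contribution stage."""
    p_low = lottery_probability(treatment, d)
    offer_star, _ = spe_split(p_low, config.pot_success)
    return config.pot_success - offer_star, offer_star


def contribution_equilibria(
    cont_high: int, cont_low: int, config: GameConfig = GameConfig()
) -> set[tuple[int, int]]:
    """All pure-strategy Nash profiles of the contribution stage.

    Enumerates the full integer grid [0, E]^2 and keeps profiles with no
    strictly profitable unilateral deviation (weak deviations do not break
    equilibrium).  Payoffs: ``E - c_i + cont_i`` on success, ``E - c_i``
    otherwise.
    """
    if cont_high + cont_low != config.pot_success:
        raise ValueError("continuation values must sum to the successful pot")
    E, T = config.endowment, config.threshold
    cont = (cont_high, cont_low)

    def payoff(i: int, c: tuple[int, int]) -> int:
        base = E - c[i]
        return base + cont[i] if c[0] + c[1] >= T else base

    equilibria = set()
    for c_high in range(E + 1):
        for c_low in range(E + 1):
            profile = (c_high, c_low)
            ok = True
            for i in (0, 1):
                best = payoff(i, profile)
                for dev in range(E + 1):
                    alt = list(profile)
                    alt[i] = dev
                    if payoff(i, tuple(alt)) > best:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                equilibria.add(profile)
    return equilibria


def default_selection_rule(
    cont_high: int, cont_low: int, config: GameConfig = GameConfig()
) -> tuple[int, int]:
    """Pick one cooperative contribution equilibrium for equilibrium play.

    The low player contributes ``min(cont_low, T // 2)`` — never more than
    their continuation value and never more than an equal split of the
    threshold — and the high player covers the rest.  This is the successful
    profile with minimal individual exposure.
    """
    c_low = min(cont_low, config.threshold // 2)
    return config.threshold - c_low, c_low


def spe_full_game(
    treatment: "Treatment | str",
    d: Optional[int] = None,
    config: GameConfig = GameConfig(),
    selection_rule: Callable[[int, int, GameConfig], tuple[int, int]] = default_selection_rule,
) -> SPEResult:
    """Solve the full game for one state by backward induction."""
    tr = get_treatment(treatment)
    p_low = lottery_probability(tr, d)
    offer_star, accept_star = spe_split(p_low, config.pot_success)
    cont_high, cont_low = config.pot_success - offer_star, offer_star
    if tr.has_cooperation_phase:
        eq_set = contribution_equilibria(cont_high, cont_low, config)
        assert eq_set, "contribution stage cannot have an empty equilibrium set"
        selected = selection_rule(cont_high, cont_low, config)
        assert selected in eq_set, "selection rule must pick a Nash profile"
    else:
        eq_set, selected = set(), None
    return SPEResult(
        p_low=p_low,
        offer_star=offer_star,
        accept_star=accept_star,
        cont_high=cont_high,
        cont_low=cont_low,
        contribution_eq_set=frozenset(eq_set),
        selected_contribution=selected,
    )
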