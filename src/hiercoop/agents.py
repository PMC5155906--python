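"""Decision policies mapping a player's state to contribution, offer, threshold.

Three agent kinds:

``nash``
    Plays the backward-induction solution: the selection-rule contribution,
    the equilibrium offer and the equilibrium acceptance threshold.
``inequity_averse``
    Best-responds under Fehr-Schmidt utility
    ``U_i = x_i - alpha * max(x_j - x_i, 0) - beta * max(x_i - x_j, 0)``
    with the disadvantageous-inequity weight ``alpha >= beta >= 0``.  With
    ``alpha = beta = 0`` it reproduces the nash agent exactly.
``empirical``
    A calibration device reproducing the qualitative behavioral patterns of
    the experiment (offers and thresholds anchored near the equilibrium with
    positive shifts, lower-ranked contributions rising with the
    rank-difference group k and falling over rounds), not a fit to data.

Agents never observe the partner's contribution, only success/failure, so
policies condition on (role, k, round) only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .game_core import (
    GameConfig,
    Treatment,
    get_treatment,
    k_from_rank_difference,
    lottery_probability,
)
from .equilibrium import default_selection_rule, spe_split

__all__ = ["EmpiricalParams", "AgentParams", "decide_contribution", "decide_offer", "decide_threshold"]


@dataclass(frozen=True)
class EmpiricalParams:
    """Calibrated coefficients of the empirical policy (all overridable).

    Contributions (units, before rounding/clipping): per-role intercept plus
    a slope on the rank-difference group k and a slope on the mean-centered
    round.  Offers/thresholds: equilibrium anchor plus a shift.  The
    hierarchy offer shift ``max(0, base + slope * k)`` shrinks toward Nash as
    ranks get closer; the control shift of -5 units puts mean offers 25%
    below mean thresholds (offers 15 vs thresholds 20).  Thresholds always
    sit ``threshold_shift_extra`` units above the offer shift.
    """

    contrib_intercept_low: float = 10.0
    contrib_slope_k_low: float = 1.0
    contrib_slope_t_low: float = -0.5
    contrib_intercept_high: float = 10.0
    contrib_slope_k_high: float = -0.5
    contrib_slope_t_high: float = 0.5
    contrib_mean_control: float = 11.0
    offer_shift_base: float = 8.0
    offer_shift_slope: float = -1.5
    offer_shift_control: float = -5.0
    threshold_shift_extra: float = 5.0
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def offer_shift(self, has_hierarchy: bool, k: Optional[int]) -> float:
        if not has_hierarchy:
            return self.offer_shift_control
        return max(0.0, self.offer_shift_base + self.offer_shift_slope * k)

    def threshold_shift(self, has_hierarchy: bool, k: Optional[int]) -> float:
        return self.offer_shift(has_hierarchy, k) + self.threshold_shift_extra


@dataclass(frozen=True)
class AgentParams:
    kind: str = "empirical"  # nash | inequity_averse | empirical
    alpha: float = 0.0  # disadvantageous-inequity weight
    beta: float = 0.0  # advantageous-inequity weight
    empirical: EmpiricalParams = field(default_factory=EmpiricalParams)

    def __post_init__(self) -> None:
        if self.kind not in ("nash", "inequity_averse", "empirical"):
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if self.kind == "inequity_averse" and not (self.alpha >= self.beta >= 0):
            raise ValueError("inequity aversion requires alpha >= beta >= 0")

    def with_noise_sd(self, sd: float) -> "AgentParams":
        return replace(self, empirical=replace(self.empirical, noise_sd=sd))


def _state(treatment, d):
    tr = get_treatment(treatment)
    k = k_from_rank_difference(d) if tr.has_hierarchy else None
    return tr, k


def _round_centered(t: int, config: GameConfig) -> float:
    if not 1 <= t <= config.n_rounds:
        raise ValueError(f"round must be in 1..{config.n_rounds}, got {t}")
    return t - (config.n_rounds + 1) / 2.0


def _noise(params: EmpiricalParams, rng: Optional[np.random.Generator]) -> float:
    if params.noise_sd == 0:
        return 0.0
    if rng is None:
        raise ValueError("rng is required when noise_sd > 0")
    return rng.normal(0.0, params.noise_sd)


def _clip_int(x: float, lo: int, hi: int) -> int:
    return int(np.clip(round(x), lo, hi))


def fehr_schmidt(x_i: float, x_j: float, alpha: float, beta: float) -> float:
    """Inequity-averse utility of own payoff x_i against partner payoff x_j."""
    return x_i - alpha * max(x_j - x_i, 0.0) - beta * max(x_i - x_j, 0.0)


def decide_contribution(
    params: AgentParams,
    role: str,
    treatment: "Treatment | str",
    d: Optional[int],
    t: int,
    config: GameConfig = GameConfig(),
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Contribution in [0, endowment] for a player in the given state.

    ``role`` is ``"high"`` or ``"low"`` (proposer/responder in the control).
    """
    if role not in ("high", "low"):
        raise ValueError(f"role must be 'high' or 'low', got {role!r}")
    tr, k = _state(treatment, d)
    if not tr.has_cooperation_phase:
        raise ValueError(f"treatment {tr.label!r} has no cooperation phase")
    t_c = _round_centered(t, config)

    if params.kind == "nash":
        cont_high, cont_low = _continuation(tr, d, config)
        c_high, c_low = default_selection_rule(cont_high, cont_low, config)
        return c_high if role == "high" else c_low

    if params.kind == "inequity_averse":
        return _ia_contribution(params, role, tr, d, config)

    ep = params.empirical
    if not tr.has_hierarchy:
        mu = ep.contrib_mean_control
    elif role == "low":
        mu = ep.contrib_intercept_low + ep.contrib_slope_k_low * k + ep.contrib_slope_t_low * t_c
    else:
        mu = ep.contrib_intercept_high + ep.contrib_slope_k_high * k + ep.contrib_slope_t_high * t_c
    return _clip_int(mu + _noise(ep, rng), 0, config.endowment)


def decide_offer(
    params: AgentParams,
    treatment: "Treatment | str",
    d: Optional[int],
    config: GameConfig = GameConfig(),
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Proposer's offer in [0, pot], anchored at the equilibrium offer."""
    tr, k = _state(treatment, d)
    anchor, _ = spe_split(lottery_probability(tr, d), config.pot_success)
    if params.kind == "nash":
        return anchor
    if params.kind == "inequity_averse":
        offer, _ = _ia_split(params, tr, d, config)
        return offer
    ep = params.empirical
    shift = ep.offer_shift(tr.has_hierarchy, k)
    return _clip_int(anchor + shift + _noise(ep, rng), 0, config.pot_success)


def decide_threshold(
    params: AgentParams,
    treatment: "Treatment | str",
    d: Optional[int],
    config: GameConfig = GameConfig(),
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Responder's stated minimum acceptable offer in [0, pot]."""
    tr, k = _state(treatment, d)
    _, anchor = spe_split(lottery_probability(tr, d), config.pot_success)
    if params.kind == "nash":
        return anchor
    if params.kind == "inequity_averse":
        _, threshold = _ia_split(params, tr, d, config)
        return threshold
    ep = params.empirical
    shift = ep.threshold_shift(tr.has_hierarchy, k)
    return _clip_int(anchor + shift + _noise(ep, rng), 0, config.pot_success)


# ---------------------------------------------------------------------------
# Fehr-Schmidt best responses, solved on the integer grid by enumeration.


def _ia_split(
    params: AgentParams, tr: Treatment, d: Optional[int], config: GameConfig
) -> tuple[int, int]:
    """(offer, acceptance threshold) for inequity-averse proposer/responder."""
    pot = config.pot_success
    p_low = lottery_probability(tr, d)
    a, b = params.alpha, params.beta

    def u_resp_accept(x: int) -> float:
        return fehr_schmidt(x, pot - x, a, b)

    u_resp_reject = p_low * fehr_schmidt(pot, 0, a, b) + (1 - p_low) * fehr_schmidt(0, pot, a, b)
    threshold = pot
    for x in range(pot + 1):
        if u_resp_accept(x) >= u_resp_reject:  # accept at indifference
            threshold = x
            break

    u_prop_reject = (1 - p_low) * fehr_schmidt(pot, 0, a, b) + p_low * fehr_schmidt(0, pot, a, b)
    best_offer, best_u, best_accepted = 0, -np.inf, False
    for x in range(pot + 1):
        accepted = x >= threshold
        u = fehr_schmidt(pot - x, x, a, b) if accepted else u_prop_reject
        # ties: prefer acceptance, then the smaller offer
        if u > best_u + 1e-12 or (abs(u - best_u) <= 1e-12 and accepted and not best_accepted):
            best_offer, best_u, best_accepted = x, u, accepted
    return best_offer, threshold


def _ia_contribution(
    params: AgentParams, role: str, tr: Treatment, d: Optional[int], config: GameConfig
) -> int:
    """Best-response contribution given the partner plays the selection rule.

    Continuation amounts come from the inequity-averse splitting play itself
    (deterministic if the offer is accepted, a two-point lottery otherwise);
    utility is the expected Fehr-Schmidt utility over total trial payoffs.
    At indifference the selection-rule contribution is preferred (cooperative
    tie-break), so the alpha = beta = 0 case reproduces the nash agent.
    """
    E, T, pot = config.endowment, config.threshold, config.pot_success
    a, b = params.alpha, params.beta
    offer, threshold = _ia_split(params, tr, d, config)
    if offer >= threshold:
        share_outcomes = [(1.0, pot - offer, offer)]  # (prob, share_high, share_low)
    else:
        p_low = lottery_probability(tr, d)
        share_outcomes = [(p_low, 0, pot), (1 - p_low, pot, 0)]

    cont_high = sum(p * sh for p, sh, _ in share_outcomes)
    cont_low = sum(p * sl for p, _, sl in share_outcomes)
    ref_high, ref_low = default_selection_rule(round(cont_high), round(cont_low), config)
    c_ref = ref_high if role == "high" else ref_low
    c_partner = ref_low if role == "high" else ref_high

    def utility(c_own: int) -> float:
        if c_own + c_partner >= T:
            u = 0.0
            for p, sh, sl in share_outcomes:
                own_share, partner_share = (sh, sl) if role == "high" else (sl, sh)
                u += p * fehr_schmidt(E - c_own + own_share, E - c_partner + partner_share, a, b)
            return u
        return fehr_schmidt(E - c_own, E - c_partner, a, b)

    best_c, best_u = 0, -np.inf
    for c in range(E + 1):
        u = utility(c)
        if u > best_u + 1e-12:
            best_c, best_u = c, u
    if utility(c_ref) >= best_u - 1e-12:
        return c_ref
    return best_c


def _continuation(tr: Treatment, d: Optional[int], config: GameConfig) -> tuple[int, int]:
    offer_star, _ = spe_split(lottery_probability(tr, d), config.pot_success)
    return config.pot_success - offer_star, offer_star
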