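"""Seeded synthetic datasets with the study's full design.

Emulates the experiment: 240 participants in 24 groups of 10, five
treatments (6 groups each for control/earned/random, 3 each for the two
splitting-only treatments), nine round-robin rounds per group.  Each session
is driven by one agent policy per treatment and a spawned seed, so any stage
is independently reproducible; participants appear in exactly one session
(between-subjects design).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .agents import AgentParams, decide_contribution, decide_offer, decide_threshold
from .game_core import (
    GameConfig,
    RankPair,
    TrialRecord,
    get_treatment,
    lottery_probability,
    resolve_cooperation,
    resolve_split,
    trial_payoffs,
    write_records_csv,
)
from .population import (
    form_hierarchy_earned,
    form_hierarchy_random,
    round_robin_schedule,
)

__all__ = ["StudyDesign", "DEFAULT_GROUPS", "generate_session", "generate_study", "write_study"]

DEFAULT_GROUPS = {
    "control": 6,
    "earned": 6,
    "random": 6,
    "earned_no_coop": 3,
    "random_no_coop": 3,
}


@dataclass(frozen=True)
class StudyDesign:
    """Treatment mix and seeding for a full synthetic study.

    The default mix reproduces the study scale: 24 sessions of 10 players =
    240 participants, 180 of them in the three cooperation treatments.
    """

    groups_per_treatment: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    agent_params: dict[str, AgentParams] = field(default_factory=dict)
    master_seed: int = 0
    config: GameConfig = field(default_factory=GameConfig)

    def __post_init__(self) -> None:
        for label, n in self.groups_per_treatment.items():
            get_treatment(label)  # validates the label
            if n < 0:
                raise ValueError(f"negative group count for {label!r}")

    def params_for(self, label: str) -> AgentParams:
        return self.agent_params.get(label, AgentParams(kind="empirical"))

    @property
    def n_participants(self) -> int:
        return self.config.group_size * sum(self.groups_per_treatment.values())


def _session_streams(seed) -> dict[str, np.random.Generator]:
    """Independent RNG streams for the session stages."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    names = ("hierarchy", "schedule", "agents", "lottery")
    return dict(zip(names, (np.random.default_rng(s) for s in ss.spawn(len(names)))))


def generate_session(
    treatment: str,
    agent_params: AgentParams,
    seed,
    config: GameConfig = GameConfig(),
    session_id: Optional[str] = None,
    ranks: Optional[tuple[int, ...]] = None,
) -> list[TrialRecord]:
    """Play one full session (group of ``group_size``, all round-robin rounds).

    Returns one :class:`TrialRecord` per dyad-round, fully reproducible from
    ``seed``.  ``ranks`` pins the hierarchy explicitly (counterfactual runs:
    earned and random hierarchies share all game mechanics once the ranks
    are fixed).
    """
    tr = get_treatment(treatment)
    if session_id is None:
        session_id = f"{tr.label}-00"
    streams = _session_streams(seed)
    n = config.group_size

    if tr.has_hierarchy:
        if ranks is not None:
            if sorted(ranks) != list(range(1, n + 1)):
                raise ValueError("ranks override must be a permutation of 1..group_size")
        elif tr.label.startswith("earned"):
            scores = streams["hierarchy"].normal(0.0, 1.0, size=n)  # abstract skill scores
            ranks = form_hierarchy_earned(scores, streams["hierarchy"]).ranks
        else:
            ranks = form_hierarchy_random(n, streams["hierarchy"]).ranks
    else:
        ranks = None

    schedule = round_robin_schedule(n)
    round_order = streams["schedule"].permutation(config.n_rounds)  # random partner order

    records: list[TrialRecord] = []
    for t, ridx in enumerate(round_order, start=1):
        for a, b in schedule.rounds[ridx]:
            if ranks is not None:
                if ranks[a] < ranks[b]:
                    hi, lo = a, b
                else:
                    hi, lo = b, a
                pair = RankPair(ranks[hi], ranks[lo], group_size=n)
                d = pair.d
                rank_high, rank_low = pair.rank_high, pair.rank_low
            else:
                # control: proposer/responder roles assigned at random
                hi, lo = (a, b) if streams["agents"].random() < 0.5 else (b, a)
                d, rank_high, rank_low = None, None, None

            rec = _play_dyad(
                tr, agent_params, d, t, config, streams, session_id,
                f"{session_id}_p{hi}", f"{session_id}_p{lo}", rank_high, rank_low,
            )
            records.append(rec)
    return records


def _play_dyad(tr, params, d, t, config, streams, session_id, id_high, id_low,
               rank_high, rank_low) -> TrialRecord:
    rng = streams["agents"]
    p_low = lottery_probability(tr, d)

    if tr.has_cooperation_phase:
        c_high = decide_contribution(params, "high", tr, d, t, config, rng)
        c_low = decide_contribution(params, "low", tr, d, t, config, rng)
        coop = resolve_cooperation(c_high, c_low, config)
        success, pot = coop.success, coop.pot
    else:
        c_high = c_low = success = None
        pot = config.pot_success  # splitting-only treatments start from the full pot

    if pot > 0:
        offer = decide_offer(params, tr, d, config, rng)
        threshold = decide_threshold(params, tr, d, config, rng)
        split = resolve_split(offer, threshold, p_low, streams["lottery"], pot)
        offer_f, acc, winner = split.offer, split.accepted, split.lottery_winner
    else:
        offer_f = threshold = acc = winner = None

    rec = TrialRecord(
        session_id=session_id, treatment=tr.label, round=t,
        id_high=id_high, id_low=id_low,
        rank_high=rank_high, rank_low=rank_low,
        c_high=c_high, c_low=c_low, success=success, pot=pot,
        offer=offer_f, threshold_low=threshold, accepted=acc, lottery_winner=winner,
        payoff_high=0, payoff_low=0,
    )
    rec.payoff_high, rec.payoff_low = trial_payoffs(rec, config)
    return rec


def generate_study(design: StudyDesign) -> list[TrialRecord]:
    """Generate every session of the design, with spawned per-session seeds."""
    master = np.random.SeedSequence(design.master_seed)
    n_sessions = sum(design.groups_per_treatment.values())
    child_seeds = master.spawn(n_sessions)
    records: list[TrialRecord] = []
    i = 0
    for label in sorted(design.groups_per_treatment):
        for g in range(design.groups_per_treatment[label]):
            session_id = f"{label}-{g:02d}"
            records.extend(
                generate_session(
                    label, design.params_for(label), child_seeds[i],
                    design.config, session_id=session_id,
                )
            )
            i += 1
    return records


def write_study(design: StudyDesign, out_dir) -> dict:
    """Write one TrialRecord CSV per session plus a provenance manifest."""
    import json

    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = generate_study(design)
    sessions = sorted({r.session_id for r in records})
    for sid in sessions:
        write_records_csv([r for r in records if r.session_id == sid], out / f"{sid}.csv")
    manifest = {
        "package_version": __version__,
        "master_seed": design.master_seed,
        "groups_per_treatment": design.groups_per_treatment,
        "n_participants": design.n_participants,
        "sessions": sessions,
        "agent_kinds": {
            label: design.params_for(label).kind for label in design.groups_per_treatment
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
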