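"""Rules and payoff accounting of the two-stage hierarchy-cooperation game.

The game has two stages. In the *cooperation phase* two paired players each
hold an endowment of 20 experimental currency units (ECUs) and simultaneously
contribute any integer amount to a common pot; if the pot reaches the 20-unit
threshold it doubles to 40 units, otherwise the contributions are lost. In the
*splitting phase* the higher-ranked player proposes a division of the 40-unit
pot (an ultimatum game); if the lower-ranked player rejects, a lottery assigns
the whole pot to one of the two with probability tied to their rank difference
(equal chances when no hierarchy exists). At payout, 15 units = 1 euro.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "GameConfig",
    "Treatment",
    "TREATMENTS",
    "RankPair",
    "CooperationOutcome",
    "SplitOutcome",
    "TrialRecord",
    "k_from_rank_difference",
    "lottery_probability",
    "resolve_cooperation",
    "resolve_split",
    "trial_payoffs",
    "payout_euros",
    "records_to_frame",
    "frame_to_records",
    "write_records_csv",
    "read_records_csv",
    "CSV_COLUMNS",
]


@dataclass(frozen=True)
class GameConfig:
    """Fixed experiment constants.

    endowment
        ECUs each player holds per round (E = 20).
    threshold
        Combined contribution required for cooperative success (T = 20).
    pot_success
        Pot entering the splitting phase after success (P = 2T = 40).
    n_rounds
        Rounds per session; round-robin, so ``group_size - 1``.
    group_size
        Players per session group (10).
    units_per_euro
        Payout conversion rate (15 units = 1 euro).
    """

    endowment: int = 20
    threshold: int = 20
    pot_success: int = 40
    n_rounds: int = 9
    group_size: int = 10
    units_per_euro: int = 15

    def __post_init__(self) -> None:
        for name in dataclasses.fields(self):
            v = getattr(self, name.name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name.name} must be a positive integer, got {v!r}")
        if self.pot_success != 2 * self.threshold:
            raise ValueError("pot_success must equal 2 x threshold")
        if self.endowment != self.threshold:
            raise ValueError("endowment must equal threshold")
        if self.group_size % 2 != 0:
            raise ValueError("group_size must be even (players are paired)")
        if self.n_rounds != self.group_size - 1:
            raise ValueError("n_rounds must be group_size - 1 (round robin)")


@dataclass(frozen=True)
class Treatment:
    """One of the five experimental treatments.

    ``control`` has no hierarchy; ``earned`` and ``random`` have a hierarchy
    (earned through skill tasks or assigned arbitrarily) plus the cooperation
    phase; ``earned_no_coop`` / ``random_no_coop`` skip the cooperation phase
    and go straight to splitting a fixed 40-unit pot.
    """

    label: str
    has_hierarchy: bool
    has_cooperation_phase: bool

    def __post_init__(self) -> None:
        if self.label not in TREATMENT_LABELS:
            raise ValueError(f"unknown treatment label {self.label!r}")


TREATMENT_LABELS = (
    "control",
    "earned",
    "random",
    "earned_no_coop",
    "random_no_coop",
)

TREATMENTS: dict[str, Treatment] = {
    "control": Treatment("control", has_hierarchy=False, has_cooperation_phase=True),
    "earned": Treatment("earned", has_hierarchy=True, has_cooperation_phase=True),
    "random": Treatment("random", has_hierarchy=True, has_cooperation_phase=True),
    "earned_no_coop": Treatment("earned_no_coop", has_hierarchy=True, has_cooperation_phase=False),
    "random_no_coop": Treatment("random_no_coop", has_hierarchy=True, has_cooperation_phase=False),
}


def get_treatment(treatment: "Treatment | str") -> Treatment:
    if isinstance(treatment, Treatment):
        return treatment
    try:
        return TREATMENTS[treatment]
    except KeyError:
        raise ValueError(f"unknown treatment label {treatment!r}") from None


@dataclass(frozen=True)
class RankPair:
    """The ranks of a hierarchy dyad; rank 1 is the top of the hierarchy."""

    rank_high: int
    rank_low: int
    group_size: int = 10

    def __post_init__(self) -> None:
        if not (1 <= self.rank_high < self.rank_low <= self.group_size):
            raise ValueError(
                f"need 1 <= rank_high < rank_low <= group_size, got "
                f"({self.rank_high}, {self.rank_low}) with group_size {self.group_size}"
            )

    @property
    def d(self) -> int:
        """Rank difference rank_low - rank_high, in 1..group_size-1."""
        return self.rank_low - self.rank_high


@dataclass(frozen=True)
class CooperationOutcome:
    c_high: int
    c_low: int
    success: bool
    pot: int


@dataclass(frozen=True)
class SplitOutcome:
    """Resolution of the splitting phase.

    ``lottery_winner`` is ``"none"`` when the offer is accepted, otherwise
    ``"high"`` or ``"low"``; the winner takes the whole pot.
    """

    offer: int
    accepted: bool
    lottery_winner: str
    share_high: int
    share_low: int


@dataclass
class TrialRecord:
    """One dyad-round of the experiment.

    Rank fields are ``None`` in the control condition (the ``high``/``low``
    suffixes then mean proposer/responder); cooperation fields are ``None`` in
    the splitting-only treatments; split fields are ``None`` when cooperation
    failed (no pot to split).
    """

    session_id: str
    treatment: str
    round: int
    id_high: str
    id_low: str
    rank_high: Optional[int]
    rank_low: Optional[int]
    c_high: Optional[int]
    c_low: Optional[int]
    success: Optional[bool]
    pot: int
    offer: Optional[int]
    threshold_low: Optional[int]
    accepted: Optional[bool]
    lottery_winner: Optional[str]
    payoff_high: int
    payoff_low: int


def k_from_rank_difference(d: int) -> int:
    """Map a rank difference d in 1..9 to the rank-difference group k in 1..5.

    k = 1 covers differences 8-9, k = 2 covers 6-7, k = 3 covers 4-5,
    k = 4 covers 2-3 and k = 5 the difference of 1.  Larger k means the two
    players are closer in rank.
    """
    if not isinstance(d, (int, np.integer)) or isinstance(d, bool):
        raise ValueError(f"rank difference must be an integer, got {d!r}")
    if not 1 <= d <= 9:
        raise ValueError(f"rank difference must be in 1..9, got {d}")
    return 5 - d // 2


def lottery_probability(treatment: "Treatment | str", d: Optional[int] = None) -> float:
    """Probability that the lower-ranked player wins the rejection lottery.

    Control (no hierarchy): 0.5.  Hierarchy treatments: k/10 where k is the
    rank-difference group, so the probability rises from 0.1 (maximal rank
    gap) to 0.5 (adjacent ranks).  This is the grouping-respecting rule
    consistent with the equilibrium offer of 4k on a 40-unit pot.
    """
    tr = get_treatment(treatment)
    if not tr.has_hierarchy:
        return 0.5
    if d is None:
        raise ValueError("rank difference d is required for hierarchy treatments")
    return k_from_rank_difference(d) / 10.0


def _check_contribution(c: int, config: GameConfig, name: str) -> None:
    if not isinstance(c, (int, np.integer)) or isinstance(c, bool):
        raise ValueError(f"{name} must be an integer, got {c!r}")
    if not 0 <= c <= config.endowment:
        raise ValueError(f"{name} must be in [0, {config.endowment}], got {c}")


def resolve_cooperation(
    c_high: int, c_low: int, config: GameConfig = GameConfig()
) -> CooperationOutcome:
    """Resolve the threshold cooperation stage.

    Success iff the combined contribution reaches the threshold; the pot then
    doubles to ``pot_success``.  On failure contributions are lost and there
    is nothing to split.
    """
    _check_contribution(c_high, config, "c_high")
    _check_contribution(c_low, config, "c_low")
    success = c_high + c_low >= config.threshold
    return CooperationOutcome(
        c_high=int(c_high),
        c_low=int(c_low),
        success=success,
        pot=config.pot_success if success else 0,
    )


def resolve_split(
    offer: int,
    responder_threshold: int,
    p_low: float,
    rng: Optional[np.random.Generator] = None,
    pot: int = 40,
) -> SplitOutcome:
    """Resolve the ultimatum splitting stage with the lottery outside option.

    The responder accepts any offer at or above their stated threshold
    (acceptance at indifference).  On rejection the lottery assigns the whole
    pot to the lower-ranked player with probability ``p_low``; a seeded
    ``rng`` is required whenever rejection is possible.
    """
    if not 0 <= offer <= pot:
        raise ValueError(f"offer must be in [0, {pot}], got {offer}")
    if not 0 <= responder_threshold <= pot:
        raise ValueError(f"threshold must be in [0, {pot}], got {responder_threshold}")
    if not 0.0 <= p_low <= 1.0:
        raise ValueError(f"p_low must be in [0, 1], got {p_low}")
    if offer >= responder_threshold:
        return SplitOutcome(
            offer=int(offer),
            accepted=True,
            lottery_winner="none",
            share_high=pot - int(offer),
            share_low=int(offer),
        )
    if rng is None:
        raise ValueError("rng is required when the offer can be rejected")
    low_wins = rng.random() < p_low
    return SplitOutcome(
        offer=int(offer),
        accepted=False,
        lottery_winner="low" if low_wins else "high",
        share_high=0 if low_wins else pot,
        share_low=pot if low_wins else 0,
    )


def trial_payoffs(record: TrialRecord, config: GameConfig = GameConfig()) -> tuple[int, int]:
    """Per-player payoff in units for one trial.

    With a cooperation phase: endowment minus own contribution, plus the pot
    share (zero on failure).  Splitting-only treatments: the pot share alone.
    """
    tr = get_treatment(record.treatment)
    share_high, share_low = _shares(record)
    if tr.has_cooperation_phase:
        if record.c_high is None or record.c_low is None or record.success is None:
            raise ValueError("cooperation fields missing from a cooperation-phase record")
        return (
            config.endowment - record.c_high + share_high,
            config.endowment - record.c_low + share_low,
        )
    return share_high, share_low


def _shares(record: TrialRecord) -> tuple[int, int]:
    if record.offer is None:  # no splitting phase happened (failed cooperation)
        return 0, 0
    if record.accepted is None or record.lottery_winner is None:
        raise ValueError("split fields incomplete")
    if record.accepted:
        return record.pot - record.offer, record.offer
    if record.lottery_winner == "low":
        return 0, record.pot
    return record.pot, 0


def payout_euros(total_units: int, config: GameConfig = GameConfig()) -> float:
    """Convert a unit total to euros at the experiment's exchange rate, to cents."""
    return round(total_units / config.units_per_euro, 2)


# ---------------------------------------------------------------------------
# TrialRecord CSV interface: one row per dyad-round, empty fields for stages
# that did not apply, mandatory header, UTF-8.

CSV_COLUMNS = [
    "session_id",
    "treatment",
    "round",
    "id_high",
    "id_low",
    "rank_high",
    "rank_low",
    "c_high",
    "c_low",
    "success",
    "pot",
    "offer",
    "threshold_low",
    "accepted",
    "lottery_winner",
    "payoff_high",
    "payoff_low",
]

_INT_COLS = ["rank_high", "rank_low", "c_high", "c_low", "offer", "threshold_low"]
_BOOL_COLS = ["success", "accepted"]


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=CSV_COLUMNS)
    for col in _INT_COLS:
        df[col] = df[col].astype("Int64")
    for col in _BOOL_COLS:
        df[col] = df[col].astype("boolean")
    return df


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for row in df.itertuples(index=False):
        kw = {}
        for col in CSV_COLUMNS:
            v = getattr(row, col)
            if pd.isna(v):
                v = None
            elif col in _INT_COLS or col in ("round", "pot", "payoff_high", "payoff_low"):
                v = int(v)
            elif col in _BOOL_COLS:
                v = bool(v)
            kw[col] = v
        records.append(TrialRecord(**kw))
    return records


def write_records_csv(records: Iterable[TrialRecord], path_or_buf) -> None:
    df = records_to_frame(records)
    out = df.copy()
    for col in _BOOL_COLS:  # stable True/False text rather than pandas' repr of NA
        out[col] = out[col].map({True: "True", False: "False"}, na_action="ignore")
    out.to_csv(path_or_buf, index=False, encoding="utf-8")


def read_records_csv(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, encoding="utf-8")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial record CSV missing columns: {sorted(missing)}")
    for col in _INT_COLS:
        df[col] = df[col].astype("Int64")
    for col in _BOOL_COLS:
        df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
        df[col] = df[col].astype("boolean")
    return df[CSV_COLUMNS]


def records_csv_string(records: Iterable[TrialRecord]) -> str:
    buf = io.StringIO()
    write_records_csv(records, buf)
    return buf.getvalue()
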