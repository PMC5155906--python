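"""Statistical pipeline: contrast coding, dyad bootstrap, model families, summaries.

The inferential contract is a nonparametric cluster bootstrap: grouping units
(dyads for the success analysis, individuals for the contribution and
ultimatum analyses) are resampled with replacement, one member of each
sampled dyad is selected at random where member-level covariates enter, a
fixed-effects model (logistic for success, linear otherwise) is fit per
replicate, and 95% confidence intervals are taken as the 2.5/97.5 percentiles
of the replicate coefficients.  Treatments are contrast coded with the
orthogonal set h1 = +2 (no hierarchy) vs -1/-1 (hierarchy) and
h2 = -1 (random) vs +1 (earned); round is mean-centered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .game_core import TrialRecord, get_treatment, records_to_frame

__all__ = [
    "BootstrapFit",
    "encode_contrasts",
    "dyad_bootstrap",
    "fit_success_model",
    "fit_contribution_model",
    "fit_rank_difference_model",
    "fit_ultimatum_model",
    "summarize_figures",
    "rank_earnings_correlation",
]

Records = Union[pd.DataFrame, Sequence[TrialRecord]]

COOP_TREATMENTS = ("control", "earned", "random")
HIERARCHY_COOP = ("earned", "random")
HIERARCHY_ALL = ("earned", "random", "earned_no_coop", "random_no_coop")


def _as_frame(records: Records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def encode_contrasts(treatment: str) -> tuple[int, int]:
    """Orthogonal treatment contrasts for the cooperation-phase analyses.

    h1 contrasts no-hierarchy (+2) against the two hierarchy conditions (-1
    each); h2 contrasts random (-1) against earned (+1) within the hierarchy
    conditions.
    """
    codes = {"control": (2, 0), "random": (-1, -1), "earned": (-1, 1)}
    tr = get_treatment(treatment)
    if treatment not in codes:
        raise ValueError(
            f"treatment {tr.label!r} is outside the cooperation-phase contrast set"
        )
    return codes[treatment]


@dataclass
class BootstrapFit:
    """Point estimates with percentile bootstrap confidence intervals."""

    table: pd.DataFrame  # index: coefficient; columns: estimate, ci_low, ci_high
    n_boot: int
    n_dropped: int
    seed: Optional[int] = None
    point_fit_ok: bool = True

    @property
    def coefficients(self) -> pd.Series:
        return self.table["estimate"]

    def ci(self, name: str) -> tuple[float, float]:
        return float(self.table.loc[name, "ci_low"]), float(self.table.loc[name, "ci_high"])

    def excludes_zero(self, name: str) -> bool:
        lo, hi = self.ci(name)
        return lo > 0 or hi < 0


class FitError(RuntimeError):
    pass


def _fit_glm(df: pd.DataFrame, response: str, terms: list[str], logistic: bool) -> pd.Series:
    X = sm.add_constant(df[terms].astype(float), has_constant="add")
    y = df[response].astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if logistic:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            else:
                res = sm.OLS(y, X).fit()
        except Exception as exc:  # separation, singular design, non-convergence
            raise FitError(str(exc)) from exc
    params = res.params
    if not np.all(np.isfinite(params)):
        raise FitError("non-finite coefficients")
    return params


def dyad_bootstrap(
    df: pd.DataFrame,
    fit_fn: Callable[[pd.DataFrame], pd.Series],
    unit: str,
    n_boot: int = 100,
    rng: Optional[np.random.Generator] = None,
    max_drop_frac: float = 0.2,
    select_member: Optional[Callable[[pd.DataFrame, np.random.Generator], pd.DataFrame]] = None,
) -> BootstrapFit:
    """Cluster bootstrap over grouping units with percentile CIs.

    Per replicate, units (values of ``df[unit]``) are resampled with
    replacement, ``select_member`` (when given) randomly keeps one member of
    each dyad, and ``fit_fn`` returns the replicate's coefficients.
    Non-convergent replicates are dropped; the fit fails if more than
    ``max_drop_frac`` of replicates drop.
    """
    if df.empty:
        raise ValueError("no records to fit")
    if rng is None:
        rng = np.random.default_rng()

    point_ok = True
    try:
        point = fit_fn(df if select_member is None else select_member(df, rng))
    except FitError:
        point_ok = False
        point = None

    flat = df.reset_index(drop=True)
    positions = flat.groupby(unit, sort=True).indices
    idx_by_unit = [np.asarray(positions[uid]) for uid in sorted(positions)]
    n_units = len(idx_by_unit)
    replicates, n_dropped = [], 0
    for _ in range(n_boot):
        sampled = rng.integers(0, n_units, size=n_units)
        rows = np.concatenate([idx_by_unit[u] for u in sampled])
        boot = flat.take(rows).reset_index(drop=True)
        if select_member is not None:
            boot = select_member(boot, rng)
        try:
            replicates.append(fit_fn(boot))
        except FitError:
            n_dropped += 1
    if n_dropped > max_drop_frac * n_boot:
        raise FitError(
            f"{n_dropped}/{n_boot} bootstrap replicates failed to converge"
        )
    if not replicates:
        raise FitError("all bootstrap replicates failed")
    boot_df = pd.DataFrame(replicates)
    if point is None:
        point = boot_df.mean()
    table = pd.DataFrame(
        {
            "estimate": point,
            "ci_low": boot_df.quantile(0.025),
            "ci_high": boot_df.quantile(0.975),
        }
    )
    return BootstrapFit(table=table, n_boot=n_boot, n_dropped=n_dropped, point_fit_ok=point_ok)


# ---------------------------------------------------------------------------
# Data-frame builders for the model families.


def _centered_round(df: pd.DataFrame) -> pd.Series:
    return df["round"].astype(float) - df["round"].astype(float).mean()


def success_frame(records: Records) -> pd.DataFrame:
    """One row per dyad-trial in the three cooperation treatments."""
    df = _as_frame(records)
    df = df[df["treatment"].isin(COOP_TREATMENTS)].copy()
    if df.empty:
        raise ValueError("no cooperation-phase records")
    h = df["treatment"].map(encode_contrasts)
    df["h1"] = [c[0] for c in h]
    df["h2"] = [c[1] for c in h]
    df["round_c"] = _centered_round(df)
    df["h1_round"] = df["h1"] * df["round_c"]
    df["success"] = df["success"].astype(float)
    df["dyad_id"] = df["id_high"].astype(str) + "|" + df["id_low"].astype(str)
    return df


def _member_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Long format: one row per trial member, with role and own/partner rank."""
    rows = []
    for role, other in (("high", "low"), ("low", "high")):
        sub = df.copy()
        sub["individual_id"] = df[f"id_{role}"]
        sub["role"] = role
        sub["contribution"] = df[f"c_{role}"]
        sub["own_rank"] = df[f"rank_{role}"]
        sub["partner_rank"] = df[f"rank_{other}"]
        sub["payoff"] = df[f"payoff_{role}"]
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def contribution_frame(records: Records) -> pd.DataFrame:
    """Member-level contributions in the hierarchy cooperation treatments."""
    df = _as_frame(records)
    df = df[df["treatment"].isin(HIERARCHY_COOP)]
    if df.empty:
        raise ValueError("no hierarchy cooperation records")
    long = _member_rows(df)
    long["rank_code"] = np.where(long["role"] == "high", 1.0, -1.0)
    long["round_c"] = _centered_round(long)
    long["rank_round"] = long["rank_code"] * long["round_c"]
    long["contribution"] = long["contribution"].astype(float)
    return long


def rank_difference_frame(records: Records, group_size: int = 10) -> pd.DataFrame:
    """Member-level contributions vs signed rank difference.

    The sign convention follows the focal player: negative differences mean
    the focal player outranks the partner (own rank 1 vs partner 9 gives -8).
    The top- and bottom-ranked individuals are excluded.
    """
    long = contribution_frame(records)
    long = long[(long["own_rank"] > 1) & (long["own_rank"] < group_size)].copy()
    if long.empty:
        raise ValueError("no records left after excluding extreme ranks")
    long["signed_diff"] = (long["own_rank"] - long["partner_rank"]).astype(float)
    long["round_c"] = _centered_round(long)
    return long


def ultimatum_frame(records: Records) -> pd.DataFrame:
    """Offer/threshold rows for the four hierarchy treatments.

    The absolute rank difference enters the model, so the control condition
    (no ranks) is outside this family.  Role is +1 for the receiver
    (threshold row) and -1 for the proposer (offer row); cooperation-phase
    presence is +1/-1.
    """
    df = _as_frame(records)
    df = df[df["treatment"].isin(HIERARCHY_ALL) & df["offer"].notna()].copy()
    if df.empty:
        raise ValueError("no hierarchy splitting-phase records")
    coop = df["treatment"].map(
        lambda s: 1.0 if get_treatment(s).has_cooperation_phase else -1.0
    )
    abs_d = (df["rank_low"] - df["rank_high"]).astype(float)
    base = pd.DataFrame(
        {
            "session_id": df["session_id"],
            "round": df["round"].astype(int),
            "coop_present": coop,
            "abs_d": abs_d,
        }
    )
    prop = base.copy()
    prop["individual_id"] = df["id_high"].values
    prop["role"] = -1.0
    prop["value"] = df["offer"].astype(float).values
    resp = base.copy()
    resp["individual_id"] = df["id_low"].values
    resp["role"] = 1.0
    resp["value"] = df["threshold_low"].astype(float).values
    long = pd.concat([prop, resp], ignore_index=True)
    long["round_c"] = _centered_round(long)
    return long


# ---------------------------------------------------------------------------
# Model families.


def _select_member(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Keep one randomly selected member per dyad row (role-balanced)."""
    keep = rng.integers(0, 2, size=len(df))
    df = df.copy()
    df["selected_role"] = np.where(keep == 0, "high", "low")
    return df


def fit_success_model(records: Records, n_boot: int = 100,
                      rng: Optional[np.random.Generator] = None) -> BootstrapFit:
    """Logistic model of cooperative success with treatment contrasts.

    Fixed effects: h1, h2, mean-centered round and the h1 x round
    interaction; dyads are the bootstrap grouping unit.
    """
    df = success_frame(records)
    terms = ["h1", "h2", "round_c", "h1_round"]
    fit = lambda d: _fit_glm(d, "success", terms, logistic=True)
    return dyad_bootstrap(df, fit, unit="dyad_id", n_boot=n_boot, rng=rng,
                          select_member=_select_member)


def fit_contribution_model(records: Records, n_boot: int = 100,
                           rng: Optional[np.random.Generator] = None) -> BootstrapFit:
    """Linear model of contributions on rank code, round and their interaction.

    Rank is +1 for the higher- and -1 for the lower-ranked member;
    individuals are the bootstrap grouping unit.
    """
    long = contribution_frame(records)
    terms = ["rank_code", "round_c", "rank_round"]
    fit = lambda d: _fit_glm(d, "contribution", terms, logistic=False)
    return dyad_bootstrap(long, fit, unit="individual_id", n_boot=n_boot, rng=rng)


def fit_rank_difference_model(records: Records, n_boot: int = 100,
                              rng: Optional[np.random.Generator] = None,
                              group_size: int = 10) -> BootstrapFit:
    """Linear model of contributions on the signed, continuous rank difference.

    Extreme-ranked individuals (ranks 1 and ``group_size``) are excluded;
    individuals are the bootstrap grouping unit.
    """
    long = rank_difference_frame(records, group_size=group_size)
    terms = ["signed_diff", "round_c"]
    fit = lambda d: _fit_glm(d, "contribution", terms, logistic=False)
    return dyad_bootstrap(long, fit, unit="individual_id", n_boot=n_boot, rng=rng)


def fit_ultimatum_model(records: Records, n_boot: int = 100,
                        rng: Optional[np.random.Generator] = None) -> BootstrapFit:
    """Linear model of offers/thresholds on cooperation presence, role, |d|, round."""
    long = ultimatum_frame(records)
    terms = ["coop_present", "role", "abs_d", "round_c"]
    fit = lambda d: _fit_glm(d, "value", terms, logistic=False)
    return dyad_bootstrap(long, fit, unit="individual_id", n_boot=n_boot, rng=rng)


# ---------------------------------------------------------------------------
# Figure-style summary tables.


def _per_player_success(df: pd.DataFrame) -> pd.DataFrame:
    long = _member_rows(df)
    per = (
        long.groupby(["treatment", "individual_id"], observed=True)["success"]
        .apply(lambda s: float(s.astype(float).sum()))
        .rename("n_successes")
        .reset_index()
    )
    return per


def summarize_figures(records: Records) -> dict[str, pd.DataFrame]:
    """Summary tables mirroring the study's figure panels.

    Returns a dict with keys fig1a (mean per-player successes by condition,
    max 9), fig1b (mean contribution by condition), fig1c (success rate by
    round and hierarchy presence), fig2a (contribution by role and
    condition), fig2b (contribution by role, round and hierarchy presence),
    fig2c (contribution by signed rank difference), fig3 (contribution by
    role, success and condition) and fig4 (mean offer and threshold vs k per
    treatment, with the 4k equilibrium line).
    """
    from .equilibrium import spe_split
    from .game_core import k_from_rank_difference, lottery_probability

    df = _as_frame(records)
    coop = df[df["treatment"].isin(COOP_TREATMENTS)].copy()
    out: dict[str, pd.DataFrame] = {}

    if not coop.empty:
        coop["success_f"] = coop["success"].astype(float)
        per = _per_player_success(coop)
        out["fig1a"] = (
            per.groupby("treatment")["n_successes"].mean().rename("mean_successes").reset_index()
        )
        long = _member_rows(coop)
        long["contribution"] = long["contribution"].astype(float)
        out["fig1b"] = (
            long.groupby("treatment")["contribution"].mean().rename("mean_contribution").reset_index()
        )
        coop["hierarchy"] = np.where(coop["treatment"] == "control", "none", "hierarchy")
        out["fig1c"] = (
            coop.groupby(["hierarchy", "round"])["success_f"].mean()
            .rename("success_rate").reset_index()
        )
        long["role_label"] = long["role"]
        out["fig2a"] = (
            long.groupby(["treatment", "role_label"])["contribution"].mean()
            .rename("mean_contribution").reset_index()
        )
        long["hierarchy"] = np.where(long["treatment"] == "control", "none", "hierarchy")
        out["fig2b"] = (
            long.groupby(["hierarchy", "role_label", "round"])["contribution"].mean()
            .rename("mean_contribution").reset_index()
        )
        hier = long[long["treatment"].isin(HIERARCHY_COOP)].copy()
        if not hier.empty:
            hier["signed_diff"] = (hier["own_rank"] - hier["partner_rank"]).astype(int)
            out["fig2c"] = (
                hier.groupby("signed_diff")["contribution"].mean()
                .rename("mean_contribution").reset_index()
            )
        long["outcome"] = np.where(long["success"].astype(bool), "success", "failure")
        out["fig3"] = (
            long.groupby(["treatment", "role_label", "outcome"])["contribution"].mean()
            .rename("mean_contribution").reset_index()
        )

    split = df[df["offer"].notna()].copy()
    if not split.empty:
        has_rank = split["rank_high"].notna()
        split["k"] = 0
        split.loc[has_rank, "k"] = [
            k_from_rank_difference(int(d))
            for d in (split.loc[has_rank, "rank_low"] - split.loc[has_rank, "rank_high"])
        ]
        rows = []
        for (label, k), sub in split.groupby(["treatment", "k"]):
            tr = get_treatment(label)
            d_repr = None if not tr.has_hierarchy else {1: 9, 2: 7, 3: 5, 4: 3, 5: 1}[k]
            nash, _ = spe_split(lottery_probability(tr, d_repr), int(sub["pot"].iloc[0]))
            rows.append(
                {
                    "treatment": label,
                    "k": int(k) if tr.has_hierarchy else pd.NA,
                    "mean_offer": float(sub["offer"].astype(float).mean()),
                    "mean_threshold": float(sub["threshold_low"].astype(float).mean()),
                    "nash_offer": nash,
                    "n": len(sub),
                }
            )
        out["fig4"] = pd.DataFrame(rows)
    return out


def rank_earnings_correlation(records: Records) -> float:
    """Spearman correlation between status and total earnings.

    Status recodes hierarchy rank so larger = higher (top rank 1 becomes the
    largest status value); earnings are total units over an individual's
    trials in the hierarchy treatments.  Returns NaN when undefined
    (constant earnings or ranks).
    """
    df = _as_frame(records)
    df = df[df["treatment"].isin(HIERARCHY_ALL)]
    if df.empty:
        raise ValueError("no hierarchy-treatment records")
    long = _member_rows(df)
    per = long.groupby("individual_id").agg(
        rank=("own_rank", "first"), earnings=("payoff", "sum")
    )
    n = per["rank"].max()
    status = n + 1 - per["rank"].astype(float)
    if per["earnings"].nunique() <= 1 or per["rank"].nunique() <= 1:
        return float("nan")
    rho, _ = scipy.stats.spearmanr(status, per["earnings"].astype(float))
    return float(rho)
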