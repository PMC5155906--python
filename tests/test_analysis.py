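import numpy as np
import pandas as pd
import pytest

from hiercoop import analysis as an
from hiercoop.agents import AgentParams
from hiercoop.game_core import TrialRecord, records_to_frame
from hiercoop.synthetic_data import StudyDesign, generate_study


def _trial(**kw):
    base = dict(
        session_id="s0", treatment="earned", round=1, id_high="a", id_low="b",
        rank_high=2, rank_low=7, c_high=12, c_low=8, success=True, pot=40,
        offer=12, threshold_low=10, accepted=True, lottery_winner="none",
        payoff_high=36, payoff_low=24,
    )
    base.update(kw)
    return TrialRecord(**base)


class TestContrasts:
    @pytest.mark.parametrize(
        "treatment,codes", [("control", (2, 0)), ("random", (-1, -1)), ("earned", (-1, 1))]
    )
    def test_coding(self, treatment, codes):
        assert an.encode_contrasts(treatment) == codes

    def test_no_coop_labels_outside_contrast_set(self):
        with pytest.raises(ValueError):
            an.encode_contrasts("earned_no_coop")

    def test_orthogonal_over_balanced_design(self):
        codes = [an.encode_contrasts(t) for t in ("control", "random", "earned")]
        h1, h2 = zip(*codes)
        assert sum(a * b for a, b in zip(h1, h2)) == 0
        assert sum(h1) == 0 and sum(h2) == 0

    def test_design_matrix_matches_hand_built_toy(self):
        recs = [
            _trial(treatment="control", rank_high=None, rank_low=None, round=1),
            _trial(treatment="control", rank_high=None, rank_low=None, round=9),
            _trial(treatment="random", round=1),
            _trial(treatment="random", round=9),
            _trial(treatment="earned", round=1),
            _trial(treatment="earned", round=9),
        ]
        df = an.success_frame(records_to_frame(recs))
        assert df["h1"].tolist() == [2, 2, -1, -1, -1, -1]
        assert df["h2"].tolist() == [0, 0, -1, -1, 1, 1]
        assert df["round_c"].tolist() == [-4, 4, -4, 4, -4, 4]
        assert df["h1_round"].tolist() == [-8, 8, 4, -4, 4, -4]


class TestDyadBootstrap:
    @staticmethod
    def _mean_fit(d):
        return pd.Series({"mu": d["y"].mean()})

    def test_single_replicate_ci_collapses(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "unit": ["a", "b", "c"]})
        rng = np.random.default_rng(0)
        fit = an.dyad_bootstrap(df, self._mean_fit, unit="unit", n_boot=1, rng=rng)
        lo, hi = fit.ci("mu")
        assert lo == hi  # one replicate: degenerate percentile interval

    def test_identical_seeds_give_identical_cis(self, small_study_frame):
        fits = [
            an.fit_success_model(small_study_frame, n_boot=25, rng=np.random.default_rng(5))
            for _ in range(2)
        ]
        assert fits[0].table.equals(fits[1].table)

    def test_excessive_drop_fraction_fails(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "unit": ["a", "b"]})

        def always_fail(d):
            raise an.FitError("no")

        with pytest.raises(an.FitError):
            an.dyad_bootstrap(df, always_fail, unit="unit", n_boot=10,
                              rng=np.random.default_rng(0))

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            an.dyad_bootstrap(pd.DataFrame(), self._mean_fit, unit="unit")


@pytest.fixture(scope="module")
def hierarchy_study():
    design = StudyDesign(
        groups_per_treatment={"control": 4, "earned": 4, "random": 4,
                              "earned_no_coop": 4, "random_no_coop": 4},
        master_seed=99,
    )
    return records_to_frame(generate_study(design))


class TestModelFamilies:
    def test_contribution_model_recovers_rank_gap(self, hierarchy_study):
        # the default calibration makes lower-ranked members out-contribute
        # higher-ranked ones on average, so the +1-high rank code is negative
        rng = np.random.default_rng(21)
        fit = an.fit_contribution_model(hierarchy_study, n_boot=60, rng=rng)
        lo, hi = fit.ci("rank_code")
        assert hi < 0

    def test_rank_difference_slope_recovers_generated_sign(self, hierarchy_study):
        # under the default calibration lower-ranked members (positive signed
        # difference) contribute more on average, so the recovered slope is
        # positive: the model recovers the sign of the generated gradient
        rng = np.random.default_rng(22)
        fit = an.fit_rank_difference_model(hierarchy_study, n_boot=60, rng=rng)
        lo, hi = fit.ci("signed_diff")
        assert lo > 0

    def test_rank_difference_frame_excludes_extreme_ranks(self, hierarchy_study):
        frame = an.rank_difference_frame(hierarchy_study)
        assert frame["own_rank"].min() == 2
        assert frame["own_rank"].max() == 9

    def test_ultimatum_cooperation_presence_is_null(self):
        # with noiseless agents every cooperation trial succeeds, so the
        # splitting data are generated identically with and without the
        # cooperation phase and the presence contrast covers zero
        params = {t: AgentParams().with_noise_sd(0.0)
                  for t in ("earned", "random", "earned_no_coop", "random_no_coop")}
        design = StudyDesign(
            groups_per_treatment={t: 3 for t in params}, agent_params=params,
            master_seed=12,
        )
        df = records_to_frame(generate_study(design))
        fit = an.fit_ultimatum_model(df, n_boot=60, rng=np.random.default_rng(23))
        lo, hi = fit.ci("coop_present")
        assert lo <= 0 <= hi

    def test_ultimatum_receivers_expect_more_than_proposers_offer(self, hierarchy_study):
        rng = np.random.default_rng(24)
        fit = an.fit_ultimatum_model(hierarchy_study, n_boot=60, rng=rng)
        lo, hi = fit.ci("role")
        assert lo > 0

    def test_all_success_data_flagged_not_crashed(self):
        recs = []
        for i, tr in enumerate(["control", "earned", "random"]):
            recs += generate_study(StudyDesign(
                groups_per_treatment={tr: 1}, master_seed=i,
                agent_params={tr: AgentParams(kind="nash")}))
        fit = an.fit_success_model(records_to_frame(recs), n_boot=10,
                                   rng=np.random.default_rng(1))
        assert fit.n_boot == 10  # returns a result; boundary estimates allowed

    def test_empty_subset_rejected(self):
        control_only = records_to_frame(generate_study(
            StudyDesign(groups_per_treatment={"control": 1}, master_seed=0)))
        with pytest.raises(ValueError):
            an.fit_contribution_model(control_only)


class TestSummaries:
    def test_figure_tables_on_full_study(self, hierarchy_study):
        tables = an.summarize_figures(hierarchy_study)
        assert set(tables) == {"fig1a", "fig1b", "fig1c", "fig2a", "fig2b",
                               "fig2c", "fig3", "fig4"}
        assert (tables["fig1a"]["mean_successes"] <= 9).all()
        assert set(tables["fig4"]["treatment"]) == {
            "control", "earned", "random", "earned_no_coop", "random_no_coop"}
        hier4 = tables["fig4"].dropna(subset=["k"])
        assert (hier4["nash_offer"] == 4 * hier4["k"].astype(int)).all()

    def test_nash_agents_offers_equal_4k_exactly(self):
        design = StudyDesign(
            groups_per_treatment={"earned": 3},
            agent_params={"earned": AgentParams(kind="nash")},
            master_seed=8,
        )
        tables = an.summarize_figures(records_to_frame(generate_study(design)))
        fig4 = tables["fig4"]
        assert (fig4["mean_offer"] == 4 * fig4["k"].astype(int)).all()
        assert (fig4["mean_threshold"] == 4 * fig4["k"].astype(int)).all()

    def test_signed_difference_sign_convention(self):
        # a focal player ranked 1 against a partner ranked 9 sits at -8
        recs = [_trial(rank_high=1, rank_low=9)]
        table = an.summarize_figures(records_to_frame(recs))["fig2c"]
        assert set(table["signed_diff"]) == {-8, 8}
        row = table[table["signed_diff"] == -8].iloc[0]
        assert row["mean_contribution"] == 12  # the high-ranked player's contribution


class TestRankEarningsCorrelation:
    def test_nash_play_yields_positive_correlation(self):
        design = StudyDesign(
            groups_per_treatment={"earned": 3, "random": 3},
            agent_params={t: AgentParams(kind="nash") for t in ("earned", "random")},
            master_seed=6,
        )
        rho = an.rank_earnings_correlation(generate_study(design))
        assert rho > 0

    def test_default_calibration_yields_positive_correlation(self, hierarchy_study):
        assert an.rank_earnings_correlation(hierarchy_study) > 0

    def test_constant_earnings_flagged_as_nan(self):
        recs = [
            _trial(id_high="a", id_low="b", rank_high=1, rank_low=2,
                   payoff_high=30, payoff_low=30),
            _trial(id_high="c", id_low="d", rank_high=3, rank_low=4,
                   payoff_high=30, payoff_low=30),
        ]
        assert np.isnan(an.rank_earnings_correlation(recs))

    def test_no_hierarchy_records_rejected(self):
        control = generate_study(StudyDesign(groups_per_treatment={"control": 1}))
        with pytest.raises(ValueError):
            an.rank_earnings_correlation(control)
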