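"""Cox model contrasts against a brute-force partial-likelihood oracle,
quintile machinery, and subgroup analyses."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import grid_search_beta
from punctakit import survival
from punctakit.simulate import CohortSimParams, simulate_event_cohort


def two_arm_params(hr: float, n: int, seed: int, **kw) -> CohortSimParams:
    return CohortSimParams(
        n_cells=n,
        groups=("A", "B"),
        log_hazard_death={"A": 0.0, "B": math.log(hr)},
        log_hazard_puncta={"A": 0.0, "B": 0.0},
        seed=seed,
        **kw,
    )


class TestFitCox:
    def test_matches_grid_search_oracle(self, toy_cox_dataset):
        """On tiny datasets the fitted log-hazard equals the argmax of the
        Efron partial likelihood found by exhaustive grid search."""
        df = toy_cox_dataset
        x = (df["group"] == "B").astype(float).to_numpy()
        beta_oracle = grid_search_beta(df["time"], df["event"], x)
        res = survival.fit_cox(df, reference="A")[0]
        assert res.beta == pytest.approx(beta_oracle, abs=1e-3)
        assert res.hazard_ratio == pytest.approx(math.exp(res.beta))

    def test_exchangeable_groups_give_unit_hazard(self):
        df = pd.DataFrame(
            {
                "time": [1, 2, 3, 1, 2, 3],
                "event": [1, 1, 1, 1, 1, 1],
                "group": ["A"] * 3 + ["B"] * 3,
            }
        )
        res = survival.fit_cox(df, reference="A")[0]
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    def test_simulated_cohort_recovery_within_3_se(self):
        events = simulate_event_cohort(two_arm_params(1.6, 2000, seed=42))
        res = survival.fit_cox(events, reference="A", strata_col="stratum")[0]
        assert abs(res.beta - math.log(1.6)) <= 3 * res.se

    def test_no_events_rejected(self):
        df = pd.DataFrame(
            {"time": [1, 2], "event": [0, 0], "group": ["A", "B"]}
        )
        with pytest.raises(survival.SurvivalError, match="no observed events"):
            survival.fit_cox(df, reference="A")

    def test_complete_separation_flagged(self):
        # every A event precedes every B observation: monotone likelihood
        df = pd.DataFrame(
            {
                "time": [1, 2, 3, 10, 11, 12],
                "event": [1, 1, 1, 0, 0, 0],
                "group": ["A", "A", "A", "B", "B", "B"],
            }
        )
        with pytest.raises(survival.SeparationError):
            survival.fit_cox(df, reference="B")

    def test_invariant_to_strata_relabeling_and_time_rescaling(self):
        events = simulate_event_cohort(two_arm_params(1.4, 600, seed=3))
        base = survival.fit_cox(events, reference="A", strata_col="stratum")[0]
        relabeled = events.copy()
        relabeled["stratum"] = relabeled["stratum"].map(
            {"exp1": "z9", "exp2": "z1", "exp3": "z5"}
        )
        res2 = survival.fit_cox(relabeled, reference="A", strata_col="stratum")[0]
        assert res2.beta == pytest.approx(base.beta, rel=1e-8)
        rescaled = events.copy()
        rescaled["time"] *= 7.3
        res3 = survival.fit_cox(rescaled, reference="A", strata_col="stratum")[0]
        assert res3.beta == pytest.approx(base.beta, rel=1e-6)


class TestQuintiles:
    def test_distinct_values_split_evenly(self):
        bins = survival.quintile_bin(np.arange(1, 11))
        assert list(bins[:2]) == [1, 1]
        assert [np.sum(bins == q) for q in range(1, 6)] == [2] * 5

    def test_five_values_one_each(self):
        assert sorted(survival.quintile_bin([5.0, 1.0, 3.0, 2.0, 4.0])) == [1, 2, 3, 4, 5]

    def test_ties_resolved_by_stable_rank(self):
        bins = survival.quintile_bin([1, 1, 1, 1, 2, 2, 2, 2, 3, 3])
        assert [np.sum(bins == q) for q in range(1, 6)] == [2] * 5
        # stable order: the first two 1s land in quintile 1
        assert list(bins[:2]) == [1, 1]

    def test_too_few_values_rejected(self):
        with pytest.raises(survival.SurvivalError):
            survival.quintile_bin([1.0, 2.0])

    def test_monotone_hazard_under_expression_effect(self):
        """A log-linear expression effect on the death hazard yields
        monotone increasing quintile hazard ratios."""
        params = two_arm_params(1.0, 4000, seed=11)
        params.expression_effect_death = 0.5
        events = simulate_event_cohort(params)
        tab = survival.hazard_by_quintile(
            events, value_col="day1_intensity", within_col=None
        )
        hrs = tab.sort_values("quintile")["hazard_ratio"].to_numpy()
        assert np.all(np.diff(hrs) > 0)
        assert hrs[-1] > 1.5  # top vs bottom quintile spans > exp(0.5 * 2 sd)

    def test_null_quintile_cis_cover_one(self):
        params = two_arm_params(1.0, 1000, seed=21)
        events = simulate_event_cohort(params)
        tab = survival.hazard_by_quintile(
            events, value_col="day1_intensity", within_col="group"
        )
        covered = (tab["ci_low"] <= 1.0) & (1.0 <= tab["ci_high"])
        assert covered.mean() >= 0.75  # single replicate; acceptance covers many


class TestDiffusePunctate:
    @staticmethod
    def make_events(hr_punctate: float, n: int, seed: int) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        group = np.r_[["iRFP"] * n, ["WT"] * n, ["WT"] * n]
        flag = np.r_[np.zeros(n), np.zeros(n), np.ones(n)].astype(bool)
        rate = 0.13 * np.where(flag, hr_punctate, 1.0)
        latent = rng.exponential(1.0 / rate)
        return pd.DataFrame(
            {
                "group": group,
                "day1_punctate": flag,
                "time": np.minimum(latent, 9.0),
                "event": (latent <= 9.0).astype(int),
            }
        )

    def test_null_gives_unit_hazards(self):
        events = self.make_events(1.0, 800, seed=5)
        vs_control, within = survival.diffuse_vs_punctate_analysis(
            events, control_group="iRFP"
        )
        for r in vs_control + within:
            assert abs(r.beta) <= 3 * r.se  # single replicate: 3 SE band

    def test_punctate_excess_risk_recovered(self):
        events = self.make_events(1.3, 2000, seed=6)
        _, within = survival.diffuse_vs_punctate_analysis(events, control_group="iRFP")
        (res,) = within
        assert res.term == "WT_punctate"
        assert abs(res.beta - math.log(1.3)) <= 3 * res.se

    def test_empty_control_rejected(self):
        events = self.make_events(1.0, 50, seed=7)
        with pytest.raises(survival.SurvivalError, match="control group"):
            survival.diffuse_vs_punctate_analysis(events, control_group="nope")


class TestRiskTable:
    def test_single_unit_result(self):
        res = survival.CoxResult(
            term="WT", reference="iRFP", n=10, hazard_ratio=1.0,
            ci_low=0.5, ci_high=2.0, p=1.0, beta=0.0, se=0.35,
        )
        table = survival.risk_table_report([res])
        assert table.iloc[0]["group"] == "iRFP"  # reference row first, HR 1
        assert table.iloc[0]["hazard_ratio"] == 1.0
        assert table.iloc[1]["hazard_ratio"] == 1.0000

    def test_round_trip_preserves_values(self, tmp_path):
        events = simulate_event_cohort(two_arm_params(1.5, 400, seed=9))
        table = survival.risk_table_report(
            survival.fit_cox(events, reference="A")
        )
        path = tmp_path / "risk.csv"
        table.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, table, check_dtype=False)

    def test_seven_group_cohort_reference_row(self):
        events = simulate_event_cohort(CohortSimParams(n_cells=1400, seed=13))
        results = survival.fit_cox(
            events, reference="iRFP", strata_col="stratum"
        )
        table = survival.risk_table_report(results)
        assert len(table) == 7
        assert table.iloc[0]["group"] == "iRFP"
        assert table.iloc[0]["hazard_ratio"] == 1.0
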