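"""Analysis stages on canonical decision tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crdtiming.analysis import (
    ConditionalTable,
    ExperimentTable,
    ValidationError,
    classify_profiles,
    conditional_table,
    constant_contributor_count,
    fairness_classification,
    half_split,
    load_table,
    per_round_means,
    success_fraction,
    weighted_regression,
)
from crdtiming.strategies import StrategyKind
from crdtiming.synthetic import CohortSpec, fixture_suite, generate


@pytest.fixture()
def all2_table(make_table):
    """Two NU groups of six all-2 players: 60 rows each, C = F for all."""
    return ExperimentTable(
        make_table(
            ("NU", "g0", [[2] * 10] * 6),
            ("NU", "g1", [[2] * 10] * 6),
        )
    )


class TestLoadAndValidate:
    def test_canonical_fixture_ingests_all_rows(self, tmp_path, make_table):
        df = make_table(("NU", "g0", [[2] * 10] * 6))
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        table = load_table(path)
        assert len(table.df) == 60

    def test_schema_map_renames_and_reports_missing(self, tmp_path, make_table):
        df = make_table(("NU", "g0", [[2] * 10] * 6)).rename(columns={"action": "contrib"})
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        table = load_table(path, schema_map={"action": "contrib"})
        assert len(table.df) == 60
        with pytest.raises(ValidationError, match="nope"):
            load_table(path, schema_map={"action": "nope"})

    def test_non_action_value_rejected_with_row(self, make_table):
        df = make_table(("NU", "g0", [[2] * 10] * 6))
        df.loc[13, "action"] = 3
        with pytest.raises(ValidationError, match="13"):
            ExperimentTable(df)

    def test_inconsistent_group_length_rejected(self, make_table):
        df = make_table(("NU", "g0", [[2] * 10] * 5 + [[2] * 9]))
        with pytest.raises(ValidationError, match="length"):
            ExperimentTable(df)

    def test_overspent_endowment_rejected(self, make_table):
        df = make_table(("NU", "g0", [[4] * 10] * 5 + [[4] * 10]))
        df.loc[df["round"] > 0, "action"] = 4  # fine: C = 40 = E
        ExperimentTable(df.copy())
        df2 = make_table(("NU", "g0", [[4] * 11] * 6))  # C = 44 > 40
        with pytest.raises(ValidationError, match="endowment"):
            ExperimentTable(df2)


class TestPerRoundMeans:
    def test_constant_contributions_have_zero_width_ci(self, all2_table):
        out = per_round_means(all2_table, "NU")
        assert (out["mean"] == 12).all()
        assert out["ci_low"].to_numpy() == pytest.approx(out["ci_high"].to_numpy())

    def test_two_groups_textbook_t_interval(self, make_table):
        table = ExperimentTable(
            make_table(
                ("NU", "g0", [[2, 2, 2, 2, 2, 2, 2, 2, 2, 2]] * 5 + [[0] * 10]),
                ("NU", "g1", [[2] * 10] * 6 + []),
            )
        )
        # round-1 group totals are 10 and 14
        table.df.loc[
            (table.df.group_id == "g1") & (table.df.player_id == "g1-p0"), "action"
        ] = [4] + [2] * 9
        table = ExperimentTable(table.df)
        out = per_round_means(table, "NU").set_index("round")
        mean = out.loc[1, "mean"]
        assert mean == pytest.approx(12.0)
        sem = np.std([10, 14], ddof=1) / np.sqrt(2)
        t975 = stats.t.ppf(0.975, df=1)
        assert out.loc[1, "ci_low"] == pytest.approx(12 - t975 * sem)
        assert out.loc[1, "ci_high"] == pytest.approx(12 + t975 * sem)

    def test_single_group_flags_undefined_ci(self, make_table):
        table = ExperimentTable(make_table(("NU", "g0", [[2] * 10] * 6)))
        out = per_round_means(table, "NU")
        assert (out["mean"] == 12).all()
        assert out["ci_low"].isna().all()


class TestSuccessFraction:
    def test_fraction_and_clopper_pearson_interval(self, make_table):
        groups = [("NU", f"g{i}", [[2] * 10] * 6) for i in range(8)]
        groups += [("NU", f"f{i}", [[0] * 10] * 6) for i in range(4)]
        table = ExperimentTable(make_table(*groups))
        out = success_fraction(table, "NU")
        assert out["fraction"] == pytest.approx(8 / 12)
        assert out["n_groups"] == 12
        # Clopper-Pearson bounds from the beta quantile closed form
        lo = stats.beta.ppf(0.025, 8, 12 - 8 + 1)
        hi = stats.beta.ppf(0.975, 8 + 1, 12 - 8)
        assert out["ci_low"] == pytest.approx(lo)
        assert out["ci_high"] == pytest.approx(hi)

    def test_degenerate_fractions(self, all2_table, make_table):
        assert success_fraction(all2_table, "NU")["fraction"] == 1.0
        table = ExperimentTable(make_table(("NU", "g0", [[0] * 10] * 6)))
        assert success_fraction(table, "NU")["fraction"] == 0.0


class TestFairnessAndHalves:
    def test_all_fair_share_players(self, all2_table):
        out = fairness_classification(all2_table, "NU")
        assert (out["below"], out["equal"], out["above"]) == (0.0, 1.0, 0.0)

    def test_polarized_group_splits_half_half(self):
        table = ExperimentTable(fixture_suite()["polarized"])
        out = fairness_classification(table, "NU", successful_only=True)
        assert out["below"] == pytest.approx(0.5)
        assert out["equal"] == 0.0
        assert out["above"] == pytest.approx(0.5)

    def test_fractions_partition(self, all2_table):
        out = fairness_classification(all2_table, "NU")
        assert out["below"] + out["equal"] + out["above"] == pytest.approx(1.0)

    def test_front_loader_is_above_in_first_half(self, make_table):
        acts = [4, 4, 4, 0, 0, 0, 0, 0, 0, 0]
        others = [[2] * 10] * 5
        table = ExperimentTable(make_table(("NU", "g0", [acts] + others)))
        out = half_split(table, "NU", successful_only=None).set_index("half")
        # the front-loader: first-half C = 12 > 10; the all-2 players sit at 10
        assert out.loc["first", "above"] == pytest.approx(1 / 6)
        assert out.loc["first", "equal"] == pytest.approx(5 / 6)

    def test_all2_players_exactly_meet_half_fair_share(self, all2_table):
        out = half_split(all2_table, "NU").set_index("half")
        assert out.loc["first", "equal"] == 1.0
        assert out.loc["second", "equal"] == 1.0

    def test_early_cohort_first_half_exceeds_second(self):
        table = ExperimentTable(fixture_suite()["hu_early"])
        out = half_split(table, "HU", successful_only=None).set_index("half")
        assert out.loc["first", "above"] > out.loc["second", "above"]


class TestConditionalResponse:
    def test_all2_groups_give_single_bin(self, all2_table):
        ct = conditional_table(all2_table, "NU")
        assert list(ct.data["x"]) == [10]
        assert ct.data.loc[0, "mean"] == pytest.approx(2.0)
        assert ct.data.loc[0, "freq_2"] == 1.0

    def test_reciprocal_groups_hold_at_high_bin_until_target(self, make_table):
        spec = CohortSpec(
            treatment="NU",
            n_groups=3,
            mixture={StrategyKind.RECIPROCAL: 1.0},
            seed=1,
        )
        table, _ = generate(spec)
        ct = conditional_table(table, "NU", pre_success_only=True)
        assert list(ct.data["x"]) == [20]
        assert ct.data.loc[0, "mean"] == pytest.approx(4.0)

    def test_bin_frequencies_sum_to_one(self, all2_table):
        ct = conditional_table(all2_table, "NU")
        freq_cols = [c for c in ct.data.columns if c.startswith("freq_")]
        assert ct.data[freq_cols].sum(axis=1).to_numpy() == pytest.approx(1.0)


class TestWeightedRegression:
    def test_exact_linear_input_recovers_coefficients(self):
        data = pd.DataFrame(
            {"x": [0, 4, 8, 12], "mean": [1.0, 1.4, 1.8, 2.2], "count": [5, 5, 5, 5]}
        )
        fit = weighted_regression(ConditionalTable(data, "NU", None))
        assert fit.slope == pytest.approx(0.1, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)

    def test_flat_means_give_zero_slope(self):
        data = pd.DataFrame({"x": [0, 10, 20], "mean": [2.0, 2.0, 2.0], "count": [3, 9, 1]})
        fit = weighted_regression(ConditionalTable(data, "NU", None))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_is_flagged_undefined(self, all2_table):
        ct = conditional_table(all2_table, "NU")
        with pytest.raises(ValidationError, match="fewer than 2"):
            weighted_regression(ct)

    def test_planted_cohorts_recover_slope_signs(self):
        recip = CohortSpec(
            treatment="HU",
            n_groups=40,
            mixture={
                StrategyKind.RECIPROCAL: 0.5,
                StrategyKind.ALWAYS2: 0.3,
                StrategyKind.ALWAYS0: 0.2,
            },
            seed=21,
        )
        table, _ = generate(recip)
        fit = weighted_regression(conditional_table(table, "HU", pre_success_only=True))
        assert fit.slope > 0

        comp = CohortSpec(
            treatment="HU",
            n_groups=40,
            mixture={
                StrategyKind.COMPENSATOR: 0.5,
                StrategyKind.ALWAYS4: 0.25,
                StrategyKind.ALWAYS0: 0.25,
            },
            seed=22,
        )
        table, _ = generate(comp)
        fit = weighted_regression(conditional_table(table, "HU", pre_success_only=True))
        assert fit.slope < 0


class TestCountsAndProfiles:
    def test_planted_constant_contributors_are_counted(self):
        table = ExperimentTable(fixture_suite()["planted_two_all2"])
        assert constant_contributor_count(table, "NU", 2) == 2
        assert constant_contributor_count(table, "NU", 2, successful_only=True) == 2

    def test_constant_player_is_unconditional(self, all2_table):
        out = classify_profiles(all2_table, "NU")
        assert (out["profile"] == "unconditional-2").all()

    def test_simulated_conditional_players_recovered(self):
        spec = CohortSpec(
            treatment="HU",
            n_groups=40,
            mixture={
                StrategyKind.RECIPROCAL: 0.3,
                StrategyKind.COMPENSATOR: 0.3,
                StrategyKind.ALWAYS0: 0.2,
                StrategyKind.ALWAYS2: 0.2,
            },
            seed=5,
        )
        table, truth = generate(spec)
        got = classify_profiles(table, "HU").set_index(["group_id", "player_id"])["profile"]
        hits = total = 0
        for g in truth["groups"]:
            for j, eff in enumerate(g["effective_profiles"]):
                total += 1
                hits += got[(g["group_id"], f"{g['group_id']}-p{j}")] == eff
        assert hits / total >= 0.95
        # and conditional players do get recovered as conditional
        assert (got == "reciprocal-like").any()
        assert (got == "compensator-like").any()

    def test_slope_method_agrees_on_clean_conditionals(self, make_table):
        # a reciprocal-style player facing a varying context
        focal = [4, 4, 0, 4, 0, 4, 0, 0, 0, 0]
        others = [
            [4, 0, 4, 0, 4, 0, 0, 0, 0, 0],
            [4, 0, 4, 0, 4, 0, 0, 0, 0, 0],
            [4, 0, 4, 0, 4, 0, 0, 0, 0, 0],
            [2] * 10,
            [2] * 10,
        ]
        table = ExperimentTable(make_table(("NU", "g0", [focal] + others)))
        out = classify_profiles(table, "NU", method="slope").set_index("player_id")
        assert out.loc["g0-p0", "profile"] == "reciprocal-like"

    def test_pipeline_is_deterministic(self, all2_table):
        a = classify_profiles(all2_table, "NU")
        b = classify_profiles(all2_table, "NU")
        pd.testing.assert_frame_equal(a, b)
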