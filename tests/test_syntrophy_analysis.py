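"""Scenario evaluation, equilibrium formate, critical H2, windows, shares."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from syntherm import (
    MediumConditions,
    Scenario,
    actual_delta_g,
    build_activity_set,
    critical_h2,
    energy_partition,
    equilibrium_formate,
    evaluate_scenario,
    h2_window,
    load_scenario,
    standard_delta_g,
)
from syntherm.errors import (
    ActivityDomainError,
    ConfigError,
    UndefinedPartitionError,
    UsageError,
)
from syntherm.reactions import (
    ACETATE_OXIDATION,
    HYDROGENOTROPHIC_METHANOGENESIS,
    MSAO_TOTAL,
)
from syntherm.syntrophy_analysis import ReactionEnergy, ScenarioResult


class TestEvaluateScenario:
    def test_standard_state_recovers_dg0(self, table):
        """All activities 1 and gases at 1 atm collapse dG to dG0."""
        conditions = MediumConditions(
            temperature=298.15,
            pH=0.0,
            solutes={"acetate": 2.0, "HCO3-": 2.0},  # conc * f_mono = 1
            gases={"H2": 101325.0, "CH4": 101325.0},
            h2_frame="pure_water",
        )
        scenario = Scenario(
            label="standard",
            producer_reaction=ACETATE_OXIDATION,
            consumer_reaction=HYDROGENOTROPHIC_METHANOGENESIS,
            total_reaction=MSAO_TOTAL,
            conditions=conditions,
        )
        result = evaluate_scenario(scenario, table)
        for role, reaction in scenario.reactions():
            assert result.delta_g(role, "pure_water") == pytest.approx(
                standard_delta_g(reaction, table), abs=1e-9
            )

    def test_partner_energies_add_to_total_both_frames(self, scenarios, table):
        for label in ("M-SAO", "S-SAO"):
            result = evaluate_scenario(scenarios[label], table)
            for frame in ("pure_water", "soda_corrected"):
                assert result.delta_g("producer", frame) + result.delta_g(
                    "consumer", frame
                ) == pytest.approx(result.delta_g("total", frame), abs=1e-9)

    def test_total_reaction_is_frame_independent(self, scenarios, table):
        for label in ("M-SAO", "S-SAO"):
            result = evaluate_scenario(scenarios[label], table)
            rec = result.record("total")
            assert rec.dg1 == pytest.approx(rec.dg1_star, abs=1e-12)

    def test_inconsistent_total_is_rejected(self, msao):
        with pytest.raises(ConfigError, match="total"):
            Scenario(
                label="broken",
                producer_reaction=ACETATE_OXIDATION,
                consumer_reaction=HYDROGENOTROPHIC_METHANOGENESIS,
                total_reaction=ACETATE_OXIDATION,
                conditions=msao.conditions,
            )

    def test_missing_species_error_names_it(self, table, msao):
        conditions = msao.conditions.replace(solutes={"HCO3-": 0.6})  # no acetate
        scenario = Scenario(
            label="incomplete",
            producer_reaction=ACETATE_OXIDATION,
            conditions=conditions,
        )
        with pytest.raises(Exception, match="acetate"):
            evaluate_scenario(scenario, table)


class TestEquilibriumFormate:
    def test_linear_in_h2_pressure(self, msao):
        base = msao.conditions
        doubled = base.replace()
        doubled.gases["H2"] = base.gases["H2"] * 2
        assert equilibrium_formate(doubled) == pytest.approx(
            2 * equilibrium_formate(base), rel=1e-12
        )

    def test_proportional_to_bicarbonate_activity(self, msao):
        base = msao.conditions
        richer = base.replace(
            solutes={**base.solutes, "HCO3-": base.solutes["HCO3-"] * 3}
        )
        assert equilibrium_formate(richer) == pytest.approx(
            3 * equilibrium_formate(base), rel=1e-12
        )

    def test_below_detection_at_maximum_uninhibited_h2(self, msao):
        conditions = msao.conditions.replace()
        conditions.gases["H2"] = 12.3
        value = equilibrium_formate(conditions)
        assert value == pytest.approx(25.0, abs=0.5)
        assert value < 50.0

    def test_requires_positive_h2(self, msao):
        conditions = msao.conditions.replace(gases={})
        with pytest.raises(ActivityDomainError, match="H2"):
            equilibrium_formate(conditions)

    def test_closed_form_solves_dg_equal_zero(self, table, msao):
        """Plugging the returned concentration back in gives dG = 0."""
        from syntherm.reactions import FORMATE_OXIDATION

        conditions = msao.conditions
        uM = equilibrium_formate(conditions, table)
        conds = conditions.replace(
            solutes={**conditions.solutes, "formate": uM * 1e-6}
        )
        acts = build_activity_set(conds, table)
        dg = actual_delta_g(FORMATE_OXIDATION, table, acts, conds.temperature)
        assert dg == pytest.approx(0.0, abs=1e-9)


class TestCriticalH2:
    def test_fixed_point_of_actual_delta_g(self, table, msao):
        for frame in ("pure_water", "soda_corrected"):
            conds = msao.conditions.replace(h2_frame=frame)
            for threshold in (0.0, -5.0):
                p_star = critical_h2(ACETATE_OXIDATION, conds, table, threshold)
                check = conds.replace()
                check.gases["H2"] = p_star
                acts = build_activity_set(check, table)
                dg = actual_delta_g(ACETATE_OXIDATION, table, acts, conds.temperature)
                assert dg == pytest.approx(threshold, abs=1e-9)

    def test_agrees_with_bisection_oracle(self, table, msao):
        conds = msao.conditions.replace(h2_frame="pure_water")

        def dg_at(p):
            c = conds.replace()
            c.gases["H2"] = p
            acts = build_activity_set(c, table)
            return actual_delta_g(ACETATE_OXIDATION, table, acts, c.temperature)

        oracle = brentq(dg_at, 1e-6, 1e6, xtol=1e-12, rtol=1e-14)
        closed = critical_h2(ACETATE_OXIDATION, conds, table)
        assert abs(closed - oracle) / oracle < 1e-6

    def test_producer_ceiling_just_below_measured_plateau(self, table, msao):
        conds = msao.conditions.replace(h2_frame="pure_water")
        p_star = critical_h2(ACETATE_OXIDATION, conds, table)
        assert p_star == pytest.approx(10.24, abs=0.05)
        assert p_star < 11.5

    def test_consumer_floor_far_below_measured_plateau(self, table, msao):
        conds = msao.conditions.replace(h2_frame="pure_water")
        p_star = critical_h2(HYDROGENOTROPHIC_METHANOGENESIS, conds, table)
        assert p_star < 1.0  # methanogenesis stays exergonic far above this

    def test_reaction_without_h2_is_rejected(self, table, msao):
        with pytest.raises(UsageError, match="H2"):
            critical_h2(MSAO_TOTAL, msao.conditions, table)


class TestH2Window:
    def test_msao_window_contains_measured_plateau(self, msao, table):
        window = h2_window(msao, table)
        assert window.nonempty
        assert 11.5 in window

    def test_ssao_window_contains_measured_plateau(self, ssao, table):
        window = h2_window(ssao, table)
        assert window.nonempty
        assert 4.7 in window

    def test_infeasible_threshold_gives_empty_window(self, msao, table):
        window = h2_window(msao, table, threshold=-60.0)
        assert not window.nonempty
        assert 11.5 not in window

    def test_missing_consumer_is_a_usage_error(self, scenarios, table):
        with pytest.raises(UsageError, match="consumer"):
            h2_window(scenarios["M-SAO+BES"], table)

    def test_membership_property_on_random_media(self, table, msao):
        """Inside a nonempty window both partners clear the threshold;
        outside, at least one does not."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(200):
            conds = msao.conditions.replace(
                pH=rng.uniform(8.5, 10.5),
                solutes={
                    "acetate": rng.uniform(0.001, 0.1),
                    "HCO3-": rng.uniform(0.1, 1.0),
                },
                h2_frame=rng.choice(["pure_water", "soda_corrected"]),
            )
            conds.gases["CH4"] = rng.uniform(1000.0, 80000.0)
            threshold = rng.uniform(-12.0, 2.0)
            scenario = Scenario(
                label="random",
                producer_reaction=ACETATE_OXIDATION,
                consumer_reaction=HYDROGENOTROPHIC_METHANOGENESIS,
                conditions=conds,
            )
            window = h2_window(scenario, table, threshold=threshold)

            def both_dg(p):
                c = conds.replace()
                c.gases["H2"] = p
                acts = build_activity_set(c, table)
                return (
                    actual_delta_g(ACETATE_OXIDATION, table, acts, c.temperature),
                    actual_delta_g(
                        HYDROGENOTROPHIC_METHANOGENESIS, table, acts, c.temperature
                    ),
                )

            if window.nonempty:
                inside = math.sqrt(window.p_min * window.p_max)
                assert all(dg < threshold for dg in both_dg(inside))
                checked += 1
            for outside in (window.p_min * 0.5, window.p_max * 2.0):
                assert any(dg >= threshold - 1e-9 for dg in both_dg(outside))
        assert checked > 20  # the sampling must actually exercise both branches


class TestEnergyPartition:
    @staticmethod
    def result_from(dg_producer, dg_consumer):
        records = [
            ReactionEnergy("p", "producer", "", dg_producer, dg_producer),
            ReactionEnergy("c", "consumer", "", dg_consumer, dg_consumer),
            ReactionEnergy(
                "t", "total", "", dg_producer + dg_consumer, dg_producer + dg_consumer
            ),
        ]
        return ScenarioResult("synthetic", records, None, None)

    def test_equal_partners_split_evenly(self):
        shares = energy_partition(self.result_from(-10.0, -10.0), "pure_water")
        assert shares == {"producer_share": 0.5, "consumer_share": 0.5}

    def test_published_msao_numbers_give_near_equal_shares(self):
        # the reported soda-frame energies: -13.7 and -15.3 over -29
        shares = energy_partition(self.result_from(-13.7, -15.3), "soda_corrected")
        assert shares["producer_share"] == pytest.approx(0.47, abs=0.01)
        assert shares["consumer_share"] == pytest.approx(0.53, abs=0.01)

    def test_shares_sum_to_one(self, scenarios, table):
        result = evaluate_scenario(scenarios["S-SAO"], table)
        shares = energy_partition(result, "soda_corrected")
        assert shares["producer_share"] + shares["consumer_share"] == 1.0

    def test_endergonic_total_is_rejected(self):
        with pytest.raises(UndefinedPartitionError):
            energy_partition(self.result_from(+10.0, +5.0), "pure_water")


class TestScenarioFiles:
    def test_load_evaluate_round_trip(self, tmp_path, msao, table):
        text = msao.conditions.to_toml() + (
            '\n[scenario]\nlabel = "M-SAO"\n'
            "\n[reactions]\n"
            'producer = "acetate_oxidation"\n'
            'consumer = "hydrogenotrophic_methanogenesis"\n'
            'total = "msao_total"\n'
        )
        path = tmp_path / "msao.toml"
        path.write_text(text, encoding="utf-8")
        scenario = load_scenario(path)
        result = evaluate_scenario(scenario, table)
        reference = evaluate_scenario(msao, table)
        for role in ("producer", "consumer", "total"):
            assert result.delta_g(role, "pure_water") == pytest.approx(
                reference.delta_g(role, "pure_water"), abs=1e-12
            )

    def test_inline_reaction_definition(self, tmp_path, msao, table):
        text = msao.conditions.to_toml() + (
            "\n[reactions]\n"
            'producer = "ox"\n'
            "\n[reactions.define.ox]\n"
            '"acetate" = -1\n"H2O" = -4\n"HCO3-" = 2\n"H2" = 4\n"H+" = 1\n'
        )
        path = tmp_path / "inline.toml"
        path.write_text(text, encoding="utf-8")
        scenario = load_scenario(path)
        assert scenario.producer_reaction.stoichiometry == ACETATE_OXIDATION.stoichiometry

    def test_missing_producer_rejected(self, tmp_path, msao):
        path = tmp_path / "bad.toml"
        path.write_text(msao.conditions.to_toml(), encoding="utf-8")
        with pytest.raises(ConfigError, match="producer"):
            load_scenario(path)
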