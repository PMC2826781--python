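import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea import (
    ARM_FAC,
    ARM_TAC,
    ArmTrialSummary,
    ConfigValidationError,
    HealthState,
    ModelConfig,
    UtilityInputs,
    annual_followup_cost,
    arm_utilities,
    average_ae_cost,
    load_model_config,
    save_model_config,
    secondary_prophylaxis_cost,
    treatment_cost,
)

# hand-checked arithmetic, frozen from direct evaluation of the inputs
TAC_AE_EXPECTED = 0.247 * 2367.23 + 0.071 * 3151.18 + 0.038 * 2760.30 + 0.039 * 2367.30
TAC_PROPHYLAXIS_EXPECTED = 1239.77 * (217 / 744) * (799 / 217)


class TestLoadConfig:
    def test_bundled_fixture_arm_sizes(self, base_config):
        assert base_config.arms[ARM_TAC].n_treated == 744
        assert base_config.arms[ARM_FAC].n_treated == 736

    def test_ae_rate_out_of_bounds_names_field(self, config_dict):
        config_dict["arms"]["TAC"]["ae_rates"]["febrile_neutropenia"] = 1.2
        with pytest.raises(ConfigValidationError, match="febrile_neutropenia"):
            ModelConfig.from_dict(config_dict)

    def test_negative_cost_names_field(self, config_dict):
        config_dict["costs"]["lab_tests"] = -1.0
        with pytest.raises(ConfigValidationError, match="lab_tests"):
            ModelConfig.from_dict(config_dict)

    def test_missing_her2_fraction_gets_default(self, config_dict):
        del config_dict["costs"]["her2_positive_fraction"]
        cfg = ModelConfig.from_dict(config_dict)
        assert cfg.costs.her2_positive_fraction == 0.20

    def test_counts_cannot_exceed_n_treated(self):
        with pytest.raises(ConfigValidationError, match="n_recurrences"):
            ArmTrialSummary("X", 100, 101, 0, {})

    def test_round_trip(self, base_config, tmp_path):
        path = tmp_path / "cfg.yaml"
        save_model_config(base_config, path)
        reloaded = load_model_config(path)
        assert reloaded.to_dict() == base_config.to_dict()

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model_config(tmp_path / "nope.yaml")


class TestTreatmentCost:
    def test_tac_total(self, base_config):
        assert treatment_cost(base_config.costs, ARM_TAC) == pytest.approx(10546.08)

    def test_fac_total(self, base_config):
        assert treatment_cost(base_config.costs, ARM_FAC) == pytest.approx(1215.18)

    def test_zero_components(self, config_dict):
        config_dict["costs"]["drug_acquisition"]["TAC"] = 0.0
        config_dict["costs"]["chemo_administration"]["TAC"] = 0.0
        cfg = ModelConfig.from_dict(config_dict)
        assert treatment_cost(cfg.costs, ARM_TAC) == 0.0

    def test_unknown_arm(self, base_config):
        with pytest.raises(KeyError):
            treatment_cost(base_config.costs, "XYZ")


class TestAverageAECost:
    def test_tac_hand_sum(self, base_config):
        arm = base_config.arms[ARM_TAC]
        total = average_ae_cost(arm, base_config.costs)
        assert total - base_config.costs.antibiotic_prophylaxis == pytest.approx(
            TAC_AE_EXPECTED
        )
        assert round(total - 314.10, 2) == 1005.66

    def test_all_rates_zero_leaves_antibiotics(self, base_config):
        arm = ArmTrialSummary("TAC", 10, 0, 0, {k: 0.0 for k in base_config.costs.ae_unit_costs})
        assert average_ae_cost(arm, base_config.costs) == pytest.approx(314.10)

    def test_antibiotic_component(self, base_config):
        assert base_config.costs.antibiotic_prophylaxis == pytest.approx(314.10)

    def test_rate_without_cost_raises(self, base_config):
        arm = ArmTrialSummary("TAC", 10, 0, 0, {"mystery_event": 0.1})
        with pytest.raises(ConfigValidationError, match="mystery_event"):
            average_ae_cost(arm, base_config.costs)

    @given(rate=st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None)
    def test_linear_in_each_rate(self, base_config, rate):
        costs = base_config.costs
        arm0 = ArmTrialSummary("TAC", 10, 0, 0, {"diarrhea": 0.0})
        arm1 = ArmTrialSummary("TAC", 10, 0, 0, {"diarrhea": rate})
        delta = average_ae_cost(arm1, costs) - average_ae_cost(arm0, costs)
        assert delta == pytest.approx(rate * costs.ae_unit_costs["diarrhea"])


class TestSecondaryProphylaxis:
    def test_tac_value(self, base_config):
        arm = base_config.arms[ARM_TAC]
        value = secondary_prophylaxis_cost(arm, base_config.costs)
        assert value == pytest.approx(TAC_PROPHYLAXIS_EXPECTED)
        assert round(value, 2) == 1331.42

    def test_fac_value_direct_arithmetic(self, base_config):
        arm = base_config.arms[ARM_FAC]
        value = secondary_prophylaxis_cost(arm, base_config.costs)
        assert value == pytest.approx(1239.77 * 126 / 736)

    def test_no_prophylaxis_is_zero(self, base_config):
        arm = ArmTrialSummary("TAC", 100, 0, 0, {}, prophylaxis_patients=0)
        assert secondary_prophylaxis_cost(arm, base_config.costs) == 0.0

    @given(
        n=st.integers(1, 1000),
        patients=st.integers(1, 1000),
        cycles=st.integers(0, 5000),
    )
    @settings(max_examples=50, deadline=None)
    def test_three_factor_form_cancels(self, base_config, n, patients, cycles):
        patients = min(patients, n)
        arm = ArmTrialSummary(
            "TAC", n, 0, 0, {}, prophylaxis_patients=patients, prophylaxis_cycles=cycles
        )
        value = secondary_prophylaxis_cost(arm, base_config.costs)
        assert value == pytest.approx(base_config.costs.gcsf_cost_per_event * cycles / n)

    def test_table_ratios(self, base_config):
        tac = base_config.arms[ARM_TAC]
        assert round(tac.mean_prophylaxis_cycles_per_recipient, 1) == 3.7
        assert round(tac.prophylaxis_administrations_per_patient, 2) == 1.07


class TestArmUtilities:
    def test_tac_treatment_phase(self, base_config):
        u = arm_utilities(base_config.utilities, ARM_TAC)
        assert u["treatment"] == pytest.approx(0.7163)

    def test_fac_treatment_phase(self, base_config):
        u = arm_utilities(base_config.utilities, ARM_FAC)
        assert u["treatment"] == pytest.approx(0.72)

    def test_distant_midpoint(self, base_config):
        u = arm_utilities(base_config.utilities, ARM_TAC)
        assert u[HealthState.DISTANT] == pytest.approx(0.57)

    def test_equal_disutilities(self, base_config):
        util = UtilityInputs(
            u_no_recurrence=0.96,
            u_locoregional=0.816,
            u_distant_range=(0.49, 0.65),
            u_adjuvant_fac=0.72,
            disutility_tac=0.0035,
            disutility_fac=0.0035,
        )
        assert arm_utilities(util, ARM_TAC)["treatment"] == pytest.approx(0.72)
        assert arm_utilities(util, ARM_FAC)["treatment"] == pytest.approx(0.72)

    def test_state_utilities_same_for_both_arms(self, base_config):
        u_tac = arm_utilities(base_config.utilities, ARM_TAC)
        u_fac = arm_utilities(base_config.utilities, ARM_FAC)
        for state in HealthState:
            assert u_tac[state] == u_fac[state]

    @given(
        u_adj=st.floats(0.0, 1.0),
        d_fac=st.floats(0.0, 0.5),
        d_extra=st.floats(0.0, 0.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_weights_stay_in_unit_interval(self, u_adj, d_fac, d_extra):
        d_tac = min(d_fac + d_extra, 1.0)
        util = UtilityInputs(
            u_no_recurrence=0.96,
            u_locoregional=0.816,
            u_distant_range=(0.49, 0.65),
            u_adjuvant_fac=u_adj,
            disutility_tac=d_tac,
            disutility_fac=d_fac,
        )
        for arm in (ARM_TAC, ARM_FAC):
            for value in arm_utilities(util, arm).values():
                assert 0.0 <= value <= 1.0

    def test_disutility_ordering_enforced(self):
        with pytest.raises(ConfigValidationError, match="disutility_tac"):
            UtilityInputs(0.96, 0.816, (0.49, 0.65), 0.72, 0.001, 0.0035)


class TestFollowupCosts:
    def test_locoregional_six_year_average(self, base_config):
        value = annual_followup_cost(HealthState.LOCOREGIONAL, 1, base_config.costs)
        assert round(value, 2) == 805.89

    def test_no_recurrence_schedule(self, base_config):
        assert annual_followup_cost(
            HealthState.NO_RECURRENCE, 2, base_config.costs
        ) == pytest.approx(582.82)
        assert annual_followup_cost(
            HealthState.NO_RECURRENCE, 5, base_config.costs
        ) == pytest.approx(356.93)

    def test_distant_flat(self, base_config):
        for year in (1, 3, 10):
            assert annual_followup_cost(
                HealthState.DISTANT, year, base_config.costs
            ) == pytest.approx(1729.10)

    def test_dead_state_rejected(self, base_config):
        with pytest.raises(ValueError):
            annual_followup_cost(HealthState.DEAD, 1, base_config.costs)


class TestSupportiveCare:
    def test_arm_totals_and_average(self, base_config):
        costs = base_config.costs
        assert costs.supportive_care_total(ARM_TAC) == pytest.approx(79.10)
        assert costs.supportive_care_total(ARM_FAC) == pytest.approx(51.06)
        assert costs.supportive_care_average() == pytest.approx(65.08)


class TestTrialProportions:
    def test_printed_percentages(self, base_config):
        tac = base_config.arms[ARM_TAC]
        fac = base_config.arms[ARM_FAC]
        assert round(100 * tac.recurrence_proportion, 1) == 19.0
        assert round(100 * tac.death_proportion, 1) == 21.8
        assert round(100 * fac.recurrence_proportion, 1) == 26.5
        assert round(100 * fac.death_proportion, 1) == 33.4

    def test_line4_cost_equals_line3(self, base_config):
        costs = base_config.costs
        assert costs._line_cost_range(ARM_TAC, 4) == costs._line_cost_range(ARM_TAC, 3)
        assert costs._line_cost_range(ARM_TAC, 5) == costs._line_cost_range(ARM_TAC, 3)
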