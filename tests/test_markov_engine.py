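import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markovcea import (
    ARM_TAC,
    EconomicSettings,
    HealthState,
    TransitionModel,
    discount_factor,
    run_arm,
    run_cohort,
)
from markovcea.parameters import ModelConfig

from .oracles import enumerate_expected_alive_years, enumerate_occupancy

UNIT_UTILITIES = {
    HealthState.NO_RECURRENCE: 1.0,
    HealthState.LOCOREGIONAL: 1.0,
    HealthState.DISTANT: 1.0,
    HealthState.DEAD: 0.0,
    "treatment": 1.0,
}


def _model(p_relapse=0.0, pmr=0.5, p_met=0.0, pd_n=0.0, pd_l=0.0, pd_d=0.0):
    return TransitionModel(
        arm_label="toy",
        p_relapse=p_relapse,
        percent_met_relapse=pmr,
        p_met_relapse=p_met,
        p_death_from={
            HealthState.NO_RECURRENCE: pd_n,
            HealthState.LOCOREGIONAL: pd_l,
            HealthState.DISTANT: pd_d,
        },
    )


class TestDiscountFactor:
    def test_cycle_zero(self, base_config):
        assert discount_factor(0, base_config.settings) == 1.0

    def test_one_year_at_five_percent(self, base_config):
        assert discount_factor(2, base_config.settings) == pytest.approx(1 / 1.05)

    def test_zero_rate(self):
        settings_ = EconomicSettings(discount_rate_annual=0.0)
        for c in range(20):
            assert discount_factor(c, settings_) == 1.0

    def test_negative_cycle_rejected(self, base_config):
        with pytest.raises(ValueError):
            discount_factor(-1, base_config.settings)


class TestRunCohort:
    def test_static_cohort_accrues_discounted_annuity(self, base_config):
        # everyone stays in No Recurrence; LE 0 -> LYs are the 10-cycle
        # discounted annuity of half-years (closed-form oracle)
        settings_ = EconomicSettings(remaining_life_expectancy={})
        trace = run_cohort(
            _model(), base_config.costs, UNIT_UTILITIES, settings_, ARM_TAC
        )
        expected = sum(0.5 * 1.05 ** (-0.5 * c) for c in range(10))
        assert trace.total_lys == pytest.approx(expected, abs=1e-12)
        assert trace.occupancy[-1, HealthState.NO_RECURRENCE] == 1.0

    def test_unit_utilities_make_qalys_equal_lys(self, base_config):
        trace = run_cohort(
            _model(p_relapse=0.05, p_met=0.1, pd_n=0.01, pd_l=0.02, pd_d=0.3),
            base_config.costs,
            UNIT_UTILITIES,
            base_config.settings,
            ARM_TAC,
        )
        assert trace.total_qalys == pytest.approx(trace.total_lys, abs=1e-12)

    def test_half_death_toy_matches_path_enumeration(self, base_config):
        # p(death) = 0.5 per cycle from every alive state, no discounting:
        # E[LYs] = 0.5 * (1 + 0.5 + 0.25)
        settings_ = EconomicSettings(
            discount_rate_annual=0.0, trial_horizon_cycles=3, remaining_life_expectancy={}
        )
        model = _model(pd_n=0.5, pd_l=0.5, pd_d=0.5)
        trace = run_cohort(model, base_config.costs, UNIT_UTILITIES, settings_, ARM_TAC)
        assert trace.total_lys == pytest.approx(0.5 * (1 + 0.5 + 0.25), abs=1e-12)
        oracle = enumerate_expected_alive_years(model.matrix, 3, 0.5)
        assert trace.total_lys == pytest.approx(oracle, abs=1e-12)

    def test_trial_phase_matches_enumeration_on_four_cycles(self, base_config):
        settings_ = EconomicSettings(
            trial_horizon_cycles=4, remaining_life_expectancy={}
        )
        model = _model(p_relapse=0.2, pmr=0.3, p_met=0.15, pd_n=0.05, pd_l=0.1, pd_d=0.25)
        trace = run_cohort(model, base_config.costs, UNIT_UTILITIES, settings_, ARM_TAC)
        occ_oracle = enumerate_occupancy(model.matrix, 4)
        np.testing.assert_allclose(trace.occupancy, occ_oracle, atol=1e-12)
        lys_oracle = sum(
            0.5 * occ_oracle[c, :3].sum() * discount_factor(c, settings_)
            for c in range(4)
        )
        assert trace.total_lys == pytest.approx(lys_oracle, abs=1e-12)

    def test_missing_utility_state_raises(self, base_config):
        utilities = dict(UNIT_UTILITIES)
        del utilities[HealthState.DISTANT]
        with pytest.raises(KeyError):
            run_cohort(
                _model(), base_config.costs, utilities, base_config.settings, ARM_TAC
            )

    def test_time_zero_cost_is_undiscounted_and_additive(self, base_config):
        t0 = run_cohort(
            _model(), base_config.costs, UNIT_UTILITIES, base_config.settings, ARM_TAC
        )
        t1 = run_cohort(
            _model(),
            base_config.costs,
            UNIT_UTILITIES,
            base_config.settings,
            ARM_TAC,
            time_zero_cost=1234.5,
        )
        assert t1.total_cost - t0.total_cost == pytest.approx(1234.5, abs=1e-9)


class TestEngineProperties:
    def test_qalys_never_exceed_lys_in_base_case(self, base_run):
        for trace in base_run.traces.values():
            assert trace.total_qalys <= trace.total_lys

    @pytest.mark.parametrize("rate_pair", [(0.0, 0.03), (0.03, 0.05), (0.05, 0.10)])
    def test_totals_nonincreasing_in_discount_rate(self, base_config, rate_pair):
        lo, hi = rate_pair

        def totals(rate):
            raw = base_config.to_dict()
            raw["settings"]["discount_rate_annual"] = rate
            cfg = ModelConfig.from_dict(raw)
            trace = run_arm(cfg, ARM_TAC)
            return trace.total_cost, trace.total_lys, trace.total_qalys

        for a, b in zip(totals(hi), totals(lo)):
            assert a <= b + 1e-9

    def test_doubling_unit_costs_doubles_total_cost(self, base_config):
        raw = base_config.to_dict()
        c = raw["costs"]
        for key in (
            "gcsf_cost_per_event",
            "antibiotic_prophylaxis",
            "diagnostics_at_diagnosis",
            "lab_tests",
            "followup_metastatic_annual",
        ):
            c[key] = c[key] * 2
        for mapping in ("drug_acquisition", "chemo_administration", "ae_unit_costs"):
            c[mapping] = {k: v * 2 for k, v in c[mapping].items()}
        c["followup_no_recurrence"] = {
            k: v * 2 for k, v in c["followup_no_recurrence"].items()
        }
        c["followup_locoregional_year_costs"] = [
            v * 2 for v in c["followup_locoregional_year_costs"]
        ]
        c["supportive_care_components"] = {
            arm: {comp: [v[0] * 2, v[1]] for comp, v in comps.items()}
            for arm, comps in c["supportive_care_components"].items()
        }
        c["met_chemo_line_costs"] = {
            arm: {line: [v[0] * 2, v[1] * 2] for line, v in lines.items()}
            for arm, lines in c["met_chemo_line_costs"].items()
        }
        doubled = ModelConfig.from_dict(raw)
        base_trace = run_arm(base_config, ARM_TAC)
        doubled_trace = run_arm(doubled, ARM_TAC)
        assert doubled_trace.total_cost == pytest.approx(2 * base_trace.total_cost, rel=1e-12)
        assert doubled_trace.total_lys == pytest.approx(base_trace.total_lys, abs=1e-15)

    @given(
        p_relapse=st.floats(0.0, 0.3),
        pd_n=st.floats(0.0, 0.3),
        pd_d=st.floats(0.0, 0.9),
    )
    @settings(max_examples=25, deadline=None)
    def test_occupancy_invariants(self, base_config, p_relapse, pd_n, pd_d):
        model = _model(p_relapse=p_relapse, pd_n=pd_n, pd_d=pd_d, p_met=0.1, pd_l=0.1)
        trace = run_cohort(
            model, base_config.costs, UNIT_UTILITIES, base_config.settings, ARM_TAC
        )
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        dead = trace.occupancy[:, HealthState.DEAD]
        assert (np.diff(dead) >= -1e-12).all()


class TestTraceExport:
    def test_frame_has_cycle_rows(self, base_run):
        frame = base_run.traces[ARM_TAC].to_frame()
        assert len(frame) == 11
        assert list(frame["cycle"]) == list(range(11))
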