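"""Glue between parameters, transitions and the engine: per-arm runs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .markov_engine import CohortTrace, run_cohort
from .outcomes import CEResult, compute_ce_result
from .parameters import (
    ARM_FAC,
    ARM_TAC,
    ArmTrialSummary,
    CostInputs,
    ModelConfig,
    arm_utilities,
    average_ae_cost,
    secondary_prophylaxis_cost,
    treatment_cost,
)
from .transitions import TransitionModel, calibrate_arm_model


def time_zero_cost(
    arm: ArmTrialSummary,
    costs: CostInputs,
    *,
    ae_rates: Mapping[str, float] | None = None,
    include_secondary_prophylaxis: bool = True,
    extra: float = 0.0,
) -> float:
    """One-off undiscounted cost block applied at model start for one arm."""
    total = treatment_cost(costs, arm.arm_label)
    total += average_ae_cost(arm, costs, ae_rates=ae_rates)
    if include_secondary_prophylaxis:
        total += secondary_prophylaxis_cost(arm, costs)
    total += costs.supportive_care_average()
    total += costs.diagnostics_at_diagnosis
    total += costs.lab_tests
    total += extra
    return total


def build_arm_model(config: ModelConfig, arm_label: str) -> TransitionModel:
    """Calibrated transition model for one configured arm."""
    return calibrate_arm_model(
        config.arms[arm_label],
        config.transition,
        config.settings.trial_horizon_cycles,
    )


def run_arm(
    config: ModelConfig,
    arm_label: str,
    *,
    ae_rates: Mapping[str, float] | None = None,
    include_secondary_prophylaxis: bool = True,
    extra_time_zero: float = 0.0,
    model: TransitionModel | None = None,
) -> CohortTrace:
    """Calibrate (unless given) and simulate one arm of the configuration."""
    arm = config.arms[arm_label]
    if model is None:
        model = build_arm_model(config, arm_label)
    utilities = arm_utilities(config.utilities, arm_label)
    t0 = time_zero_cost(
        arm,
        config.costs,
        ae_rates=ae_rates,
        include_secondary_prophylaxis=include_secondary_prophylaxis,
        extra=extra_time_zero,
    )
    return run_cohort(
        model,
        config.costs,
        utilities,
        config.settings,
        arm_label,
        time_zero_cost=t0,
    )


@dataclass
class BaseCaseRun:
    """Traces, calibrated models and the incremental result of one analysis."""

    traces: dict[str, CohortTrace]
    models: dict[str, TransitionModel]
    result: CEResult


def run_base_case(
    config: ModelConfig,
    intervention: str = ARM_TAC,
    comparator: str = ARM_FAC,
) -> BaseCaseRun:
    """Run both arms of a configuration and compare them."""
    models = {label: build_arm_model(config, label) for label in (intervention, comparator)}
    traces = {
        label: run_arm(config, label, model=models[label])
        for label in (intervention, comparator)
    }
    result = compute_ce_result(traces[intervention], traces[comparator])
    return BaseCaseRun(traces=traces, models=models, result=result)
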