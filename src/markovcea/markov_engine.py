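"""Discounted cohort simulation over the two-phase lifetime horizon.

Phase 1 iterates the transition matrix over the trial horizon (ten 6-month
cycles), accumulating discounted costs, life-years and QALYs with state
membership evaluated at cycle start (no half-cycle correction).  Phase 2
assigns each surviving patient a state-specific remaining life expectancy,
discounted as a continuous annuity anchored at the end of the trial horizon,
with state-appropriate follow-up costs and utility weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .parameters import CostInputs, EconomicSettings, annual_followup_cost
from .states import ALIVE_STATES, N_STATES, STATE_LABELS, HealthState
from .transitions import TransitionModel


def discount_factor(cycle_index: int, settings: EconomicSettings) -> float:
    """Discount factor at the start of ``cycle_index`` (cycle 0 -> 1.0)."""
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    years = cycle_index * settings.cycle_length
    return (1.0 + settings.discount_rate_annual) ** (-years)


def _continuous_annuity(years: float, annual_rate: float) -> float:
    """Present value of 1/year paid continuously for ``years`` years."""
    if years <= 0:
        return 0.0
    if annual_rate == 0:
        return years
    delta = math.log1p(annual_rate)
    return (1.0 - math.exp(-delta * years)) / delta


@dataclass
class CohortTrace:
    """Per-cycle state occupancy with discounted accumulators for one arm.

    Row ``c`` of ``occupancy`` is the cohort distribution at the start of
    cycle ``c`` (row 0 = everyone in No Recurrence).  ``cycle_costs[0]``
    holds the undiscounted time-0 cost block.  The ``extrap_*`` fields hold
    the post-trial extrapolation phase totals.
    """

    arm_label: str
    occupancy: np.ndarray
    cycle_costs: np.ndarray
    cycle_lys: np.ndarray
    cycle_qalys: np.ndarray
    cycle_lys_undiscounted: np.ndarray
    extrap_cost: float = 0.0
    extrap_lys: float = 0.0
    extrap_qalys: float = 0.0
    extrap_lys_undiscounted: float = 0.0

    def __post_init__(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise AssertionError("occupancy rows must sum to 1")
        dead = self.occupancy[:, HealthState.DEAD]
        if np.any(np.diff(dead) < -1e-12):
            raise AssertionError("Dead occupancy must be nondecreasing")

    @property
    def total_cost(self) -> float:
        return float(self.cycle_costs.sum() + self.extrap_cost)

    @property
    def total_lys(self) -> float:
        return float(self.cycle_lys.sum() + self.extrap_lys)

    @property
    def total_qalys(self) -> float:
        return float(self.cycle_qalys.sum() + self.extrap_qalys)

    @property
    def life_expectancy_undiscounted(self) -> float:
        """Undiscounted per-patient life expectancy over both phases."""
        return float(self.cycle_lys_undiscounted.sum() + self.extrap_lys_undiscounted)

    def to_frame(self) -> pd.DataFrame:
        cols = {STATE_LABELS[HealthState(i)]: self.occupancy[:, i] for i in range(N_STATES)}
        cols["discounted_cost"] = self.cycle_costs
        cols["discounted_lys"] = self.cycle_lys
        cols["discounted_qalys"] = self.cycle_qalys
        frame = pd.DataFrame(cols)
        frame.insert(0, "cycle", np.arange(len(frame)))
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def run_cohort(
    model: TransitionModel,
    costs: CostInputs,
    utilities: Mapping[Any, float],
    settings: EconomicSettings,
    arm: str,
    *,
    time_zero_cost: float = 0.0,
    met_entry_cost: float | None = None,
) -> CohortTrace:
    """Simulate one arm's cohort and accumulate discounted outcomes.

    Parameters
    ----------
    utilities:
        Map of :class:`HealthState` -> utility, plus a ``"treatment"`` key
        giving the weight applied to No Recurrence occupancy during the
        treatment phase (first ``settings.treatment_phase_cycles`` cycles).
    time_zero_cost:
        One-off undiscounted cost block applied at model start (treatment,
        adverse events, prophylaxis, supportive care, diagnostics, labs).
    met_entry_cost:
        Expected lifetime metastatic chemotherapy cost charged on each
        transition into Distant; defaults to the configured expectation.
    """
    for state in HealthState:
        if state not in utilities:
            raise KeyError(f"utility map missing state {state.key!r}")
    if met_entry_cost is None:
        met_entry_cost = costs.expected_metastatic_cost(arm)

    n_cycles = settings.trial_horizon_cycles
    half_year = settings.cycle_length
    m = model.matrix

    occupancy = np.zeros((n_cycles + 1, N_STATES))
    occupancy[0, HealthState.NO_RECURRENCE] = 1.0
    cycle_costs = np.zeros(n_cycles + 1)
    cycle_lys = np.zeros(n_cycles + 1)
    cycle_qalys = np.zeros(n_cycles + 1)
    cycle_lys_undisc = np.zeros(n_cycles + 1)
    cycle_costs[0] = time_zero_cost

    for c in range(1, n_cycles + 1):
        prev = occupancy[c - 1]
        df_start = discount_factor(c - 1, settings)
        df_end = discount_factor(c, settings)

        # outcomes accrue on state membership at cycle start
        alive = prev[list(ALIVE_STATES)].sum()
        cycle_lys[c] = half_year * alive * df_start
        cycle_lys_undisc[c] = half_year * alive

        u_no_rec = (
            utilities["treatment"]
            if c <= settings.treatment_phase_cycles
            else utilities[HealthState.NO_RECURRENCE]
        )
        qaly = (
            prev[HealthState.NO_RECURRENCE] * u_no_rec
            + prev[HealthState.LOCOREGIONAL] * utilities[HealthState.LOCOREGIONAL]
            + prev[HealthState.DISTANT] * utilities[HealthState.DISTANT]
        )
        cycle_qalys[c] = half_year * qaly * df_start

        # follow-up costs: half the annual cost per 6-month cycle; the
        # No Recurrence schedule advances one year every two cycles
        year = math.ceil(c / 2)
        followup = sum(
            prev[s] * annual_followup_cost(s, year, costs) * half_year
            for s in ALIVE_STATES
        )
        cycle_costs[c] += followup * df_start

        # metastatic chemotherapy charged on the flow into Distant this cycle
        inflow_distant = (
            prev[HealthState.NO_RECURRENCE] * m[HealthState.NO_RECURRENCE, HealthState.DISTANT]
            + prev[HealthState.LOCOREGIONAL] * m[HealthState.LOCOREGIONAL, HealthState.DISTANT]
        )
        cycle_costs[c] += inflow_distant * met_entry_cost * df_end

        occupancy[c] = prev @ m

    trace = CohortTrace(
        arm_label=arm,
        occupancy=occupancy,
        cycle_costs=cycle_costs,
        cycle_lys=cycle_lys,
        cycle_qalys=cycle_qalys,
        cycle_lys_undiscounted=cycle_lys_undisc,
    )

    # extrapolation phase: survivors receive a state-specific remaining life
    # expectancy, discounted as a continuous annuity anchored at trial end
    df_end_of_trial = discount_factor(n_cycles, settings)
    final = occupancy[n_cycles]
    extrap_years_done = n_cycles * half_year
    for s in ALIVE_STATES:
        share = final[s]
        if share == 0:
            continue
        life_years = settings.life_expectancy(s)
        annuity = _continuous_annuity(life_years, settings.discount_rate_annual)
        year_after_trial = int(extrap_years_done) + 1
        annual_cost = annual_followup_cost(s, year_after_trial, costs)
        trace.extrap_lys += share * annuity * df_end_of_trial
        trace.extrap_qalys += share * annuity * df_end_of_trial * utilities[s]
        trace.extrap_cost += share * annuity * df_end_of_trial * annual_cost
        trace.extrap_lys_undiscounted += share * life_years
    return trace
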