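"""Economic endpoints: per-arm totals and incremental ratios."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .markov_engine import CohortTrace

DOMINANCE_NONE = "none"
DOMINANCE_DOMINANT = "dominant"
DOMINANCE_DOMINATED = "dominated"


@dataclass
class ArmEconomics:
    """Totals for one arm (discounted unless stated otherwise)."""

    arm_label: str
    total_cost: float
    total_lys: float
    total_qalys: float
    life_expectancy_undiscounted: float

    @classmethod
    def from_trace(cls, trace: CohortTrace) -> "ArmEconomics":
        return cls(
            arm_label=trace.arm_label,
            total_cost=trace.total_cost,
            total_lys=trace.total_lys,
            total_qalys=trace.total_qalys,
            life_expectancy_undiscounted=trace.life_expectancy_undiscounted,
        )


@dataclass
class CEResult:
    """Incremental cost-effectiveness comparison of two arms.

    Ratios are ``None`` when their denominator is zero; negative or
    degenerate incrementals set ``dominance_flag`` instead of producing a
    signed (uninterpretable) ratio.
    """

    intervention: ArmEconomics
    comparator: ArmEconomics
    delta_cost: float
    delta_lys: float
    delta_qalys: float
    icer: float | None
    icur: float | None
    dominance_flag: str
    delta_life_expectancy_undiscounted: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm in (self.intervention, self.comparator):
            rows.append(
                {
                    "arm": arm.arm_label,
                    "total_cost": arm.total_cost,
                    "total_lys": arm.total_lys,
                    "total_qalys": arm.total_qalys,
                    "life_expectancy_undiscounted": arm.life_expectancy_undiscounted,
                }
            )
        frame = pd.DataFrame(rows)
        frame["delta_cost"] = [self.delta_cost, None]
        frame["delta_lys"] = [self.delta_lys, None]
        frame["delta_qalys"] = [self.delta_qalys, None]
        frame["icer"] = [self.icer, None]
        frame["icur"] = [self.icur, None]
        frame["dominance"] = [self.dominance_flag, None]
        return frame

    def report_block(self) -> str:
        """Human-readable summary with fixed 2-decimal currency formatting."""
        def money(v: float | None) -> str:
            return "undefined" if v is None else f"{v:,.2f}"

        lines = [
            f"{'arm':<14}{'cost (CAD)':>16}{'LYs':>12}{'QALYs':>12}",
        ]
        for arm in (self.intervention, self.comparator):
            lines.append(
                f"{arm.arm_label:<14}{arm.total_cost:>16,.2f}"
                f"{arm.total_lys:>12.4f}{arm.total_qalys:>12.4f}"
            )
        lines += [
            f"incremental cost: {money(self.delta_cost)}",
            f"incremental LYs: {self.delta_lys:.4f}",
            f"incremental QALYs: {self.delta_qalys:.4f}",
            f"ICER (CAD/LY): {money(self.icer)}",
            f"ICUR (CAD/QALY): {money(self.icur)}",
            f"dominance: {self.dominance_flag}",
        ]
        return "\n".join(lines)

    def write_summary(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def compute_ce_result(
    trace_intervention: CohortTrace, trace_comparator: CohortTrace
) -> CEResult:
    """Aggregate two traces into incremental ratios (intervention - comparator)."""
    a = ArmEconomics.from_trace(trace_intervention)
    b = ArmEconomics.from_trace(trace_comparator)
    delta_cost = a.total_cost - b.total_cost
    delta_lys = a.total_lys - b.total_lys
    delta_qalys = a.total_qalys - b.total_qalys

    icer = delta_cost / delta_lys if delta_lys != 0 else None
    icur = delta_cost / delta_qalys if delta_qalys != 0 else None

    flag = DOMINANCE_NONE
    if delta_cost <= 0 and delta_lys >= 0 and delta_qalys >= 0:
        flag = DOMINANCE_DOMINANT
    elif delta_cost >= 0 and delta_lys <= 0 and delta_qalys <= 0:
        flag = DOMINANCE_DOMINATED
    if flag is not DOMINANCE_NONE:
        # a dominated/dominant comparison has no meaningful signed ratio
        icer = None
        icur = None

    return CEResult(
        intervention=a,
        comparator=b,
        delta_cost=delta_cost,
        delta_lys=delta_lys,
        delta_qalys=delta_qalys,
        icer=icer,
        icur=icur,
        dominance_flag=flag,
        delta_life_expectancy_undiscounted=(
            a.life_expectancy_undiscounted - b.life_expectancy_undiscounted
        ),
    )
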