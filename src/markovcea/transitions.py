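"""Derivation of 6-month transition probabilities from 5-year outcome counts.

Five-year cumulative proportions are converted to constant per-cycle
probabilities with ``1 - exp(-rate * time)``, treating the cumulative
proportion itself as the rate.  Note this differs from the actuarial
``-ln(1 - P)`` conversion; the simpler convention is implemented on purpose
and documented here (its worked example: a 0.30 five-year proportion over
ten cycles gives a 0.029 per-cycle probability).

Unprinted structural parameters - the locoregional/distant split of
relapses, the locoregional-to-distant progression probability and the
allocation of deaths across origin states - are configuration inputs
(:class:`~markovcea.parameters.TransitionSettings`).  A bounded scalar
calibration (:func:`calibrate_arm_model`) rescales the relapse and death
hazards so that the simulated 5-year cumulative outcomes match the observed
arm-level proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .parameters import ArmTrialSummary, TransitionSettings
from .states import ALIVE_STATES, N_STATES, STATE_LABELS, HealthState


class CalibrationError(RuntimeError):
    """The bounded scalar search could not match the target outcome."""


def rate_to_probability(cumulative_rate: float, time_fraction: float) -> float:
    """Convert a cumulative event proportion to a constant per-cycle probability.

    ``1 - exp(-cumulative_rate * time_fraction)``, with the cumulative
    proportion used directly as the rate.

    Parameters
    ----------
    cumulative_rate:
        Cumulative event proportion over the whole horizon (>= 0).
    time_fraction:
        Fraction of the horizon covered by one cycle, e.g. ``1/10`` for a
        6-month cycle within a 5-year horizon (> 0).
    """
    if cumulative_rate < 0:
        raise ValueError(f"cumulative_rate must be >= 0, got {cumulative_rate}")
    if time_fraction <= 0:
        raise ValueError(f"time_fraction must be > 0, got {time_fraction}")
    return -math.expm1(-cumulative_rate * time_fraction)


@dataclass
class TransitionModel:
    """Per-arm 6-month transition structure.

    Per-cycle outcomes from a state are mutually exclusive: from No
    Recurrence a patient dies, relapses (locoregionally or distantly, split
    by ``percent_met_relapse``) or stays; from Locoregional she dies,
    progresses to Distant or stays; Distant patients die or stay; Dead is
    absorbing.
    """

    arm_label: str
    p_relapse: float
    percent_met_relapse: float
    p_met_relapse: float
    p_death_from: dict[HealthState, float]
    matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name, p in (
            ("p_relapse", self.p_relapse),
            ("percent_met_relapse", self.percent_met_relapse),
            ("p_met_relapse", self.p_met_relapse),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p!r} outside [0, 1]")
        for state in ALIVE_STATES:
            p = self.p_death_from.get(state, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_death_from[{state.key}] = {p!r} outside [0, 1]")
        self.matrix = self._build_matrix()

    def _build_matrix(self) -> np.ndarray:
        n, l, d, x = (
            HealthState.NO_RECURRENCE,
            HealthState.LOCOREGIONAL,
            HealthState.DISTANT,
            HealthState.DEAD,
        )
        pd_n = self.p_death_from.get(n, 0.0)
        pd_l = self.p_death_from.get(l, 0.0)
        pd_d = self.p_death_from.get(d, 0.0)
        m = np.zeros((N_STATES, N_STATES))
        m[n, l] = self.p_relapse * (1.0 - self.percent_met_relapse)
        m[n, d] = self.p_relapse * self.percent_met_relapse
        m[n, x] = pd_n
        m[n, n] = 1.0 - self.p_relapse - pd_n
        m[l, d] = self.p_met_relapse
        m[l, x] = pd_l
        m[l, l] = 1.0 - self.p_met_relapse - pd_l
        m[d, x] = pd_d
        m[d, d] = 1.0 - pd_d
        m[x, x] = 1.0
        if (m < -1e-12).any():
            raise ValueError(
                f"per-cycle probabilities of arm {self.arm_label!r} exceed 1 in total; "
                "reduce death or relapse probabilities"
            )
        m = np.clip(m, 0.0, 1.0)
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise AssertionError("transition rows must sum to 1")
        return m

    def to_frame(self) -> pd.DataFrame:
        labels = [STATE_LABELS[HealthState(i)] for i in range(N_STATES)]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, float_format="%.10g")


def derive_transition_model(
    arm: ArmTrialSummary,
    percent_met_relapse: float,
    death_allocation: dict[HealthState, float],
    n_cycles: int,
    *,
    p_met_relapse: float = 0.0,
    relapse_scale: float = 1.0,
    death_scale: float = 1.0,
) -> TransitionModel:
    """Build a :class:`TransitionModel` from 5-year arm-level counts.

    The relapse probability converts the 5-year cumulative recurrence
    proportion; the total 5-year death burden is allocated across origin
    states by ``death_allocation`` weights (summing to 1) and converted
    per state.  ``relapse_scale``/``death_scale`` multiply the cumulative
    rates before conversion (used by calibration; both default to 1).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    wsum = sum(death_allocation.get(s, 0.0) for s in ALIVE_STATES)
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"death_allocation weights sum to {wsum}, expected 1")
    tf = 1.0 / n_cycles
    p_relapse = rate_to_probability(relapse_scale * arm.recurrence_proportion, tf)
    death_prop = arm.death_proportion
    p_death_from = {
        s: rate_to_probability(
            death_scale * death_prop * death_allocation.get(s, 0.0), tf
        )
        for s in ALIVE_STATES
    }
    return TransitionModel(
        arm_label=arm.arm_label,
        p_relapse=p_relapse,
        percent_met_relapse=percent_met_relapse,
        p_met_relapse=p_met_relapse,
        p_death_from=p_death_from,
    )


def calibrate_five_year_outcomes(
    model: TransitionModel, n_cycles: int
) -> tuple[float, float]:
    """Run the matrix ``n_cycles`` steps and report cumulative outcomes.

    Starting from a full cohort in No Recurrence, returns the cumulative
    proportion that ever left No Recurrence for a recurrence state and the
    proportion dead at the end of the horizon.
    """
    n = HealthState.NO_RECURRENCE
    occ = np.zeros(N_STATES)
    occ[n] = 1.0
    relapse_out = model.matrix[n, HealthState.LOCOREGIONAL] + model.matrix[n, HealthState.DISTANT]
    recurred = 0.0
    for _ in range(n_cycles):
        recurred += occ[n] * relapse_out
        occ = occ @ model.matrix
    return recurred, float(occ[HealthState.DEAD])


def _bracketed_root(f, lo: float, hi_start: float, hi_max: float) -> float:
    """Find a sign change by geometric bracket expansion, then brentq."""
    f_lo = f(lo)
    if abs(f_lo) < 1e-12:
        return lo
    hi = hi_start
    while hi <= hi_max:
        try:
            f_hi = f(hi)
        except ValueError:
            # invalid matrix (row probabilities exceed 1): shrink toward lo
            hi_max = hi * 0.99
            hi = hi * 0.5
            continue
        if f_lo * f_hi <= 0:
            return brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
        hi *= 2.0
    raise CalibrationError("target outcome not attainable within parameter bounds")


def calibrate_arm_model(
    arm: ArmTrialSummary,
    transition: TransitionSettings,
    n_cycles: int,
    *,
    max_rounds: int = 8,
    tol: float = 1e-8,
) -> TransitionModel:
    """Calibrate hazard scales so simulated 5-year outcomes match the arm.

    Alternates two bounded scalar searches: ``relapse_scale`` targets the
    observed cumulative recurrence proportion and ``death_scale`` the
    observed cumulative death proportion.  The coupling between the two is
    weak, so a handful of alternations converges well below ``tol``.
    """
    target_rec = arm.recurrence_proportion
    target_death = arm.death_proportion

    def build(rs: float, ds: float) -> TransitionModel:
        return derive_transition_model(
            arm,
            transition.percent_met_relapse,
            transition.death_allocation,
            n_cycles,
            p_met_relapse=transition.p_met_relapse,
            relapse_scale=rs,
            death_scale=ds,
        )

    rs, ds = 1.0, 1.0
    for _ in range(max_rounds):
        if target_rec > 0:
            def f_rec(x: float) -> float:
                rec, _ = calibrate_five_year_outcomes(build(x, ds), n_cycles)
                return rec - target_rec

            rs = _bracketed_root(f_rec, 1e-9, 1.0, 1e4)
        if target_death > 0:
            def f_death(x: float) -> float:
                _, dead = calibrate_five_year_outcomes(build(rs, x), n_cycles)
                return dead - target_death

            ds = _bracketed_root(f_death, 1e-9, 1.0, 1e4)
        model = build(rs, ds)
        rec, dead = calibrate_five_year_outcomes(model, n_cycles)
        if abs(rec - target_rec) < tol and abs(dead - target_death) < tol:
            return model
    raise CalibrationError(
        f"calibration of arm {arm.arm_label!r} did not converge: "
        f"recurred {rec:.6f} vs {target_rec:.6f}, dead {dead:.6f} vs {target_death:.6f}"
    )
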