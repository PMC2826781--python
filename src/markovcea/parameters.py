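"""Model inputs: trial arm summaries, unit costs, utilities and settings.

Everything the analysis consumes is loaded from a single YAML configuration
file (a bundled file reproduces the published 2006 CAD inputs).  All loaders
validate invariants eagerly and raise :class:`ConfigValidationError` naming
the offending field.  Monetary values are 2006 Canadian dollars.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .states import ALIVE_STATES, STATE_KEYS, HealthState

log = logging.getLogger(__name__)

ARM_TAC = "TAC"
ARM_FAC = "FAC"
ARMS = (ARM_TAC, ARM_FAC)

#: defaults applied when optional cost fields are absent from the config
DEFAULT_HER2_POSITIVE_FRACTION = 0.20
DEFAULT_LINE_UTILIZATION = {1: 1.0, 2: 0.7, 3: 0.4, 4: 0.2, 5: 0.1}


class ConfigValidationError(ValueError):
    """A configuration value violated an invariant; ``field`` names it."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


def _require_proportion(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0):
        raise ConfigValidationError(name, f"proportion {value!r} outside [0, 1]")
    return value


def _require_nonnegative(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ConfigValidationError(name, f"must be finite and >= 0, got {value!r}")
    return value


# ---------------------------------------------------------------------------
# trial arm summary
# ---------------------------------------------------------------------------


@dataclass
class ArmTrialSummary:
    """Arm-level 5-year outcome counts and adverse-event rates.

    Counts are stored as floats so that sensitivity scenarios may scale them
    continuously; generated/observed data use integers.
    """

    arm_label: str
    n_treated: float
    n_recurrences: float
    n_deaths: float
    ae_rates: dict[str, float]
    prophylaxis_patients: float = 0.0
    prophylaxis_cycles: float = 0.0

    def __post_init__(self) -> None:
        p = f"arms.{self.arm_label}"
        _require_nonnegative(f"{p}.n_treated", self.n_treated)
        if self.n_treated < 1:
            raise ConfigValidationError(f"{p}.n_treated", "must be >= 1")
        for name in ("n_recurrences", "n_deaths", "prophylaxis_patients"):
            v = _require_nonnegative(f"{p}.{name}", getattr(self, name))
            if v > self.n_treated:
                raise ConfigValidationError(f"{p}.{name}", f"{v!r} exceeds n_treated {self.n_treated!r}")
        _require_nonnegative(f"{p}.prophylaxis_cycles", self.prophylaxis_cycles)
        for ae, rate in self.ae_rates.items():
            _require_proportion(f"{p}.ae_rates.{ae}", rate)

    # -- derived proportions -------------------------------------------------

    @property
    def recurrence_proportion(self) -> float:
        """5-year cumulative recurrence proportion."""
        return self.n_recurrences / self.n_treated

    @property
    def death_proportion(self) -> float:
        """5-year cumulative death proportion."""
        return self.n_deaths / self.n_treated

    @property
    def mean_prophylaxis_cycles_per_recipient(self) -> float:
        """Average cycles with prophylaxis among patients who received any."""
        if self.prophylaxis_patients == 0:
            return 0.0
        return self.prophylaxis_cycles / self.prophylaxis_patients

    @property
    def prophylaxis_administrations_per_patient(self) -> float:
        """Average prophylaxis administrations over the whole arm."""
        return self.prophylaxis_cycles / self.n_treated


# ---------------------------------------------------------------------------
# costs
# ---------------------------------------------------------------------------


@dataclass
class CostInputs:
    """All unit costs of the model (2006 CAD).

    ``supportive_care_components`` maps arm -> component -> (cost, proportion
    receiving); the base case uses the cross-arm average of the component
    totals.  ``met_chemo_line_costs`` maps arm -> line number -> (low, high)
    where the range spans HER2-negative to HER2-positive regimens; lines
    beyond the highest tabulated line reuse the last tabulated cost.
    """

    drug_acquisition: dict[str, float]
    chemo_administration: dict[str, float]
    ae_unit_costs: dict[str, float]
    gcsf_cost_per_event: float
    antibiotic_prophylaxis: float
    supportive_care_components: dict[str, dict[str, tuple[float, float]]]
    diagnostics_at_diagnosis: float
    lab_tests: float
    followup_no_recurrence_years_1_3: float
    followup_no_recurrence_after_year_3: float
    followup_locoregional_year_costs: list[float]
    followup_metastatic_annual: float
    met_chemo_line_costs: dict[str, dict[int, tuple[float, float]]]
    her2_positive_fraction: float = DEFAULT_HER2_POSITIVE_FRACTION
    line_utilization: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LINE_UTILIZATION)
    )

    def __post_init__(self) -> None:
        for mapping, name in (
            (self.drug_acquisition, "drug_acquisition"),
            (self.chemo_administration, "chemo_administration"),
            (self.ae_unit_costs, "ae_unit_costs"),
        ):
            for key, v in mapping.items():
                _require_nonnegative(f"costs.{name}.{key}", v)
        _require_nonnegative("costs.gcsf_cost_per_event", self.gcsf_cost_per_event)
        _require_nonnegative("costs.antibiotic_prophylaxis", self.antibiotic_prophylaxis)
        _require_nonnegative("costs.diagnostics_at_diagnosis", self.diagnostics_at_diagnosis)
        _require_nonnegative("costs.lab_tests", self.lab_tests)
        _require_nonnegative(
            "costs.followup_no_recurrence.years_1_3", self.followup_no_recurrence_years_1_3
        )
        _require_nonnegative(
            "costs.followup_no_recurrence.after_year_3",
            self.followup_no_recurrence_after_year_3,
        )
        if not self.followup_locoregional_year_costs:
            raise ConfigValidationError(
                "costs.followup_locoregional_year_costs", "must list at least one year"
            )
        for i, v in enumerate(self.followup_locoregional_year_costs):
            _require_nonnegative(f"costs.followup_locoregional_year_costs[{i}]", v)
        _require_nonnegative("costs.followup_metastatic_annual", self.followup_metastatic_annual)
        for arm, comps in self.supportive_care_components.items():
            for comp, (cost, prop) in comps.items():
                _require_nonnegative(f"costs.supportive_care_components.{arm}.{comp}[0]", cost)
                _require_proportion(f"costs.supportive_care_components.{arm}.{comp}[1]", prop)
        for arm, lines in self.met_chemo_line_costs.items():
            for line, (lo, hi) in lines.items():
                _require_nonnegative(f"costs.met_chemo_line_costs.{arm}.{line}[0]", lo)
                _require_nonnegative(f"costs.met_chemo_line_costs.{arm}.{line}[1]", hi)
                if hi < lo:
                    raise ConfigValidationError(
                        f"costs.met_chemo_line_costs.{arm}.{line}", "range high < low"
                    )
        _require_proportion("costs.her2_positive_fraction", self.her2_positive_fraction)
        for line, u in self.line_utilization.items():
            _require_proportion(f"costs.line_utilization.{line}", u)

    # -- aggregates ----------------------------------------------------------

    def supportive_care_total(self, arm: str) -> float:
        """Per-patient supportive-care cost of one arm (component sum)."""
        comps = self.supportive_care_components[arm]
        return sum(cost * prop for cost, prop in comps.values())

    def supportive_care_average(self) -> float:
        """Averaged per-patient supportive-care cost used in the base case."""
        totals = [self.supportive_care_total(a) for a in self.supportive_care_components]
        return sum(totals) / len(totals)

    def locoregional_followup_annual(self) -> float:
        """Single annual locoregional follow-up cost (multi-year average)."""
        ys = self.followup_locoregional_year_costs
        return sum(ys) / len(ys)

    def _line_cost_range(self, arm: str, line: int) -> tuple[float, float]:
        lines = self.met_chemo_line_costs[arm]
        if line in lines:
            return lines[line]
        # lines past the tabulated ones cost the same as the last tabulated line
        return lines[max(lines)]

    def expected_metastatic_cost(self, arm: str) -> float:
        """Expected per-patient chemotherapy cost after entering Distant.

        Sum over lines of utilization x HER2-prevalence-weighted cost, with
        the HER2-negative/positive range collapsed by ``her2_positive_fraction``.
        """
        if arm not in self.met_chemo_line_costs:
            raise KeyError(f"unknown arm label {arm!r}")
        f = self.her2_positive_fraction
        total = 0.0
        for line, util in self.line_utilization.items():
            lo, hi = self._line_cost_range(arm, line)
            total += util * ((1.0 - f) * lo + f * hi)
        return total


def treatment_cost(costs: CostInputs, arm: str) -> float:
    """Six-cycle treatment cost: drug acquisition + administration (time 0)."""
    if arm not in costs.drug_acquisition or arm not in costs.chemo_administration:
        raise KeyError(f"unknown arm label {arm!r}")
    return costs.drug_acquisition[arm] + costs.chemo_administration[arm]


def average_ae_cost(
    arm: ArmTrialSummary, costs: CostInputs, *, ae_rates: Mapping[str, float] | None = None
) -> float:
    """Expected per-patient adverse-event cost, plus antibiotic prophylaxis.

    Each grade-3/4 event contributes rate x unit cost; every patient also
    receives prophylactic antibiotics once.  Applied at time 0.
    ``ae_rates`` overrides the arm's observed rates (used by alternative
    prophylaxis scenarios).
    """
    rates = dict(arm.ae_rates if ae_rates is None else ae_rates)
    total = 0.0
    for ae, rate in rates.items():
        if ae not in costs.ae_unit_costs:
            raise ConfigValidationError(
                f"costs.ae_unit_costs.{ae}", "rate given but no unit cost configured"
            )
        total += rate * costs.ae_unit_costs[ae]
    return total + costs.antibiotic_prophylaxis


def secondary_prophylaxis_cost(arm: ArmTrialSummary, costs: CostInputs) -> float:
    """Per-patient cost of G-CSF given after a first febrile-neutropenia event.

    Cost per event x proportion receiving any prophylaxis x average cycles
    under prophylaxis among recipients; applied once at time 0.  Algebraically
    this equals cost_per_event x total prophylaxis cycles / n_treated.
    """
    if arm.prophylaxis_patients == 0:
        return 0.0
    proportion = arm.prophylaxis_patients / arm.n_treated
    return (
        costs.gcsf_cost_per_event
        * proportion
        * arm.mean_prophylaxis_cycles_per_recipient
    )


def annual_followup_cost(state: HealthState, year: int, costs: CostInputs) -> float:
    """Annual follow-up cost for a non-absorbing state in a given year (1-based)."""
    if year < 1:
        raise ValueError(f"year must be >= 1, got {year}")
    if state is HealthState.NO_RECURRENCE:
        if year <= 3:
            return costs.followup_no_recurrence_years_1_3
        return costs.followup_no_recurrence_after_year_3
    if state is HealthState.LOCOREGIONAL:
        return costs.locoregional_followup_annual()
    if state is HealthState.DISTANT:
        return costs.followup_metastatic_annual
    raise ValueError("no follow-up cost defined for the Dead state")


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------


@dataclass
class UtilityInputs:
    """Health-state utility weights and per-regimen adverse-event disutilities."""

    u_no_recurrence: float
    u_locoregional: float
    u_distant_range: tuple[float, float]
    u_adjuvant_fac: float
    disutility_tac: float
    disutility_fac: float

    def __post_init__(self) -> None:
        _require_proportion("utilities.u_no_recurrence", self.u_no_recurrence)
        _require_proportion("utilities.u_locoregional", self.u_locoregional)
        lo, hi = self.u_distant_range
        _require_proportion("utilities.u_distant_range[0]", lo)
        _require_proportion("utilities.u_distant_range[1]", hi)
        if hi < lo:
            raise ConfigValidationError("utilities.u_distant_range", "range high < low")
        _require_proportion("utilities.u_adjuvant_fac", self.u_adjuvant_fac)
        _require_proportion("utilities.disutility_tac", self.disutility_tac)
        _require_proportion("utilities.disutility_fac", self.disutility_fac)
        if self.disutility_tac < self.disutility_fac:
            raise ConfigValidationError(
                "utilities.disutility_tac", "must be >= disutility_fac"
            )

    @property
    def u_distant(self) -> float:
        """Midpoint of the distant-recurrence utility range."""
        lo, hi = self.u_distant_range
        return (lo + hi) / 2.0

    def disutility(self, arm: str) -> float:
        if arm == ARM_TAC:
            return self.disutility_tac
        if arm == ARM_FAC:
            return self.disutility_fac
        raise KeyError(f"unknown arm label {arm!r}")


def arm_utilities(util: UtilityInputs, arm: str) -> dict[Any, float]:
    """Per-state utility map for one arm, plus the treatment-phase weight.

    State utilities are identical across arms; the treatment-phase weight is
    the adjuvant utility less the arm's incremental disutility relative to
    the reference (FAC) regimen.
    """
    treatment = max(
        0.0, util.u_adjuvant_fac - (util.disutility(arm) - util.disutility_fac)
    )
    return {
        HealthState.NO_RECURRENCE: util.u_no_recurrence,
        HealthState.LOCOREGIONAL: util.u_locoregional,
        HealthState.DISTANT: util.u_distant,
        HealthState.DEAD: 0.0,
        "treatment": treatment,
    }


# ---------------------------------------------------------------------------
# settings
# ---------------------------------------------------------------------------


@dataclass
class EconomicSettings:
    """Discounting, horizon and extrapolation settings."""

    discount_rate_annual: float = 0.05
    cycle_length: float = 0.5
    trial_horizon_cycles: int = 10
    treatment_phase_cycles: int = 6
    gcsf_days_per_cycle: int = 7
    patient_weight_kg: float = 60.0
    remaining_life_expectancy: dict[HealthState, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require_nonnegative("settings.discount_rate_annual", self.discount_rate_annual)
        if self.cycle_length <= 0:
            raise ConfigValidationError("settings.cycle_length", "must be > 0")
        if self.trial_horizon_cycles < 1:
            raise ConfigValidationError("settings.trial_horizon_cycles", "must be >= 1")
        if self.treatment_phase_cycles < 0:
            raise ConfigValidationError("settings.treatment_phase_cycles", "must be >= 0")
        for state, years in self.remaining_life_expectancy.items():
            _require_nonnegative(f"settings.remaining_life_expectancy.{state.key}", years)

    def life_expectancy(self, state: HealthState) -> float:
        return self.remaining_life_expectancy.get(state, 0.0)


@dataclass
class TransitionSettings:
    """Free parameters of the transition structure (calibrated or configured)."""

    percent_met_relapse: float = 0.5
    p_met_relapse: float = 0.04
    death_allocation: dict[HealthState, float] = field(
        default_factory=lambda: {
            HealthState.NO_RECURRENCE: 0.30,
            HealthState.LOCOREGIONAL: 0.15,
            HealthState.DISTANT: 0.55,
        }
    )

    def __post_init__(self) -> None:
        _require_proportion("transition.percent_met_relapse", self.percent_met_relapse)
        _require_proportion("transition.p_met_relapse", self.p_met_relapse)
        total = 0.0
        for state, w in self.death_allocation.items():
            _require_proportion(f"transition.death_allocation.{state.key}", w)
            total += w
        if abs(total - 1.0) > 1e-9:
            raise ConfigValidationError(
                "transition.death_allocation", f"weights sum to {total!r}, expected 1"
            )


# ---------------------------------------------------------------------------
# whole-model configuration
# ---------------------------------------------------------------------------

BUNDLED_CONFIG = "tacfac_2006.yaml"
BUNDLED_SCENARIOS = "base_scenarios.yaml"
BUNDLED_PRIMARY_PROPHYLAXIS = "primary_prophylaxis.yaml"


@dataclass
class ModelConfig:
    """Complete, validated set of model inputs for one analysis."""

    arms: dict[str, ArmTrialSummary]
    costs: CostInputs
    utilities: UtilityInputs
    settings: EconomicSettings
    transition: TransitionSettings

    def copy(self) -> "ModelConfig":
        return ModelConfig.from_dict(self.to_dict())

    # -- (de)serialisation ---------------------------------------------------

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "ModelConfig":
        raw = copy.deepcopy(dict(raw))
        try:
            arms_raw = raw["arms"]
            costs_raw = raw["costs"]
            util_raw = raw["utilities"]
            settings_raw = raw.get("settings", {})
            transition_raw = raw.get("transition", {})
        except KeyError as exc:  # pragma: no cover - defensive
            raise ConfigValidationError(str(exc), "missing top-level section") from exc

        arms = {
            label: ArmTrialSummary(
                arm_label=label,
                n_treated=a["n_treated"],
                n_recurrences=a["n_recurrences"],
                n_deaths=a["n_deaths"],
                ae_rates={k: float(v) for k, v in a.get("ae_rates", {}).items()},
                prophylaxis_patients=a.get("prophylaxis_patients", 0),
                prophylaxis_cycles=a.get("prophylaxis_cycles", 0),
            )
            for label, a in arms_raw.items()
        }

        fu_nr = costs_raw["followup_no_recurrence"]
        if "her2_positive_fraction" not in costs_raw:
            log.info(
                "costs.her2_positive_fraction absent; default %.2f applied",
                DEFAULT_HER2_POSITIVE_FRACTION,
            )
        if "line_utilization" not in costs_raw:
            log.info(
                "costs.line_utilization absent; default %s applied", DEFAULT_LINE_UTILIZATION
            )
        costs = CostInputs(
            drug_acquisition={k: float(v) for k, v in costs_raw["drug_acquisition"].items()},
            chemo_administration={
                k: float(v) for k, v in costs_raw["chemo_administration"].items()
            },
            ae_unit_costs={k: float(v) for k, v in costs_raw["ae_unit_costs"].items()},
            gcsf_cost_per_event=costs_raw["gcsf_cost_per_event"],
            antibiotic_prophylaxis=costs_raw["antibiotic_prophylaxis"],
            supportive_care_components={
                arm: {comp: (float(v[0]), float(v[1])) for comp, v in comps.items()}
                for arm, comps in costs_raw["supportive_care_components"].items()
            },
            diagnostics_at_diagnosis=costs_raw["diagnostics_at_diagnosis"],
            lab_tests=costs_raw["lab_tests"],
            followup_no_recurrence_years_1_3=fu_nr["years_1_3"],
            followup_no_recurrence_after_year_3=fu_nr["after_year_3"],
            followup_locoregional_year_costs=[
                float(v) for v in costs_raw["followup_locoregional_year_costs"]
            ],
            followup_metastatic_annual=costs_raw["followup_metastatic_annual"],
            met_chemo_line_costs={
                arm: {int(line): (float(v[0]), float(v[1])) for line, v in lines.items()}
                for arm, lines in costs_raw["met_chemo_line_costs"].items()
            },
            her2_positive_fraction=costs_raw.get(
                "her2_positive_fraction", DEFAULT_HER2_POSITIVE_FRACTION
            ),
            line_utilization={
                int(k): float(v)
                for k, v in costs_raw.get("line_utilization", DEFAULT_LINE_UTILIZATION).items()
            },
        )

        utilities = UtilityInputs(
            u_no_recurrence=util_raw["u_no_recurrence"],
            u_locoregional=util_raw["u_locoregional"],
            u_distant_range=tuple(float(v) for v in util_raw["u_distant_range"]),
            u_adjuvant_fac=util_raw["u_adjuvant_fac"],
            disutility_tac=util_raw["disutility_tac"],
            disutility_fac=util_raw["disutility_fac"],
        )

        rle_raw = settings_raw.get("remaining_life_expectancy", {})
        for key in rle_raw:
            if key not in STATE_KEYS:
                raise ConfigValidationError(
                    f"settings.remaining_life_expectancy.{key}", "unknown state"
                )
        settings = EconomicSettings(
            discount_rate_annual=settings_raw.get("discount_rate_annual", 0.05),
            cycle_length=settings_raw.get("cycle_length", 0.5),
            trial_horizon_cycles=settings_raw.get("trial_horizon_cycles", 10),
            treatment_phase_cycles=settings_raw.get("treatment_phase_cycles", 6),
            gcsf_days_per_cycle=settings_raw.get("gcsf_days_per_cycle", 7),
            patient_weight_kg=settings_raw.get("patient_weight_kg", 60.0),
            remaining_life_expectancy={
                STATE_KEYS[k]: float(v) for k, v in rle_raw.items()
            },
        )

        alloc_raw = transition_raw.get("death_allocation")
        transition = TransitionSettings(
            percent_met_relapse=transition_raw.get("percent_met_relapse", 0.5),
            p_met_relapse=transition_raw.get("p_met_relapse", 0.04),
            **(
                {"death_allocation": {STATE_KEYS[k]: float(v) for k, v in alloc_raw.items()}}
                if alloc_raw
                else {}
            ),
        )

        cfg = cls(
            arms=arms,
            costs=costs,
            utilities=utilities,
            settings=settings,
            transition=transition,
        )
        return cfg

    def to_dict(self) -> dict[str, Any]:
        c = self.costs
        return {
            "arms": {
                label: {
                    "n_treated": a.n_treated,
                    "n_recurrences": a.n_recurrences,
                    "n_deaths": a.n_deaths,
                    "ae_rates": dict(a.ae_rates),
                    "prophylaxis_patients": a.prophylaxis_patients,
                    "prophylaxis_cycles": a.prophylaxis_cycles,
                }
                for label, a in self.arms.items()
            },
            "costs": {
                "drug_acquisition": dict(c.drug_acquisition),
                "chemo_administration": dict(c.chemo_administration),
                "ae_unit_costs": dict(c.ae_unit_costs),
                "gcsf_cost_per_event": c.gcsf_cost_per_event,
                "antibiotic_prophylaxis": c.antibiotic_prophylaxis,
                "supportive_care_components": {
                    arm: {comp: [v[0], v[1]] for comp, v in comps.items()}
                    for arm, comps in c.supportive_care_components.items()
                },
                "diagnostics_at_diagnosis": c.diagnostics_at_diagnosis,
                "lab_tests": c.lab_tests,
                "followup_no_recurrence": {
                    "years_1_3": c.followup_no_recurrence_years_1_3,
                    "after_year_3": c.followup_no_recurrence_after_year_3,
                },
                "followup_locoregional_year_costs": list(c.followup_locoregional_year_costs),
                "followup_metastatic_annual": c.followup_metastatic_annual,
                "met_chemo_line_costs": {
                    arm: {line: [v[0], v[1]] for line, v in lines.items()}
                    for arm, lines in c.met_chemo_line_costs.items()
                },
                "her2_positive_fraction": c.her2_positive_fraction,
                "line_utilization": dict(c.line_utilization),
            },
            "utilities": {
                "u_no_recurrence": self.utilities.u_no_recurrence,
                "u_locoregional": self.utilities.u_locoregional,
                "u_distant_range": list(self.utilities.u_distant_range),
                "u_adjuvant_fac": self.utilities.u_adjuvant_fac,
                "disutility_tac": self.utilities.disutility_tac,
                "disutility_fac": self.utilities.disutility_fac,
            },
            "settings": {
                "discount_rate_annual": self.settings.discount_rate_annual,
                "cycle_length": self.settings.cycle_length,
                "trial_horizon_cycles": self.settings.trial_horizon_cycles,
                "treatment_phase_cycles": self.settings.treatment_phase_cycles,
                "gcsf_days_per_cycle": self.settings.gcsf_days_per_cycle,
                "patient_weight_kg": self.settings.patient_weight_kg,
                "remaining_life_expectancy": {
                    state.key: years
                    for state, years in self.settings.remaining_life_expectancy.items()
                },
            },
            "transition": {
                "percent_met_relapse": self.transition.percent_met_relapse,
                "p_met_relapse": self.transition.p_met_relapse,
                "death_allocation": {
                    state.key: w for state, w in self.transition.death_allocation.items()
                },
            },
        }

    def log_echo(self) -> None:
        """Echo every resolved parameter to the log (auditability)."""
        for line in yaml.safe_dump(self.to_dict(), sort_keys=True).splitlines():
            log.info("config: %s", line)


def load_model_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from a YAML file."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigValidationError(str(path), "configuration root must be a mapping")
    cfg = ModelConfig.from_dict(raw)
    cfg.log_echo()
    return cfg


def save_model_config(config: ModelConfig, path: str | Path) -> None:
    """Serialize a configuration back to YAML (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def bundled_data_path(name: str) -> Path:
    """Path of a data file shipped with the package."""
    return Path(str(resources.files("markovcea").joinpath("data", name)))


def load_bundled_config() -> ModelConfig:
    """Load the bundled base-case configuration (published 2006 CAD inputs)."""
    return load_model_config(bundled_data_path(BUNDLED_CONFIG))
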