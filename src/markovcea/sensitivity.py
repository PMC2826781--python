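"""One-way scenario catalogue, bootstrap uncertainty and primary prophylaxis.

Scenarios are declarative perturbations of the serialized configuration:
dotted parameter paths (wildcard ``*`` expands over mapping keys, integer
segments index lists) combined with a ``scale`` or ``set`` operation.  The
bundled catalogue reproduces the published one-way analyses; the bootstrap
redraws arm-level outcome counts binomially and the primary-prophylaxis
model swaps adverse-event rates and G-CSF costing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .analysis import run_arm, run_base_case
from .outcomes import CEResult, compute_ce_result
from .parameters import (
    ARM_FAC,
    ARM_TAC,
    ConfigValidationError,
    ModelConfig,
    bundled_data_path,
    BUNDLED_PRIMARY_PROPHYLAXIS,
    BUNDLED_SCENARIOS,
)


class ScenarioError(ValueError):
    """A scenario referenced an unresolvable parameter path."""


@dataclass
class Perturbation:
    path: str
    op: str  # "scale" | "set"
    value: Any

    def __post_init__(self) -> None:
        if self.op not in ("scale", "set"):
            raise ScenarioError(f"unknown operation {self.op!r} for path {self.path!r}")
        if self.op == "scale" and not (isinstance(self.value, (int, float)) and self.value > 0):
            raise ScenarioError(f"scale factor for {self.path!r} must be > 0")


@dataclass
class Scenario:
    name: str
    perturbations: list[Perturbation] = field(default_factory=list)


def load_scenarios(path: str | Path) -> list[Scenario]:
    """Load a scenario catalogue from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    scenarios = []
    for s in raw["scenarios"]:
        perts = [
            Perturbation(path=p["path"], op=p["op"], value=p["value"])
            for p in s.get("perturbations", [])
        ]
        scenarios.append(Scenario(name=s["name"], perturbations=perts))
    return scenarios


def load_bundled_scenarios() -> list[Scenario]:
    return load_scenarios(bundled_data_path(BUNDLED_SCENARIOS))


# -- path resolution ---------------------------------------------------------


def _resolve(container: Any, segments: Sequence[str], path: str) -> list[tuple[Any, Any]]:
    """Expand a dotted path to (parent, key) leaf references."""
    if not segments:
        raise ScenarioError(f"empty parameter path {path!r}")
    seg, rest = segments[0], segments[1:]
    if isinstance(container, dict):
        if seg == "*":
            keys = list(container)
        elif seg in container:
            keys = [seg]
        else:
            raise ScenarioError(f"path {path!r}: key {seg!r} not found")
    elif isinstance(container, list):
        try:
            idx = int(seg)
        except ValueError as exc:
            raise ScenarioError(f"path {path!r}: list index expected, got {seg!r}") from exc
        if not -len(container) <= idx < len(container):
            raise ScenarioError(f"path {path!r}: index {idx} out of range")
        keys = [idx]
    else:
        raise ScenarioError(f"path {path!r}: cannot descend into {type(container).__name__}")
    leaves: list[tuple[Any, Any]] = []
    for key in keys:
        if rest:
            leaves.extend(_resolve(container[key], rest, path))
        else:
            leaves.append((container, key))
    return leaves


def apply_scenario(config: ModelConfig, scenario: Scenario) -> ModelConfig:
    """Return a modified deep copy of the configuration; the base is untouched."""
    raw = config.to_dict()
    for pert in scenario.perturbations:
        leaves = _resolve(raw, pert.path.split("."), pert.path)
        for parent, key in leaves:
            if pert.op == "scale":
                current = parent[key]
                if not isinstance(current, (int, float)):
                    raise ScenarioError(
                        f"path {pert.path!r} does not address a numeric value"
                    )
                parent[key] = current * pert.value
            else:
                parent[key] = pert.value
    try:
        return ModelConfig.from_dict(raw)
    except ConfigValidationError as exc:
        raise ScenarioError(f"scenario {scenario.name!r} produced invalid config: {exc}") from exc


# -- one-way suite -----------------------------------------------------------


def run_one_way_suite(
    config: ModelConfig, scenarios: Iterable[Scenario]
) -> pd.DataFrame:
    """Base case plus one row per scenario with ICER/ICUR and incrementals."""
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("scenario list must be nonempty")
    rows = []

    def row(name: str, result: CEResult) -> dict[str, Any]:
        return {
            "scenario": name,
            "icer": result.icer,
            "icur": result.icur,
            "delta_cost": result.delta_cost,
            "delta_lys": result.delta_lys,
            "delta_qalys": result.delta_qalys,
            "dominance": result.dominance_flag,
        }

    rows.append(row("Base case", run_base_case(config).result))
    for scenario in scenarios:
        modified = apply_scenario(config, scenario)
        rows.append(row(scenario.name, run_base_case(modified).result))
    return pd.DataFrame(rows)


# -- bootstrap ---------------------------------------------------------------


@dataclass
class BootstrapResult:
    """ICER/ICUR replicates with extreme and percentile summaries."""

    samples: pd.DataFrame
    best_case: dict[str, float]
    worst_case: dict[str, float]
    percentiles: dict[str, tuple[float, float]]
    n_invalid: int


def bootstrap_icer(
    config: ModelConfig, n_boot: int, seed: int
) -> BootstrapResult:
    """Nonparametric binomial resampling of arm-level outcome counts.

    Each replicate redraws recurrence and death counts per arm as
    ``Binomial(n_treated, observed proportion)``, re-derives and
    recalibrates the transition models, reruns both arms and records the
    incremental ratios.  Replicates with non-positive incremental effect
    (undefined ratio) are counted in ``n_invalid`` and excluded from the
    summaries.  Deterministic for a fixed seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    n_invalid = 0
    base_raw = config.to_dict()
    for rep in range(n_boot):
        raw = ModelConfig.from_dict(base_raw).to_dict()
        for label in (ARM_TAC, ARM_FAC):
            arm = config.arms[label]
            n = int(round(arm.n_treated))
            raw["arms"][label]["n_recurrences"] = int(
                rng.binomial(n, arm.recurrence_proportion)
            )
            raw["arms"][label]["n_deaths"] = int(rng.binomial(n, arm.death_proportion))
        result = run_base_case(ModelConfig.from_dict(raw)).result
        if result.icer is None or result.icur is None:
            n_invalid += 1
            continue
        records.append({"replicate": rep, "icer": result.icer, "icur": result.icur})
    samples = pd.DataFrame(records, columns=["replicate", "icer", "icur"])
    if samples.empty:
        raise RuntimeError("all bootstrap replicates produced undefined ratios")
    best = samples.loc[samples["icer"].idxmin()]
    worst = samples.loc[samples["icer"].idxmax()]
    percentiles = {
        col: (
            float(np.percentile(samples[col], 2.5)),
            float(np.percentile(samples[col], 97.5)),
        )
        for col in ("icer", "icur")
    }
    return BootstrapResult(
        samples=samples,
        best_case={"icer": float(best["icer"]), "icur": float(best["icur"])},
        worst_case={"icer": float(worst["icer"]), "icur": float(worst["icur"])},
        percentiles=percentiles,
        n_invalid=n_invalid,
    )


# -- primary G-CSF prophylaxis ----------------------------------------------


@dataclass
class PrimaryProphylaxisInputs:
    """Adverse-event rates with/without primary G-CSF prophylaxis.

    ``ae_rates_pre``/``ae_rates_post`` are the intervention arm's rates
    without and with primary prophylaxis; ``ae_rates_fac`` the comparator's
    observed rates in the same source study.  ``gcsf_cost_all_cycles`` is the
    per-patient cost of giving G-CSF before every treatment cycle (default:
    per-event acquisition cost x 6 cycles).
    """

    ae_rates_pre: dict[str, float]
    ae_rates_post: dict[str, float]
    ae_rates_fac: dict[str, float]
    gcsf_cost_all_cycles: float | None = None

    def __post_init__(self) -> None:
        for name, rates in (
            ("ae_rates_pre", self.ae_rates_pre),
            ("ae_rates_post", self.ae_rates_post),
            ("ae_rates_fac", self.ae_rates_fac),
        ):
            for ae, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ConfigValidationError(f"{name}.{ae}", f"rate {r!r} outside [0, 1]")
        pre_fn = self.ae_rates_pre.get("febrile_neutropenia")
        post_fn = self.ae_rates_post.get("febrile_neutropenia")
        if pre_fn is not None and post_fn is not None and post_fn > pre_fn:
            raise ConfigValidationError(
                "ae_rates_post.febrile_neutropenia",
                "post-prophylaxis rate exceeds pre-prophylaxis rate",
            )


def load_primary_prophylaxis(path: str | Path | None = None) -> PrimaryProphylaxisInputs:
    """Load primary-prophylaxis inputs (bundled file by default)."""
    if path is None:
        path = bundled_data_path(BUNDLED_PRIMARY_PROPHYLAXIS)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return PrimaryProphylaxisInputs(
        ae_rates_pre={k: float(v) for k, v in raw["ae_rates_pre"].items()},
        ae_rates_post={k: float(v) for k, v in raw["ae_rates_post"].items()},
        ae_rates_fac={k: float(v) for k, v in raw["ae_rates_fac"].items()},
        gcsf_cost_all_cycles=raw.get("gcsf_cost_all_cycles"),
    )


def primary_prophylaxis_model(
    config: ModelConfig, pp: PrimaryProphylaxisInputs
) -> CEResult:
    """Alternative model with G-CSF given before every intervention cycle.

    The intervention (TAC) arm uses post-prophylaxis adverse-event rates,
    pays the all-cycles G-CSF cost at time 0 and drops the secondary
    prophylaxis cost; the comparator uses the source study's observed rates
    and keeps secondary prophylaxis.  Transition probabilities are unchanged.
    """
    gcsf_all = pp.gcsf_cost_all_cycles
    if gcsf_all is None:
        gcsf_all = config.costs.gcsf_cost_per_event * 6
    # a zero all-cycles cost means no primary prophylaxis is actually given,
    # so the secondary-prophylaxis cost of the base model is retained
    trace_tac = run_arm(
        config,
        ARM_TAC,
        ae_rates=pp.ae_rates_post,
        include_secondary_prophylaxis=(gcsf_all == 0),
        extra_time_zero=gcsf_all,
    )
    trace_fac = run_arm(config, ARM_FAC, ae_rates=pp.ae_rates_fac)
    return compute_ce_result(trace_tac, trace_fac)
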