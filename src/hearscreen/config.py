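"""Run configuration: schema, validation, loading and the bundled fixture.

A run configuration (YAML or JSON) carries every model parameter: the birth
cohort, per-modality cost inventories and throughput economics, test
performances, cascade parameterizations, utility weights, treatment
scenarios, the OOPE profile, and optional Monte-Carlo settings.  Validation
is schema-based (pydantic) and enumerates every violation, not just the
first; cross-reference checks (modality names, mode requirements) are
collected the same way.

``reference_values`` holds externally printed figures the pipeline compares
its computed results against; mismatches land in the discrepancy log.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cascade import CascadeMode, CohortSpec, TestPerformance
from .costing import CostInventory, ScreeningModality, StaffCostLine, staff_annual_cost
from .economics import (
    DEFAULT_TRANSPORT,
    FACILITY_LEVELS,
    OOPEProfile,
    TreatmentScenario,
    UtilityWeights,
)

#: Name of the bundled fixture reproducing the 2019-20 parameter set.
PAPER_FIXTURE = "paper_2019_20.yaml"


class ConfigError(ValueError):
    """Configuration failed validation; the message lists every violation."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortCfg(_Model):
    size: float = Field(100_000, ge=0)
    prevalence_per_1000: float = Field(5.0, ge=0, le=1000)
    life_expectancy_years: float = Field(69.2, ge=0)

    def build(self) -> CohortSpec:
        return CohortSpec(self.size, self.prevalence_per_1000, self.life_expectancy_years)


class InventoryCfg(_Model):
    human_resource: float = Field(0.0, ge=0)
    medical_consumables: float = Field(0.0, ge=0)
    non_medical_consumables: float = Field(0.0, ge=0)
    medical_equipment: float = Field(0.0, ge=0)
    non_medical_equipment: float = Field(0.0, ge=0)
    overheads: float = Field(0.0, ge=0)

    def build(self) -> CostInventory:
        return CostInventory(**self.model_dump())


class ModalityCfg(_Model):
    name: str
    role: Literal["first_line", "confirmatory"]
    test_duration_minutes: float = Field(gt=0)
    working_days_per_year: int = Field(260, gt=0)
    effective_screening_hours_per_day: float = Field(6.0, gt=0)
    inventory: InventoryCfg = Field(default_factory=InventoryCfg)

    def build(self) -> ScreeningModality:
        return ScreeningModality(
            name=self.name,
            test_duration_minutes=self.test_duration_minutes,
            inventory=self.inventory.build(),
            working_days_per_year=self.working_days_per_year,
            effective_screening_hours_per_day=self.effective_screening_hours_per_day,
        )


class PerformanceCfg(_Model):
    sensitivity: Optional[float] = Field(None, ge=0, le=1)
    specificity: Optional[float] = Field(None, ge=0, le=1)
    ppv: Optional[float] = Field(None, ge=0, le=1)
    npv: Optional[float] = Field(None, ge=0, le=1)

    def build(self) -> TestPerformance:
        return TestPerformance(**self.model_dump())


class CascadeModeCfg(_Model):
    mode: Literal["sens_spec", "observed"] = "sens_spec"
    observed_referred: Optional[float] = Field(None, ge=0)
    observed_confirmed: Optional[float] = Field(None, ge=0)
    observed_under_detected: float = Field(0.0, ge=0)

    def build(self) -> CascadeMode:
        return CascadeMode(**self.model_dump())


class UtilitiesCfg(_Model):
    normal_hearing: float = Field(0.95, ge=0, le=1)
    hl_any: float = Field(0.77, ge=0, le=1)
    hl_unilateral: float = Field(0.85, ge=0, le=1)
    hl_bilateral: float = Field(0.69, ge=0, le=1)

    def build(self) -> UtilityWeights:
        return UtilityWeights(**self.model_dump())


class ScenarioCfg(_Model):
    name: str
    cost_per_treated_child: float = Field(ge=0)
    treated_utility: Optional[float] = Field(None, ge=0, le=1)

    def build(self) -> TreatmentScenario:
        return TreatmentScenario(**self.model_dump())


class OOPECfg(_Model):
    transport_per_visit_by_level: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_TRANSPORT)
    )
    wage_loss_per_visit: float = Field(0.0, ge=0)
    visits_per_screened: float = Field(1.0, ge=0)
    visits_per_referred: float = Field(1.0, ge=0)
    facility_mix: dict[str, float] = Field(
        default_factory=lambda: {k: 0.25 for k in FACILITY_LEVELS}
    )

    def build(self) -> OOPEProfile:
        return OOPEProfile(**self.model_dump())


class SimulationCfg(_Model):
    n_newborns: int = Field(100_000, ge=0)
    n_replicates: int = Field(1, ge=1)
    seed: int = 0


class DirectCostLineCfg(_Model):
    """One line of a direct-cost (annual health-system) table: either a plain
    annual amount or an apportioned monthly salary."""

    label: str
    annual_amount: Optional[float] = Field(None, ge=0)
    monthly_salary: Optional[float] = Field(None, ge=0)
    apportioning_statistic: float = Field(1.0, ge=0, le=1)

    def annual(self) -> float:
        if self.monthly_salary is not None:
            return staff_annual_cost(
                StaffCostLine(
                    role=self.label,
                    monthly_salary=self.monthly_salary,
                    apportioning_statistic=self.apportioning_statistic,
                )
            )
        return float(self.annual_amount or 0.0)


class RunConfig(_Model):
    """Fully-resolved run configuration for one cost-effectiveness analysis."""

    schema_version: int = 1
    cohort: CohortCfg = Field(default_factory=CohortCfg)
    modalities: list[ModalityCfg]
    intervention: str
    comparator: str
    performances: dict[str, PerformanceCfg] = Field(default_factory=dict)
    cascade_modes: dict[str, CascadeModeCfg] = Field(default_factory=dict)
    utilities: UtilitiesCfg = Field(default_factory=UtilitiesCfg)
    scenarios: list[ScenarioCfg] = Field(default_factory=list)
    oope: OOPECfg = Field(default_factory=OOPECfg)
    simulation: Optional[SimulationCfg] = None
    output_dir: str = "results"
    delta_qaly_override: Optional[float] = None
    unit_cost_overrides: dict[str, Optional[float]] = Field(default_factory=dict)
    direct_cost_tables: dict[str, list[DirectCostLineCfg]] = Field(default_factory=dict)
    reference_values: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _cross_references(self) -> "RunConfig":
        problems: list[str] = []
        names = [m.name for m in self.modalities]
        if len(set(names)) != len(names):
            problems.append(f"duplicate modality names: {names}")
        confirmatory = [m for m in self.modalities if m.role == "confirmatory"]
        first_line = [m for m in self.modalities if m.role == "first_line"]
        if len(confirmatory) != 1:
            problems.append(
                f"exactly one confirmatory modality required, found {len(confirmatory)}"
            )
        if len(first_line) < 2:
            problems.append(
                f"at least two first-line strategies required, found {len(first_line)}"
            )
        fl_names = {m.name for m in first_line}
        for label, ref in (("intervention", self.intervention), ("comparator", self.comparator)):
            if ref not in fl_names:
                problems.append(f"{label} {ref!r} is not a first-line modality")
        for key in list(self.performances) + list(self.cascade_modes) + list(
            self.unit_cost_overrides
        ) + list(self.direct_cost_tables):
            if key not in names:
                problems.append(f"referenced-but-undefined modality {key!r}")
        for name in fl_names:
            mode = self.cascade_modes.get(name, CascadeModeCfg())
            perf = self.performances.get(name)
            if mode.mode == "sens_spec" and (
                perf is None or perf.sensitivity is None or perf.specificity is None
            ):
                problems.append(
                    f"strategy {name!r} uses sens_spec mode but lacks sensitivity/specificity"
                )
        scen_names = [s.name for s in self.scenarios]
        if len(set(scen_names)) != len(scen_names):
            problems.append(f"duplicate scenario names: {scen_names}")
        if problems:
            raise ValueError("; ".join(problems))
        return self

    # convenience accessors -------------------------------------------------

    @property
    def first_line_names(self) -> list[str]:
        return [m.name for m in self.modalities if m.role == "first_line"]

    @property
    def confirmatory_name(self) -> str:
        return next(m.name for m in self.modalities if m.role == "confirmatory")

    def modality(self, name: str) -> ModalityCfg:
        return next(m for m in self.modalities if m.name == name)

    def cascade_mode_for(self, name: str) -> CascadeModeCfg:
        return self.cascade_modes.get(name, CascadeModeCfg())

    def performance_for(self, name: str) -> PerformanceCfg:
        return self.performances.get(name, PerformanceCfg())


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"  - {loc}: {e['msg']}")
    return "configuration invalid ({} violation{}):\n{}".format(
        len(lines), "s" if len(lines) != 1 else "", "\n".join(lines)
    )


def parse_config(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError(
            "configuration must be a mapping with keys: "
            + ", ".join(RunConfig.model_fields)
        )
    try:
        return RunConfig(**data)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from None


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"configuration file not found: {p}")
    text = p.read_text()
    if p.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        raise ConfigError(
            "configuration file is empty; required keys: modalities, intervention, "
            "comparator (plus optional cohort, performances, cascade_modes, utilities, "
            "scenarios, oope, simulation)"
        )
    return parse_config(data)


def load_paper_fixture() -> RunConfig:
    """The bundled 2019-20 parameter set (all printed model inputs)."""
    with resources.files("hearscreen.data").joinpath(PAPER_FIXTURE).open() as fh:
        return parse_config(yaml.safe_load(fh))


def paper_fixture_path() -> Path:
    return Path(str(resources.files("hearscreen.data").joinpath(PAPER_FIXTURE)))
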