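"""QALY, perspective-specific costs, ICER and cost-per-case computations.

QALYs are undiscounted lifetime values: utility weight per year times life
expectancy at birth, summed over the cohort.  Detected-and-treated children
are assigned the treated utility (default: the normal-hearing weight);
undetected hearing-loss cases carry the pooled HL weight for life.

Two perspectives are modeled: the health system (screening + confirmation +
lifetime treatment of detected cases) and the societal perspective, which
adds patient-side out-of-pocket expenditure (transport by facility level plus
wage loss over screening and referral visits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cascade import CascadeCounts, CohortSpec
from .util import InvalidParameterError, UndefinedMetricError, round_half_up

#: Mean transport cost (INR) per screening visit, by facility level.
DEFAULT_TRANSPORT = {
    "medical_college": 440.0,
    "district": 300.0,
    "community_health_centre": 207.0,
    "primary_health_centre": 99.0,
}

FACILITY_LEVELS = tuple(DEFAULT_TRANSPORT)


@dataclass(frozen=True)
class UtilityWeights:
    """Annual health-state utilities for the hearing states."""

    normal_hearing: float = 0.95
    hl_any: float = 0.77
    hl_unilateral: float = 0.85
    hl_bilateral: float = 0.69

    def __post_init__(self) -> None:
        for name in ("normal_hearing", "hl_any", "hl_unilateral", "hl_bilateral"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"utility {name} = {v} outside [0, 1]")
        if self.normal_hearing < self.hl_any:
            raise InvalidParameterError("normal-hearing utility must be >= HL utility")


@dataclass(frozen=True)
class TreatmentScenario:
    """Lifetime treatment pathway for a confirmed case (cochlear implant or hearing aid)."""

    name: str
    cost_per_treated_child: float
    treated_utility: float | None = None  # None -> normal_hearing weight

    def __post_init__(self) -> None:
        if self.cost_per_treated_child < 0:
            raise InvalidParameterError("cost_per_treated_child must be >= 0")


@dataclass(frozen=True)
class OOPEProfile:
    """Out-of-pocket expenditure profile: transport by facility level plus wage loss.

    ``facility_mix`` gives the share of visits at each level; per-visit cost is
    the mix-weighted mean transport plus the wage loss.
    """

    transport_per_visit_by_level: dict = field(
        default_factory=lambda: dict(DEFAULT_TRANSPORT)
    )
    wage_loss_per_visit: float = 0.0
    visits_per_screened: float = 1.0
    visits_per_referred: float = 1.0
    facility_mix: dict = field(
        default_factory=lambda: {k: 0.25 for k in FACILITY_LEVELS}
    )

    def __post_init__(self) -> None:
        if min(self.transport_per_visit_by_level.values(), default=0.0) < 0:
            raise InvalidParameterError("transport costs must be >= 0")
        if min(self.wage_loss_per_visit, self.visits_per_screened,
               self.visits_per_referred) < 0:
            raise InvalidParameterError("OOPE parameters must be >= 0")
        mix_sum = sum(self.facility_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise InvalidParameterError(f"facility_mix sums to {mix_sum}, not 1")
        unknown = set(self.facility_mix) - set(self.transport_per_visit_by_level)
        if unknown:
            raise InvalidParameterError(f"facility_mix has unknown levels: {sorted(unknown)}")

    @property
    def mean_transport_per_visit(self) -> float:
        return sum(
            w * self.transport_per_visit_by_level[lvl]
            for lvl, w in self.facility_mix.items()
        )

    @property
    def cost_per_visit(self) -> float:
        return self.mean_transport_per_visit + self.wage_loss_per_visit


@dataclass(frozen=True)
class CEAResult:
    """Incremental comparison of strategy A against strategy B."""

    cost_a: float
    cost_b: float
    qaly_a: float
    qaly_b: float
    delta_cost: float
    delta_qaly: float
    icer: float | None
    flag: str  # "", "dominant_a", "dominant_b", "cost_minimization", "equivalent"
    cost_per_case_detected_a: float | None = None
    cost_per_case_detected_b: float | None = None

    @property
    def icer_reported(self) -> float | None:
        """ICER rounded half-up to 2 decimals, the reporting convention."""
        return None if self.icer is None else round_half_up(self.icer, 2)


def strategy_qalys(
    cohort: CohortSpec,
    counts: CascadeCounts,
    weights: UtilityWeights,
    treated_utility: float | None = None,
    discount_rate: float = 0.0,
) -> float:
    """Undiscounted lifetime QALYs of the cohort under one screening strategy.

    Everyone except undetected HL cases accrues the normal-hearing (or treated)
    utility for a full life expectancy; undetected cases accrue the pooled HL
    utility.  A nonzero ``discount_rate`` applies standard annual discounting
    of the life-years stream (default 0: undiscounted).
    """
    u_normal = weights.normal_hearing
    u_treated = treated_utility if treated_utility is not None else u_normal
    le = cohort.life_expectancy_years
    if discount_rate > 0.0:
        # present value of an annuity over the (possibly fractional) lifespan
        le = (1.0 - (1.0 + discount_rate) ** (-le)) / discount_rate
    undetected = counts.under_detected
    detected = counts.confirmed_cases
    unaffected = cohort.size - detected - undetected
    return (unaffected * u_normal + detected * u_treated + undetected * weights.hl_any) * le


@dataclass(frozen=True)
class CostBreakdown:
    """Perspective total with its decomposition."""

    total: float
    screening: float
    treatment: float
    oope: float


def oope_total(cohort: CohortSpec, counts: CascadeCounts, oope: OOPEProfile) -> float:
    """Expected societal out-of-pocket expenditure for one strategy.

    Every screened newborn incurs ``visits_per_screened`` visits; every
    referred newborn incurs ``visits_per_referred`` additional visits.
    """
    per_visit = oope.cost_per_visit
    return (
        cohort.size * oope.visits_per_screened * per_visit
        + counts.referred * oope.visits_per_referred * per_visit
    )


def strategy_total_cost(
    perspective: str,
    scenario: TreatmentScenario,
    screening_cost: float,
    counts: CascadeCounts,
    oope: OOPEProfile | None = None,
    cohort: CohortSpec | None = None,
) -> CostBreakdown:
    """Total strategy cost under a perspective and treatment scenario.

    health_system = screening cost + confirmed cases x treatment cost;
    societal adds the OOPE total (requires ``oope`` and ``cohort``).
    """
    if perspective not in ("health_system", "societal"):
        raise InvalidParameterError(f"unknown perspective {perspective!r}")
    treatment = counts.confirmed_cases * scenario.cost_per_treated_child
    oope_cost = 0.0
    if perspective == "societal":
        if oope is None or cohort is None:
            raise InvalidParameterError("societal perspective requires oope and cohort")
        oope_cost = oope_total(cohort, counts, oope)
    return CostBreakdown(
        total=screening_cost + treatment + oope_cost,
        screening=screening_cost,
        treatment=treatment,
        oope=oope_cost,
    )


def icer(cost_a: float, cost_b: float, qaly_a: float, qaly_b: float) -> CEAResult:
    """Incremental cost-effectiveness ratio of strategy A vs strategy B.

    When the QALY difference is zero the comparison degenerates to cost
    minimization (flagged, no finite ICER); identical strategies are flagged
    equivalent.  A strategy that is cheaper and more effective dominates.
    """
    dc = cost_a - cost_b
    dq = qaly_a - qaly_b
    if dq == 0.0 and dc == 0.0:
        flag, value = "equivalent", None
    elif dq == 0.0:
        flag, value = "cost_minimization", None
    else:
        value = dc / dq
        if dc < 0 and dq > 0:
            flag = "dominant_a"
        elif dc > 0 and dq < 0:
            flag = "dominant_b"
        else:
            flag = ""
    return CEAResult(
        cost_a=cost_a, cost_b=cost_b, qaly_a=qaly_a, qaly_b=qaly_b,
        delta_cost=dc, delta_qaly=dq, icer=value, flag=flag,
    )


def cost_per_case_detected(total_screening_cost: float, confirmed_cases: float) -> float:
    """Program screening cost divided by confirmed cases."""
    if confirmed_cases <= 0:
        raise UndefinedMetricError("cost per detected case undefined: no confirmed cases")
    return total_screening_cost / confirmed_cases


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------

#: Registered scalar inputs for one-way sweeps.  Values are (section, field)
#: paths into a RunConfig; strategy-specific names take the pattern
#: "sensitivity.<name>", "specificity.<name>", "unit_cost.<name>",
#: "treatment_cost.<scenario>".
SWEEPABLE_PARAMETERS = (
    "prevalence_per_1000",
    "life_expectancy_years",
    "normal_hearing_utility",
    "hl_utility",
    "wage_loss_per_visit",
    "sensitivity.<strategy>",
    "specificity.<strategy>",
    "unit_cost.<modality>",
    "treatment_cost.<scenario>",
)


def one_way_sensitivity(
    config,
    parameter: str,
    bounds: tuple[float, float],
    steps: int,
    scenario: str | None = None,
    perspective: str = "health_system",
) -> pd.DataFrame:
    """Re-evaluate the full pipeline over a grid of one scalar input.

    The cascade is evaluated in sens_spec mode (observed mode pins the counts,
    so accuracy and prevalence sweeps would be inert) and the model-derived
    QALY difference is used.  Returns one row per grid point with the
    incremental cost, incremental QALYs and ICER of the intervention vs the
    comparator.
    """
    from .pipeline import evaluate_incremental  # deferred: pipeline imports this module

    if steps < 1:
        raise InvalidParameterError("steps must be >= 1")
    low, high = bounds
    rows = []
    for i in range(steps):
        value = low if steps == 1 else low + (high - low) * i / (steps - 1)
        cfg = _with_parameter(config, parameter, value)
        dc, dq, ratio = evaluate_incremental(
            cfg, scenario=scenario, perspective=perspective, force_sens_spec=True
        )
        rows.append({"value": value, "delta_cost": dc, "delta_qaly": dq, "icer": ratio})
    return pd.DataFrame(rows)


def _with_parameter(config, parameter: str, value: float):
    """Deep-copied RunConfig with one registered scalar input replaced."""
    cfg = config.model_copy(deep=True)
    name, _, key = parameter.partition(".")
    if name == "prevalence_per_1000":
        cfg.cohort.prevalence_per_1000 = value
    elif name == "life_expectancy_years":
        cfg.cohort.life_expectancy_years = value
    elif name == "normal_hearing_utility":
        cfg.utilities.normal_hearing = value
    elif name == "hl_utility":
        cfg.utilities.hl_any = value
    elif name == "wage_loss_per_visit":
        cfg.oope.wage_loss_per_visit = value
    elif name == "sensitivity" and key in cfg.performances:
        cfg.performances[key].sensitivity = value
    elif name == "specificity" and key in cfg.performances:
        cfg.performances[key].specificity = value
    elif name == "unit_cost" and key:
        cfg.unit_cost_overrides[key] = value
    elif name == "treatment_cost":
        matches = [s for s in cfg.scenarios if s.name == key]
        if not matches:
            raise InvalidParameterError(f"unknown treatment scenario {key!r}")
        matches[0].cost_per_treated_child = value
    else:
        raise InvalidParameterError(
            f"unknown sweep parameter {parameter!r}; registered: {SWEEPABLE_PARAMETERS}"
        )
    return cfg
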