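"""End-to-end pipeline: costing -> cascade -> health economics -> reports.

``run_pipeline`` executes the full deterministic analysis for a validated
``RunConfig`` and returns a :class:`ReportBundle` holding the costing table,
the per-branch cascade table, the CEA grid (perspective x scenario), the
discrepancy log and run metadata.  When Monte-Carlo settings are present the
individual-level simulator is run per strategy and the empirical branch
counts are tabulated against the deterministic expectations with their
binomial standard errors.

Every reported rounded number in the bundle has an unrounded counterpart, and
re-running with an identical configuration (and seed) writes byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cascade import (
    CascadeCounts,
    CascadeMode,
    expected_cascade,
    derived_ppv_npv,
    program_screening_cost,
)
from .cohort import SimulationConfig, estimate_metrics, simulate_cohort, simulate_observed_cohort
from .config import RunConfig
from .costing import costing_report, unit_cost
from .economics import (
    TreatmentScenario,
    cost_per_case_detected,
    icer,
    strategy_qalys,
    strategy_total_cost,
)
from .util import UndefinedMetricError, round_half_up

log = logging.getLogger("hearscreen")

#: |computed - reference| above this triggers a discrepancy entry (printed
#: reference values carry at most two decimals).
DISCREPANCY_TOLERANCE = 0.005


@dataclass(frozen=True)
class Discrepancy:
    key: str
    computed: float
    reference: float
    note: str = ""

    @property
    def difference(self) -> float:
        return self.computed - self.reference

    def __str__(self) -> str:
        s = (f"{self.key}: computed {self.computed:,.2f} vs reference "
             f"{self.reference:,.2f} (diff {self.difference:+,.2f})")
        return f"{s} — {self.note}" if self.note else s


@dataclass
class ReportBundle:
    """Everything one analysis run produces."""

    costing_table: pd.DataFrame
    cascade_table: pd.DataFrame
    cea_table: pd.DataFrame
    discrepancy_log: list[Discrepancy]
    run_metadata: dict
    monte_carlo_table: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def write(self, output_dir) -> Path:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.costing_table.to_csv(out / "costing.csv")
        self.cascade_table.to_csv(out / "cascade.csv", index=False)
        self.cea_table.to_csv(out / "cea.csv", index=False)
        if self.monte_carlo_table is not None:
            self.monte_carlo_table.to_csv(out / "monte_carlo.csv", index=False)
        (out / "discrepancies.txt").write_text(
            "\n".join(str(d) for d in self.discrepancy_log) + "\n"
            if self.discrepancy_log else "no discrepancies detected\n"
        )
        payload = {
            "run_metadata": self.run_metadata,
            "extras": self.extras,
            "discrepancies": [
                {"key": d.key, "computed": d.computed, "reference": d.reference,
                 "difference": d.difference, "note": d.note}
                for d in self.discrepancy_log
            ],
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return out


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


def _check(
    log_entries: list[Discrepancy],
    references: dict[str, float],
    key: str,
    computed: float,
    note: str = "",
) -> None:
    ref = references.get(key)
    if ref is not None and abs(computed - ref) > DISCREPANCY_TOLERANCE:
        log_entries.append(Discrepancy(key=key, computed=computed, reference=ref, note=note))


def _strategy_counts(config: RunConfig, name: str, force_sens_spec: bool = False) -> CascadeCounts:
    cohort = config.cohort.build()
    mode_cfg = config.cascade_mode_for(name)
    mode = CascadeMode() if force_sens_spec else mode_cfg.build()
    return expected_cascade(
        cohort,
        config.performance_for(name).build(),
        config.performance_for(config.confirmatory_name).build(),
        mode,
    )


def _unit_costs(config: RunConfig) -> dict[str, tuple[float, float]]:
    """name -> (unrounded, reported) unit cost, honoring explicit overrides."""
    out = {}
    for mcfg in config.modalities:
        override = config.unit_cost_overrides.get(mcfg.name)
        if override is not None:
            out[mcfg.name] = (float(override), round_half_up(override))
        else:
            uc = unit_cost(mcfg.build())
            out[mcfg.name] = (uc.unrounded, float(uc.reported))
    return out


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full deterministic analysis (plus Monte-Carlo validation if configured)."""
    cohort = config.cohort.build()
    utilities = config.utilities.build()
    oope = config.oope.build()
    refs = config.reference_values
    discrepancies: list[Discrepancy] = []

    # ----- costing -----
    modalities = [m.build() for m in config.modalities]
    costing = costing_report(modalities)
    units = _unit_costs(config)
    for m in modalities:
        _check(discrepancies, refs, f"total_annual_cost.{m.name}", m.inventory.total,
               "annual inventory sum vs printed total")
        _check(discrepancies, refs, f"unit_cost.{m.name}", units[m.name][1],
               "reported unit cost per screen")
    for name, lines in config.direct_cost_tables.items():
        total = sum(line.annual() for line in lines)
        _check(discrepancies, refs, f"direct_cost_total.{name}", total,
               "sum of direct health-system cost lines vs printed total")
    confirm_name = config.confirmatory_name
    confirm_unit = units[confirm_name][0]

    # ----- cascade + screening cost + QALYs per strategy -----
    strategies = config.first_line_names
    per_strategy: dict[str, dict] = {}
    cascade_rows = []
    for name in strategies:
        counts = _strategy_counts(config, name)
        cost = program_screening_cost(cohort, units[name][0], confirm_unit, counts)
        qalys = strategy_qalys(cohort, counts, utilities)
        try:
            pv = derived_ppv_npv(counts)
        except UndefinedMetricError:
            pv = None
        try:
            per_case = cost_per_case_detected(cost.total, counts.confirmed_cases)
        except UndefinedMetricError:
            per_case = None
        per_strategy[name] = {
            "counts": counts, "cost": cost, "qalys": qalys,
            "ppv_npv": pv, "cost_per_case": per_case,
        }
        _check(discrepancies, refs, f"screening_program_cost.{name}", cost.total,
               "N x unrounded unit cost + referrals x confirmation unit cost")
        _check(discrepancies, refs, f"qalys.{name}", round_half_up(qalys, 2),
               "model-derived cohort QALYs")
        if per_case is not None:
            _check(discrepancies, refs, f"cost_per_case_detected.{name}",
                   round_half_up(per_case, 2),
                   "quotient of screening cost and detected cases vs printed figure")
        if counts.mode == "observed":
            implied = counts.diseased_implied
            if abs(implied - cohort.diseased) > DISCREPANCY_TOLERANCE:
                discrepancies.append(Discrepancy(
                    key=f"implied_diseased.{name}",
                    computed=implied, reference=cohort.diseased,
                    note="observed cascade counts imply a different case load than "
                         "the configured prevalence",
                ))
        rounded = counts.rounded()
        for branch, screen_n, branch_cost in (
            ("A", counts.screen_true_positive, cost.branch_a),
            ("B", counts.screen_false_negative, cost.branch_b),
            ("C", counts.screen_false_positive, cost.branch_c),
            ("D", counts.screen_true_negative, cost.branch_d),
        ):
            cascade_rows.append({
                "strategy": name, "row": f"branch_{branch}", "mode": counts.mode,
                "count": screen_n, "count_rounded": round_half_up(screen_n),
                "cost": branch_cost,
            })
        cascade_rows.append({
            "strategy": name, "row": "summary", "mode": counts.mode,
            "count": cohort.size, "count_rounded": cohort.size, "cost": cost.total,
            "referred": rounded.referred, "confirmed_cases": rounded.confirmed_cases,
            "false_referrals": rounded.false_referrals,
            "under_detected": rounded.under_detected,
            "ppv": None if pv is None else pv.ppv,
            "npv": None if pv is None else pv.npv,
            "qalys": qalys,
            "cost_per_case_detected": per_case,
        })
    cascade_table = pd.DataFrame(cascade_rows)

    # ----- CEA grid -----
    a, b = config.intervention, config.comparator
    dq_model = per_strategy[a]["qalys"] - per_strategy[b]["qalys"]
    dq_used = config.delta_qaly_override if config.delta_qaly_override is not None else dq_model
    if config.delta_qaly_override is not None:
        _check(discrepancies, refs, "delta_qaly", round_half_up(dq_model, 2),
               "model-derived QALY difference vs configured override")
    cea_rows = []
    for perspective in ("health_system", "societal"):
        for scen_cfg in config.scenarios:
            scenario = scen_cfg.build()
            totals = {}
            for name in (a, b):
                totals[name] = strategy_total_cost(
                    perspective, scenario, per_strategy[name]["cost"].total,
                    per_strategy[name]["counts"], oope=oope, cohort=cohort,
                )
                _check(discrepancies, refs,
                       f"total_cost.{perspective}.{scenario.name}.{name}",
                       round_half_up(totals[name].total, 2),
                       "computed perspective total vs printed figure")
            res = icer(totals[a].total, totals[b].total,
                       per_strategy[a]["qalys"], per_strategy[b]["qalys"])
            icer_override = (
                None if dq_used == 0 else round_half_up(res.delta_cost / dq_used, 2)
            )
            cea_rows.append({
                "perspective": perspective, "scenario": scenario.name,
                f"cost_{a}": totals[a].total, f"cost_{b}": totals[b].total,
                f"qaly_{a}": res.qaly_a, f"qaly_{b}": res.qaly_b,
                "delta_cost": res.delta_cost,
                "delta_qaly_model": dq_model, "delta_qaly_used": dq_used,
                "icer_model": res.icer_reported, "icer": icer_override,
                "flag": res.flag,
            })
    # screening-only (no treatment) comparison — the headline ICER
    dc_screen = per_strategy[a]["cost"].total - per_strategy[b]["cost"].total
    final_icer = None if dq_used == 0 else round_half_up(dc_screen / dq_used, 2)
    final_icer_model = None if dq_model == 0 else round_half_up(dc_screen / dq_model, 2)
    flag = icer(per_strategy[a]["cost"].total, per_strategy[b]["cost"].total,
                per_strategy[a]["qalys"], per_strategy[b]["qalys"]).flag
    cea_rows.append({
        "perspective": "health_system", "scenario": "screening_only",
        f"cost_{a}": per_strategy[a]["cost"].total,
        f"cost_{b}": per_strategy[b]["cost"].total,
        f"qaly_{a}": per_strategy[a]["qalys"], f"qaly_{b}": per_strategy[b]["qalys"],
        "delta_cost": dc_screen,
        "delta_qaly_model": dq_model, "delta_qaly_used": dq_used,
        "icer_model": final_icer_model, "icer": final_icer, "flag": flag,
    })
    cea_table = pd.DataFrame(cea_rows)
    if final_icer is not None:
        _check(discrepancies, refs, "final_icer", final_icer,
               "screening-only incremental cost / QALY difference")

    # ----- Monte-Carlo validation -----
    mc_table = None
    if config.simulation is not None:
        mc_table = monte_carlo_validation(config)

    metadata = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "seed": None if config.simulation is None else config.simulation.seed,
        "intervention": a,
        "comparator": b,
        "cascade_modes": {
            name: config.cascade_mode_for(name).mode for name in strategies
        },
    }
    extras = {
        "unit_costs": {name: {"unrounded": u, "reported": r} for name, (u, r) in units.items()},
        "per_strategy": {
            name: {
                "counts": info["counts"].as_dict(),
                "screening_cost": info["cost"].as_dict(),
                "qalys": info["qalys"],
                "cost_per_case_detected": info["cost_per_case"],
                "ppv": None if info["ppv_npv"] is None else info["ppv_npv"].ppv,
                "npv": None if info["ppv_npv"] is None else info["ppv_npv"].npv,
            }
            for name, info in per_strategy.items()
        },
        "delta_qaly_model": dq_model,
        "delta_qaly_used": dq_used,
        "final_icer": final_icer,
        "final_icer_model": final_icer_model,
    }
    log.info("pipeline complete: final ICER %s (model %s), %d discrepancies",
             final_icer, final_icer_model, len(discrepancies))
    return ReportBundle(
        costing_table=costing,
        cascade_table=cascade_table,
        cea_table=cea_table,
        discrepancy_log=discrepancies,
        run_metadata=metadata,
        monte_carlo_table=mc_table,
        extras=extras,
    )


def monte_carlo_validation(config: RunConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate each first-line strategy and tabulate empirical vs expected counts.

    Expected counts come from the deterministic cascade scaled to the
    simulated cohort size; the ``z`` column is the deviation in binomial
    standard errors, the convergence-rate check for the Monte-Carlo oracle.
    """
    sim = config.simulation or SimulationConfig()
    base_seed = sim.seed if seed is None else seed
    cohort = config.cohort.build()
    rows = []
    for k, name in enumerate(config.first_line_names):
        mode_cfg = config.cascade_mode_for(name)
        expected = _strategy_counts(config, name)
        n = sim.n_newborns
        scale = n / cohort.size if cohort.size else 0.0
        strategy_seed = base_seed + k
        if mode_cfg.mode == "observed":
            infants = simulate_observed_cohort(
                n,
                referred=mode_cfg.observed_referred * scale,
                confirmed=mode_cfg.observed_confirmed * scale,
                under_detected=mode_cfg.observed_under_detected * scale,
                seed=strategy_seed,
            )
        else:
            sim_cfg = SimulationConfig(
                n_newborns=n,
                prevalence_per_1000=config.cohort.prevalence_per_1000,
                first_line=config.performance_for(name).build(),
                confirmatory=config.performance_for(config.confirmatory_name).build(),
                seed=strategy_seed,
            )
            infants = simulate_cohort(sim_cfg)
        empirical = estimate_metrics(infants).counts
        for quantity in ("screen_true_positive", "screen_false_negative",
                         "screen_false_positive", "screen_true_negative",
                         "referred", "confirmed_cases"):
            exp_n = getattr(expected, quantity) * scale
            emp_n = getattr(empirical, quantity)
            p = exp_n / n if n else 0.0
            se = float(np.sqrt(n * p * (1.0 - p)))
            z = 0.0 if se == 0 else (emp_n - exp_n) / se
            rows.append({
                "strategy": name, "quantity": quantity, "n": n,
                "expected": exp_n, "empirical": emp_n, "se": se, "z": z,
            })
    return pd.DataFrame(rows)


def evaluate_incremental(
    config: RunConfig,
    scenario: str | None = None,
    perspective: str = "health_system",
    force_sens_spec: bool = False,
) -> tuple[float, float, float | None]:
    """(delta_cost, delta_qaly, icer) of intervention vs comparator.

    The workhorse behind one-way sensitivity sweeps: re-derives unit costs,
    cascades, QALYs and perspective totals from the configuration and returns
    the incremental comparison using the model-derived QALY difference.
    """
    cohort = config.cohort.build()
    utilities = config.utilities.build()
    oope = config.oope.build()
    units = _unit_costs(config)
    confirm_unit = units[config.confirmatory_name][0]
    if scenario is None:
        scen = (config.scenarios[0].build() if config.scenarios
                else TreatmentScenario(name="none", cost_per_treated_child=0.0))
    else:
        scen = next(s for s in config.scenarios if s.name == scenario).build()
    totals, qalys = {}, {}
    for name in (config.intervention, config.comparator):
        counts = _strategy_counts(config, name, force_sens_spec=force_sens_spec)
        cost = program_screening_cost(cohort, units[name][0], confirm_unit, counts)
        totals[name] = strategy_total_cost(
            perspective, scen, cost.total, counts, oope=oope, cohort=cohort
        ).total
        qalys[name] = strategy_qalys(cohort, counts, utilities)
    res = icer(totals[config.intervention], totals[config.comparator],
               qalys[config.intervention], qalys[config.comparator])
    return res.delta_cost, res.delta_qaly, res.icer
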