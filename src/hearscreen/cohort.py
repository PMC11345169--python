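"""Individual-level birth-cohort simulator — the Monte-Carlo oracle.

Generates cohorts with exactly the statistical structure the decision tree
assumes: hearing-loss status is Bernoulli at the stated prevalence, and the
screen and confirmation outcomes are conditionally independent given true
status, with refer probability equal to the sensitivity for affected and one
minus the specificity for unaffected newborns.  Confirmation is applied only
to referred infants.

All randomness flows through a single ``numpy.random.Generator`` seeded from
``SimulationConfig.seed``; a fixed seed yields a byte-identical cohort.
Cohorts are held as pandas DataFrames, one row per infant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import CascadeCounts, PERFECT_TEST, TestPerformance
from .economics import FACILITY_LEVELS, OOPEProfile
from .util import InvalidParameterError

#: Column layout of a simulated cohort frame.
COHORT_COLUMNS = (
    "hl_status", "screen_result", "confirmation_result", "facility_level",
    "oope_incurred",
)


@dataclass
class SimulationConfig:
    """Parameters of one Monte-Carlo cohort run."""

    n_newborns: int = 100_000
    prevalence_per_1000: float = 5.0
    first_line: TestPerformance = field(
        default_factory=lambda: TestPerformance(sensitivity=1.0, specificity=0.97)
    )
    confirmatory: TestPerformance = field(default_factory=lambda: PERFECT_TEST)
    seed: int = 0
    n_replicates: int = 1
    facility_mix: dict = field(default_factory=lambda: {k: 0.25 for k in FACILITY_LEVELS})

    def __post_init__(self) -> None:
        if self.n_newborns < 0:
            raise InvalidParameterError("n_newborns must be >= 0")
        if not 0.0 <= self.prevalence_per_1000 <= 1000.0:
            raise InvalidParameterError("prevalence_per_1000 must be in [0, 1000]")
        if self.first_line.sensitivity is None or self.first_line.specificity is None:
            raise InvalidParameterError("first_line needs sensitivity and specificity")
        mix_sum = sum(self.facility_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise InvalidParameterError(f"facility_mix sums to {mix_sum}, not 1")
        if any(not 0.0 <= v <= 1.0 for v in self.facility_mix.values()):
            raise InvalidParameterError("facility_mix fractions must be in [0, 1]")


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one cohort of newborns through screen and confirmation.

    Returns a DataFrame with one row per infant: boolean ``hl_status``,
    ``screen_result`` in {pass, refer}, ``confirmation_result`` in
    {confirmed, not_confirmed, not_tested} (not_tested iff the screen passed),
    the facility level drawn from the configured mix, and a zero
    ``oope_incurred`` column filled in by :func:`simulate_oope`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_newborns
    p = config.prevalence_per_1000 / 1000.0
    hl = rng.random(n) < p
    sens = config.first_line.sensitivity
    spec = config.first_line.specificity
    refer_prob = np.where(hl, sens, 1.0 - spec)
    refer = rng.random(n) < refer_prob

    conf_sens = config.confirmatory.sensitivity if config.confirmatory.sensitivity is not None else 1.0
    conf_spec = config.confirmatory.specificity if config.confirmatory.specificity is not None else 1.0
    confirm_prob = np.where(hl, conf_sens, 1.0 - conf_spec)
    confirm_draw = rng.random(n) < confirm_prob

    confirmation = np.full(n, "not_tested", dtype=object)
    confirmation[refer & confirm_draw] = "confirmed"
    confirmation[refer & ~confirm_draw] = "not_confirmed"

    levels = list(config.facility_mix)
    probs = np.array([config.facility_mix[k] for k in levels], dtype=float)
    facility = rng.choice(np.array(levels, dtype=object), size=n, p=probs)

    return pd.DataFrame(
        {
            "hl_status": hl,
            "screen_result": np.where(refer, "refer", "pass"),
            "confirmation_result": confirmation,
            "facility_level": facility,
            "oope_incurred": np.zeros(n),
        }
    )


def simulate_observed_cohort(
    n: int,
    referred: float,
    confirmed: float,
    under_detected: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort drawn from the observed-scenario categorical model.

    Each infant falls in one of four categories with probabilities calibrated
    so the expected referred/confirmed/under-detected counts match the
    observed figures — the fixture-parity counterpart of the observed cascade
    mode.
    """
    if confirmed > referred or min(referred, confirmed, under_detected) < 0:
        raise InvalidParameterError("inconsistent observed counts")
    if referred + under_detected > n:
        raise InvalidParameterError("observed counts exceed cohort size")
    rng = np.random.default_rng(seed)
    probs = np.array([
        confirmed / n,               # confirmed HL case
        (referred - confirmed) / n,  # false referral
        under_detected / n,          # screen-missed HL
        1.0 - (referred + under_detected) / n,
    ])
    cat = rng.choice(4, size=n, p=probs)
    hl = (cat == 0) | (cat == 2)
    refer = (cat == 0) | (cat == 1)
    confirmation = np.full(n, "not_tested", dtype=object)
    confirmation[cat == 0] = "confirmed"
    confirmation[cat == 1] = "not_confirmed"
    facility = rng.choice(np.array(FACILITY_LEVELS, dtype=object), size=n)
    return pd.DataFrame(
        {
            "hl_status": hl,
            "screen_result": np.where(refer, "refer", "pass"),
            "confirmation_result": confirmation,
            "facility_level": facility,
            "oope_incurred": np.zeros(n),
        }
    )


@dataclass(frozen=True)
class EmpiricalMetrics:
    """Empirical test performance and cascade counts from a simulated cohort."""

    performance: TestPerformance
    counts: CascadeCounts
    flags: frozenset


def estimate_metrics(infants: pd.DataFrame) -> EmpiricalMetrics:
    """Cross-tabulate simulated truth vs outcomes into empirical metrics.

    Degenerate denominators (no diseased, no referrals, ...) produce ``None``
    metrics plus a flag instead of raising, so replicate sweeps never abort.
    """
    if len(infants) == 0:
        raise InvalidParameterError("empty cohort")
    hl = infants["hl_status"].to_numpy(dtype=bool)
    refer = (infants["screen_result"] == "refer").to_numpy()
    confirmed = (infants["confirmation_result"] == "confirmed").to_numpy()

    tp = int((hl & refer).sum())
    fn = int((hl & ~refer).sum())
    fp = int((~hl & refer).sum())
    tn = int((~hl & ~refer).sum())
    n_confirmed = int(confirmed.sum())

    flags = set()
    sens = spec = ppv = npv = None
    if tp + fn > 0:
        sens = tp / (tp + fn)
    else:
        flags.add("sensitivity_undefined")
    if fp + tn > 0:
        spec = tn / (fp + tn)
    else:
        flags.add("specificity_undefined")
    if tp + fp > 0:
        ppv = n_confirmed / (tp + fp)
    else:
        flags.add("ppv_undefined")
    if tn + fn > 0:
        npv = tn / (tn + fn)
    else:
        flags.add("npv_undefined")

    counts = CascadeCounts(
        screen_true_positive=float(tp),
        screen_false_negative=float(fn),
        screen_false_positive=float(fp),
        screen_true_negative=float(tn),
        referred=float(tp + fp),
        confirmed_cases=float(n_confirmed),
        false_referrals=float(tp + fp - n_confirmed),
        under_detected=float((hl & ~confirmed).sum()),
        mode="empirical",
    )
    return EmpiricalMetrics(
        performance=TestPerformance(sensitivity=sens, specificity=spec, ppv=ppv, npv=npv),
        counts=counts,
        flags=frozenset(flags),
    )


def simulate_oope(
    infants: pd.DataFrame,
    oope: OOPEProfile,
    seed: int = 0,
    dispersion_cv: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Accrue out-of-pocket expenditure per infant; returns (frame, total).

    Deterministic per facility level unless ``dispersion_cv`` (coefficient of
    variation of a per-infant Gamma multiplier) is supplied.
    """
    transport = infants["facility_level"].map(oope.transport_per_visit_by_level).to_numpy(dtype=float)
    per_visit = transport + oope.wage_loss_per_visit
    refer = (infants["screen_result"] == "refer").to_numpy()
    visits = oope.visits_per_screened + np.where(refer, oope.visits_per_referred, 0.0)
    cost = per_visit * visits
    if dispersion_cv is not None and dispersion_cv > 0:
        rng = np.random.default_rng(seed)
        shape = 1.0 / dispersion_cv**2
        cost = cost * rng.gamma(shape, 1.0 / shape, size=len(cost))
    out = infants.copy()
    out["oope_incurred"] = cost
    return out, float(cost.sum())


def write_cohort_csv(infants: pd.DataFrame, path) -> None:
    infants.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidParameterError(f"cohort CSV missing columns: {sorted(missing)}")
    df["hl_status"] = df["hl_status"].astype(bool)
    return df
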