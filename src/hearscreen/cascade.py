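"""Four-branch decision-tree cascade for a screen-and-confirm strategy.

Each first-line device defines four branches over a birth cohort of size N
with D expected congenital hearing-loss (HL) cases:

  A  screen-positive, truly HL      -> confirmed by BERA (cost: screen + confirm)
  B  screen-negative, truly HL      -> discharged, under-detected (cost: screen)
  C  screen-positive, normal        -> false referral to BERA (cost: screen + confirm)
  D  screen-negative, normal        -> discharged (cost: screen)

Two parameterizations are supported.  ``sens_spec`` derives the branch counts
from prevalence, sensitivity and specificity — the self-consistent textbook
tree.  ``observed`` pins the referred/confirmed counts to externally observed
detection figures (e.g. from a feasibility study) and back-fills the branches
around them; this is required because observed referral patterns in field data
are generally not reproducible from bench sensitivity/specificity.

Counts are real-valued expectations; rounding happens only in reporting views.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .util import InvalidParameterError, UndefinedMetricError, round_half_up


@dataclass(frozen=True)
class CohortSpec:
    """Birth cohort entering the screening program."""

    size: float = 100_000
    prevalence_per_1000: float = 5.0
    life_expectancy_years: float = 69.2

    def __post_init__(self) -> None:
        if self.size < 0:
            raise InvalidParameterError("cohort size must be >= 0")
        if not 0.0 <= self.prevalence_per_1000 <= 1000.0:
            raise InvalidParameterError("prevalence_per_1000 must be in [0, 1000]")
        if self.life_expectancy_years < 0:
            raise InvalidParameterError("life_expectancy_years must be >= 0")

    @property
    def prevalence(self) -> float:
        return self.prevalence_per_1000 / 1000.0

    @property
    def diseased(self) -> float:
        """Expected number of HL cases, D = N x prevalence."""
        return self.size * self.prevalence


@dataclass(frozen=True)
class TestPerformance:
    """Diagnostic accuracy of a test; PPV/NPV optional (observed or derived)."""

    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} = {v} outside [0, 1]")


#: A perfect confirmatory test — the default model for gold-standard BERA.
PERFECT_TEST = TestPerformance(sensitivity=1.0, specificity=1.0)


@dataclass(frozen=True)
class CascadeMode:
    """Which parameterization drives the cascade.

    In ``observed`` mode the referred and confirmed counts are inputs;
    ``observed_under_detected`` carries screen-missed HL cases that later
    surfaced (0 if none are known).
    """

    mode: str = "sens_spec"
    observed_referred: float | None = None
    observed_confirmed: float | None = None
    observed_under_detected: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("sens_spec", "observed"):
            raise InvalidParameterError(f"unknown cascade mode {self.mode!r}")
        if self.mode == "observed":
            if self.observed_referred is None or self.observed_confirmed is None:
                raise InvalidParameterError(
                    "observed mode requires observed_referred and observed_confirmed"
                )
            if self.observed_confirmed > self.observed_referred:
                raise InvalidParameterError(
                    "observed_confirmed cannot exceed observed_referred"
                )
            if min(self.observed_referred, self.observed_confirmed,
                   self.observed_under_detected) < 0:
                raise InvalidParameterError("observed counts must be >= 0")


@dataclass(frozen=True)
class CascadeCounts:
    """Expected counts through one strategy's screen-and-confirm cascade."""

    screen_true_positive: float
    screen_false_negative: float
    screen_false_positive: float
    screen_true_negative: float
    referred: float
    confirmed_cases: float
    false_referrals: float
    under_detected: float
    mode: str = "sens_spec"

    @property
    def total(self) -> float:
        return (self.screen_true_positive + self.screen_false_negative
                + self.screen_false_positive + self.screen_true_negative)

    @property
    def diseased_implied(self) -> float:
        """Diseased count implied by the branch structure (TP + FN)."""
        return self.screen_true_positive + self.screen_false_negative

    def rounded(self) -> "CascadeCounts":
        """Half-up integer view for reporting; invariants may break by rounding."""
        return replace(
            self,
            **{
                f: round_half_up(getattr(self, f))
                for f in (
                    "screen_true_positive", "screen_false_negative",
                    "screen_false_positive", "screen_true_negative",
                    "referred", "confirmed_cases", "false_referrals",
                    "under_detected",
                )
            },
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "screen_true_positive": self.screen_true_positive,
            "screen_false_negative": self.screen_false_negative,
            "screen_false_positive": self.screen_false_positive,
            "screen_true_negative": self.screen_true_negative,
            "referred": self.referred,
            "confirmed_cases": self.confirmed_cases,
            "false_referrals": self.false_referrals,
            "under_detected": self.under_detected,
            "mode": self.mode,
        }


def expected_cascade(
    cohort: CohortSpec,
    first_line: TestPerformance,
    confirmatory: TestPerformance = PERFECT_TEST,
    mode: CascadeMode = CascadeMode(),
) -> CascadeCounts:
    """Expected branch counts for one strategy.

    sens_spec mode:
        TP = D*sens, FN = D*(1-sens), FP = (N-D)*(1-spec), TN = (N-D)*spec,
        referred = TP + FP, confirmed = TP * confirmatory sensitivity.

    observed mode:
        referred/confirmed (and known under-detected cases) are taken as
        given; the screen branches are back-filled so that the conservation
        invariants hold against the cascade-implied diseased count
        confirmed + under_detected.  Inconsistent inputs (negative back-filled
        counts) raise rather than being clamped.
    """
    n = cohort.size
    d = cohort.diseased
    if mode.mode == "sens_spec":
        if first_line.sensitivity is None or first_line.specificity is None:
            raise InvalidParameterError(
                "sens_spec mode requires first-line sensitivity and specificity"
            )
        conf_sens = confirmatory.sensitivity if confirmatory.sensitivity is not None else 1.0
        tp = d * first_line.sensitivity
        fn = d * (1.0 - first_line.sensitivity)
        fp = (n - d) * (1.0 - first_line.specificity)
        tn = (n - d) * first_line.specificity
        referred = tp + fp
        confirmed = tp * conf_sens
        return CascadeCounts(
            screen_true_positive=tp,
            screen_false_negative=fn,
            screen_false_positive=fp,
            screen_true_negative=tn,
            referred=referred,
            confirmed_cases=confirmed,
            false_referrals=referred - confirmed,
            under_detected=d - confirmed,
            mode="sens_spec",
        )

    # observed mode
    referred = float(mode.observed_referred)
    confirmed = float(mode.observed_confirmed)
    under = float(mode.observed_under_detected)
    if cohort.prevalence == 0.0 and confirmed > 0:
        raise InvalidParameterError(
            "observed confirmed cases > 0 are inconsistent with zero prevalence"
        )
    tn = n - referred - under
    if tn < 0:
        raise InvalidParameterError(
            f"observed counts exceed cohort size: referred {referred} + "
            f"under-detected {under} > N {n}"
        )
    return CascadeCounts(
        screen_true_positive=confirmed,
        screen_false_negative=under,
        screen_false_positive=referred - confirmed,
        screen_true_negative=tn,
        referred=referred,
        confirmed_cases=confirmed,
        false_referrals=referred - confirmed,
        under_detected=under,
        mode="observed",
    )


def derived_ppv_npv(counts: CascadeCounts) -> TestPerformance:
    """Predictive values implied by the cascade counts.

    PPV is the fraction of referrals that end as confirmed HL; NPV the
    fraction of screen-negatives that are truly normal.
    """
    if counts.referred <= 0:
        raise UndefinedMetricError("PPV undefined: no referrals")
    negatives = counts.screen_true_negative + counts.screen_false_negative
    if negatives <= 0:
        raise UndefinedMetricError("NPV undefined: no screen-negative newborns")
    return TestPerformance(
        ppv=counts.confirmed_cases / counts.referred,
        npv=counts.screen_true_negative / negatives,
    )


@dataclass(frozen=True)
class ProgramCost:
    """Screening-and-confirmation cost of one strategy, with branch decomposition."""

    total: float
    branch_a: float  # screen + confirm, truly HL
    branch_b: float  # screen only, missed HL
    branch_c: float  # screen + confirm, false referral
    branch_d: float  # screen only, truly normal

    def as_dict(self) -> dict[str, float]:
        return {
            "total": self.total,
            "branch_a": self.branch_a,
            "branch_b": self.branch_b,
            "branch_c": self.branch_c,
            "branch_d": self.branch_d,
        }


def program_screening_cost(
    cohort: CohortSpec,
    first_line_unit_cost: float,
    confirmatory_unit_cost: float,
    counts: CascadeCounts,
) -> ProgramCost:
    """Total program cost: every newborn screened once, every referral confirmed once.

    total = N x first-line unit cost + referred x confirmatory unit cost.
    Unit costs must be the unrounded values so downstream totals do not
    accumulate rounding error.
    """
    if first_line_unit_cost < 0 or confirmatory_unit_cost < 0:
        raise InvalidParameterError("unit costs must be >= 0")
    screen = first_line_unit_cost
    confirm = confirmatory_unit_cost
    a = counts.screen_true_positive * (screen + confirm)
    b = counts.screen_false_negative * screen
    c = counts.screen_false_positive * (screen + confirm)
    d = counts.screen_true_negative * screen
    total = cohort.size * screen + counts.referred * confirm
    return ProgramCost(total=total, branch_a=a, branch_b=b, branch_c=c, branch_d=d)
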