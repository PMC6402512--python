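"""The multistage (Armitage-Doll) log-log fit and step-count conversion.

Under a multistage model, disease manifests after n sequential
rate-limiting transitions with per-step rates λ₁…λₙ.  In the rare-event
regime the age-specific incidence rate satisfies

    ln i(t) = (n - 1) ln t + c,        c = ln(λ₁λ₂…λₙ) + const,

so an ordinary least-squares fit of log incidence against log age over
5-year age bands estimates n - 1 as its slope; the adjusted R² of the
same fit is the linearity diagnostic.  Bands with little exposure or
very low rates are excluded first, because rates in the extremes of the
age distribution are unstable: the defaults drop bands with fewer than
500 person-years or a rate below 1 per 1000 person-years.

Natural logarithms are used throughout and are not configurable: the
slope is base-invariant but the intercept is not, and a silently mixed
base would corrupt the constant c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm

from .cohort import CohortTable
from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    SlopeDomainError,
    UndefinedRateError,
)
from .persontime import AgeBand, BandTable, accrue_person_time, total_person_years

AgePoint = Literal["midpoint", "lower", "mean-py"]

MIN_BANDS_FOR_FIT = 3


@dataclass(frozen=True)
class BandFilterConfig:
    """Retention thresholds for age bands (both inclusive minima)."""

    min_person_years: float = 500.0
    min_rate: float = 0.001  # events per person-year

    def __post_init__(self) -> None:
        if self.min_person_years < 0 or self.min_rate < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping for bands and participants dropped by the rate filter."""

    excluded_bands: int
    excluded_person_years: float
    excluded_participants: int  # exit age below the first retained band
    first_retained_lower: float


@dataclass
class MultistageFit:
    """Result of the log incidence vs log age regression.

    ``slope`` estimates n - 1; ``n_steps`` is the slope converted to a
    whole number of steps (nearest integer, halves away from zero).
    ``points`` holds the (ln age, ln rate) pairs actually fitted.
    """

    slope: float
    slope_ci_low: float
    slope_ci_high: float
    intercept: float
    adjusted_r2: float
    r2: float
    n_steps: int
    points: list[tuple[float, float]]
    age_point: str = "midpoint"
    excluded_person_years: float = 0.0
    excluded_participants: int = 0
    n_events: int = 0
    n_participants: int = 0

    @property
    def n_steps_ci(self) -> tuple[int, int]:
        """Step-count bounds derived from the slope CI (a convenience)."""
        return (steps_from_slope(self.slope_ci_low), steps_from_slope(self.slope_ci_high))

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_ci_low": self.slope_ci_low,
            "slope_ci_high": self.slope_ci_high,
            "intercept": self.intercept,
            "adjusted_r2": self.adjusted_r2,
            "r2": self.r2,
            "n_steps": self.n_steps,
            "n_steps_ci": list(self.n_steps_ci),
            "age_point": self.age_point,
            "k_points": len(self.points),
            "points": [{"log_age": x, "log_rate": y} for x, y in self.points],
            "excluded_person_years": self.excluded_person_years,
            "excluded_participants": self.excluded_participants,
            "n_events": self.n_events,
            "n_participants": self.n_participants,
        }

    def plot_data(self) -> list[tuple[float, float, float]]:
        """(ln age, ln rate, fitted ln rate) triples for the fit figure."""
        return [
            (x, y, self.intercept + self.slope * x) for x, y in self.points
        ]


def band_incidence(band: AgeBand) -> float:
    """Incidence rate of a band: events per person-year."""
    if band.person_years <= 0:
        raise UndefinedRateError(
            f"band [{band.lower}, {band.upper}) has no person-years; rate undefined"
        )
    return band.events / band.person_years


def filter_bands(
    bands: BandTable,
    cfg: BandFilterConfig | None = None,
    cohort: CohortTable | None = None,
) -> tuple[list[AgeBand], ExclusionReport]:
    """Apply the person-years and minimum-rate retention thresholds.

    Retains bands with person_years >= min_person_years AND rate >=
    min_rate (both inclusive).  The report counts excluded person-years
    and, when the cohort is supplied, the participants whose exit age
    falls below the first retained band (the subjects contributing no
    information to the fitted line).
    """
    cfg = cfg or BandFilterConfig()
    retained: list[AgeBand] = []
    excluded_py = 0.0
    excluded_bands = 0
    for b in bands:
        rate = (b.events / b.person_years) if b.person_years > 0 else 0.0
        if b.person_years >= cfg.min_person_years and rate >= cfg.min_rate:
            retained.append(b)
        else:
            excluded_bands += 1
            excluded_py += b.person_years
    if len(retained) < MIN_BANDS_FOR_FIT:
        raise InsufficientDataError(
            f"only {len(retained)} age bands pass the filter "
            f"(min_person_years={cfg.min_person_years}, min_rate={cfg.min_rate}); "
            f"at least {MIN_BANDS_FOR_FIT} are required"
        )
    first_lower = retained[0].lower
    excluded_participants = 0
    if cohort is not None:
        excluded_participants = int((cohort.frame["exit_age"] < first_lower).sum())
    report = ExclusionReport(
        excluded_bands=excluded_bands,
        excluded_person_years=excluded_py,
        excluded_participants=excluded_participants,
        first_retained_lower=first_lower,
    )
    return retained, report


def _age_abscissa(band: AgeBand, age_point: AgePoint) -> float:
    if age_point == "midpoint":
        return band.midpoint
    if age_point == "lower":
        return band.lower
    if age_point == "mean-py":
        return band.mean_age
    raise ValueError(f"unknown age_point {age_point!r}")


def fit_loglog(
    retained: Sequence[AgeBand],
    age_point: AgePoint = "midpoint",
    method: Literal["ols", "poisson"] = "ols",
) -> MultistageFit:
    """Unweighted OLS of ln(rate) on ln(age) over the retained bands.

    Returns the slope (the n - 1 estimate), its two-sided 95% CI from
    the t distribution with k - 2 degrees of freedom, the intercept c,
    and both plain and adjusted R².  ``method="poisson"`` substitutes a
    Poisson log-link regression of event counts with a log person-years
    offset — a sensitivity analysis, not the primary estimator (its R²
    fields are reported as NaN).
    """
    if len(retained) < MIN_BANDS_FOR_FIT:
        raise InsufficientDataError(
            f"{len(retained)} bands supplied; need >= {MIN_BANDS_FOR_FIT}"
        )
    x = np.array([_age_abscissa(b, age_point) for b in retained], dtype=float)
    if np.any(x <= 0):
        raise DegenerateDesignError("log age undefined: non-positive abscissa")
    rates = np.array([band_incidence(b) for b in retained], dtype=float)
    if np.any(rates <= 0):
        raise UndefinedRateError("zero rate in a retained band; cannot take logs")
    lx = np.log(x)
    if np.ptp(lx) == 0:
        raise DegenerateDesignError("all log-age values identical")
    ly = np.log(rates)

    if method == "poisson":
        events = np.array([b.events for b in retained], dtype=float)
        offset = np.log(np.array([b.person_years for b in retained], dtype=float))
        model = sm.GLM(
            events, sm.add_constant(lx), family=sm.families.Poisson(), offset=offset
        ).fit()
        ci = model.conf_int(alpha=0.05)
        slope = float(model.params[1])
        return MultistageFit(
            slope=slope,
            slope_ci_low=float(ci[1][0]),
            slope_ci_high=float(ci[1][1]),
            intercept=float(model.params[0]),
            adjusted_r2=float("nan"),
            r2=float("nan"),
            n_steps=steps_from_slope(slope),
            points=list(zip(lx.tolist(), ly.tolist())),
            age_point=age_point,
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        model = sm.OLS(ly, sm.add_constant(lx)).fit()
        r2 = float(model.rsquared)
        adj_r2 = float(model.rsquared_adj)
    if not math.isfinite(r2):
        # constant response: R^2 is 0/0; a flat line with zero residual
        # is a perfect fit, anything else leaves it undefined
        perfect = float(model.ssr) < 1e-24
        r2 = adj_r2 = 1.0 if perfect else float("nan")
    ci = model.conf_int(alpha=0.05)
    slope = float(model.params[1])
    return MultistageFit(
        slope=slope,
        slope_ci_low=float(ci[1][0]),
        slope_ci_high=float(ci[1][1]),
        intercept=float(model.params[0]),
        adjusted_r2=adj_r2,
        r2=r2,
        n_steps=steps_from_slope(slope),
        points=list(zip(lx.tolist(), ly.tolist())),
        age_point=age_point,
    )


def steps_from_slope(slope: float) -> int:
    """Convert a fitted slope (n - 1 estimate) to a whole step count.

    Rounds slope + 1 to the nearest integer, halves away from zero.
    A slope <= -1 would imply a non-positive number of steps and flags
    a fit that is not multistage-like at all.
    """
    if not math.isfinite(slope):
        raise SlopeDomainError(f"slope must be finite, got {slope}")
    if slope <= -1:
        raise SlopeDomainError(
            f"slope {slope} <= -1 implies a non-positive step count"
        )
    n = slope + 1.0
    return int(math.floor(n + 0.5)) if n >= 0 else int(math.ceil(n - 0.5))


def fit_cohort(
    cohort: CohortTable,
    cfg: BandFilterConfig | None = None,
    band_width: float = 5.0,
    origin: float = 0.0,
    age_point: AgePoint = "midpoint",
    method: Literal["ols", "poisson"] = "ols",
) -> MultistageFit:
    """Accrue -> filter -> fit -> step count, with exclusion bookkeeping.

    The one-call version of the whole analysis chain; permutation of
    participants never changes any output.
    """
    bands = accrue_person_time(cohort, band_width=band_width, origin=origin)
    retained, report = filter_bands(bands, cfg, cohort)
    fit = fit_loglog(retained, age_point=age_point, method=method)
    fit.excluded_person_years = report.excluded_person_years
    fit.excluded_participants = report.excluded_participants
    fit.n_events = int(sum(b.events for b in retained))
    fit.n_participants = len(cohort) - report.excluded_participants
    return fit
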