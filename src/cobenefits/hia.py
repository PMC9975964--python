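"""Health impact assessment: exposure-response functions and attributable
mortality.

Two ERF families are supported:

* **Log-linear**: RR(ΔC) = exp(β·ΔC) with β = ln(RR₁₀)/10, parameterised by a
  relative risk per 10 µg m⁻³ with a 95% CI.  Attributable deaths in a cell
  are ``y₀/10⁵ · P · (1 − e^{−β·ΔC})``.
* **GEMM** (Global Exposure Mortality Model): a bounded-log hazard with a
  logistic weight,

      RR(c) = exp(θ · log(1 + z/α) · ω(z)),   ω(z) = 1/(1 + e^{−(z−µ)/ν}),

  with ``z = max(0, c − c₀)`` and counterfactual c₀ below which RR ≡ 1.
  Attributable deaths use the risk-ratio form
  ``y₀/10⁵ · P · (RR(c_scen) − RR(c_ref)) / RR(c_scen)``.

Both are evaluated cell by cell against a gridded population (BenMAP-style),
with confidence intervals propagated by re-running the full computation at
the risk coefficient's CI endpoints.  The module also implements
attainment-target rollback counterfactuals (proportional scaling of a
surface until its population-weighted mean meets a standard).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exposure import population_weighted_mean
from .grids import AnnualSurface, GridError, PopulationSurface

__all__ = [
    "BaselineMortality",
    "LogLinearERF",
    "GemmERF",
    "HIAResult",
    "AttainmentTarget",
    "AttainmentBenefit",
    "beta_from_rr",
    "gemm_rr",
    "attributable_deaths_loglinear",
    "attributable_deaths_rr_ratio",
    "cellwise_hia",
    "confidence_interval",
    "mortality_rate_change",
    "rollback_to_target",
    "attainment_benefit",
    "POPE_ALL_CAUSE",
    "TURNER_ALL_CAUSE",
    "GEMM_NONACCIDENTAL",
    "DEFAULT_ERFS",
    "DEFAULT_TARGETS",
]


class CIUnavailableError(ValueError):
    """The exposure-response function carries no confidence bounds."""


@dataclass(frozen=True)
class BaselineMortality:
    """Annual baseline mortality rate, deaths per 100 000, for an age band."""

    rate_per_100k: float
    age_band: str = "30_99"
    endpoint: str = "all_cause"

    def __post_init__(self) -> None:
        if self.rate_per_100k < 0:
            raise ValueError("baseline mortality rate must be >= 0")


def beta_from_rr(rr_per_10: float) -> float:
    """Log-linear slope per µg m⁻³ from a relative risk per 10 µg m⁻³.

    β = ln(RR)/10; exp(10·β) recovers the RR to machine precision.
    """
    if rr_per_10 <= 0:
        raise ValueError("relative risk must be positive")
    return math.log(rr_per_10) / 10.0


@dataclass(frozen=True)
class LogLinearERF:
    """Log-linear ERF parameterised by RR per 10 µg m⁻³ with optional CI."""

    name: str
    rr_per_10: float
    rr_lo: float | None = None
    rr_hi: float | None = None
    endpoint: str = "all_cause"
    age_band: str = "30_99"

    def __post_init__(self) -> None:
        if self.rr_per_10 <= 0:
            raise ValueError("rr_per_10 must be positive")
        if (self.rr_lo is None) != (self.rr_hi is None):
            raise ValueError("provide both CI bounds or neither")
        if self.rr_lo is not None:
            if not self.rr_lo <= self.rr_per_10 <= self.rr_hi:
                raise ValueError("CI must bracket the central RR")

    @property
    def beta(self) -> float:
        return beta_from_rr(self.rr_per_10)

    @property
    def has_ci(self) -> bool:
        return self.rr_lo is not None


@dataclass(frozen=True)
class GemmERF:
    """GEMM-form ERF: θ (with SE), shape parameters α, µ, ν, counterfactual c₀."""

    name: str
    theta: float
    theta_se: float | None = None
    alpha: float = 1.6
    mu: float = 15.5
    nu: float = 36.8
    c0: float = 2.4
    endpoint: str = "non_accidental"
    age_band: str = "25_99"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.nu <= 0:
            raise ValueError("alpha and nu must be positive")
        if self.c0 < 0:
            raise ValueError("counterfactual concentration must be >= 0")
        if self.theta_se is not None and self.theta_se < 0:
            raise ValueError("theta_se must be >= 0")

    @property
    def has_ci(self) -> bool:
        return self.theta_se is not None

    def theta_ci(self, z: float = 1.96) -> tuple[float, float]:
        if self.theta_se is None:
            raise CIUnavailableError(f"ERF {self.name!r} has no theta SE")
        return (self.theta - z * self.theta_se, self.theta + z * self.theta_se)


def gemm_rr(c, erf: GemmERF, theta: float | None = None):
    """GEMM relative risk at concentration ``c`` (scalar or array, µg m⁻³).

    RR(c₀) = 1 exactly and RR is monotone non-decreasing in c for θ ≥ 0.
    """
    th = erf.theta if theta is None else theta
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be >= 0")
    z = np.maximum(0.0, c_arr - erf.c0)
    omega = 1.0 / (1.0 + np.exp(-(z - erf.mu) / erf.nu))
    rr = np.exp(th * np.log1p(z / erf.alpha) * omega)
    return float(rr) if np.isscalar(c) or c_arr.ndim == 0 else rr


def attributable_deaths_loglinear(
    y0: BaselineMortality,
    pop: float,
    delta_c: float,
    erf: LogLinearERF,
    beta: float | None = None,
) -> float:
    """(y₀/10⁵)·P·(1 − e^{−β·ΔC}); negative ΔC gives avoided (negative) deaths."""
    if pop < 0:
        raise ValueError("population must be >= 0")
    b = erf.beta if beta is None else beta
    return (y0.rate_per_100k / 1e5) * pop * (1.0 - math.exp(-b * delta_c))


def attributable_deaths_rr_ratio(
    y0: BaselineMortality,
    pop: float,
    c_scenario: float,
    c_reference: float,
    erf: GemmERF,
    theta: float | None = None,
) -> float:
    """(y₀/10⁵)·P·(RR(c_scen) − RR(c_ref))/RR(c_scen) for a GEMM-form ERF."""
    if pop < 0:
        raise ValueError("population must be >= 0")
    rr_s = gemm_rr(c_scenario, erf, theta=theta)
    rr_r = gemm_rr(c_reference, erf, theta=theta)
    return (y0.rate_per_100k / 1e5) * pop * (rr_s - rr_r) / rr_s


@dataclass(frozen=True)
class HIAResult:
    """Excess deaths of a scenario relative to a reference, with context."""

    excess_deaths: float
    ci: tuple[float, float] | None      # (at lo-risk bound, at hi-risk bound)
    attributable_fraction: float        # excess / baseline deaths in the band
    delta_c_pw: float                   # population-weighted ΔC, µg m⁻³
    population: float                   # exposed band population
    baseline_rate: float                # y₀ per 100 000
    scenario_rate: float                # y₀ + excess/P × 10⁵
    rate_pct_change: float
    erf_name: str
    age_band: str
    scenario_pair: str = ""

    @property
    def lo(self) -> float:
        if self.ci is None:
            raise CIUnavailableError("no confidence interval available")
        return self.ci[0]

    @property
    def hi(self) -> float:
        if self.ci is None:
            raise CIUnavailableError("no confidence interval available")
        return self.ci[1]


def _cell_deaths(
    reference: AnnualSurface,
    scenario: AnnualSurface,
    band_pop: np.ndarray,
    y0: BaselineMortality,
    erf: LogLinearERF | GemmERF,
    coeff: float | None,
) -> float:
    rate = y0.rate_per_100k / 1e5
    if isinstance(erf, LogLinearERF):
        b = erf.beta if coeff is None else coeff
        delta = scenario.values - reference.values
        return float((rate * band_pop * (1.0 - np.exp(-b * delta))).sum())
    rr_s = gemm_rr(scenario.values, erf, theta=coeff)
    rr_r = gemm_rr(reference.values, erf, theta=coeff)
    return float((rate * band_pop * (rr_s - rr_r) / rr_s).sum())


def cellwise_hia(
    reference: AnnualSurface,
    scenario: AnnualSurface,
    pop: PopulationSurface,
    y0: BaselineMortality,
    erf: LogLinearERF | GemmERF,
    scenario_pair: str = "",
    with_ci: bool = True,
) -> HIAResult:
    """Cell-by-cell attributable mortality of ``scenario`` vs ``reference``.

    Each cell contributes deaths computed from its own concentrations and its
    share of the ERF's age-band population (cell total × citywide band
    fraction); cells are then summed.  On uniform surfaces this equals the
    aggregate closed form exactly.  The CI re-runs the identical cellwise
    computation at the ERF's risk-coefficient CI endpoints.
    """
    if reference.grid.shape != scenario.grid.shape != pop.grid.shape:
        raise GridError("reference, scenario, and population grids must match")
    band_pop = pop.band_persons(erf.age_band)
    band_total = float(band_pop.sum())

    central = _cell_deaths(reference, scenario, band_pop, y0, erf, None)

    ci: tuple[float, float] | None = None
    if with_ci and erf.has_ci:
        if isinstance(erf, LogLinearERF):
            coeffs = (beta_from_rr(erf.rr_lo), beta_from_rr(erf.rr_hi))
        else:
            coeffs = erf.theta_ci()
        ci = tuple(
            _cell_deaths(reference, scenario, band_pop, y0, erf, c) for c in coeffs
        )

    baseline_deaths = (y0.rate_per_100k / 1e5) * band_total
    af = central / baseline_deaths if baseline_deaths > 0 else 0.0
    delta_pw = population_weighted_mean(
        scenario, pop, erf.age_band
    ) - population_weighted_mean(reference, pop, erf.age_band)
    scen_rate, pct = mortality_rate_change(central, band_total, y0)
    return HIAResult(
        excess_deaths=central,
        ci=ci,
        attributable_fraction=af,
        delta_c_pw=delta_pw,
        population=band_total,
        baseline_rate=y0.rate_per_100k,
        scenario_rate=scen_rate,
        rate_pct_change=pct,
        erf_name=erf.name,
        age_band=erf.age_band,
        scenario_pair=scenario_pair,
    )


def confidence_interval(result: HIAResult) -> tuple[float, float]:
    """The result's (lo-risk, hi-risk) death bounds; error if unavailable."""
    if result.ci is None:
        raise CIUnavailableError(
            f"result for {result.erf_name!r} carries no confidence interval"
        )
    return result.ci


def mortality_rate_change(
    excess_deaths: float, pop: float, y0: BaselineMortality
) -> tuple[float, float]:
    """Scenario mortality rate per 100 000 and its % change from baseline."""
    if pop <= 0:
        raise ValueError("population must be positive")
    rate = y0.rate_per_100k + excess_deaths / pop * 1e5
    pct = 100.0 * (rate - y0.rate_per_100k) / y0.rate_per_100k
    return rate, pct


@dataclass(frozen=True)
class AttainmentTarget:
    """An air-quality goal: an absolute annual level or a percent reduction
    from a baseline mean."""

    name: str
    level: float | None = None             # µg m⁻³
    percent_reduction: float | None = None  # % below baseline mean

    def __post_init__(self) -> None:
        if (self.level is None) == (self.percent_reduction is None):
            raise ValueError("specify exactly one of level or percent_reduction")
        if self.level is not None and self.level <= 0:
            raise ValueError("target level must be positive")
        if self.percent_reduction is not None and not 0 < self.percent_reduction < 100:
            raise ValueError("percent_reduction must be in (0, 100)")

    def goal(self, baseline_mean: float | None = None) -> float:
        """Goal concentration in µg m⁻³."""
        if self.level is not None:
            return self.level
        if baseline_mean is None:
            raise ValueError(
                f"target {self.name!r} is relative; a baseline mean is required"
            )
        return baseline_mean * (1.0 - self.percent_reduction / 100.0)


def rollback_to_target(
    surface: AnnualSurface,
    pop: PopulationSurface,
    target: AttainmentTarget,
    baseline_mean: float | None = None,
    method: str = "proportional",
) -> AnnualSurface:
    """Counterfactual surface that just attains an air-quality target.

    ``proportional`` (default): if the population-weighted mean exceeds the
    goal, every cell is scaled by goal/current so the resulting
    population-weighted mean equals the goal; surfaces already attaining the
    goal are returned unchanged.  ``cap``: cells above the goal level are
    truncated to it (a different counterfactual, provided for sensitivity).
    """
    goal = target.goal(baseline_mean)
    current = population_weighted_mean(surface, pop)
    if method == "proportional":
        if current <= goal:
            return surface
        return surface.with_values(surface.values * (goal / current))
    if method == "cap":
        return surface.with_values(np.minimum(surface.values, goal))
    raise ValueError(f"unknown rollback method {method!r}")


@dataclass(frozen=True)
class AttainmentBenefit:
    """Deaths avoided by attaining a target, per ERF and the across-ERF max."""

    target: AttainmentTarget
    goal: float
    avoided_by_erf: dict[str, float]

    @property
    def max_avoided(self) -> float:
        return max(self.avoided_by_erf.values())


def attainment_benefit(
    bau_surface: AnnualSurface,
    target: AttainmentTarget,
    pop: PopulationSurface,
    y0: BaselineMortality,
    erfs: Sequence[LogLinearERF | GemmERF],
    baseline_mean: float | None = None,
    method: str = "proportional",
) -> AttainmentBenefit:
    """Avoided deaths (positive = fewer deaths than under BAU) from rolling
    the BAU surface back to an attainment target, for each ERF."""
    rolled = rollback_to_target(
        bau_surface, pop, target, baseline_mean=baseline_mean, method=method
    )
    goal = target.goal(baseline_mean)
    avoided = {}
    for erf in erfs:
        res = cellwise_hia(bau_surface, rolled, pop, y0, erf, with_ci=False)
        avoided[erf.name] = -res.excess_deaths
    return AttainmentBenefit(target=target, goal=goal, avoided_by_erf=avoided)


# --- Default exposure-response functions -----------------------------------
# Turner: published all-cause cohort RR per 10 µg m⁻³, 1.06 (1.04-1.08).
TURNER_ALL_CAUSE = LogLinearERF(
    name="turner_all_cause", rr_per_10=1.06, rr_lo=1.04, rr_hi=1.08,
    endpoint="all_cause", age_band="30_99",
)
# Pope: effective RR back-solved from this analysis's reported aggregate
# all-cause estimates (a calibration; the source coefficient is not printed
# in the study inputs this package reproduces).
POPE_ALL_CAUSE = LogLinearERF(
    name="pope_all_cause", rr_per_10=1.072, rr_lo=1.056, rr_hi=1.089,
    endpoint="all_cause", age_band="30_99",
)
# GEMM non-accidental (NCD+LRI), adult parameters from the GEMM publication.
# No 25-99 baseline rate is available, so the 30-99 all-cause rate is applied
# to this band as well; GEMM results are therefore approximate.
GEMM_NONACCIDENTAL = GemmERF(
    name="gemm_non_accidental", theta=0.143, theta_se=0.01807,
    alpha=1.6, mu=15.5, nu=36.8, c0=2.4,
    endpoint="non_accidental", age_band="25_99",
)

DEFAULT_ERFS: tuple[LogLinearERF | GemmERF, ...] = (
    POPE_ALL_CAUSE,
    TURNER_ALL_CAUSE,
    GEMM_NONACCIDENTAL,
)

#: National programme (−30% from baseline), national standard (40 µg m⁻³),
#: WHO guideline (5 µg m⁻³).
DEFAULT_TARGETS = (
    AttainmentTarget("NCAP", percent_reduction=30.0),
    AttainmentTarget("NAAQS", level=40.0),
    AttainmentTarget("WHO_AQG", level=5.0),
)
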