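"""Discounting, QALY/life-year accumulation, ICER and net monetary benefit.

Costs and health outcomes are discounted continuously at the annual rate
over the cycle grid: the factor at cycle t is (1+r)^(-t*cycle_days/365.25).
Accrual is at cycle start, over trace rows 0..n.  Both utility-weighted
QALYs and unweighted discounted life-years are accumulated; which of the
two the incremental analysis treats as "effectiveness" is a model
configuration choice (see the methods note on reproducing the published
analysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .costing import CostInputs, PatientProfile, state_cost

if TYPE_CHECKING:  # pragma: no cover
    from .markov import CohortTrace, ModelConfig, TreatmentArm

__all__ = [
    "UtilitySet",
    "ArmResult",
    "CEResult",
    "discount_factor",
    "discount_factors",
    "accumulate",
    "icer",
    "nmb",
    "convert_currency",
]


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities and the per-arm on-treatment AE disutility."""

    u_pfs: float = 0.856
    u_pd: float = 0.768

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_pd <= self.u_pfs <= 1.0):
            raise ValueError(
                f"utilities must satisfy 0 <= u_pd <= u_pfs <= 1, "
                f"got u_pfs={self.u_pfs}, u_pd={self.u_pd}"
            )


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals for one strategy."""

    name: str
    cost: float
    qalys: float
    life_years_discounted: float
    life_years: float

    def __post_init__(self) -> None:
        if self.cost < 0 or self.qalys < 0:
            raise ValueError("cost and qalys must be >= 0")

    def effectiveness(self, measure: str) -> float:
        if measure == "qaly":
            return self.qalys
        if measure == "life-years":
            return self.life_years_discounted
        raise ValueError(f"unknown effectiveness measure {measure!r}")


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of a comparator against a reference arm."""

    delta_cost: float
    delta_qalys: float
    icer: float | None  # None when delta_qalys == 0
    dominant: bool      # cheaper and more effective
    dominated: bool     # costlier and less effective


def discount_factor(config: "ModelConfig", cycle: float) -> float:
    """(1 + r)^(-cycle * cycle_days / 365.25); exactly 1 at cycle 0."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    years = cycle * config.cycle_days / 365.25
    return (1.0 + config.annual_discount) ** (-years)


def discount_factors(config: "ModelConfig", n_cycles: int) -> np.ndarray:
    t = np.arange(n_cycles + 1, dtype=float)
    return (1.0 + config.annual_discount) ** (-(t * config.cycle_days / 365.25))


def accumulate(
    trace: "CohortTrace",
    arm: "TreatmentArm",
    config: "ModelConfig",
    costs: CostInputs,
    utilities: UtilitySet,
    profile: PatientProfile | None = None,
) -> ArmResult:
    """Discounted cost, QALYs and life-years of one simulated arm.

    QALYs weight occupancy by state utility, with the arm's AE disutility
    subtracted while on first-line treatment; life-years weight all alive
    states by 1.  The optional half-cycle correction halves the first and
    last rows.
    """
    if profile is None:
        profile = PatientProfile()
    if arm.ae_disutility > utilities.u_pfs:
        raise ValueError("AE disutility must be smaller than the PFS utility")

    n = trace.n_cycles
    d = discount_factors(config, n)
    weights = np.ones(n + 1)
    if config.half_cycle_correction:
        weights[0] = weights[-1] = 0.5

    occ = trace.occupancy
    cyc_yr = config.cycle_years
    q_row = (
        occ[:, 0] * (utilities.u_pfs - arm.ae_disutility)
        + occ[:, 1] * utilities.u_pfs
        + occ[:, 2] * utilities.u_pd
    ) * cyc_yr
    alive_row = occ[:, :3].sum(axis=1) * cyc_yr

    cost = 0.0
    for t in range(n + 1):
        c = state_cost(
            occ[t], trace.new_deaths[t], arm, config, costs, profile, t
        )
        cost += d[t] * weights[t] * c

    return ArmResult(
        name=arm.name,
        cost=float(cost),
        qalys=float((d * weights * q_row).sum()),
        life_years_discounted=float((d * weights * alive_row).sum()),
        life_years=float((weights * alive_row).sum()),
    )


def icer(
    reference: ArmResult,
    comparator: ArmResult,
    measure: str = "life-years",
) -> CEResult:
    """Incremental cost-effectiveness of ``comparator`` vs ``reference``.

    The ICER is undefined (None) when the effectiveness difference is
    exactly zero; dominance flags mark the unambiguous quadrants.
    """
    delta_cost = comparator.cost - reference.cost
    delta_q = comparator.effectiveness(measure) - reference.effectiveness(measure)
    ratio = None if delta_q == 0.0 else delta_cost / delta_q
    return CEResult(
        delta_cost=delta_cost,
        delta_qalys=delta_q,
        icer=ratio,
        dominant=delta_cost < 0 and delta_q > 0,
        dominated=delta_cost > 0 and delta_q < 0,
    )


def nmb(ce: CEResult, wtp: float) -> float:
    """Net monetary benefit wtp*dQALY - dCost; >= 0 means cost-effective."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * ce.delta_qalys - ce.delta_cost


def convert_currency(amount: float, direction: str, fx: float) -> float:
    """Convert between USD and CNY at ``fx`` CNY per USD."""
    if fx <= 0:
        raise ValueError("fx must be > 0")
    if direction == "usd_to_cny":
        return amount * fx
    if direction == "cny_to_usd":
        return amount / fx
    raise ValueError(f"unknown direction {direction!r}")
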