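"""Deterministic Markov cohort engine over four health states.

States: PFS on first-line treatment, PFS with treatment discontinued
(after a grade III/IV adverse event), progressive disease (PD), and
death.  The whole cohort starts progression-free on treatment.  Each
3-week cycle the cohort redistributes according to per-cycle conditional
probabilities derived from the OS and PFS Weibull curves:

* death (from any alive state) at ``1 - S_os(t)/S_os(t-1)``;
* PFS exit at ``1 - S_pfs(t)/S_pfs(t-1)``, of which the part exceeding
  the death probability moves to PD (floored at zero in early cycles
  where the fitted OS hazard exceeds the PFS exit hazard);
* among patients who remain progression-free and alive while on
  treatment, a constant per-cycle probability of AE-driven
  discontinuation moves mass to the off-treatment PFS substate.

Survival transitions are applied first within a cycle, then
discontinuation among the PFS stayers; discontinuation is one-way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .costing import DrugComponent
from .survival import (
    HazardRatioPair,
    WeibullParams,
    apply_hazard_ratio,
)

__all__ = [
    "ModelConfig",
    "TreatmentArm",
    "CohortTrace",
    "CyclePlan",
    "transition_probabilities",
    "run_cohort",
    "life_years",
]

STATES = ("pfs_on", "pfs_off", "pd", "death")
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class ModelConfig:
    """Structural settings of the cohort model.

    ``wtp_per_qaly`` is in USD (three times China's 2020 per-capita GDP);
    ``fx_cny_per_usd`` converts reported figures to CNY.  ``billing``
    selects per-mg proration (``linear-mg``) or whole-vial rounding.
    ``effectiveness_measure`` chooses what the incremental analysis calls
    "effectiveness": discounted life-years (the reading that reproduces
    the published results) or utility-weighted QALYs.
    """

    cycle_days: int = 21
    horizon_years: float = 30.0
    annual_discount: float = 0.05
    wtp_per_qaly: float = 33438.0
    fx_cny_per_usd: float = 6.8974
    max_chemo_cycles: int = 6
    p_subsequent_therapy: float = 1.0
    half_cycle_correction: bool = False
    billing: str = "linear-mg"
    effectiveness_measure: str = "life-years"

    def __post_init__(self) -> None:
        if self.cycle_days <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle_days and horizon_years must be positive")
        if not (0.0 <= self.annual_discount <= 0.08):
            raise ValueError("annual_discount must lie in [0, 0.08]")
        if not (0.0 <= self.p_subsequent_therapy <= 1.0):
            raise ValueError("p_subsequent_therapy must lie in [0, 1]")
        if self.wtp_per_qaly <= 0 or self.fx_cny_per_usd <= 0:
            raise ValueError("wtp_per_qaly and fx_cny_per_usd must be positive")
        if self.max_chemo_cycles < 1:
            raise ValueError("max_chemo_cycles must be >= 1")
        if self.billing not in ("linear-mg", "round-up-vial"):
            raise ValueError(f"unknown billing mode {self.billing!r}")
        if self.effectiveness_measure not in ("life-years", "qaly"):
            raise ValueError(
                f"unknown effectiveness_measure {self.effectiveness_measure!r}"
            )
        if self.n_cycles < 1:
            raise ValueError("horizon shorter than one cycle")

    @property
    def n_cycles(self) -> int:
        """Number of transitions simulated; 521 at the 30-year default."""
        return int(self.horizon_years * DAYS_PER_YEAR // self.cycle_days)

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR

    @property
    def wtp_cny(self) -> float:
        return self.wtp_per_qaly * self.fx_cny_per_usd


@dataclass(frozen=True)
class TreatmentArm:
    """One strategy: drugs, hazard ratios vs the reference, AE profile."""

    name: str
    hr: HazardRatioPair
    p_discontinue_ae: float
    ae_cost: float
    ae_disutility: float
    regimen: tuple[DrugComponent, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_discontinue_ae < 1.0):
            raise ValueError("p_discontinue_ae must lie in [0, 1)")
        if self.ae_cost < 0:
            raise ValueError("ae_cost must be >= 0")
        if not (0.0 <= self.ae_disutility < 1.0):
            raise ValueError("ae_disutility must lie in [0, 1)")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy (rows 0..n_cycles) and new deaths."""

    occupancy: np.ndarray  # shape (n_cycles+1, 4), rows sum to 1
    new_deaths: np.ndarray  # shape (n_cycles+1,), new_deaths[0] == 0

    def __post_init__(self) -> None:
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != 4:
            raise ValueError("occupancy must be (n+1, 4)")
        if np.any(occ < -1e-12) or np.any(~np.isfinite(occ)):
            raise ValueError("occupancy has negative or non-finite entries")
        row_sums = occ.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise ValueError("occupancy rows must sum to 1")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def column(self, state: str) -> np.ndarray:
        return self.occupancy[:, STATES.index(state)]

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, :3].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATES)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df["new_deaths"] = self.new_deaths
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CyclePlan:
    """Outflow probabilities for one cycle, for one arm."""

    p_death: float          # from any alive state
    p_pfs_to_pd: float      # from either PFS substate
    p_discontinue: float    # among on-treatment PFS stayers

    def __post_init__(self) -> None:
        for name in ("p_death", "p_pfs_to_pd", "p_discontinue"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not np.isfinite(v):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_death + self.p_pfs_to_pd > 1.0 + 1e-12:
            raise ValueError("outflows from PFS exceed 1")


def _per_cycle_exit_probs(params: WeibullParams, n_cycles: int) -> np.ndarray:
    """Vector of 1 - S(t)/S(t-1) for t = 1..n_cycles, underflow-safe."""
    t = np.arange(n_cycles + 1, dtype=float)
    h = params.cumulative_hazard(t)
    return -np.expm1(h[:-1] - h[1:])


def transition_probabilities(
    arm: TreatmentArm,
    os_adj: WeibullParams,
    pfs_adj: WeibullParams,
    t: int,
) -> CyclePlan:
    """Outflow probabilities at cycle ``t`` from arm-adjusted curves.

    ``os_adj``/``pfs_adj`` must already carry the arm's hazard-ratio
    adjustment.  The PFS->PD probability is the PFS exit probability in
    excess of the death probability, floored at zero.
    """
    if t < 1:
        raise ValueError("cycle index must be >= 1")
    from .survival import conditional_exit_prob

    p_death = float(conditional_exit_prob(os_adj, t))
    p_exit_pfs = float(conditional_exit_prob(pfs_adj, t))
    return CyclePlan(
        p_death=p_death,
        p_pfs_to_pd=max(0.0, p_exit_pfs - p_death),
        p_discontinue=arm.p_discontinue_ae,
    )


def run_cohort(
    arm: TreatmentArm,
    config: ModelConfig,
    os_ref: WeibullParams,
    pfs_ref: WeibullParams,
) -> CohortTrace:
    """Iterate the cohort from (1, 0, 0, 0) for ``config.n_cycles`` cycles.

    ``os_ref``/``pfs_ref`` are the reference-arm curves; the arm's hazard
    ratios are applied here.
    """
    os_adj = apply_hazard_ratio(os_ref, arm.hr.hr_os)
    pfs_adj = apply_hazard_ratio(pfs_ref, arm.hr.hr_pfs)
    n = config.n_cycles

    p_death = _per_cycle_exit_probs(os_adj, n)
    p_exit_pfs = _per_cycle_exit_probs(pfs_adj, n)
    p_to_pd = np.maximum(0.0, p_exit_pfs - p_death)
    p_dc = arm.p_discontinue_ae

    occ = np.zeros((n + 1, 4))
    occ[0, 0] = 1.0
    new_deaths = np.zeros(n + 1)
    for t in range(1, n + 1):
        on, off, pd_, dead = occ[t - 1]
        pdth = p_death[t - 1]
        ppd = p_to_pd[t - 1]
        stay_pfs = 1.0 - pdth - ppd
        stayers_on = on * stay_pfs
        occ[t, 0] = stayers_on * (1.0 - p_dc)
        occ[t, 1] = off * stay_pfs + stayers_on * p_dc
        occ[t, 2] = pd_ * (1.0 - pdth) + (on + off) * ppd
        nd = (on + off + pd_) * pdth
        occ[t, 3] = dead + nd
        new_deaths[t] = nd

    if np.any(~np.isfinite(occ)) or np.any(occ < -1e-12):
        raise ArithmeticError("cohort trace left the probability simplex")
    return CohortTrace(occupancy=occ, new_deaths=new_deaths)


def life_years(trace: CohortTrace, config: ModelConfig) -> float:
    """Undiscounted life-years: sum of alive occupancy times cycle length.

    Accrual is at cycle start (rows 0..n), matching the cost/QALY
    accumulation convention.
    """
    return float(trace.alive.sum() * config.cycle_years)
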