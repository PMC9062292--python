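"""Cost model: drug acquisition, AE treatment, and disease management.

Drug doses depend on patient anthropometry (mg/kg, mg/m², or the Calvert
formula for carboplatin), prices are per small priced unit, and costs
accrue by health state: first-line drugs plus routine follow-up while
progression-free on treatment, follow-up alone after AE discontinuation,
subsequent anticancer therapy or best supportive care in PD, and one
terminal cycle of palliative care per death.  Aggregate AE treatment
costs are charged once to the whole cohort at treatment start.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .markov import CohortTrace, ModelConfig, TreatmentArm

__all__ = [
    "PatientProfile",
    "DrugComponent",
    "CostInputs",
    "dose_mg",
    "drug_cost_per_cycle",
    "state_cost",
    "cost_breakdown_frame",
]


@dataclass(frozen=True)
class PatientProfile:
    """Anthropometrics of the modelled patient."""

    weight_kg: float = 65.0
    bsa_m2: float = 1.72
    crcl_ml_min: float = 70.0

    def __post_init__(self) -> None:
        if min(self.weight_kg, self.bsa_m2, self.crcl_ml_min) <= 0:
            raise ValueError("all anthropometric values must be > 0")


@dataclass(frozen=True)
class DrugComponent:
    """One priced drug with its dosing rule.

    ``dose_rule`` is one of ``per_kg`` (dose_value in mg/kg), ``per_bsa``
    (mg/m²) or ``calvert`` (dose_value is the target AUC; dose in mg is
    AUC x (CrCl + 25)).  ``cycles_cap`` limits how many treatment cycles
    the component is given (None = until progression/discontinuation).
    ``dose_multiplier`` supports scenario analyses such as the real-world
    half dosage.
    """

    name: str
    unit_mg: float
    unit_price: float
    dose_rule: str
    dose_value: float
    cycles_cap: int | None = None
    dose_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.unit_mg <= 0:
            raise ValueError("unit_mg must be > 0")
        if self.unit_price < 0:
            raise ValueError("unit_price must be >= 0")
        if self.dose_rule not in ("per_kg", "per_bsa", "calvert"):
            raise ValueError(f"unknown dose_rule {self.dose_rule!r}")
        if self.dose_value <= 0 or self.dose_multiplier <= 0:
            raise ValueError("dose_value and dose_multiplier must be > 0")

    def with_multiplier(self, multiplier: float) -> "DrugComponent":
        return DrugComponent(
            name=self.name,
            unit_mg=self.unit_mg,
            unit_price=self.unit_price,
            dose_rule=self.dose_rule,
            dose_value=self.dose_value,
            cycles_cap=self.cycles_cap,
            dose_multiplier=multiplier,
        )


@dataclass(frozen=True)
class CostInputs:
    """Per-cycle management costs (USD)."""

    followup_per_cycle: float = 55.60
    subsequent_per_cycle: float = 854.05
    bsc_per_cycle: float = 337.50
    palliative_per_cycle: float = 2627.80

    def __post_init__(self) -> None:
        if min(
            self.followup_per_cycle,
            self.subsequent_per_cycle,
            self.bsc_per_cycle,
            self.palliative_per_cycle,
        ) < 0:
            raise ValueError("all per-cycle costs must be >= 0")


def dose_mg(component: DrugComponent, profile: PatientProfile) -> float:
    """Administered dose in mg for one cycle."""
    if component.dose_rule == "per_kg":
        base = component.dose_value * profile.weight_kg
    elif component.dose_rule == "per_bsa":
        base = component.dose_value * profile.bsa_m2
    else:  # calvert
        base = component.dose_value * (profile.crcl_ml_min + 25.0)
    return base * component.dose_multiplier


def drug_cost_per_cycle(
    regimen: Sequence[DrugComponent],
    profile: PatientProfile,
    cycle: int,
    billing: str = "linear-mg",
) -> float:
    """Acquisition cost of the regimen at treatment cycle ``cycle`` (1-based).

    Components past their ``cycles_cap`` contribute nothing.  Linear-mg
    billing prorates to the exact mg; round-up-vial charges whole priced
    units.
    """
    if cycle < 1:
        raise ValueError("treatment cycle must be >= 1")
    if billing not in ("linear-mg", "round-up-vial"):
        raise ValueError(f"unknown billing mode {billing!r}")
    total = 0.0
    for comp in regimen:
        if comp.cycles_cap is not None and cycle > comp.cycles_cap:
            continue
        units = dose_mg(comp, profile) / comp.unit_mg
        if billing == "round-up-vial":
            units = math.ceil(units - 1e-9)
        total += units * comp.unit_price
    return total


def state_cost(
    row: np.ndarray,
    new_deaths: float,
    arm: "TreatmentArm",
    config: "ModelConfig",
    costs: CostInputs,
    profile: PatientProfile,
    cycle: int,
) -> float:
    """Undiscounted cohort cost accrued at one trace row.

    ``cycle`` is the row index (0 = first treatment cycle).  Drug and
    follow-up costs are weighted by on-treatment PFS occupancy; PD
    management mixes subsequent therapy and BSC by the configured
    proportion; each new death incurs one terminal palliative cycle.
    The arm's aggregate AE cost is charged once, on the first cycle.
    """
    pfs_on, pfs_off, pd_, _ = row
    drug = drug_cost_per_cycle(arm.regimen, profile, cycle + 1, config.billing)
    pd_management = (
        config.p_subsequent_therapy * costs.subsequent_per_cycle
        + (1.0 - config.p_subsequent_therapy) * costs.bsc_per_cycle
    )
    total = (
        pfs_on * (drug + costs.followup_per_cycle)
        + pfs_off * costs.followup_per_cycle
        + pd_ * pd_management
        + new_deaths * costs.palliative_per_cycle
    )
    if cycle == 0:
        total += arm.ae_cost
    return total


def cost_breakdown_frame(
    trace: "CohortTrace",
    arm: "TreatmentArm",
    config: "ModelConfig",
    costs: CostInputs,
    profile: PatientProfile,
    currency: str = "USD",
) -> pd.DataFrame:
    """Per-cycle undiscounted cost components, one row per trace row."""
    rows = []
    pd_management = (
        config.p_subsequent_therapy * costs.subsequent_per_cycle
        + (1.0 - config.p_subsequent_therapy) * costs.bsc_per_cycle
    )
    for t in range(trace.n_cycles + 1):
        pfs_on, pfs_off, pd_, _ = trace.occupancy[t]
        drug = pfs_on * drug_cost_per_cycle(
            arm.regimen, profile, t + 1, config.billing
        )
        followup = (pfs_on + pfs_off) * costs.followup_per_cycle
        pd_cost = pd_ * pd_management
        palliative = trace.new_deaths[t] * costs.palliative_per_cycle
        ae = arm.ae_cost if t == 0 else 0.0
        rows.append(
            {
                "cycle": t,
                "drug": drug,
                "followup": followup,
                "pd_management": pd_cost,
                "palliative": palliative,
                "ae": ae,
                "total": drug + followup + pd_cost + palliative + ae,
                "currency": currency,
            }
        )
    return pd.DataFrame(rows)
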