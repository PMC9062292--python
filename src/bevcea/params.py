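"""Model inputs: the parameter table and its translation to model objects.

A single YAML document (``data/table1_default.yaml``) transcribes every
base-case value, sensitivity range and distribution family, plus the
structural settings the published analysis leaves open (chemotherapy
cycle cap, PD subsequent-therapy proportion, carboplatin target AUC,
billing mode, effectiveness measure).  ``ModelInputs`` is the flat,
immutable in-memory form; ``build_model`` turns it into the arm, curve,
cost and utility objects the engine consumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .costing import CostInputs, DrugComponent, PatientProfile
from .economics import UtilitySet
from .markov import ModelConfig, TreatmentArm
from .survival import HazardRatioPair, WeibullParams

__all__ = [
    "ModelInputs",
    "ParamSpec",
    "default_inputs",
    "load_inputs",
    "dump_inputs",
    "build_model",
    "default_param_specs",
    "CALIBRATED_STRUCTURAL",
]

#: Structural choices fixed by calibration against the published Table 2
#: and frozen across the base case, scenario, DSA and PSA.
CALIBRATED_STRUCTURAL: dict[str, Any] = {
    "max_chemo_cycles": 6,
    "p_subsequent_therapy": 1.0,
    "carboplatin_target_auc": 6.0,
    "billing": "linear-mg",
    "effectiveness_measure": "life-years",
}


@dataclass(frozen=True)
class ParamSpec:
    """One sensitivity-analysis parameter: base value, range, distribution."""

    name: str
    base: float
    low: float
    high: float
    dist: str  # beta | gamma | normal | fixed

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"{self.name}: require low <= base <= high, "
                f"got ({self.low}, {self.base}, {self.high})"
            )
        if self.dist not in ("beta", "gamma", "normal", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.dist!r}")

    @property
    def degenerate(self) -> bool:
        return self.low == self.high


@dataclass(frozen=True)
class ModelInputs:
    """Every scalar the two-arm model consumes, in one flat record."""

    # Weibull curves of the reference (chemotherapy) arm, per-cycle scale
    weibull_os_scale: float = 0.004716
    weibull_os_shape: float = 1.533854
    weibull_pfs_scale: float = 0.003867
    weibull_pfs_shape: float = 2.335407
    # Hazard ratios: combination vs chemotherapy
    hr_os: float = 0.654
    hr_pfs: float = 0.405
    # Per-cycle AE-discontinuation probabilities
    p_discontinue_combo: float = 0.004298
    p_discontinue_chemo: float = 0.006372
    # Unit drug prices (USD per priced unit)
    ly01008_price: float = 24.99      # per 15 mg
    paclitaxel_price: float = 57.51   # per 175 mg
    carboplatin_price: float = 1.37   # per 6 mg
    nivolumab_price: float = 60.35    # per 4.5 mg (DSA completeness; PD costs
                                      # use the lump subsequent-therapy figure)
    # Management costs (USD per cycle) and lump AE costs (USD)
    followup_cost: float = 55.60
    subsequent_cost: float = 854.05
    bsc_cost: float = 337.50
    palliative_cost: float = 2627.80
    ae_cost_combo: float = 1025.82
    ae_cost_chemo: float = 745.01
    # Utilities and AE disutilities
    u_pfs: float = 0.856
    u_pd: float = 0.768
    disutility_combo: float = 0.061
    disutility_chemo: float = 0.080
    # Discounting and anthropometrics
    discount_rate: float = 0.05
    weight: float = 65.0
    bsa: float = 1.72
    crcl: float = 70.0
    # Structural settings
    cycle_days: int = 21
    horizon_years: float = 30.0
    wtp_per_qaly_usd: float = 33438.0
    fx_cny_per_usd: float = 6.8974
    max_chemo_cycles: int = 6
    p_subsequent_therapy: float = 1.0
    carboplatin_target_auc: float = 6.0
    half_cycle_correction: bool = False
    billing: str = "linear-mg"
    effectiveness_measure: str = "life-years"
    ly01008_dose_mg_per_kg: float = 15.0
    ly01008_dose_multiplier: float = 1.0
    # Hazard-ratio confidence intervals (for DSA ranges / PSA spread)
    hr_os_ci: tuple[float, float] = (0.302, 1.410)
    hr_pfs_ci: tuple[float, float] = (0.078, 2.160)

    def with_overrides(self, **overrides: Any) -> "ModelInputs":
        return replace(self, **overrides)


_STRUCTURAL_KEYS = (
    "cycle_days",
    "horizon_years",
    "wtp_per_qaly_usd",
    "fx_cny_per_usd",
    "max_chemo_cycles",
    "p_subsequent_therapy",
    "carboplatin_target_auc",
    "half_cycle_correction",
    "billing",
    "effectiveness_measure",
    "ly01008_dose_mg_per_kg",
    "ly01008_dose_multiplier",
)


def _packaged_yaml() -> dict:
    text = resources.files("bevcea").joinpath("data/table1_default.yaml").read_text()
    return yaml.safe_load(text)


def _inputs_from_doc(doc: Mapping[str, Any]) -> tuple[ModelInputs, list[ParamSpec]]:
    structural = dict(doc.get("structural", {}))
    params = doc.get("parameters", {})
    values: dict[str, Any] = {}
    specs: list[ParamSpec] = []
    for name, entry in params.items():
        base = float(entry["value"])
        values[name] = base
        if "low" in entry or "high" in entry:
            specs.append(
                ParamSpec(
                    name=name,
                    base=base,
                    low=float(entry["low"]),
                    high=float(entry["high"]),
                    dist=str(entry.get("dist", "fixed")),
                )
            )
    # discount_rate is called discount_rate both places; structural keys map 1:1
    for key in _STRUCTURAL_KEYS:
        if key in structural:
            values[key] = structural[key]
    inputs = ModelInputs(**values)
    return inputs, specs


def load_inputs(path: str | Path) -> tuple[ModelInputs, list[ParamSpec]]:
    """Read a YAML configuration in the packaged-document layout."""
    doc = yaml.safe_load(Path(path).read_text())
    return _inputs_from_doc(doc)


def default_inputs() -> tuple[ModelInputs, list[ParamSpec]]:
    """The packaged base-case configuration and its sensitivity table."""
    return _inputs_from_doc(_packaged_yaml())


def dump_inputs(inputs: ModelInputs, specs: list[ParamSpec], path: str | Path) -> None:
    """Write a configuration document that ``load_inputs`` round-trips."""
    spec_by_name = {s.name: s for s in specs}
    parameters: dict[str, Any] = {}
    for f in dataclasses.fields(ModelInputs):
        if f.name in _STRUCTURAL_KEYS or f.name.endswith("_ci"):
            continue
        entry: dict[str, Any] = {"value": getattr(inputs, f.name)}
        if f.name in spec_by_name:
            s = spec_by_name[f.name]
            entry.update(low=s.low, high=s.high, dist=s.dist)
        else:
            entry["dist"] = "fixed"
        parameters[f.name] = entry
    doc = {
        "structural": {k: getattr(inputs, k) for k in _STRUCTURAL_KEYS},
        "parameters": parameters,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


@dataclass(frozen=True)
class BuiltModel:
    """Engine-ready objects derived from one ``ModelInputs`` record."""

    config: ModelConfig
    os_params: WeibullParams
    pfs_params: WeibullParams
    reference_arm: TreatmentArm
    comparator_arm: TreatmentArm
    costs: CostInputs
    utilities: UtilitySet
    profile: PatientProfile


def build_model(inputs: ModelInputs) -> BuiltModel:
    """Assemble arms, curves, costs and utilities from the flat inputs."""
    config = ModelConfig(
        cycle_days=inputs.cycle_days,
        horizon_years=inputs.horizon_years,
        annual_discount=inputs.discount_rate,
        wtp_per_qaly=inputs.wtp_per_qaly_usd,
        fx_cny_per_usd=inputs.fx_cny_per_usd,
        max_chemo_cycles=inputs.max_chemo_cycles,
        p_subsequent_therapy=inputs.p_subsequent_therapy,
        half_cycle_correction=inputs.half_cycle_correction,
        billing=inputs.billing,
        effectiveness_measure=inputs.effectiveness_measure,
    )
    chemo_backbone = (
        DrugComponent(
            name="paclitaxel",
            unit_mg=175.0,
            unit_price=inputs.paclitaxel_price,
            dose_rule="per_bsa",
            dose_value=175.0,
            cycles_cap=inputs.max_chemo_cycles,
        ),
        DrugComponent(
            name="carboplatin",
            unit_mg=6.0,
            unit_price=inputs.carboplatin_price,
            dose_rule="calvert",
            dose_value=inputs.carboplatin_target_auc,
            cycles_cap=inputs.max_chemo_cycles,
        ),
    )
    ly01008 = DrugComponent(
        name="ly01008",
        unit_mg=15.0,
        unit_price=inputs.ly01008_price,
        dose_rule="per_kg",
        dose_value=inputs.ly01008_dose_mg_per_kg,
        cycles_cap=None,  # maintenance until progression or discontinuation
        dose_multiplier=inputs.ly01008_dose_multiplier,
    )
    hr = HazardRatioPair(
        hr_os=inputs.hr_os,
        hr_os_ci=_widen_ci(inputs.hr_os, inputs.hr_os_ci),
        hr_pfs=inputs.hr_pfs,
        hr_pfs_ci=_widen_ci(inputs.hr_pfs, inputs.hr_pfs_ci),
    )
    reference = TreatmentArm(
        name="chemotherapy",
        hr=HazardRatioPair.identity(),
        p_discontinue_ae=inputs.p_discontinue_chemo,
        ae_cost=inputs.ae_cost_chemo,
        ae_disutility=inputs.disutility_chemo,
        regimen=chemo_backbone,
    )
    comparator = TreatmentArm(
        name="ly01008_chemotherapy",
        hr=hr,
        p_discontinue_ae=inputs.p_discontinue_combo,
        ae_cost=inputs.ae_cost_combo,
        ae_disutility=inputs.disutility_combo,
        regimen=(ly01008,) + chemo_backbone,
    )
    return BuiltModel(
        config=config,
        os_params=WeibullParams(inputs.weibull_os_scale, inputs.weibull_os_shape),
        pfs_params=WeibullParams(inputs.weibull_pfs_scale, inputs.weibull_pfs_shape),
        reference_arm=reference,
        comparator_arm=comparator,
        costs=CostInputs(
            followup_per_cycle=inputs.followup_cost,
            subsequent_per_cycle=inputs.subsequent_cost,
            bsc_per_cycle=inputs.bsc_cost,
            palliative_per_cycle=inputs.palliative_cost,
        ),
        utilities=UtilitySet(u_pfs=inputs.u_pfs, u_pd=inputs.u_pd),
        profile=PatientProfile(
            weight_kg=inputs.weight,
            bsa_m2=inputs.bsa,
            crcl_ml_min=inputs.crcl,
        ),
    )


def _widen_ci(point: float, ci: tuple[float, float]) -> tuple[float, float]:
    """CI that always brackets the point, so sensitivity overrides of the
    point estimate (e.g. hr_os at its own CI limit) stay constructible."""
    lo, hi = ci
    return (min(lo, point), max(hi, point))


def default_param_specs(specs: list[ParamSpec] | None = None) -> list[ParamSpec]:
    """Sensitivity table: 95% CIs for HRs/utilities, 0-8% for the discount
    rate, +/-50% of baseline for everything else; Weibull parameters fixed."""
    if specs is None:
        _, specs = default_inputs()
    return list(specs)
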