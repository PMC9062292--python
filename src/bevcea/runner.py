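"""High-level pipeline: base case, dosage scenario, DSA and PSA runs.

``evaluate`` is the single entry every analysis goes through: it takes a
flat ``ModelInputs`` record (optionally with named overrides), simulates
both arms, and returns discounted outcomes plus the incremental
comparison.  The ``run_*`` functions wrap it with result dictionaries,
file writers and a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Sequence

from . import __version__
from .dsa import TornadoEntry, one_way, tornado_frame, tornado_plot
from .economics import ArmResult, CEResult, accumulate, convert_currency, icer, nmb
from .markov import CohortTrace, run_cohort
from .params import (
    CALIBRATED_STRUCTURAL,
    ModelInputs,
    ParamSpec,
    build_model,
    default_inputs,
)
from .psa import (
    CEACPoint,
    PSAResult,
    TwoArmEval,
    ce_plane_plot,
    ceac,
    ceac_frame,
    ceac_plot,
    run_psa,
    samples_frame,
)

__all__ = [
    "TwoArmOutcome",
    "RunManifest",
    "evaluate",
    "make_runner",
    "run_base_case",
    "run_scenario",
    "run_dsa",
    "run_psa_analysis",
]


@dataclass(frozen=True)
class TwoArmOutcome:
    """Both arms' discounted outcomes and their incremental comparison."""

    reference: ArmResult
    comparator: ArmResult
    ce: CEResult
    nmb_at_wtp: float
    wtp: float
    reference_trace: CohortTrace
    comparator_trace: CohortTrace

    @property
    def cost_effective(self) -> bool:
        return self.nmb_at_wtp >= 0.0


def evaluate(
    inputs: ModelInputs, overrides: Mapping[str, float] | None = None
) -> TwoArmOutcome:
    """Run the full two-arm comparison for one parameter vector."""
    if overrides:
        inputs = inputs.with_overrides(**dict(overrides))
    m = build_model(inputs)
    traces = {}
    results = {}
    for arm in (m.reference_arm, m.comparator_arm):
        trace = run_cohort(arm, m.config, m.os_params, m.pfs_params)
        traces[arm.name] = trace
        results[arm.name] = accumulate(
            trace, arm, m.config, m.costs, m.utilities, m.profile
        )
    ref = results[m.reference_arm.name]
    comp = results[m.comparator_arm.name]
    ce = icer(ref, comp, measure=m.config.effectiveness_measure)
    return TwoArmOutcome(
        reference=ref,
        comparator=comp,
        ce=ce,
        nmb_at_wtp=nmb(ce, m.config.wtp_per_qaly),
        wtp=m.config.wtp_per_qaly,
        reference_trace=traces[m.reference_arm.name],
        comparator_trace=traces[m.comparator_arm.name],
    )


def make_runner(inputs: ModelInputs, kind: str = "ce"):
    """Adapter turning ``evaluate`` into the callable DSA/PSA expect."""
    if kind == "ce":
        return lambda overrides: evaluate(inputs, overrides).ce
    if kind == "psa":
        def _runner(overrides: Mapping[str, float]) -> TwoArmEval:
            out = evaluate(inputs, overrides)
            return TwoArmEval(
                reference=out.reference, comparator=out.comparator, ce=out.ce
            )
        return _runner
    raise ValueError(f"unknown runner kind {kind!r}")


@dataclass(frozen=True)
class RunManifest:
    """Provenance record written next to every output set."""

    command: str
    config_hash: str
    seed: int | None
    package_version: str
    timestamp: str
    calibration_metadata: dict[str, Any]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2) + "\n"


def _config_hash(inputs: ModelInputs) -> str:
    payload = json.dumps(dataclasses.asdict(inputs), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _manifest(command: str, inputs: ModelInputs, seed: int | None) -> RunManifest:
    return RunManifest(
        command=command,
        config_hash=_config_hash(inputs),
        seed=seed,
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        calibration_metadata=dict(CALIBRATED_STRUCTURAL),
    )


def _arm_payload(res: ArmResult, fx: float) -> dict[str, float]:
    return {
        "cost_usd": round(res.cost, 2),
        "cost_cny": round(convert_currency(res.cost, "usd_to_cny", fx), 2),
        "qalys": round(res.qalys, 4),
        "life_years_discounted": round(res.life_years_discounted, 4),
        "life_years": round(res.life_years, 4),
    }


def results_payload(outcome: TwoArmOutcome, inputs: ModelInputs) -> dict[str, Any]:
    """JSON-ready summary of one two-arm evaluation."""
    fx = inputs.fx_cny_per_usd
    ce = outcome.ce
    incremental: dict[str, Any] = {
        "delta_cost_usd": round(ce.delta_cost, 2),
        "delta_cost_cny": round(convert_currency(ce.delta_cost, "usd_to_cny", fx), 2),
        "delta_effectiveness": round(ce.delta_qalys, 4),
        "icer_usd": None if ce.icer is None else round(ce.icer, 2),
        "icer_cny": None
        if ce.icer is None
        else round(convert_currency(ce.icer, "usd_to_cny", fx), 2),
        "icer_undefined": ce.icer is None,
        "dominant": ce.dominant,
        "dominated": ce.dominated,
        "nmb_usd_at_wtp": round(outcome.nmb_at_wtp, 2),
        "wtp_usd": inputs.wtp_per_qaly_usd,
        "cost_effective": outcome.cost_effective,
    }
    return {
        "arms": {
            outcome.reference.name: _arm_payload(outcome.reference, fx),
            outcome.comparator.name: _arm_payload(outcome.comparator, fx),
        },
        "incremental": incremental,
        "effectiveness_measure": inputs.effectiveness_measure,
        "config_echo": {
            k: getattr(inputs, k)
            for k in (
                "cycle_days",
                "horizon_years",
                "discount_rate",
                "wtp_per_qaly_usd",
                "fx_cny_per_usd",
                "ly01008_dose_mg_per_kg",
                "ly01008_dose_multiplier",
            )
        },
        "calibration_metadata": dict(CALIBRATED_STRUCTURAL),
    }


def _write_json(payload: Mapping[str, Any], path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_base_case(
    inputs: ModelInputs | None = None, out_dir: str | Path | None = None
) -> dict[str, Any]:
    """Both arms at base values (LY01008 15 mg/kg); optional file output."""
    if inputs is None:
        inputs, _ = default_inputs()
    outcome = evaluate(inputs)
    payload = results_payload(outcome, inputs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(payload, out / "base_case.json")
        outcome.reference_trace.to_csv(out / "trace_chemotherapy.csv")
        outcome.comparator_trace.to_csv(out / "trace_ly01008_chemotherapy.csv")
        (out / "manifest_base_case.json").write_text(
            _manifest("base-case", inputs, None).to_json()
        )
    return payload


def run_scenario(
    inputs: ModelInputs | None = None,
    dose_multiplier: float = 0.5,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Real-world dosage scenario: LY01008 dose scaled (default halved)."""
    if inputs is None:
        inputs, _ = default_inputs()
    if dose_multiplier <= 0:
        raise ValueError("dose_multiplier must be > 0")
    scen = inputs.with_overrides(ly01008_dose_multiplier=dose_multiplier)
    payload = run_base_case(scen, out_dir=None)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(payload, out / "scenario.json")
        (out / "manifest_scenario.json").write_text(
            _manifest(f"scenario(dose_multiplier={dose_multiplier})", scen, None).to_json()
        )
    return payload


def run_dsa(
    inputs: ModelInputs | None = None,
    specs: Sequence[ParamSpec] | None = None,
    out_dir: str | Path | None = None,
) -> list[TornadoEntry]:
    """One-way DSA over all ranged parameters, tornado-ranked."""
    if inputs is None or specs is None:
        default_in, default_specs = default_inputs()
        inputs = inputs or default_in
        specs = specs if specs is not None else default_specs
    entries = one_way(specs, make_runner(inputs, "ce"), wtp=inputs.wtp_per_qaly_usd)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tornado_frame(entries).to_csv(out / "tornado.csv", index=False)
        tornado_plot(entries, out / "tornado.svg", wtp=inputs.wtp_per_qaly_usd)
        (out / "manifest_dsa.json").write_text(
            _manifest("dsa", inputs, None).to_json()
        )
    return entries


def run_psa_analysis(
    inputs: ModelInputs | None = None,
    specs: Sequence[ParamSpec] | None = None,
    n_draws: int = 1000,
    seed: int = 0,
    wtp_grid: Sequence[float] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[PSAResult, list[CEACPoint]]:
    """Monte-Carlo PSA plus the acceptability curve over a WTP grid."""
    if inputs is None or specs is None:
        default_in, default_specs = default_inputs()
        inputs = inputs or default_in
        specs = specs if specs is not None else default_specs
    if wtp_grid is None:
        wtp = inputs.wtp_per_qaly_usd
        wtp_grid = [round(f * wtp) for f in
                    (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 3.0, 4.0, 6.0)]
    result = run_psa(specs, make_runner(inputs, "psa"), n_draws=n_draws, seed=seed)
    curve = ceac(result.samples, wtp_grid)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        samples_frame(result.samples).to_csv(out / "psa_samples.csv", index=False)
        ceac_frame(curve).to_csv(out / "ceac.csv", index=False)
        ceac_plot(curve, out / "ceac.svg", wtp=inputs.wtp_per_qaly_usd)
        ce_plane_plot(result.samples, out / "ce_plane.svg", wtp=inputs.wtp_per_qaly_usd)
        (out / "manifest_psa.json").write_text(
            _manifest(f"psa(n={n_draws})", inputs, seed).to_json()
        )
    return result, curve
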