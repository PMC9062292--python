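"""Probabilistic sensitivity analysis: Monte-Carlo parameter uncertainty.

Each non-fixed parameter is assigned a sampling distribution by the
method of moments from its base value and range (sd = (high-low)/3.92,
the range being read as a 95% interval): Beta for probabilities and
utilities, Gamma for costs, Normal for anthropometrics.  Hazard ratios
are sampled log-normally by default — normal on the log scale with
sd = (log high - log low)/3.92 — because a plain normal can go negative;
a plain-normal option (truncated at machine epsilon) is retained.

One master seed spawns an independent substream per draw, so draws are
order-independent and reproducible.  Draws whose sampled parameters
violate model validity (e.g. u_pd > u_pfs) are re-sampled up to 100
times from the draw's own substream and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import ArmResult, CEResult
from .params import ParamSpec

__all__ = [
    "PSASample",
    "CEACPoint",
    "PSAResult",
    "build_distribution",
    "run_psa",
    "ceac",
    "ceac_frame",
    "samples_frame",
]

ModelRunner = Callable[[Mapping[str, float]], "TwoArmEval"]


@dataclass(frozen=True)
class TwoArmEval:
    """What the PSA needs back from one model evaluation."""

    reference: ArmResult
    comparator: ArmResult
    ce: CEResult


@dataclass(frozen=True)
class PSASample:
    draw_index: int
    parameters: dict[str, float]
    reference: ArmResult
    comparator: ArmResult
    delta_cost: float
    delta_qalys: float
    resamples: int = 0


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    prob_ce: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob_ce <= 1.0):
            raise ValueError("prob_ce must lie in [0, 1]")


@dataclass(frozen=True)
class PSAResult:
    samples: list[PSASample]
    n_failed: int
    total_resamples: int


def build_distribution(
    spec: ParamSpec, hr_scale: str = "log"
) -> Callable[[np.random.Generator, int], np.ndarray]:
    """Sampler for one parameter, mean-matched to its base value.

    Degenerate ranges yield a point mass at the base value.  ``hr_scale``
    selects log-normal (default) or truncated plain-normal sampling for
    hazard-ratio parameters (names starting with ``hr_``).
    """
    if spec.dist == "fixed":
        raise ValueError(f"{spec.name} is fixed; no distribution to build")
    if spec.degenerate:
        base = spec.base
        return lambda rng, size=1: np.full(size, base)

    mean = spec.base
    sd = (spec.high - spec.low) / (2.0 * 1.96)
    if sd <= 0:
        raise ValueError(f"{spec.name}: non-positive sd from range")

    if spec.name.startswith("hr_"):
        if hr_scale == "log":
            mu = np.log(mean)
            sigma = (np.log(spec.high) - np.log(spec.low)) / (2.0 * 1.96)
            return lambda rng, size=1: rng.lognormal(mu, sigma, size)
        if hr_scale == "normal":
            return lambda rng, size=1: np.maximum(
                rng.normal(mean, sd, size), np.finfo(float).eps
            )
        raise ValueError(f"unknown hr_scale {hr_scale!r}")

    if spec.dist == "beta":
        if not (0.0 < mean < 1.0):
            raise ValueError(f"{spec.name}: beta mean must lie in (0, 1)")
        common = mean * (1.0 - mean) / sd**2 - 1.0
        if common <= 0:
            raise ValueError(f"{spec.name}: sd too large for a beta on [0, 1]")
        alpha, beta = mean * common, (1.0 - mean) * common
        return lambda rng, size=1: rng.beta(alpha, beta, size)
    if spec.dist == "gamma":
        shape = (mean / sd) ** 2
        scale = sd**2 / mean
        return lambda rng, size=1: rng.gamma(shape, scale, size)
    if spec.dist == "normal":
        return lambda rng, size=1: rng.normal(mean, sd, size)
    raise ValueError(f"{spec.name}: unknown distribution {spec.dist!r}")


def _valid_draw(values: Mapping[str, float]) -> bool:
    """Joint validity of one sampled parameter vector."""
    u_pfs = values.get("u_pfs", 0.856)
    u_pd = values.get("u_pd", 0.768)
    if not (0.0 < u_pd <= u_pfs <= 1.0):
        return False
    for name, v in values.items():
        if name.startswith(("p_discontinue",)) and not (0.0 <= v < 1.0):
            return False
        if name.startswith("disutility") and not (0.0 <= v < u_pfs):
            return False
        if name.startswith("hr_") and v <= 0:
            return False
        if name in ("weight", "bsa", "crcl") and v <= 0:
            return False
        if (name.endswith(("_price", "_cost")) or name == "discount_rate") and v < 0:
            return False
    return True


def run_psa(
    specs: Sequence[ParamSpec],
    model_runner: ModelRunner,
    n_draws: int = 1000,
    seed: int = 0,
    hr_scale: str = "log",
    max_resamples: int = 100,
) -> PSAResult:
    """Monte-Carlo propagation: ``n_draws`` joint re-evaluations.

    Parameters with ``dist: fixed`` (Weibull curves, discount rate) stay
    at base.  Per-draw evaluation failures are excluded and counted.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    sampled = [s for s in specs if s.dist != "fixed"]
    samplers = {s.name: build_distribution(s, hr_scale=hr_scale) for s in sampled}
    streams = np.random.SeedSequence(seed).spawn(n_draws)
    samples: list[PSASample] = []
    n_failed = 0
    total_resamples = 0
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        values: dict[str, float] = {}
        attempts = 0
        while True:
            values = {name: float(samplers[name](rng, 1)[0]) for name in samplers}
            if _valid_draw(values):
                break
            attempts += 1
            if attempts >= max_resamples:
                raise RuntimeError(
                    f"draw {i}: no valid parameter vector in {max_resamples} attempts"
                )
        total_resamples += attempts
        try:
            ev = model_runner(values)
        except Exception:  # noqa: BLE001 - draw flagged and excluded
            n_failed += 1
            continue
        samples.append(
            PSASample(
                draw_index=i,
                parameters=values,
                reference=ev.reference,
                comparator=ev.comparator,
                delta_cost=ev.ce.delta_cost,
                delta_qalys=ev.ce.delta_qalys,
                resamples=attempts,
            )
        )
    return PSAResult(samples=samples, n_failed=n_failed, total_resamples=total_resamples)


def ceac(samples: Sequence[PSASample], wtp_grid: Sequence[float]) -> list[CEACPoint]:
    """P(cost-effective) = fraction of draws with non-negative NMB, per WTP."""
    if not samples:
        raise ValueError("no PSA samples supplied")
    dq = np.array([s.delta_qalys for s in samples])
    dc = np.array([s.delta_cost for s in samples])
    return [
        CEACPoint(wtp=float(w), prob_ce=float(np.mean(w * dq - dc >= 0.0)))
        for w in wtp_grid
    ]


def ceac_frame(points: Sequence[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame({"wtp": [p.wtp for p in points],
                         "prob_ce": [p.prob_ce for p in points]})


def samples_frame(samples: Sequence[PSASample]) -> pd.DataFrame:
    """Tidy draws: sampled parameters plus per-arm discounted outcomes."""
    rows = []
    for s in samples:
        row: dict[str, float] = {"draw": s.draw_index, **s.parameters}
        row.update(
            cost_ref=s.reference.cost,
            qaly_ref=s.reference.qalys,
            ly_disc_ref=s.reference.life_years_discounted,
            cost_comp=s.comparator.cost,
            qaly_comp=s.comparator.qalys,
            ly_disc_comp=s.comparator.life_years_discounted,
            delta_cost=s.delta_cost,
            delta_qalys=s.delta_qalys,
            resamples=s.resamples,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def ce_plane_plot(samples: Sequence[PSASample], path, wtp: float | None = None) -> None:
    """Incremental cost vs incremental effectiveness scatter."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    dq = [s.delta_qalys for s in samples]
    dc = [s.delta_cost for s in samples]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(dq, dc, s=6, alpha=0.4)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    if wtp is not None:
        xs = np.linspace(min(dq + [0]), max(dq + [0]), 50)
        ax.plot(xs, wtp * xs, "r--", lw=1, label=f"WTP {wtp:,.0f}")
        ax.legend(fontsize=8)
    ax.set_xlabel("incremental effectiveness")
    ax.set_ylabel("incremental cost (US$)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def ceac_plot(points: Sequence[CEACPoint], path, wtp: float | None = None) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot([p.wtp for p in points], [p.prob_ce for p in points], "-o", ms=3)
    if wtp is not None:
        ax.axvline(wtp, color="r", ls="--", lw=1)
    ax.set_xlabel("willingness-to-pay (US$ per unit effectiveness)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
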