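"""One-way deterministic sensitivity analysis with tornado ranking.

Each parameter is pushed in turn to the low and high end of its range
(95% CI for hazard ratios and utilities, 0-8% for the discount rate,
+/-50% of baseline otherwise) while everything else stays at base, the
full two-arm model is re-run, and the resulting ICERs are ranked by
spread.  A parameter whose extreme makes the comparator dominated
(negative incremental effectiveness) still yields an ICER value, but
cost-effectiveness calls are made on net monetary benefit, never on the
raw ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .economics import CEResult
from .params import ParamSpec

__all__ = ["TornadoEntry", "one_way", "tornado_frame", "tornado_plot"]

#: A model runner maps parameter overrides {name: value} to the
#: incremental result of the full two-arm comparison.
ModelRunner = Callable[[Mapping[str, float]], CEResult]


@dataclass(frozen=True)
class TornadoEntry:
    """ICERs at the two ends of one parameter's range."""

    name: str
    base_icer: float
    icer_at_low: float | None
    icer_at_high: float | None
    nmb_at_low: float
    nmb_at_high: float
    error: str | None = None

    @property
    def spread(self) -> float:
        if self.icer_at_low is None or self.icer_at_high is None:
            return 0.0
        return abs(self.icer_at_high - self.icer_at_low)


def one_way(
    specs: Sequence[ParamSpec],
    model_runner: ModelRunner,
    wtp: float,
) -> list[TornadoEntry]:
    """Run the two-arm model at each spec's low and high value.

    Returns entries sorted by decreasing ICER spread.  A model failure at
    an extreme is recorded on the entry and the analysis continues.
    """
    base_ce = model_runner({})
    if base_ce.icer is None:
        raise ValueError("base case has zero incremental effectiveness")
    entries: list[TornadoEntry] = []
    for spec in specs:
        results: dict[str, CEResult] = {}
        error = None
        for bound, value in (("low", spec.low), ("high", spec.high)):
            try:
                results[bound] = model_runner({spec.name: value})
            except Exception as exc:  # noqa: BLE001 - entry-level capture
                error = f"{bound}: {exc}"
                break
        if error is not None:
            entries.append(
                TornadoEntry(
                    name=spec.name,
                    base_icer=base_ce.icer,
                    icer_at_low=None,
                    icer_at_high=None,
                    nmb_at_low=float("nan"),
                    nmb_at_high=float("nan"),
                    error=error,
                )
            )
            continue
        lo, hi = results["low"], results["high"]
        entries.append(
            TornadoEntry(
                name=spec.name,
                base_icer=base_ce.icer,
                icer_at_low=lo.icer,
                icer_at_high=hi.icer,
                nmb_at_low=wtp * lo.delta_qalys - lo.delta_cost,
                nmb_at_high=wtp * hi.delta_qalys - hi.delta_cost,
            )
        )
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [e.name for e in entries],
            "base_icer": [e.base_icer for e in entries],
            "icer_low": [e.icer_at_low for e in entries],
            "icer_high": [e.icer_at_high for e in entries],
            "spread": [e.spread for e in entries],
            "nmb_low": [e.nmb_at_low for e in entries],
            "nmb_high": [e.nmb_at_high for e in entries],
            "error": [e.error for e in entries],
        }
    )


def tornado_plot(
    entries: Sequence[TornadoEntry],
    path: str | Path,
    top: int = 10,
    wtp: float | None = None,
) -> None:
    """Horizontal tornado diagram of the ``top`` widest parameters."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    shown = [e for e in entries if e.error is None][:top]
    fig, ax = plt.subplots(figsize=(7, 0.45 * max(len(shown), 1) + 1.2))
    base = shown[0].base_icer if shown else 0.0
    for i, e in enumerate(reversed(shown)):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878d0")
    ax.axvline(base, color="k", lw=1, label="base-case ICER")
    if wtp is not None:
        ax.axvline(wtp, color="r", lw=1, ls="--", label="WTP")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([e.name for e in reversed(shown)])
    ax.set_xlabel("ICER (US$ / unit effectiveness)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
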