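"""Shared fixtures: default model inputs and expensive session-scoped runs."""

from __future__ import annotations

import time

import pytest

from bevcea import default_inputs, evaluate, run_psa_analysis

#: Seed used by every stochastic test in the suite.
SUITE_SEED = 20201231


@pytest.fixture(scope="session")
def default_model():
    """Packaged base-case inputs and their sensitivity-parameter table."""
    return default_inputs()


@pytest.fixture(scope="session")
def inputs(default_model):
    return default_model[0]


@pytest.fixture(scope="session")
def specs(default_model):
    return default_model[1]


@pytest.fixture(scope="session")
def base_outcome(inputs):
    """Both arms evaluated once at base values."""
    return evaluate(inputs)


@pytest.fixture(scope="session")
def scenario_outcome(inputs):
    """Both arms with the LY01008 dose halved (7.5 mg/kg)."""
    return evaluate(inputs, {"ly01008_dose_multiplier": 0.5})


@pytest.fixture(scope="session")
def psa_run(inputs, specs):
    """Full 1,000-draw PSA with the suite seed; returns (result, curve, seconds)."""
    t0 = time.perf_counter()
    result, curve = run_psa_analysis(
        inputs, specs, n_draws=1000, seed=SUITE_SEED, out_dir=None
    )
    elapsed = time.perf_counter() - t0
    return result, curve, elapsed
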