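"""Weibull curves, hazard-ratio adjustment and right-censored MLE."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from bevcea import (
    SurvivalRecord,
    WeibullParams,
    apply_hazard_ratio,
    conditional_exit_prob,
    fit_weibull_mle,
    survival,
    weibull_median,
)

OS = WeibullParams(0.004716, 1.533854)
PFS = WeibullParams(0.003867, 2.335407)


class TestSurvivalCurve:
    @pytest.mark.parametrize("params", [OS, PFS], ids=["os", "pfs"])
    def test_survival_starts_at_one(self, params):
        assert survival(params, 0.0) == 1.0

    @pytest.mark.parametrize(
        ("params", "expected_median"),
        [(OS, 25.88), (PFS, 9.22)],
        ids=["os", "pfs"],
    )
    def test_median_matches_analytic_formula_and_root(self, params, expected_median):
        """Analytic median (ln 2 / scale)^(1/shape) agrees with root-finding
        on S(t) = 1/2, and sits where a 3-week cycle grid puts the trial
        medians (~17.9 and ~6.4 months)."""
        analytic = weibull_median(params)
        root = brentq(lambda t: survival(params, t) - 0.5, 1e-6, 1e4, xtol=1e-10)
        assert analytic == pytest.approx(root, abs=1e-6)
        assert survival(params, analytic) == pytest.approx(0.5, abs=1e-12)
        assert analytic == pytest.approx(expected_median, abs=0.01)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival(OS, -0.1)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            WeibullParams(-1.0, 1.0)
        with pytest.raises(ValueError):
            WeibullParams(0.01, 0.0)


class TestConditionalExitProb:
    def test_first_cycle_collapses_to_one_minus_exp(self):
        assert conditional_exit_prob(OS, 1) == pytest.approx(
            1.0 - math.exp(-0.004716), abs=1e-12
        )
        assert conditional_exit_prob(PFS, 1) == pytest.approx(
            1.0 - math.exp(-0.003867), abs=1e-12
        )

    def test_identity_with_survival_ratio_over_full_horizon(self):
        """1 - S(t)/S(t-1) to 1e-12 for every cycle of the 30-year grid."""
        t = np.arange(1, 522)
        direct = conditional_exit_prob(OS, t)
        ratio = 1.0 - survival(OS, t) / survival(OS, t - 1)
        assert np.max(np.abs(direct - ratio)) < 1e-12

    def test_vanishing_scale_limit_gives_zero_hazard(self):
        tiny = WeibullParams(1e-300, 2.0)
        assert conditional_exit_prob(tiny, 50) == pytest.approx(0.0, abs=1e-290)

    def test_cycle_below_one_rejected(self):
        with pytest.raises(ValueError):
            conditional_exit_prob(OS, 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        scale=st.floats(1e-5, 0.02),
        shape=st.floats(0.3, 2.0),
        t=st.integers(1, 521),
    )
    def test_probability_bounds_hold_everywhere(self, scale, shape, t):
        # parameter box keeps per-cycle hazard increments below ~21 so the
        # exit probability stays strictly below 1 in double precision
        params = WeibullParams(scale, shape)
        p = conditional_exit_prob(params, t)
        assert 0.0 <= p < 1.0
        s = survival(params, float(t))
        assert 0.0 < s <= 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(scale=st.floats(1e-4, 0.05), shape=st.floats(1.01, 4.0))
    def test_hazard_nondecreasing_when_shape_above_one(self, scale, shape):
        params = WeibullParams(scale, shape)
        probs = conditional_exit_prob(params, np.arange(1, 100))
        assert np.all(np.diff(probs) >= -1e-15)


class TestHazardRatio:
    def test_identity_and_direct_multiplication(self):
        assert apply_hazard_ratio(OS, 1.0) == OS
        adjusted = apply_hazard_ratio(OS, 0.654)
        assert adjusted.scale == pytest.approx(0.004716 * 0.654, rel=1e-15)
        assert adjusted.shape == OS.shape

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hr1=st.floats(0.05, 3.0), hr2=st.floats(0.05, 3.0))
    def test_composition_equals_product(self, hr1, hr2):
        once = apply_hazard_ratio(OS, hr1 * hr2)
        twice = apply_hazard_ratio(apply_hazard_ratio(OS, hr1), hr2)
        assert twice.scale == pytest.approx(once.scale, rel=1e-12)
        assert twice.shape == once.shape

    def test_protective_hr_dominates_at_every_time(self):
        t = np.linspace(0.5, 200, 400)
        s_ref = survival(OS, t)
        s_adj = survival(apply_hazard_ratio(OS, 0.5), t)
        assert np.all(s_adj > s_ref)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(OS, 0.0)


def _draw_records(params, n, censor, seed):
    """Independent inverse-CDF draws with administrative censoring."""
    rng = np.random.default_rng(seed)
    t = (-np.log(rng.random(n)) / params.scale) ** (1.0 / params.shape)
    return [
        SurvivalRecord(time=min(ti, censor), event=bool(ti <= censor)) for ti in t
    ]


class TestWeibullMLE:
    # censoring time with ~30% administrative censoring under the OS curve
    CENSOR = (math.log(1 / 0.3) / OS.scale) ** (1 / OS.shape)

    def test_parameter_recovery_under_censoring(self):
        records = _draw_records(OS, 10_000, self.CENSOR, seed=11)
        frac_censored = 1 - np.mean([r.event for r in records])
        assert 0.25 < frac_censored < 0.35
        fit = fit_weibull_mle(records)
        assert fit.params.scale == pytest.approx(OS.scale, rel=0.05)
        assert fit.params.shape == pytest.approx(OS.shape, rel=0.05)
        assert fit.se_scale > 0 and fit.se_shape > 0

    def test_estimator_is_consistent(self):
        """Relative error shrinks by an order of magnitude from n=1e3 to 1e4."""
        errs = {}
        for n in (1_000, 10_000):
            fit = fit_weibull_mle(_draw_records(OS, n, self.CENSOR, seed=7))
            errs[n] = abs(fit.params.shape - OS.shape) / OS.shape + abs(
                fit.params.scale - OS.scale
            ) / OS.scale
        assert errs[10_000] < errs[1_000]

    def test_exponential_special_case_recovers_unit_shape(self):
        expo = WeibullParams(0.05, 1.0)
        fit = fit_weibull_mle(_draw_records(expo, 5_000, 100.0, seed=3))
        assert abs(fit.params.shape - 1.0) < 1.96 * fit.se_shape

    def test_agrees_with_lifelines(self):
        """Independent cross-check: lifelines' Weibull fitter, reparametrised
        from S(t)=exp(-(t/lambda)^rho) to our scale = lambda^(-rho)."""
        from lifelines import WeibullFitter

        records = _draw_records(OS, 4_000, self.CENSOR, seed=5)
        times = [r.time for r in records]
        events = [r.event for r in records]
        wf = WeibullFitter().fit(times, events)
        ll_scale = wf.lambda_ ** (-wf.rho_)
        ours = fit_weibull_mle(records)
        assert ours.params.scale == pytest.approx(ll_scale, rel=1e-3)
        assert ours.params.shape == pytest.approx(wf.rho_, rel=1e-3)

    @pytest.mark.parametrize(
        "records",
        [
            [],
            [SurvivalRecord(5.0, False)] * 10,
            [SurvivalRecord(5.0, True)] + [SurvivalRecord(5.0, False)] * 9,
        ],
        ids=["empty", "all-censored", "one-event"],
    )
    def test_degenerate_inputs_rejected(self, records):
        with pytest.raises(ValueError):
            fit_weibull_mle(records)

    def test_nonpositive_times_rejected(self):
        recs = [SurvivalRecord(0.0, True), SurvivalRecord(2.0, True)]
        with pytest.raises(ValueError):
            fit_weibull_mle(recs)
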