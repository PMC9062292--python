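"""Parameter recovery: simulate survival data, refit the Weibull curves.

Draws a synthetic cohort from the base-case overall-survival Weibull
(administratively censored), fits the right-censored maximum-likelihood
estimator, and compares the recovered scale/shape with the truth.
"""

from bevcea import (
    HazardRatioPair,
    SyntheticCohortSpec,
    WeibullParams,
    km_fit_roundtrip,
    weibull_median,
)

os_params = WeibullParams(0.004716, 1.533854)
pfs_params = WeibullParams(0.003867, 2.335407)
print(f"true OS median: {weibull_median(os_params):.2f} cycles "
      f"(~{weibull_median(os_params) * 21 / 30.44:.1f} months)")

spec = SyntheticCohortSpec(
    n_patients=10_000,
    os_params=os_params,
    pfs_params=pfs_params,
    hr_pair=HazardRatioPair.identity(),
    censor_time=100.0,
    seed=2024,
)
report = km_fit_roundtrip(spec, endpoint="os")
print(f"fitted scale {report.fitted.scale:.6f} (true {os_params.scale}), "
      f"relative error {report.rel_err_scale:.2%}")
print(f"fitted shape {report.fitted.shape:.4f} (true {os_params.shape}), "
      f"relative error {report.rel_err_shape:.2%}")
print(f"events observed: {report.n_events} of {spec.n_patients}")
# Both parameters come back within a few percent at n = 10,000, which is
# what licenses driving the cohort model with curve parameters fitted
# from (reconstructed) trial survival data.
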