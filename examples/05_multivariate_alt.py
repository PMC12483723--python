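"""The packaged three-series scenario: a multivariate ALT round trip.

Simulates the survey-like panel (binary drug-use indicator plus two
4-category scales over six waves, cross-lagged and concomitantly correlated),
fits the generating multivariate ALT and prints the recovered cross-lagged
block for the health series.
"""

import numpy as np

from ordalt import compute_sample_stats, dwls_fit
from ordalt.simulate import nlsy_like_scenario, simulate

scenario = nlsy_like_scenario(n=5000)
panel = simulate(scenario, seed=1)
print("panel:", panel.data.shape, "variables:", panel.var_names)
print("drug-use proportion by wave:",
      np.round([panel.column(0, t).mean() for t in range(6)], 3))

stats = compute_sample_stats(panel)
fit = dwls_fit(stats, scenario.spec)
print(f"\nchi2_adj = {fit.chi2_adj:.1f}, df = {fit.df}, converged = {fit.converged}")

idx = {n: k for k, n in enumerate(fit.param_names)}
truth = {n: v for n, v in zip(scenario.spec.param_names, scenario.theta)}
print(f"\n{'cross-lagged path (wave 4)':34s} {'truth':>6s} {'est':>7s} {'se':>6s}")
for name, label in [
    ("cross[2][0][3]", "health <- prior drug propensity"),
    ("cross[2][1][3]", "health <- prior depression"),
    ("cross[1][2][3]", "depression <- prior health"),
    ("rho[2][3]", "health autoregression"),
]:
    k = idx[name]
    print(f"{label:34s} {truth[name]:6.2f} {fit.theta[k]:7.3f} {fit.se_robust[k]:6.3f}")
print(
    "\nNegative cross-lags: higher drug-use and depression propensities drag"
    "\ndown later perceived health; estimates sit within ~2 SEs of truth."
)
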