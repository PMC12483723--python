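"""Testing threshold invariance with the constrained auxiliary model.

Whether the category cut-points stay put over time is what decides if changes
in response distributions can be read as changes in the underlying means and
variances.  The test fits the auxiliary model with every threshold equated
across waves by DWLS and reports the mean-and-variance-adjusted chi-square.
Both alternative identification rows give the same test — shown below.
"""

import numpy as np

from ordalt import Parameterization as P, build_spec, sample_admissible_theta
from ordalt.auxiliary import test_threshold_invariance
from ordalt.simulate import SimScenario, simulate

# data with truly invariant thresholds (T = 6 waves, 4 categories)
spec = build_spec("saturated", "alt1_inv", T=6, C=4)
theta = np.zeros(spec.n_free)
idx = {n: k for k, n in enumerate(spec.param_names)}
for c, v in enumerate([-0.6, 0.3, 1.2]):
    theta[idx[f"tau[0][{c}]"]] = v
for t in range(1, 6):
    theta[idx[f"mu[0][{t}]"]] = 0.05 * t
    theta[idx[f"sigma2[0][{t}]"]] = 1.0 + 0.08 * t
for i in range(6):
    for j in range(i + 1, 6):
        theta[idx[f"r[{i}][{j}]"]] = 0.45 ** abs(i - j)
panel = simulate(SimScenario(spec, theta, n=5000), seed=3)

for row in (P.ALT1_INV, P.ALT2_INV):
    fit = test_threshold_invariance(panel, row)
    print(
        f"{row:9s}: chi2_adj = {fit.chi2_adj:6.3f}, df = {fit.df}, "
        f"p = {fit.p_value:.3f}, CFI = {fit.fit_indices['CFI']:.3f}, "
        f"BIC' = {fit.fit_indices['BICp']:.1f}"
    )
print(
    "\nSame chi-square and df under either row (they are equivalent); a"
    "\nnon-significant test and negative BIC' support invariant thresholds,"
    "\nas they should here - the data were generated that way."
)
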