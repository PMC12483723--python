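"""Which identification choices matter?  Equivalence of specification pairs.

Fits several identification rows of the growth and autoregressive models to
one panel and shows that the rows theory proves equivalent share chi-square
and df exactly, while the standard delta/theta growth pair and the two
alternative ALT rows genuinely differ.  The closed-form parameter map between
equivalent rows is also demonstrated.
"""

import numpy as np

from ordalt import (
    build_spec,
    compute_sample_stats,
    dwls_fit,
    sample_admissible_theta,
    transform_params,
)
from ordalt.simulate import SimScenario, simulate

# a probe panel misspecified for every candidate (unstructured truth)
gen = build_spec("alt", "alt2_inv", 6, 4)
theta = sample_admissible_theta(gen, np.random.default_rng(42))
panel = simulate(SimScenario(gen, theta, n=2000), seed=7)
stats = compute_sample_stats(panel)

specs = {
    "LGM alt1-inv (delta)": build_spec("lgm", "alt1_inv", 6, 4, placement="delta"),
    "LGM alt1-inv (theta)": build_spec("lgm", "alt1_inv", 6, 4, placement="theta"),
    "LGM alt2-inv": build_spec("lgm", "alt2_inv", 6, 4),
    "LGM standard delta": build_spec("lgm", "standard", 6, 4, placement="delta"),
    "LGM standard theta": build_spec("lgm", "standard", 6, 4, placement="theta"),
    "AR1 standard": build_spec("ar1", "standard", 6, 4),
    "AR1 alt2 (free tau)": build_spec("ar1", "alt2", 6, 4),
    "AR1 alt1-inv (E)": build_spec("ar1", "alt1_inv", 6, 4),
    "AR1 alt2-inv (F)": build_spec("ar1", "alt2_inv", 6, 4),
    "ALT alt1-inv": build_spec("alt", "alt1_inv", 6, 4),
    "ALT alt2-inv": build_spec("alt", "alt2_inv", 6, 4),
}
fits = {}
for label, spec in specs.items():
    f = dwls_fit(stats, spec)
    fits[label] = f
    print(f"{label:22s} chi2 = {f.n * f.F_min:10.4f}  df = {f.df:2d}")

print(
    "\nEqual chi2/df within each equivalent family (growth alt rows; AR1 free-"
    "\nthreshold rows; AR1 E/F) — but the standard delta vs theta growth models"
    "\nand the two alternative ALT rows give different fits: those choices are"
    "\nsubstantive, not cosmetic."
)

e, f = specs["AR1 alt1-inv (E)"], specs["AR1 alt2-inv (F)"]
mapped = transform_params(fits["AR1 alt1-inv (E)"].theta, e, f)
err = np.max(np.abs(mapped - fits["AR1 alt2-inv (F)"].theta))
print(f"\nModel E parameters mapped onto Model F reproduce the dual fit to {err:.1e}.")
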