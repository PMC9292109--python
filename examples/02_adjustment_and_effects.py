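"""Adjustment sets and causal vs bivariate effect sizes on a simulated cohort.

Simulates a cohort from the builtin structural equation model, estimates
standardized total effects using the graph-derived minimal adjustment sets,
and contrasts them with naive single-predictor (bivariate) slopes.  Closed-
form path-product truths from the simulator show which estimator is right.
"""

import cpcausal as cp

config = cp.load_model()
g = config.graph

for exposure in ("Strength", "GDI"):
    res = cp.adjustment_sets(g, exposure, "GMFM", "total")
    print(f"minimal adjustment set for total effect of {exposure}: "
          f"{{{', '.join(sorted(res.chosen))}}}")

spec = cp.default_sem(seed=42)
cohort = cp.simulate(spec, 20_000)
std = cp.standardize_and_orient(cohort.table, config)

print(f"\nsimulated cohort: n={cohort.n}")
print(f"{'exposure':<11} {'total est':>9} {'truth':>7} {'bivariate':>9} "
      f"{'truth':>7}")
for exposure in ("SCALE", "DMC", "Strength", "Spasticity", "GDI", "TibRot"):
    est = cp.estimate_effect(std, config, exposure, "total")
    biv = cp.estimate_effect(std, config, exposure, "bivariate")
    flip = -1.0 if config.meta(exposure).sign_flip else 1.0
    t_tot = flip * cp.true_total_effect(spec, exposure, "GMFM",
                                        standardized=True)
    t_biv = flip * cp.true_bivariate_effect(spec, exposure, "GMFM",
                                            standardized=True)
    print(f"{exposure:<11} {est.beta:>9.3f} {t_tot:>7.3f} "
          f"{biv.beta:>9.3f} {t_biv:>7.3f}")

print(
    "\nAdjusted estimates track the path-product truths; bivariate slopes\n"
    "are inflated for every confounded exposure (all but age), which is the\n"
    "interpretive error the causal analysis exists to avoid."
)
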