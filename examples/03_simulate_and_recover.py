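"""Simulate two-sample summary statistics and recover the causal effect.

Generates a 10-instrument dataset with a true causal effect of 0.28
outcome units per exposure unit, runs harmonization + Wald ratios + IVW,
and repeats over seeds to show that the 95% CI covers the truth at
roughly the nominal rate.
"""

import numpy as np

from mrwald import SimulationConfig, harmonize, ivw_pool, simulate_two_sample, wald_ratio


def fit(seed: int):
    config = SimulationConfig(n_snps=10, seed=seed, allele_swap_fraction=0.3)
    exposure, outcome, truth = simulate_two_sample(config)
    estimates = [wald_ratio(h) for h in harmonize(exposure, outcome)]
    return ivw_pool(estimates), truth


pooled, truth = fit(seed=7)
print(f"true theta = {truth.theta}")
print(f"IVW estimate = {pooled.estimate:.4f} "
      f"(95% CI {pooled.ci_low:.4f} to {pooled.ci_high:.4f}) from "
      f"{pooled.n_snps} instruments")

covered = 0
n_reps = 200
for seed in range(n_reps):
    p, t = fit(seed)
    covered += p.ci_low <= t.theta <= p.ci_high
print(f"\nCI coverage over {n_reps} replicate studies: {covered / n_reps:.3f} "
      "(nominal 0.95)")
# Coverage lands near 0.95; it can sit slightly below nominal because the
# first-order Wald SE ignores exposure-side sampling noise.
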