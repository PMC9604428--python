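"""Relate an individual's intrinsic noise to its growth phenotypes.

Story: per-embryo intrinsic noise (estimated from its own left/right gene
panel) is used as a covariate in a heteroscedastic normal model of log
mass and log growth-factor concentration: both the mean and the spread of
the trait may depend on how noisy the individual's development was.
A litter-size adjustment removes the crowding effect on mass first.
"""

import numpy as np

from fanoise import (
    SimulationConfig,
    adjust_for_litter_size,
    fit_location_scale_regression,
    individual_intrinsic_noise,
    simulate_bilateral_expression,
    simulate_traits,
)

config = SimulationConfig(seed=13, n_genes=100)
matrix, truth = simulate_bilateral_expression(config)

# Per-embryo intrinsic noise from its own bilateral panel.
eta = np.array([
    individual_intrinsic_noise(matrix, j) for j in range(matrix.n_individuals)
])

# Traits generated from the *true* per-embryo noise, as nature would.
traits = simulate_traits(
    np.sqrt(truth["eta2_int_per_individual"]),
    trait_coeffs=config.trait_coeffs,
    seed=config.seed + 1,
    litter_effect=config.litter_effect,
    individual_ids=list(matrix.individual_ids),
)

for trait, column, adjust in (("mass", "mass_g", True),
                              ("plgf", "plgf_pg_ml", False)):
    y = np.log(traits[column].to_numpy())
    if adjust:
        y = adjust_for_litter_size(y, traits["litter_size"].to_numpy())
    fit = fit_location_scale_regression(y, np.log(eta))
    print(f"log {trait} ~ Normal(alpha0 + alpha*log(eta_int), "
          f"exp(beta0 + beta*log(eta_int)))")
    for name, coeffs, ses in (("location", fit.location_coeffs, fit.location_se),
                              ("scale", fit.scale_coeffs, fit.scale_se)):
        line = "  ".join(f"{k} = {v:7.3f} (se {ses[k]:.3f})"
                         for k, v in coeffs.items())
        print(f"  {name:<9} {line}")
    gen = config.trait_coeffs[trait]
    print(f"  generative alpha = {gen['alpha']:.2f}, beta = {gen['beta']:.2f}\n")

print("negative alpha: noisier embryos are smaller on average; positive "
      "beta:\ntheir phenotypes are also more variable.")
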