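"""Generate a virtual landscape and inspect its statistical structure.

Builds a 32x32-km grid of autocorrelated environmental layers, creates five
virtual species with known occupancy and abundance surfaces, and prints the
quantities the rest of the pipeline will try to recover.
"""

import numpy as np

from occ2abund.synthetic import (LandscapeConfig, gen_covariate_stack,
                                 gen_virtual_species)

config = LandscapeConfig(grid_size=32, n_covariates=5, n_species=5, seed=42)
stack = gen_covariate_stack(config)
truth = gen_virtual_species(stack, config)

print(f"covariate layers: {stack.names}")
for i, sp in enumerate(truth.species):
    p = truth.occupancy_surface[i]
    a = truth.abundance_surface[i]
    print(f"{sp}: prevalence(P>0.5) = {(p > 0.5).mean():.2f}, "
          f"zero-abundance cells = {(a == 0).mean():.2f}, "
          f"max abundance = {a.max():.1f} ha/km²")
print(f"interaction matrix (rows = affected species):\n"
      f"{np.round(truth.interaction_matrix, 2)}")
# Prevalence is the fraction of cells a species plausibly occupies; the high
# zero fraction is deliberate — real percent-cover surveys are zero-heavy.
# Negative interaction entries suppress a species' abundance where the
# competitor's occupancy is high.
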