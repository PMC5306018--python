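"""Collinearity pruning: drop one of each covariate pair with |r| > 0.7.

Builds a stack in which several layers are deliberately near-duplicates and
shows which members survive, honoring the priority ranking (1 = most
ecologically important, kept preferentially).
"""

import numpy as np

from occ2abund.covariates import PruneReport, prune_correlated
from occ2abund.grids import CovariateStack, GridSpec

rng = np.random.default_rng(3)
grid = GridSpec(nx=32, ny=32)
stack = CovariateStack(grid)
base = rng.standard_normal((32, 32))
stack.add_layer("temperature", base, priority=1)
stack.add_layer("temp_seasonality", 0.9 * base +
                0.44 * rng.standard_normal((32, 32)), priority=2)
stack.add_layer("precipitation", rng.standard_normal((32, 32)), priority=3)
stack.add_layer("precip_copy", 0.95 * stack.layers["precipitation"] +
                0.31 * rng.standard_normal((32, 32)), priority=4)

report = PruneReport()
pruned = prune_correlated(stack, threshold=0.7, report=report)
print(f"layers in : {stack.names}")
print(f"layers out: {pruned.names}")
print(report.to_frame().to_string(index=False))
# Each report row is one resolved violation: the pair, its Pearson r, and the
# lower-priority member that was removed.
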