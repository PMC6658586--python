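"""Fitting with response times missing at random.

Simulates a testlet dataset, deletes 15% of the cells completely at random,
and fits the model: every Gibbs iteration redraws the missing log times from
their conditional normal given the person's observed times, so the
covariance parameters are estimated from the observed information alone.
"""

import numpy as np

from bcsm import ModelSpec, PriorHyper, run_chain
from bcsm.simulate import SimConfig, simulate_dataset, testlet_layers

layers = testlet_layers(12, 3)
config = SimConfig(
    n_per_group=(200,), p=12, layers=layers,
    delta=(0.25,), Delta=(0.2, 0.0, 0.0), sigma2=1.0,
    missing_rate=0.15,
)
data, truth = simulate_dataset(config, rng=np.random.default_rng(8))
print(f"{data.missing.sum()} of {data.missing.size} cells missing "
      f"({100 * data.missing.mean():.1f}%)")

spec = ModelSpec(n_items=12, n_groups=1, layers=tuple(layers),
                 prior=PriorHyper(1e-3, 1e-3))
chains = run_chain(data, spec, iterations=1500, burn_in=0.1, seed=8)

pm = chains.posterior_means()
print(f"\ndelta : {pm['delta'][0]:.3f} (truth {truth.delta[0]})")
for d in range(3):
    print(f"Delta{d + 1}: {pm['Delta'][0, d]:+.3f} (truth {truth.Delta[0, d]})")
print(
    "\nEstimates stay close to the generating values: missing-at-random "
    "cells are integrated out by per-iteration imputation rather than "
    "dropped casewise."
)
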