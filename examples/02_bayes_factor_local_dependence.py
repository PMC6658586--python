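"""Test local dependence in a testlet with an importance-sampling Bayes factor.

Simulates three groups with genuine local dependence in the first testlet
(Delta1 = 0.4), fits the unrestricted model and the point-null restriction
Delta1 = 0, and estimates the log Bayes factor by importance sampling over
permuted posterior chains.  A positive log BF favors local dependence.
"""

import numpy as np

from bcsm import ModelSpec, bf_delta_restriction, restrict_layers, vague_prior
from bcsm.simulate import simulate_dataset, study2_config

config = study2_config(n_per_group=100, delta1=0.4)
data, _ = simulate_dataset(config, rng=np.random.default_rng(7))

spec_alt = ModelSpec(
    n_items=config.p,
    n_groups=3,
    layers=tuple(config.layers),
    prior=vague_prior(1e-3, 1e3),
    tie_layers_across_groups=True,
)
spec_null = restrict_layers(spec_alt, "testlet1")

result = bf_delta_restriction(
    data, spec_alt, spec_null, iterations=3000, J=500, n_rb=500, seed=7
)
log_bf = result.log_bf[("alt", "null")]
print(f"log marginal (alt) : {result.log_marginal['alt']:.1f}")
print(f"log marginal (null): {result.log_marginal['null']:.1f}")
print(f"log BF (alt vs null): {log_bf:.1f}")
print(
    "\nWith Delta1 = 0.4 in the generating population the log BF is large "
    "and positive: the data clearly favor local dependence within the first "
    "testlet.  Rerun with delta1=0.0 in study2_config to see it go negative."
)
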