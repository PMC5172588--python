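"""Categorical latent variables: why mixing parts of speech yields Zipf's law.

Builds a word-like population in which a few "grammatical" categories hold a
handful of common items while "content" categories hold thousands of rare
ones, samples a million tokens, and measures how much of the energy variance
the category label explains (PEEV) and how close the mixed curve is to
Zipf's law.
"""

import numpy as np

from zipflatent import CategoricalConfig, gen_categorical, peev, zipf_slope
from zipflatent.pipeline import empirical_zipf_curve

config = CategoricalConfig(
    vocab_sizes=(2, 20, 200, 2000),  # grammatical -> content vocabularies
    n_tokens=1_000_000,
)
sample = gen_categorical(config, seed=1)
estimate = peev(sample.dataset)

tokens = np.repeat(
    sample.dataset.items["item"].to_numpy(),
    sample.dataset.items["count"].to_numpy(),
)
slope = zipf_slope(empirical_zipf_curve(tokens.tolist()))

print(f"analytic PEEV of the designed population: {sample.analytic.peev:.3f}")
print(f"plug-in PEEV recovered from 1e6 tokens:   {estimate.peev:.3f}")
print(f"total energy variance: {estimate.total_var:.3f} nats^2 "
      f"(between categories: {estimate.between_var:.3f})")
print(f"mid-range slope of the mixed Zipf curve:  {slope:.2f}")
print()
print("PEEV near 1 means the category label controls the mean energy: each")
print("category alone spans a narrow energy band, and only their mixture")
print("covers the broad range that shows up as a slope near -1.")
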