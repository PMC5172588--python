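"""Sequence length as a latent variable: the random-word model.

Words are built by drawing from M equiprobable letters plus a stop symbol,
so length is geometric and every specific length-z string has probability
M^(-z) P(z).  The energy is dominated by the z log M term because
Var[log P(z)] is bounded by (M+1)/M -- mixing lengths broadens the energy
distribution and produces a Zipf-like curve.
"""

import math

from zipflatent import LiWordModel, zipf_slope
from zipflatent.pipeline import empirical_zipf_curve

model = LiWordModel(M=4)

print(f"P(z=1) = {model.length_pmf(1):.4f}   (exactly (1/M)(M/(M+1))^z)")
print(f"energy of any 1-letter word: {model.pattern_energy(1):.4f} nats (= log 20)")
print(f"Var[log P(z)] closed form:  {model.logpz_variance():.5f}")
print(f"Var[log P(z)] brute force:  {model.logpz_variance_bruteforce():.5f}")
print(f"bound (M+1)/M:              {5 / 4:.5f}")

words = model.sample(200_000, seed=2)
slope = zipf_slope(empirical_zipf_curve(words))
print(f"\nsampled 200k words; mid-range rank-frequency slope: {slope:.3f}")
print("(the model's exact exponent is -log(M+1)/log M = "
      f"{-math.log(5) / math.log(4):.3f}; it approaches -1 as M grows)")
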