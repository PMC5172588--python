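"""The variational bound on Var[log P(z)] for length latent variables.

The distribution maximizing the second moment of log P(z) at fixed variance
is P(y) proportional to exp(-gamma sqrt(1+y^2)).  Its moments, computed by
quadrature, obey E[(log P(z))^2] <= (c0 + (1/2) log sigma_z^2)^2 with
c0 ~ 1.58, tight in the small-gamma (Laplacian) limit where the second
moment tends to 5.
"""

from zipflatent.length_bound import (
    bound_check,
    c0_constant,
    limit_c0,
    limit_second_moment,
)

df = bound_check()
print(f"c0 (closed form):                 {c0_constant():.4f}")
print(f"c0 (small-gamma quadrature):      {limit_c0():.4f}")
print(f"second-moment limit (quadrature): {limit_second_moment():.4f}")
print(f"\nbound margin over {len(df)} gammas in [1e-3, 50]:")
print(f"  min margin   = {df['margin'].min():.3g}  (>= 0: bound verified)")
print(f"  at gamma min = {df['margin'].iloc[0]:.3g}  (tight in the Laplacian limit)")
print(f"  at gamma max = {df['margin'].iloc[-1]:.3g}")
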