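# Methods

## The rank–energy identity and its conventions

For a discrete distribution with states `x`, probabilities `P(x)` and
energies `E(x) = -log P(x)` (nats throughout; base-10 only at export), the
energy distribution is a sum of probability-weighted delta functions, and
equals `e^{-E}` times the density of states. Integrating the rank derivative
gives the identity `log r(E) = E + log P_S(E)`, where `P_S` is the energy
distribution smoothed by a one-sided exponential kernel.

Two conventions make this an *exact* identity at every atom, rather than an
approximation:

* **max-tie ranks** — the rank of an atom is the count of atoms with energy
  less than or equal to its own, so tied atoms share the largest rank of
  their group and the maximum rank equals the number of states;
* **"≤" in the smoothing sum** — `P_S(E)` includes the atom at `E` itself,
  which makes `e^E P_S(E)` exactly the cumulative atom count.

With these choices `smoothed_density` evaluates `P_S` as
`e^{-E} ×` (cumulative count) — the closed form, not a quadrature — and the
per-atom residual of the identity is zero to machine precision. The test
suite independently cross-checks `P_S` against the probability-weighted sum
`Σ_{E(x)≤E} P(x) e^{E(x)-E}` and the ranks against a brute-force
sort-and-count oracle.

**Deviation statistic.** Since departures from Zipf's law are exactly the
variations of `log P_S(E)`, `zipf_deviation` reports the P(x)-weighted
standard deviation of `log P_S(E(x))` over the atoms: zero iff the
distribution is exactly Zipf over its support, invariant under state
relabeling.

**Slope statistic.** `zipf_slope` fits `log P` against `log rank` by least
squares over the geometric interior of the rank axis (ranks in
`[R^0.15, R^0.85]`, `R` the maximum rank), with tied atoms collapsed to one
point so plateaus of equiprobable states are not over-weighted. The window
excludes the discrete head and the sampling-dominated tail; for sampled
data the tail (empirical counts of 1–2) is biased flat by undersampling,
which is a property of plug-in frequency estimates, not of the underlying
model. Any fixed window is a convention; this one is held fixed everywhere.

**Probabilities from counts.** Counts become probabilities by maximum
likelihood with no pseudocounts; zero-count states are dropped (their
energy is undefined). Probability vectors must sum to 1 within 1e-12;
renormalization happens only under an explicit flag.

## PEEV

The energy variance decomposes by the law of total variance into the
variance of the conditional mean energy across categories (between) plus
the mean conditional variance (within); PEEV is the between share.
Energies are always taken from the **marginal** `P(x)`; the conditional
distributions `P(x|z)` only reweight those energies. Using `-log P(x|z)`
as the energy is a different quantity and is deliberately not offered.
PEEV is reported as the plug-in estimate with no small-sample bias
correction. A dataset whose states are all equiprobable has zero energy
variance; PEEV is undefined there and the code raises rather than
returning a conventional value. Items listed under two categories are
rejected by default; a `split_duplicates` flag keeps them as distinct
(item, category) states instead.

For sequence data the latent variable is the length, a deterministic
function of the observation, so `P(x|z) = P(x)/P(z)` for states of length
z — the FASTA reader constructs exactly this.

## Generative models

**Random words.** Lengths are geometric, `P(z) = (1/M)(M/(M+1))^z` for
z ≥ 1, equivalently the run length before the first stop symbol among M+1
equiprobable symbols. Enumeration truncates at a `z_max` chosen so the
geometric tail mass is below 1e-12 (sampling is untruncated).
`Var[log P(z)] = M(M+1) log²(1+1/M)` in closed form, bounded by `(M+1)/M`.
Note the model's exact rank-frequency exponent is `log(M+1)/log M`
(≈ 1.16 at M = 4), approaching 1 only as M grows; sampled curves sit
between that value and −1 depending on how far the undersampled tail
enters the fit window.

**Bernoulli populations.** Rates are stored as a (Z states × n neurons)
matrix, strictly inside (0,1); the prior over latent states defaults to
uniform, matching equal-time sampling of trial-aligned bins. Marginal
pattern probabilities use log-sum-exp over all latent states with no
mixture truncation. For model-generated samples, pattern energies default
to the exact model marginal; empirical-frequency energies are available
since real data offers nothing else. Conditional spectra group samples by
latent-state blocks of 5 consecutive bins (100 ms at the 20 ms default bin
width); the block size is configurable.

**Entropy-variance scaling.** For families whose neurons share one rate
profile `p(z)`, `Var_z[H] = n² Var_z[H_1]` holds exactly and the fitted
log-log slope is 2 to within numerical precision. The incoherent control
permutes each neuron's time profile independently — preserving every
per-neuron marginal while destroying the shared modulation — and yields
slope ≈ 1 with fluctuations of order `1/√(Z·n)`; tests allow ±0.25.

**Place-field ring.** Logit rates `-h + A cos(z - θ_i)` with evenly spaced
preferred angles. H(z) is exactly periodic with period 2π/n, and for fixed
amplitude its true range over z decays *exponentially* in n (the Fourier
coefficients of the analytic tuning curve at harmonic n): about 1e-12 nats
at n = 16 and 1e-54 at n = 64. In double precision the measured grid
max−min at n ≥ 64 is therefore a rounding floor of order n·1e-16 nats. For
a size-independent O(1) statement the model also exposes
`entropy_range_bound`, the mean-value-theorem bound
`(π/n) · max_z Σ_i |dH_B/dz|`: the per-neuron derivative magnitudes are
O(1) each, so the bound is O(1) in n (≈ 0.39 nats at h = 2, A = 1 for any
n). Either way the entropy modulation is negligible against the O(n)
range Zipf's law requires. Making the amplitude depend on z breaks the
symmetry and the measured range grows linearly in n. The entropy range is
evaluated on a uniform grid of 4n angles, resolving the 2π/n spacing.

**Chain-rule decomposition.** For small enumerable joints (≤ 14 binary
elements) the conditional entropy splits exactly into per-element averaged
conditional entropies `h_i(z)`; their covariance matrix over z sums to
`Var_z[H]`. The elementwise marginal entropies and the conditional mutual
informations `I_i = H_{x_i|z} - h_i` are exposed; the per-element energy
terms of the fully general argument are theory-only and not separately
computed.

## Continuous energy densities

Densities are restricted to mixtures of uniform segments and delta atoms —
every experiment of interest uses these, and the closed forms (piecewise
exponentials, combined by log-sum-exp) keep quadrature error out of the
bound checks. `P_S` and the log cumulative state count share one
computation, so the identity holds exactly by construction; quadrature is
an independent oracle in tests. Slope estimation excludes boundary layers
of ~1 nat where the `e^{a-E}` transient dominates. The plateau level for
the sup-deviation statistic is the median of `log P_S` over the window,
robust to localized blips and holes. The delta-peak sandwich
`(1/n) log f_S ≤ (1/n) log P_S ≤ (1/n) log(α + f_S)` is checked pointwise;
α = 0 makes the bounds coincide and α = 1 (no smooth baseline) flags the
lower bound as unbounded.

## The variational length bound

The maximizer of the second moment of `log P(z)` at fixed variance, in the
continuous, sign-free idealization of z, is
`P(y) ∝ exp(-γ√(1+y²))`. The normalizer and moments are computed by
adaptive quadrature after the `y = sinh θ` substitution (relative
tolerance 1e-12, with the integration split at the decay scale
`asinh(10/γ)` to help the adaptive rule at small γ); the closed forms in
modified Bessel functions (`Z = 2K₁(γ)`, `∫y²e = (K₃−K₁)/2`) serve as
independent oracles in tests, never as the implementation. The bound
`E[(log P(z))²] ≤ (c0 + ½ log σ_z²)²` uses
`c0 = √5 − ½ log(e²/2) ≈ 1.5826`, fixed by tightness in the γ→0 limit
(second moment → 5, σ_z² → e²/2). The default verification grid is 60
log-spaced γ in [1e-3, 50]; margins are non-negative throughout, of order
γ at the small end and growing at the large end. The large-γ σ_z²
prefactor is checked only through the bound margin, not as a standalone
constant. Limits at γ = 0 are recovered numerically by quadrature at
γ ∈ {1e-2, 1e-3, 1e-4} with linear (Richardson) extrapolation, which is
what `scripts/acceptance.py` reports. No discrete-z correction is applied.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *structure* of the three data domains — a few
common-item categories vs many rare-item categories for word tables;
geometric lengths with iid letters for sequence sets; post-stimulus
decaying rates `b_i + a_i e^{-z/τ}` with per-neuron jitter for spike
rasters — and every generator returns the analytic population it drew
from, so estimators are validated by parameter recovery. Default sizes
(10⁶ tokens; 30 neurons × 100 bins × 30 trials; 10⁵ sequences) match the
sampling depths used for the population analyses here. They do not emulate
grammatical dependencies between tokens, position-dependent letter
statistics within sequences, or cross-neuron noise correlations, so
passing recovery tests demonstrates correctness of the estimators under
the stated models, not robustness to real-data misspecification. Scaling
experiments use population sizes 32–1024 and 256 latent states, sizes at
which the exact n² relation and its sampling-noise analogue are cleanly
separated while everything runs in seconds.

## Numerical choices

* probability sums validated to 1e-12; law-of-total-variance additivity to
  1e-10 relative (grouped floating sums);
* compensated (`fsum`) summation wherever a small signal rides on a large
  sum (ring entropies, smoothing oracles);
* estimated firing rates clipped to `[1/(2T), 1 - 1/(2T)]` for T trials so
  empirical energies stay finite;
* all samplers take an explicit seed and are reproducible; generator
  outputs record the seed they were built with.

## Known limitations

* PEEV requires hard category labels; soft assignments `P(z|x)` from a
  fitted model are out of scope.
* No power-law exponent estimation is provided — the object of interest is
  the exact identity and the deviation statistic, not exponent fitting.
* The word-frequency and antibody-repertoire analyses of the original
  studies require corpora that are not redistributable here; the package
  substitutes parameter-recovery tests on its own generators at matched
  scale.
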