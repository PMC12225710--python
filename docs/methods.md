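# Methods

## Model

`stairbayes` infers the demographic history of a single panmictic
population from a site frequency spectrum (SFS).  For `n = 2m` haploid
samples under the standard coalescent with an infinite-sites mutation
model, the history is parameterised by one scaled population size per
coalescent interval,

    theta_k = 4 N_k mu,   k = 2, ..., n,

where interval `k` is the period during which `k` ancestral lineages of
the sample remain (`k = n` is the most recent interval) and `mu` is the
per-site per-generation mutation rate.  Sizes are constant within an
interval and change only at the (expected) coalescent events — a
deliberately over-flexible "staircase" that the prior then regularises.

Using the expected interval durations `E[t_k] = 4 N_k / (k (k - 1))` and
Fu's descendant-count probability

    Pr(k, i | n) = C(n-i-1, k-2) / C(n-1, k-1)    (0 outside its support),

the probability that a random site shows the derived allele in `i` copies is

    p_i = sum_{k=2}^{n} Pr(k, i | n) * theta_k / (k - 1),  i = 1..n-1.

Sites are assumed unlinked, so the likelihood of the observed class counts
`xi_0..xi_{n-1}` is multinomial (a composite likelihood: real data are
linked, and the multinomial treats the per-class counts as independent
draws).  Under a constant `theta` this reduces exactly to the classical
`p_i = theta / i` spectrum, which the test suite verifies to machine
precision up to `n = 100`.

Two derivations of the monomorphic-site probability are offered:

* **complement** (default): `p0 = 1 - sum p_i`, valid only while
  `sum p_i < 1`; parameter vectors violating the bound get log-likelihood
  `-inf` (more than one expected mutation per site would break the
  infinite-sites assumption);
* **tree length**: `p0 = exp(-sum_k theta_k / (k-1))`, the no-mutation
  probability of the expected total tree length, with the polymorphic
  classes rescaled to `1 - p0`.

The two differ only at second order in `sum theta_k/(k-1)`; the test suite
checks `|difference| <= (sum theta_k/(k-1))^2 / 2` over random draws.

Ascertainment corrections condition the multinomial on the observable
classes: dropping monomorphic sites rescales by `1 - p0`; dropping
monomorphic and singleton sites removes classes `1` and `n-1` and rescales
by `1 - p0 - p_1 - p_{n-1}`.  For a folded SFS the classes `i` and `n - i`
merge (`p_i^F = p_i + p_{n-i}`, middle class kept for even `n`); the
singleton correction then removes only the merged class `i = 1` and
renormalises by `1 - p0 - p_1^F` — the unique choice consistent with the
unfolded corrections.

An all-derived class (`i = n`) cannot arise under a single mutation; it is
parsed and stored but never modeled, with a warning when nonzero.

## Prior families

Nine priors on `theta = (theta_2..theta_n)` span the no-shrinkage to
strict-shrinkage continuum.  Fixed hyperparameters, with rationale:

| family | construction | fixed hyperparameters |
|---|---|---|
| IID_UNIFORM | theta_i ~ Uniform(0, 0.1) i.i.d. | upper bound 0.1 (theta = 4 N mu above 0.1 is implausible for real populations) |
| UCLN | theta_i ~ Lognormal(ln mu_hat, sigma); mu_hat ~ Loguniform(1e-10, 1), sigma ~ Exponential(mean 3H) | H = 0.587405 (below) |
| IGR | theta_i ~ Gamma(m^2/v, rate m/v); m ~ Loguniform(1e-10, 1), v ~ Exponential(mean 0.01) | mean/variance parameterisation |
| BSP_GROUPED | b groups of consecutive intervals share one value; sizes flat (>=1 each); group j ~ Exponential(mean = value of group j-1), group 1 ~ Uniform(0, 0.1) | b = round(2m/4), round-half-even, floor 1 |
| RJ | interval equals its predecessor w.p. beta, else fresh Uniform(0, 0.1) | beta = 0.5 |
| GMRF1 / GMRF2 | first / second differences of ln theta ~ Normal(0, xi) | xi = H / sqrt(n-2) so the end-to-end log-ratio's 95% interval spans one decade |
| HSMRF1 / HSMRF2 | per-step scales gamma * xi_j, xi_j ~ HalfCauchy(0, 1) | gamma = 0.021 (equivalent to per-step HalfCauchy(0, 0.021) scales) |

`H = ln(10) / (2 z_0.975) = 0.587405` is the log-scale SD whose lognormal
95% central interval spans exactly one order of magnitude; it calibrates
both the UCLN hyperprior mean (3H) and the default GMRF global scale.
GMRF/HSMRF global scales can instead be estimated under half-Cauchy
hyperpriors (`estimate_scale: true`).

Design choices that were genuinely open:

* **UCLN location.** A Loguniform(1e-10, 1) hyperprior only makes sense
  for a positive location, so `mu_hat` is the lognormal *median* of theta
  (log-scale location `ln mu_hat`).
* **Chain orientation.** The Markov-chain priors (BSP, RJ, MRF) are
  anchored at the most recent interval (`k = n`) and run backwards in
  time, matching the skyline convention of present-anchored trajectories;
  `orientation: "past"` flips this.  The anchored element carries a
  Uniform(0, 0.1) base prior — the MRF equations define only increments,
  and a proper base is needed for a normalised joint density.
* **Densities are theta-space densities.**  MRF log-densities include the
  `d ln theta -> d theta` Jacobian, so `exp(log_prior_density)` integrates
  to 1 over theta; the test suite checks this by numerical quadrature on
  two-interval cases.
* **Log-space state.**  IGR and the MRF families keep `ln theta` as the
  sampler state: the IGR hyperpriors routinely produce gamma shapes far
  below 1, and half-Cauchy local scales produce log-steps of thousands —
  both put real prior mass outside the exp-representable range of a double.
  Generative draws use the same representation (IGR via the
  `Gamma(shape+1) * U^(1/shape)` identity on the log scale), so sampler and
  prior agree distributionally; displayed theta values are clipped to the
  smallest/largest normal doubles.
* **BSP base and autocorrelation.**  Group sizes are a flat composition of
  `n - 1` intervals into `b` positive parts; values follow the
  autocorrelated exponential chain of the original Bayesian skyline
  construction (each group's prior mean is the previous group's value).

## MCMC

Metropolis-within-Gibbs.  One *iteration* is a sweep: every scheduled move
once, single-parameter moves once per coordinate.

* Per-coordinate log-scale multiplier moves (Hastings term `ln factor`),
  window auto-tuned towards 0.44 acceptance during burn-in only.
* A joint up-down rescaling of all size parameters (target 0.23).
* Family moves: skyline group-boundary shifts; reversible-jump equality
  toggles plus Gibbs refreshes of inert values.  The RJ state is
  *saturated* — the full value vector is kept with equality indicators,
  tied entries retaining their Uniform base prior as a pseudo-prior — so
  the toggle is an ordinary fixed-dimension move with unit Jacobian and
  the marginal over active values is the intended reversible-jump prior.
* An independence redraw from the prior (10% of sweeps): its acceptance
  ratio reduces to the likelihood ratio, and it doubles as a consistency
  check between the generative sampler and the density code.

Defaults follow the reference analysis design: 500,000 iterations, four
replicate runs (for convergence diagnostics via across-replicate R-hat),
10% burn-in, thinning to about 2,000 retained samples per replicate.
Initial states are prior draws retried until the likelihood is finite,
falling back to a Watterson-style moment start
(`theta_k = S / (l sum 1/i)`).  Retained rows store the conditioned class
probabilities `p` alongside parameters, which is all the cross-validation
step needs.

**Validation.**  With zero data the likelihood is identically zero and the
sampler must reproduce each prior exactly; the acceptance suite checks the
two-sample KS distance of the theta_2 marginal (MCMC vs 10^5 generative
draws, on log10 scale) below 0.05 for all nine families.

## Model selection

Leave-one-out cross-validation from the stored per-sample class
probabilities: per site, the predictive probability is estimated by the
harmonic mean over MCMC samples of `p(X_i | theta_k)`.  Sites within a
frequency class are exchangeable, so the sum over sites collapses to a
count-weighted sum over at most `n` classes, making the whole score a
cheap post-hoc pass.  Harmonic means are computed as
`-logsumexp(-ln p) + ln K`.  `select_best` takes the arg-max score; exact
ties go to the family with fewer sampled hyperparameters.  Replicates are
pooled for the headline score; per-replicate scores are reported as a
stability diagnostic.  (Marginal likelihoods / Bayes factors are out of
scope by design: cross-validation is far less sensitive to the
hyperpriors.)

## Trajectories

Interval start times follow directly from theta:
`T_i = sum_{k=i}^{n} theta_k / (k (k-1))` in expected substitutions per
site; dividing by `mu` gives generations, multiplying by a (never
inferred) generation time gives years.  `N_k = theta_k / (4 mu)`.  Each
posterior sample is a right-continuous step function (`N_k` on
`[T_{k+1}, T_k)`, the oldest size extended flat beyond `T_2`), evaluated
on a grid — 500 log-spaced points by default, spanning up to the posterior
97.5% quantile of `T_2` — and summarised per grid point by the posterior
median and 2.5%/97.5% quantiles.

## Synthetic data

The generator defines the study conditions: six canonical single-population
histories (constant size, two-epoch, exponential growth with and without an
ancient constant period, a three-epoch complex expansion, a bottleneck) as
continuous size functions `N(t)`, with `mu = 1.2e-8` per bp per generation,
`n = 20` haploids and `l = 1e6` sites by default.  Default shape
parameters — constant `N = 1e4`; two-epoch `1e4 -> 1e5` at 5,000
generations; growth rate `1e-4`/generation from `N0 = 1e5`; bottleneck
`1e4 -> 1e3 -> 1e4` over 2,000–4,000 generations — are package choices
exercising the canonical qualitative shapes; the emitted truth file is
always authoritative for scoring.

A history maps to the model's own discretization by a fixed-point
iteration: compute interval times from the current theta, read `N` at each
interval *midpoint* (midpoints rather than endpoints halve the
discretization bias of the step approximation), set
`theta_k = 4 N(midpoint) mu`, repeat until the maximum relative change is
below 1e-10 (one step suffices for a constant history).  `l` sites are
then drawn in a single multinomial sample over classes `0..n-1` using the
complement `p0`.

What this emulates — and does not: sites are truly independent, exactly
matching the likelihood's composite assumption, whereas real genomes are
linked (the original simulation studies averaged many linked replicates,
which the independent-sites multinomial approximates in expectation).
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not robustness to linkage,
selection, population structure or sequencing error.  Mis-polarization is
modeled by moving each SNP from class `i` to `n - i` with probability
`rho` (binomial thinning per class), the error process relevant to
ancestral-allele miscalls; folding provably erases it, which the tests
exploit as an exact invariance.

## Numerical choices

* All binomials/factorials in log-gamma space; the `Pr(k, i | n)` table is
  cached per `n` and evaluation cost is O(n^2), independent of SNP count.
* `-inf` log-likelihood is a rejection sentinel; it never enters averages.
* Theta draws that still underflow after the log-space representations are
  floored at the smallest normal double so draw and density stay
  consistent.
* Round-half-even for the skyline group-count rule (`round(2m/4)`).
* Grid evaluation uses `searchsorted` on the ascending interval
  boundaries; a grid point exactly on a boundary belongs to the older
  interval (right-continuity in time-before-present).

## Problem sizes in the validation suite

The acceptance experiments run at desk scale, chosen to keep Monte-Carlo
error comfortably inside the asserted tolerances: prior recovery at n=6
with 40,000-sweep chains against 10^5 generative draws; coverage on the
constant scenario with 20 replicate datasets and 20,000-sweep chains;
polarization with 5 paired seeds and 8,000-sweep chains; model-selection
sanity with 10 seeds and 6,000-sweep chains per family.  Production
analyses should use the 500,000-iteration, four-replicate defaults.

## Known limitations

* The composite likelihood ignores linkage; credible intervals are
  narrower than the truth warrants on strongly linked data.
* The expected-coalescent-time discretization is mathematically
  inconsistent (sizes change at expected, not realised, events) but is the
  standard, empirically adequate StairwayPlot approximation.
* Horseshoe chains mix slowly near the shrinkage spike; for production
  runs use the full iteration budget and check across-replicate R-hat.
* Times and sizes scale inversely with the assumed `mu` and with the
  monomorphic count; both must come from outside the SFS.
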