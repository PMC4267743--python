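# Methods

This note records the model, the numerical choices and the design
decisions behind `recombtest`, and what the simulation-based tests do and
do not establish.

## Copying model

The likelihood of n phased haplotypes is approximated by the PAC
factorisation: each haplotype in turn is scored against the panel of
haplotypes before it, and the product of these approximate conditionals
is the surrogate likelihood.  The value depends on the conditioning
order; the default `OrderingPolicy` keeps the input order (deterministic
and reproducible), and an averaged mode over random permutations is
available for users who prefer order-robust values.  The first
haplotype's probability is the uniform allele model (S·log ½).  It is
independent of (ρ, γ, λ), appears identically in the numerator and
denominator of the likelihood-ratio statistic and cancels there, so its
crude form has no effect on any test result (asserted in the tests).

Each conditional comes from a hidden Markov model over joint states
(x, g): x is the crossover chain's donor index, g is either ∅ (outside
any conversion tract) or the conversion donor.  The site's copying donor
is g when g ≠ ∅, else x.  Per kb, the crossover chain jumps to a uniform
donor at rate ρ/k and the conversion chain initiates tracts at rate γ/k;
tracts terminate at rate 1/λ.  Both chains divide by the panel size k,
the per-haplotype intensity convention of the original PAC model, so the
likelihood is invariant under the unit change (positions×c, ρ/c, γ/c,
λ×c) — a property test.

Over an inter-SNP distance d the conversion step uses the
competing-risks kernel with c = 1 − exp(−γd/k) (a fresh tract covers the
next site) and e = 1 − exp(−d/λ) (an ongoing tract has ended):

| from \ to | ∅           | donor b (each of k) |
|-----------|-------------|---------------------|
| ∅         | 1 − c       | c/k                 |
| donor a   | (1 − c)·e   | c/k, plus (1−c)(1−e) when b = a |

Rows sum to one exactly.  A fresh tract may open while one is ongoing
(the c/k mass out of a donor state), which is how overlapping and nested
conversions are represented: the chain holds only the *current* donor
and renews it, keeping the state space at k(k+1) instead of tracking a
tract stack.  The crossover chain is frozen (identity transition)
whenever the destination site is inside a tract, producing the
prefix/insert/suffix mosaic characteristic of conversion.  The initial
distribution is uniform on x, and g = ∅ with probability 1/(1 + γλ/k),
the stationary balance of initiation (γ/k) and termination (1/λ); the
complementary mass is uniform over donors.

Emissions are the classic mosaic-copying form with per-site mutation
parameter θ̂ = (Σ_{i<n} 1/i)⁻¹: copy faithfully with probability
k/(k+θ̂), otherwise emit a uniform allele.  At γ = 0 the conversion
chain is inert and the model reduces *exactly* to the crossover-only
copying model — the two are verified against each other to 1e-10, and
both against brute-force enumeration of all hidden paths on small
instances.  This exact reduction is the non-identifiability at the
boundary (γ = 0 with any λ, or λ → 0 with any γ, give the same
likelihood) that breaks the χ² asymptotics of the LRT.

The forward recursion exploits the kernel's low-rank structure (the
conversion step needs only per-row totals, the crossover step only the
∅-column total), costing O(S·k²) per conditional.  It renormalises the
forward mass at every site and accumulates the log of the scaling
constants; nothing is truncated to zero before the log, so the value is
finite for any valid input.  The kernels are numba-compiled; the scalar
transition/emission functions in `copying_hmm` are the readable
reference implementations from which the tests' independent
path-enumeration oracle is built.

## Prior and estimation

The mean tract length carries the prior log₁₀λ ~ N(−0.5, 0.4²), chosen
to put 95% of its mass on the biologically typical 0.05–2 kb range
(quadrature in the tests confirms 0.9545).  The MAP objective is
log f(λ) + log ℓ; on the γ = 0 boundary the model has no tract length
and the prior term is dropped, making the null objective the plain
crossover-only PAC log-likelihood.

Optimization is Nelder–Mead in log₁₀ coordinates inside box bounds
ρ, γ ∈ [10⁻⁴, 10³]/kb and λ ∈ [10⁻³, 10²] kb, from three deterministic
starts, (ρ, γ, λ) = (1, 1, 0.3162), (0.1, 1, 0.3162), (1, 0.1, 0.3162)
(λ starting at the prior median).  Tolerances: simplex size 1e-4 in
log₁₀ units, objective 1e-5, at most 500 evaluations per start.
Boundary hits are reported in `FitResult.at_bounds`, never raised; a γ̂
at the lower box edge means "no conversion signal" and is mapped to 0 by
`params_summary`.  `fit_null_crossover` adds a parsimony tie-break:
when the likelihood at the lower ρ bound is within the objective
tolerance of the best start (data with no recombination signal leave the
likelihood exactly flat in ρ), the lower bound is reported.  Fits are
checked against dense log-grid maximizations (returned objective ≥ best
grid point − 1e-3).

`FitOptions.fast()` (one start, 200 evaluations, looser tolerances) is
the preset for simulation studies that need thousands of fits.  In the
bootstrap, the replicate statistics default to the *same* options as the
observed statistic, so observed and reference values are computed by an
identical procedure; the uniformity of null p-values is insensitive to
the preset precisely because of that symmetry (and is verified at the
fast preset).

## LRT and parametric bootstrap

Λ(H) = −2(log sup_null − log sup_full), unclamped — it can be slightly
negative when the prior factor or optimizer noise favours the null.  For
H₀: γ = 0 the nuisance is ρ, refitted under the crossover-only model;
for H₀: ρ = 0 the nuisances are (γ, λ) with the prior active.  B
bootstrap datasets of the same n and region length are simulated from
the fitted null, with the mutation rate set by Watterson's estimator
θ̂_W = S/(L·Σ 1/i) on the observed data (the resampling distribution
must be fully parametric, and θ is not part of the tested hypothesis).
The p-value is the plain proportion #{Λ_b ≥ Λ_obs}/B — ties count toward
the null, p = 0 is possible — with the (#+1)/(B+1) variant available.
Replicate RNG streams are spawned deterministically from the seed, so
every result is bit-reproducible.  Recommended B: 200 for simulation
studies, 500 for data analysis.  If a null fit lands on the upper ρ
bound (10³/kb — essentially free recombination, which can happen on
noisy, very short segments), the resampler will refuse to build the
corresponding enormous ancestral graph and raises its event-cap error
rather than looping; such segments are too information-poor to test.

## Coalescent simulator

The bootstrap engine and data generator is a back-in-time
ancestral-recombination-graph walk in Hudson's ms scaling: pairwise
coalescence rate 1 (a sample-of-two tree has expected height 1), per
lineage crossover rate ρL/2 with a uniform breakpoint, gene conversion
rate γL/2 with a uniform tract start and *continuous exponential* tract
length (mean λ kb; ms's geometric-in-bp tracts are indistinguishable at
the 20 kb / sub-kb-tract scale), and infinite-sites mutation at θ/2 per
kb per unit time.  Events may hit non-ancestral material (no-ops, as in
ms) and empty lineages are pruned; material whose ancestral set reaches
the whole sample is fixed, its MRCA time recorded, and dropped, so the
walk terminates at the grand MRCA of every position.  Mutations are not
placed on explicit trees: the simulator accumulates every lineage's
(interval × duration × sample-subset) branch exposure and drops a
Poisson number of mutations on it, each assigning the derived allele to
its segment's subset — equivalent to infinite-sites mutation on the
marginal trees, without building them.  A site falling exactly on a
breakpoint belongs to the right-hand segment (half-open intervals).

Validation: E[S], E[π] and mean marginal tree height match coalescent
closed forms within 3 SE at 500 replicates for crossover-only,
conversion-only and recombination-free settings; recorded tract lengths
pass a Kolmogorov–Smirnov test against the exponential; and means and
the variance-reduction of S under recombination agree with msprime at
matched scaling (haploid samples, N = 1, r = ρ/2, μ = θ/2).

## What the synthetic data does and does not show

All simulated data follow the neutral, panmictic, constant-size
coalescent with homogeneous rates and infinite-sites mutation — the same
model family the estimator assumes and the bootstrap resamples from.
Passing tests therefore demonstrate internal consistency and correct
calibration *under the model*: null p-values uniform, power rising with
the conversion/crossover ratio f and with n, and the documented boundary
inflation of γ̂ reproduced.  They say nothing about robustness to
demography (growth, structure), rate heterogeneity (hotspots),
finite-sites or sequencing error, unphased or missing data — none of
which the generator emulates.  On real data the test inherits the usual
caveats of PAC-based inference.

## Problem sizes

The package's own Monte-Carlo checks run at desk scale, chosen as the
smallest studies that still pin the summaries down to within their
sampling error: 30–50 coalescent replicates for estimator means and the
null-Λ quantile (e.g. with the inflation summary's replicate SD of
about 0.6, 30 replicates give a standard error near 0.11), 50 datasets ×
B = 100 for p-value uniformity, and 10 datasets × B = 40 per setting for
the power ordering.  `scripts/acceptance.py` uses 40/40/50 replicates
for its three summaries.  Tolerances on Monte-Carlo assertions are ±3
empirical standard errors unless a wider band is stated inline.

## Known limitations

- PAC values are ordering-dependent; the default fixed order makes runs
  reproducible but means two permutations of the same matrix give
  (slightly) different likelihoods and p-values.
- The LRT statistic inherits optimizer noise; with the default
  tolerances the grid cross-checks bound it by ~2e-3 log-units, far
  below the bootstrap's Monte-Carlo noise.
- The conversion-chain kernel is one of several parameterisations
  consistent with Poisson initiation/termination and overlap-by-renewal;
  alternatives would shift estimator means somewhat (tolerances in the
  Monte-Carlo tests allow for this).
- Very short or monomorphic segments can drive nuisance estimates to the
  box bounds; results there flag `at_bounds` and should not be
  over-interpreted.
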