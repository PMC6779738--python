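# Methods

## The problem and the model

A juvenile feeding ground is sampled at two periods roughly a decade apart
("early" ≈ 2006–2007, "late" ≈ 2015–2016). Each sampled animal contributes
an mtDNA control-region haplotype (a named 474-bp sequence variant), a
capture year and a straight carapace length (SCL). Candidate source
rookeries contribute baseline haplotype counts plus demographic data
(adult female abundance N, nest-count trends, location). The analysis asks
two questions: *did the genetic make-up of the feeding ground change over
the decade?* (diversity and ϕST), and *did it change toward the rookeries
with the highest reproductive output?* (mixed stock analysis linked to
recovery metrics).

### Partitions

Recaptured animals are treated as additional observations — one record per
(individual, year) capture event, haplotype constant per individual (mtDNA
does not change; a conflict is a data error). Partitions select records by
year-set membership and a strict SCL cutoff (`scl < cutoff`, so a 50.0 cm
animal is outside the "<50.0 cm" recent-recruit class). The <50 cm class
exists because small juveniles arrived recently, so they carry the
sharpest signal of current recruitment.

### Diversity and divergence

Haplotype diversity h = n/(n−1)(1 − Σ pᵢ²); nucleotide diversity
π = Σᵢⱼ pᵢ pⱼ dᵢⱼ / L with dᵢⱼ the number of nucleotide differences
between haplotypes i and j over the L aligned positions where both carry
an unambiguous base. The distance model is plain pairwise differences with
no multiple-hit correction: at ~474 bp with haplotypes a few substitutions
apart, corrections are far below sampling noise.

ϕST is the two-level AMOVA fixation index. With dᵢⱼ treated as squared
inter-individual distances, sums of squared deviations reduce to quadratic
forms in the per-group haplotype count vectors (SSD_total = c'Dc/2N,
SSD_within = Σ_g c_g'Dc_g/2n_g), giving σ²_within = SSD_within/(N−G) and
σ²_among = (MS_among − σ²_within)/n′ with the standard unequal-size
coefficient n′. Negative estimates are reported as computed — they are
informative about near-zero structure and clamping would bias permutation
tails. Significance: individuals are pooled and reassigned to groups of
the original sizes; p = (1 + #{ϕ_perm ≥ ϕ_obs})/(B + 1) (add-one rule, so
p is never exactly 0); permutations with a degenerate variance
decomposition count as ties, which can only be conservative. The Mantel
test correlates the pairwise ϕST matrix over yearly partitions with
|Δyear|, permuting rows/columns of one matrix simultaneously; the p-value
is one-sided (greater), the convention of the population-genetics software
this mirrors. Undefined ϕST cells (no variation in a pooled pair) are NaN
and are excluded pairwise from the Mantel triangle with a logged count.
Linearized divergence ϕ/(1−ϕ) is available but off by default.

### Mixed stock analysis

The feeding-ground sample is a finite mixture over k stocks. Stock k has
haplotype frequencies q_k with a symmetric Dirichlet(1/H) prior updated by
its baseline counts; the contribution vector θ has a symmetric
Dirichlet(1/k) prior — uniform prior mean with total weight 1, the
unweighted choice that avoids biasing the downstream demographic
correlations toward large rookeries. The Gibbs sweep is:

1. q_k ~ Dirichlet(β + baseline counts_k) — baseline sampling uncertainty
   is propagated by resampling each sweep rather than fixing q at observed
   frequencies. Mixture assignments do not feed back into q: the baselines
   are treated as the sole evidence about rookery frequencies, which keeps
   the update conjugate and prevents a large mixture from overwhelming a
   small baseline. A `fixed_q` mode (q frozen at observed frequencies)
   exists for closed-form conjugate checks.
2. z_i | θ, q for each mixture animal: P(z_i = k) ∝ θ_k q_{k,h(i)},
   sampled jointly per haplotype as a multinomial.
3. θ | z ~ Dirichlet(1/k + per-stock assignment counts).

Chains are over-dispersed (chain c starts with 0.95 of θ mass on stock
c mod k); defaults are 50,000 sweeps with the first half discarded,
thinning 1, min(k, 8) chains (≥ 2) — all configurable, and the packaged
pipeline scenario uses far fewer sweeps because its posteriors are simple.
Convergence is judged per stock by the Gelman-Rubin factor
R̂ = sqrt(((n−1)/n·W + B/n)/W) with the < 1.2 threshold. Summaries pool
post-burn-in draws across chains: posterior mean and equal-tailed 95%
intervals (linear interpolation between order statistics). Regional
summaries sum member-stock θ per draw *before* summarizing, so intervals
reflect the joint posterior. Mixture haplotypes absent from every baseline
("orphans") carry no attribution information; they are excluded from the
likelihood with a preserved tally, never silently dropped.

Temporal change in recruitment is ΔC = C_late − C_early on posterior mean
contributions, in [−1, 1].

Known MCMC caveat: when two baselines are (nearly) identical the posterior
is flat along the corresponding θ direction and the chain random-walks
that ridge; R̂ flags it, and pooled means still converge to the uniform
value but need long chains. This mirrors the genuine non-identifiability
of mixed stock analysis for genetically similar sources.

### Recovery metrics and the statistical linkage

Growth rate from an annual nest-count series of length n ≥ 4:
r = (N_L/N_F)^(1/(n−3)) − 1, with N_F, N_L the means of the first and last
three counts — the exponent is the number of year steps between the two
window centres, so a noiseless exponential series returns its true rate
exactly. Regional rates are means of member-rookery rates weighted by
adult female abundance; regional Nr multiplies regional N by the
*unrounded* regional rate (this reproduces the published regional products
where summing member Nr does not). Nr is reported rounded half away from
zero but stored at full precision. Distances are haversine on a sphere of
radius 6371.0088 km; an ellipsoidal model differs by < 0.5%, below the
reporting precision of any quantity that consumes D.

Spearman ρ is the Pearson correlation of mid-ranks (tie-corrected). For
n ≤ 8 the two-sided p-value is computed by full enumeration of all n!
rank permutations — essential at n = 4 regions, where the t approximation
is meaningless and the exact floor is 2/24 ≈ 0.083; larger n uses the
t approximation with n − 2 df. Logistic regression models
increase/decrease (ΔC > 0; the tie ΔC = 0 is deliberately classed as "not
increased") on Nr via a binomial GLM; complete separation is flagged in
the report with capped-iteration coefficients rather than raised. Stepwise
multiple regression starts from the full OLS model and moves
bidirectionally while the Gaussian AIC n·ln(RSS/n) + 2(p+1) strictly
decreases (constant likelihood terms dropped consistently, which preserves
ranking; R's `step` behaviour up to that constant), ties broken toward the
first-listed term, the full visited trace recorded. ln N is supplied as a
named candidate where abundance enters a linear model.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed), with a scenario
spawning independent child seeds per stage. They emulate the statistical
structure the analysis assumes: rookery baselines drawn from a symmetric
Dirichlet (concentration 0.2 by default — low values concentrate each
stock on few haplotypes, mimicking the strong mtDNA structure created by
natal homing), mixtures drawn stock-then-haplotype from known θ, capture
tables over paired years with uniform SCL in [30, 75) (half below the
50 cm cutoff by default), a 12% recapture rate (re-observed in a later
year, same haplotype, grown 5–20 cm), and nest series
start·(1+r)^t with mean-1 lognormal noise. Default partition sizes
(120 early / 160 late) and the default θ trajectory (north-west rising
0.12→0.38 at the regional level, east falling, south-west flat) match the
magnitudes of the motivating study system.

Not emulated: ocean-current dispersal, age structure, sequence evolution
(synthetic panels are a mutated backbone with disjoint two-site blocks, so
pairwise distances are positive but nearly constant), size- or
stock-dependent catchability, and inter-annual recruitment autocorrelation.
Passing tests therefore demonstrate the *estimators* behave correctly
under the assumed sampling model, not that the model captures every
feature of field data.

A note on "well-separated" benchmarks: a Dirichlet(0.2) draw is strongly
differentiated only on average; a single draw can produce two stocks with
heavily overlapping haplotype profiles, in which case no estimator can
resolve them (the maximum-likelihood solution itself is off). Recovery
benchmarks therefore use `structured_frequencies`, a deterministic
template giving each stock a dominant block of its own haplotypes over a
small shared background, which guarantees the separation the benchmark
presupposes.

## Numerical choices and degenerate inputs

- Permutation p-values use the add-one rule and are bit-reproducible given
  (seed, B); tie comparisons use a 1e−12 slack.
- Statistics that are mathematically undefined (zero variance, empty
  partitions, zero first-window nest counts) raise typed errors rather
  than returning NaN, except inside pairwise matrices where NaN cells are
  flagged and handled downstream.
- ϕST denominators within 1e−12 of zero are treated as undefined.
- Quantiles use linear interpolation; Nr display rounding is half away
  from zero.
- OLS AIC clips RSS at 1e−300 so a perfect fit yields a finite, strongly
  negative AIC instead of −∞.
- The Gibbs sampler asserts the impossibility of zero-probability
  assignment deadlock (guaranteed by prior positivity); in `fixed_q` mode,
  where the guarantee does not hold, support is checked explicitly.

## Problem sizes used in tests and the acceptance script

The shipped scenario uses 9 stocks in 4 regions, 12 haplotypes, baselines
of 200, partitions of 120/160 and 1,500-sweep, 3-chain samplers — small
posteriors that converge quickly. Sampler oracles use 6,000 sweeps
(conjugate case, where kept draws are iid) and 3,000 sweeps × 3 chains
(three-stock recovery at mixture n = 300, baselines n = 500). The
permutation-calibration experiment runs 500 null replicates of 25 + 25
individuals with 199 permutations each; at α = 0.05 the add-one rule makes
the null rejection probability exactly 10/200. These sizes were chosen so
each quantity's Monte-Carlo error is well inside the tolerance being
checked.

## Known limitations

- The published contribution estimates of the motivating study depend on
  its supplementary per-year haplotype tables and external baseline
  datasets, which are not redistributable here; the pipeline reproduces
  the *arithmetic and statistical layer* exactly (Nr products, ΔC from
  means, the exact regional Spearman test) and validates the genetic and
  Bayesian machinery against oracles and calibration instead.
- Mantel p-values are one-sided (greater); a negative association would
  need the linearized or reversed test.
- The stepwise search is greedy single-term; with ≤ 3 candidates it is
  effectively exhaustive, but it inherits the usual caveats of stepwise
  selection at small n.
- Regional aggregation assumes the rookery-to-region map is exhaustive;
  unmapped stocks are an error, not an "other" bucket.
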