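# Methods

This note documents the statistical models, the synthetic-data assumptions,
and the numerical choices behind `dogpop`, in the spirit of a model
reference rather than a tutorial.

## The multiplier estimator

The population estimate for each administrative source is `N = S / p`: a
subpopulation size *S* divided by the fraction *p* of all dogs belonging to
that subpopulation, estimated from a public survey. Monte-Carlo draws of
both quantities are divided pairwise (sample sets recycled to a common
length), and results are reported as the posterior median with an
equal-tailed 95% credibility interval (2.5th/97.5th percentiles, linear
interpolation; highest-posterior-density intervals are not used). The
estimator assumes the survey's dogs are exchangeable with the national
population with respect to membership — responsible-owner response bias,
for example, violates this and inflates *p* for vet-registered and insured
dogs, biasing those estimates downward.

## Membership-proportion model

Membership of each subpopulation is modelled per dog as Bernoulli(p) with a
single logit-scale intercept, `logit(p) = α`. The prior on α is Normal(0,
10): effectively flat over (0.001, 0.999) on the p scale, but proper, so
degenerate all-0/all-1 flag vectors still yield a posterior (they log a
warning). A flat prior is available and makes the dog-level posterior
exactly Beta(y, n−y) on p — the analytic oracle used by the tests.

### Sampler

Adaptive random-walk Metropolis on α. Defaults mirror common practice for
this model class: 2 chains, 100,000 iterations, 10,000 burn-in, thinning
interval 50, giving exactly 2 × 1,800 retained samples. The proposal sd
starts at 0.1 and is rescaled every 100 iterations during burn-in only
(multiplied by `exp(rate − 0.3)`, clamped to [1e-4, 25]) to target ~30%
acceptance; adaptation stops at the end of burn-in so the chain is a valid
time-homogeneous sampler thereafter. Convergence is summarised with the
Gelman–Rubin statistic `R̂ = sqrt(((n−1)/n·W + B/n)/W)`; the degenerate
zero-between-chain-variance case is reported as exactly 1. Chains are seeded
via `numpy.random.SeedSequence` spawns of a single user seed.

### Sampling units

The survey is a quota sample of 30 valid responses in each of 17
telephone-directory areas; ownership and membership cluster strongly by
area, so dog-level binomial uncertainty at n = 181 badly understates the
design's sampling variance. The default `area` mode therefore redraws the
set of areas with replacement once per thinning block and pools the
resampled counts into the Bernoulli likelihood; the retained samples
approximate a mixture of posteriors over cluster-bootstrap resamples, with
interval widths on the scale the clustered design implies (roughly ±0.25 on
p, versus ±0.07 for dog-level resampling). `dog` mode (pooled counts, no
resampling) is retained for the analytic check, and `household` mode
resamples households instead of areas. Resampling once per block rather
than every iteration lets the chain equilibrate to each resample; with a
1-D target and ~30% acceptance, 50 iterations per block is ample.

Descriptive (pre-Bayesian) membership proportions use an ordinary cluster
bootstrap over areas, 10,000 resamples by default, percentile intervals
truncated to [0, 1] — upper bounds of exactly 100% arise naturally when a
flag saturates in resampled areas.

## Survey-only population model

Per-area dogs-per-household rates r_a (area dog count / 30) follow
`r_a ~ Normal(μ, σ²)` with unknown variance. A two-block Gibbs sampler
draws σ² from its scaled inverse-χ² conditional (Jeffreys prior) and μ from
its normal conditional; retained μ draws are scaled by the number of
households in Britain (25.9 million). The informative prior — an earlier
national estimate of 10.5 million with 95% CI 9.6–11.4 million, hence
sd = 1.8/3.92 ≈ 0.459 million — is applied on the population scale, i.e. as
a Normal prior on 25.9e6·μ. With 17 areas the likelihood's standard error
(≈1.3 million on the population scale) is much wider than this prior, so
the posterior median lands near 10.3 million rather than at the scaled
sample mean of 9.2 million; the pipeline reports this as an honest
consequence of the stated prior. If all rates are equal and the prior is
flat, the estimate degenerates to the common rate times the household count
exactly.

## Practice-size mixture and the veterinary subpopulation

Per-practice registered-dog counts are fitted with a K-component (default
K = 3) univariate normal mixture by EM. Initialisation partitions the
sorted data into K quantile blocks; 19 further restarts use random cut
points. Components are ordered by mean; a component sd below 1e-3 × data sd
counts as collapse and abandons the restart; convergence is a
log-likelihood change below 1e-8 with the per-iteration trace retained
(monotone by construction of EM). An information-criterion scan over K is
available but K = 3 is the default. Goodness of fit uses the KS statistic
`D = sup|ECDF − F̂|`; because F̂ was fitted to the same data, the p-value
comes from a parametric bootstrap that refits each replicate (default 500;
fewer than 100 logs a warning).

The veterinary subpopulation draw is the sampling distribution of the
*mean* practice size: each draw averages a size-77 resample (parametric
from the mixture, or nonparametric from observed sizes) and multiplies by
the effective number of independent practices. That constant defaults to
2550; the component figures (3,638 practices, 1.32 practices per response,
whose ratio is ≈2,756) are exposed separately in the configuration and
logged, so the discrepancy between the published constant and its stated
derivation is auditable. Mean-resampling, not single-practice resampling,
is what makes the resulting interval width consistent with a ~77-response
survey.

Response bias of the practice survey is tested with Pearson χ² on the
respondents/non-respondents × stratum table (df = levels − 1, no continuity
correction; expected counts below 5 log a warning).

## Survival-adjusted registry counts

A breed registry records registrations but not deaths, so the living
registered subpopulation at reference year T is `Σ_y count_y · S(T − y)`,
with age computed as T minus registration year (registration assumed at age
0) and S ≡ 0 beyond the curve's last age; a gap inside the curve's range is
an error rather than silently interpolated. Uncertainty: each draw perturbs
the whole curve by one `z·sd(age)` shift (fully correlated across ages,
reflecting pooled all-breed survival uncertainty — independent per-age
noise would largely cancel in the sum), clamps to [0, 1], re-monotonises by
cumulative minimum, and recomputes the sum. For downstream estimation the
registry subpopulation defaults to the published survival-adjusted summary,
Normal(2,116,871, sd (2,425,060 − 1,696,647)/3.92 ≈ 185,821), so the full
pipeline runs without access to proprietary registry extracts.

## Synthetic data and the packaged fixture

`generate_survey` emulates the quota telephone design: Bernoulli validity
per call, per-area Normal(0, sd 0.55) effects on the ownership logit
(matching the 10–67% between-area ownership spread seen in practice), 1 +
Poisson extra dogs per owning household, and per-dog membership flags drawn
from a 16-cell joint table over (vet, insured, kc, travel-scheme), with an
optional probability of reusing the household's draw. It does not model
directory selection mechanics, caller behaviour, refusal correlates, or
geography; passing tests therefore demonstrate correct inference under the
assumed clustered Bernoulli structure, not robustness to real-world
response bias.

The packaged fixture reconstructs the published per-area survey table
deterministically. Columns 3–4 (owning households, dogs) are preserved
exactly (they are self-consistent, summing to 122 households and 181 dogs
over 510 retained responses); derived columns are recomputed because
several published cells are internally inconsistent (e.g. 12/30 printed as
23%, and a pooled mean of 1.47 versus 181/122 = 1.484). Membership counts
130/73/55/5 are the unique integers out of 181 whose percentages round to
the published two-decimal values. The overlap cells were never published,
so the fixture uses a documented nesting convention: dogs ordered by table
row then call order, the first 130 vet-registered, first 73 insured, first
55 kennel-club registered, first 5 travel-scheme registered. The call log
(1,656 calls, 614 valid) is reconstructed from the published per-area
response rates: 36 valid calls per area (+1 for the first two areas),
per-area totals rounded from the printed rates, invalid calls adjusted
round-robin to the exact grand total. Extra dogs within an area are
assigned round-robin over its owning households.

The synthetic survival curve and registration trend used by the simulation
pipeline are stand-ins shaped like published all-breed actuarial curves
(near-certain survival to mid-life, steep decline from age ~8, none past
18) and registry volumes (~270k/year, mild decline); they are not published
data.

## Known limitations

* The area-resampling posterior centres near the pooled survey proportion;
  published analyses of this design report slightly different medians
  (e.g. 0.77 for veterinary registration versus 0.72 pooled), consistent
  with an unstated resampling scheme that up-weights high-membership areas.
* The veterinary-based population estimate depends on the unpublished
  fitted mixture of the original practice survey; the pipeline reproduces
  the procedure (and its interval logic), not the original point estimate.
* Multinomial breed/county generation ignores spatial autocorrelation and
  breed–geography interactions.
* EM is fitted to rounded, truncated-at-1 counts with a continuous mixture;
  for practice sizes (hundreds to tens of thousands) the discretisation
  error is negligible, but the KS test is computed against the continuous
  CDF.
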