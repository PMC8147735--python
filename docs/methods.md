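# Methods

## The estimand

For a health indicator $h$ with survey-weighted mean $\mu$ and weighted
fractional rank $r$ in the socioeconomic ordering, the concentration
index is $CI = 2\,\mathrm{cov}_w(h,r)/\mu$, equivalently
$(2/\mu)\sum_i \tilde w_i h_i r_i - 1$ with normalized weights
$\tilde w$, and equivalently twice the area between the concentration
curve and the equality diagonal. The three formulations are implemented
independently (`ci_direct`, `ci_regression`, `ci_from_curve_area`) and
tested against one another: the regression slope must match the
covariance form to 1e-10, the curve area to O(1/n) discretization
error.

A sometimes-printed shortcut form of the index omits the centering
term $-1$; without it a constant indicator would not score zero, so the
package implements the standard centered form throughout, which is also
what the convenient-regression estimator equals algebraically.

## Fractional ranks

Ranks follow the midpoint rule on cumulative weight shares:
$r_i = (W_{<i} + w_i/2)/W$ after sorting ascending on the ranking
variable. Ties form a block and share the block's midpoint rank, which
makes the rank vector (and every downstream CI) deterministic and
permutation-invariant, and makes duplicating a respondent exactly
equivalent to doubling her weight. The weighted mean of $r$ is ½ by
construction; `RankedSample` enforces this to 1e-9 at construction
time, along with positivity of weights and bounds on $h$.

## Wagstaff normalization for bounded outcomes

A binary indicator with mean $\mu$ can reach at most $1-\mu$ in
absolute CI, so raw indices are not comparable across prevalence
levels. The package rescales an indicator bounded on $[a,b]$ to
$[0,1]$ — multiplying the CI by $\mu/(\mu-a)$ — and divides by
$1-\mu_s$, giving $CI_W = CI\,\mu(b-a)/((\mu-a)(b-\mu))$; for binary
bounds this is $CI/(1-\mu)$. The 0–4 knowledge score uses bounds
$(0,4)$: the paper-style "divide by one minus the mean" is only
dimensionally coherent on a unit interval, so the rescaling is applied
first. A mean at a bound (empty or saturated indicator) raises rather
than returning ±∞.

## Inference

Standard errors are the conventional WLS slope SE of the convenient
regression $2\sigma_r^2 h_i/\mu$ on $r_i$ with the sampling weights.
The Wagstaff factor is applied to the point estimate and SE jointly
(delta method with $\mu$ treated as fixed), leaving the z-statistic
unchanged by normalization. Significance is a two-sided z-test, default
$\alpha=0.05$, rendered `NS` in tables; $|CI|\ge 0.2$ (configurable) is
flagged as a relevant degree of inequality. Cluster/stratum design
effects are out of scope: primary-sampling-unit identifiers are not
part of the analyzed schema, so intervals are naive
normal-approximation intervals — including in the descriptive tables,
where a proportion near 100% may show an upper bound above 100. Under
the synthetic generator's simple random sampling this SE is
well-calibrated (the acceptance suite checks a 94–96% NS rate under the
null and 93–97% coverage of the analytic truth); on clustered real
surveys it will typically understate the variance, so borderline
significance flags there should be read cautiously.

## Indicators and missing data

Four indicators: heard of HIV/AIDS (binary), a 0–4 knowledge score
(count of four correct items: condom use and single partner prevent
transmission; mosquito bites and sharing food do not), ever tested
(binary), condom use at last intercourse (binary). "Don't know" answers
count as incorrect — they are not correct knowledge — while a
structurally missing item (question not asked) makes the composite
missing; both policies are configurable. Respondents who never heard of
AIDS score 0 on the knowledge scale rather than missing, keeping the
knowledge-score N close to the awareness N; the alternative
(`never_heard_policy: missing`) is exposed. Each indicator is analyzed
on its own complete cases (listwise per indicator); ranks and weight
normalizations are rebuilt on the analyzed subsample so the rank mean
stays exactly ½.

Eligibility is women aged 15–24 inclusive; `filter_eligible` is
idempotent and logs exclusions.

## Ranking variables and weights

*Intra-country*: respondents rank on the household wealth index as
supplied by the survey. Where one country pools two survey programs
(MICS and DHS), the two asset indices live on unrelated scales, so
wealth is min-max normalized within each country-program before the
pooled ranking; for a single-program country this is a strictly
increasing transform and provably leaves ranks and CI untouched.
Weights rescale to mean one within each country-survey — immaterial to
the CI (scale-invariant in $w$) but fixing reported effective Ns.

*Inter-country*: wealth is min-max normalized to $[0,1]$ within each
country-survey, then multiplied by the country's pc-GDP-PPP, so only
the induced cross-country ordering matters and the product stays
non-negative and monotone within country. Min-max (rather than z-score)
is the default precisely because it composes with this multiplicative
scaling; a z-score option exists for sensitivity analysis. Weights
first rescale to sum one within country, then multiply by the country's
share of the region's female 15–24 population, so each country's total
analysis weight equals its population share exactly and a small survey
in a populous country speaks with its population's voice.

Optional direct age standardization of descriptive means is not
implemented; the descriptive table reports crude weighted means, which
is what its tests assert.

## Synthetic generator

`synthetic_data` emulates the structure of a multi-country household
survey program: per country, lognormal (σ = 0.6) or uniform wealth,
mean-one gamma (shape 2) or equal sampling weights, ages uniform on
15–24, and binary responses from the linear-in-rank model
$P(h=1|r) = a + br$. The linear model is chosen over a logistic one
because it has the exact closed form $CI = b/(6\mu)$, $\mu = a+b/2$
(Wagstaff: divide by $1-\mu$), derived from
$CI = (2/\mu)\int_0^1 r(a+br)\,dr - 1$ — giving every estimator an
analytic target. Missingness is applied completely at random.

The default region has six countries, n = 3 000 each, pc-GDP-PPP from
5 000 to 25 000 international $, unequal population shares, and
awareness/knowledge/condom prevalence rising with national income while
testing prevalence is income-unrelated. These sizes are deliberate
desk-scale stand-ins for a 20-country, ~10⁵-respondent real analysis;
they keep full-pipeline runs in seconds while leaving standard errors
small enough that the built-in gradients are detected.

What passing tests on this generator do **not** show about real data:
robustness to informative missingness, to cluster-sampling design
effects, to wealth-index measurement differences between survey
programs, or to age-composition differences across countries — none of
which the generator emulates.

## Numerical choices and degenerate inputs

- Ties in the ranking variable: block-midpoint rank (no arbitrary
  order); stable sorts throughout.
- $\mu = 0$, a single respondent, zero rank variance, or a mean at an
  indicator bound raise `DegenerateIndexError` rather than returning
  NaN/±∞.
- A constant wealth index within a country min-max-normalizes to 0.5
  everywhere with a warning (everyone shares the midpoint rank).
- Concentration curves require $h \ge 0$; the covariance-form CI
  accepts negative $h$ (well-defined), though no shipped indicator
  uses it.
- Table rendering: three decimals for CI estimates, `NS`/`NA` markers;
  CSVs keep full precision. Reruns on identical inputs and config are
  byte-identical.
- Master seeds spawn per-country child seeds via `SeedSequence`, so
  adding a country leaves the other countries' draws unchanged.

## Known limitations

- No design-based (clustered) variance estimation, by scope.
- No Erreygers correction, extended/generalized CI, or decomposition.
- Inter-country comparability rests on the min-max + GDP-PPP scaling
  convention; alternative normalizations change the pooled ranking and
  are exposed in config rather than silently fixed.
- The generator's linear probability model caps gradients at
  $0 < a+br < 1$; steeper real-world gradients need the within-country
  slope and between-country intercept pattern rather than a single
  large slope.
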