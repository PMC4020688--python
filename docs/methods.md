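# Methods

`ntosim` simulates count and presence/absence data as they arise in
comparative field trials for environmental risk assessment (ERA) of
genetically modified (GM) plants — abundances of non-target organisms (NTOs)
recorded on plots carrying a GM variety, its conventional comparator,
possibly further varieties and a set of reference varieties — and evaluates
the statistical procedures applied to such trials: difference testing,
TOST equivalence testing, and prospective (Monte-Carlo) power analysis.

## Distributions

Counts per experimental unit are modeled by a Poisson distribution or one of
three overdispersed mixtures, all parameterized by the marginal mean `mu`:

| family        | mixing law on the rate        | variance                    |
|---------------|-------------------------------|-----------------------------|
| `poisson`     | —                             | `mu`                        |
| `odpoisson`   | gamma, variance `(phi-1)*mu`  | `phi*mu`, `phi >= 1`        |
| `negbin`      | gamma, variance `omega*mu^2`  | `mu + omega*mu^2`           |
| `poislognorm` | lognormal on the log scale    | `mu + (e^{sigma2}-1)*mu^2`  |

The Poisson-lognormal shares the negative-binomial variance function via
`omega = exp(sigma2) - 1`; both scales are accepted with an explicit tag and
`sigma2` is the internal canonical scale.  Its pmf has no closed form and is
evaluated by Gauss–Hermite quadrature; the order is fixed at 50 by default,
which reproduces the normalization `sum_x P(x) = 1` to well below 1e-8 over
the tested parameter grid, and is configurable per spec object.

Presence/absence counts out of `n` plants use the binomial, beta-binomial
(intraclass correlation `phi`; native beta parameters
`a = pi(1-phi)/phi`, `b = (1-pi)(1-phi)/phi`) or binomial-logitnormal family
(normal random effect with variance `sigma2` on the logit scale, quadrature
moments).  For the logit-normal family the marginal moments have no closed
form; `match_logitnormal` solves numerically for the location/variance pair
reproducing a prescribed mean `n*pi` and variance `omega*n*pi*(1-pi)` to
1e-6 relative tolerance and fails with diagnostics when the target is
unattainable (extreme `pi` with large `omega`).

Zero inflation mixes any family with a structural-zero probability `delta`:
`P(Y=0) = delta + (1-delta) P_c(0)`.  Sampling applies an independent
Bernoulli(`delta`) mask rather than inverting the mixture CDF — simpler and
the same law.  The zero-inflated Poisson has mean `mu(1-delta)` and variance
`mu(1-delta)(1+delta*mu)`.

Degenerate settings (`phi=1`, `omega=0`, `sigma2=0`) reduce exactly to the
base family instead of raising errors.  Taylor's power law is deliberately
not a generator: it specifies a variance–mean relationship, not a
distribution.

## Trial model

All effects are additive on the natural-log scale for count means and on the
logit scale for probabilities (both the presence probability and the
structural-zero probability), which keeps means positive and probabilities
in (0,1).  The unit-level linear predictor stacks:

* a variety effect — fixed for the GM plant, comparator and additional
  varieties; drawn from `N(mean, variance)` for each member of a reference
  population (varieties with a history of safe use, treated as a random
  sample used to calibrate natural variation);
* a block effect `N(0, sigma_b^2)` per block (separate variances for the
  count part and the zero part; CRD is run as RCB with zero block variance
  and blocks relabeled as plots, one unified code path);
* environment effects for multi-trial scenarios: per-trial `N(0, s^2)`
  effects for unstructured trials, or site + year + site-by-year effects for
  a site-by-year grid;
* genotype-by-environment interaction: per trial the variety effect is drawn
  `N(main effect, gxe_variance)`, so GM-vs-comparator differences keep a
  common basis across environments.  For reference populations a two-stage
  scheme is used per trial: a trial-level population mean
  `M ~ N(m, s1^2)`, then member effects `~ N(M, s2^2)`;
* a time pattern `f_p(t)` — constant, linear, or quadratic; the quadratic is
  parameterized by its peak (`beta_max` at time `beta_opt`, width
  `beta_tol`, positive for a maximum) and converted internally to polynomial
  coefficients `beta2 = -1/(2 beta_tol)`, `beta1 = beta_opt/beta_tol`,
  `beta0 = beta_max - beta_opt^2/(2 beta_tol)`;
* time random effects `v ~ MVN(0, sigma_v^2 V)` per experimental unit, with
  `V` the identity-free options: none ("independent"), compound symmetry
  (`V_kl = rho`), or AR1 (`V_kl = rho^{|k-l|}`).  Compound symmetry or AR1
  with `sigma_v^2 > 0` is itself an overdispersion mechanism; with `rho = 0`
  under a Poisson family the marginal law is exactly Poisson-lognormal,
  which the test suite verifies distributionally.

Timepoints are integers 1..T internally; user-facing labels (e.g. −14..14
days) map affinely onto them and the quadratic peak parameters are
interpreted on the label scale, since both conventions occur in practice.

Design choices where the design was genuinely open:

* Count-part and zero-part random effects are drawn independently; no
  cross-correlation parameter is offered.
* Under a time model the per-variety polynomial carries the variety level
  (`f_0(t) = beta0` is the no-time model); reference populations draw every
  `beta` coefficient from its own normal law.  G-by-E under a time model
  applies to the intercept/peak-level coefficient only.
* All varieties appear in every block (standard RCB practice).
* Random draws are keyed by variety identity (sorted-name order), so
  permuting the variety list in a configuration does not change the
  simulated joint law.
* The reference-variety zero-part effects mirror the count-part two-stage
  structure in multi-trial settings.

Dispersion is common to all varieties and trials — keeping, say, the
coefficient of variation constant instead is out of scope, as are split-plot
randomizations, unequal time spacing and per-variety correlation structures.

## Inference layer

The analyses target single-trial, single-timepoint data (repeated measures
are summed per unit first via `aggregate_time`):

* **NB/Poisson ML fits** — one mean per variety, common dispersion.  For
  fixed dispersion the ML mean of a free group is its sample mean and of the
  pooled GM+comparator pair (the null restriction) the pooled sample mean,
  so the NB likelihood is profiled in one dimension over `log omega`
  (bounded search, tolerance 1e-8, deterministic).  The `omega -> 0`
  boundary switches to the Poisson likelihood whenever Poisson attains
  essentially the same maximum (tolerance 1e-5, absorbing `gammaln`
  round-off at huge size parameters).  All-zero varieties are floored at
  1e-8 and flagged.
* **Likelihood-ratio difference test** — `2(l_full - l_null)` against
  chi-square(1).
* **Quasi-Poisson variant** — the Poisson LRT scaled by the full-model mean
  deviance whenever that exceeds 1 (Pearson-based scaling is the common
  alternative; the deviance form is what the replicated sensitivity study
  used, so it is the default here).
* **Log-ANOVA** — `log(x + 0.5·[any zero in the dataset])`, one-way ANOVA
  across varieties; the reported statistic is the GM-vs-comparator contrast
  t-test with the variance pooled over all varieties (the omnibus F is the
  alternative reading; the contrast matches the pairwise question the power
  studies ask).
* **Profile-likelihood CI for `theta = mean(GM)/mean(comparator)`** — the
  set where twice the profile log-likelihood drop is below the chi-square
  quantile, found by bracketed bisection on `log theta` to 1e-6.  For the
  Poisson family the nuisance mean has a closed-form profile
  (`mu(theta) = (S1+S2)/(N1*theta+N2)`); for the NB family the comparator
  mean and dispersion are re-maximized numerically at each `theta` with warm
  starts.  Additional-variety means stay at their sample means, their ML
  value for any dispersion.
* **TOST equivalence** — non-equivalence is rejected when the CI lies
  wholly inside the limits of concern `(L, U)`.  The default is a single
  95% interval, i.e. two one-sided tests at 2.5% each; the level is a
  parameter.  Note an ambiguity in the source material: its text describes a
  95% interval while parts of its printed equivalence table are only
  consistent with a 90% interval (TOST at 5% per side).  Exact enumeration
  over the Poisson sufficient statistics shows the two conventions differ by
  1–2 replications in the required-N tables; this package follows the
  explicit 95% description.

Zero-inflated model *fitting* is intentionally absent: the simulation
studies analyze excess-zero data with the plain NB model precisely to
quantify the damage; fitting ZI models is future work.

## Power engine

`estimate_power` simulates `n_sims` datasets at every replication level N on
a grid (default 4, 6, 8, 10, 15, 20, 30, 40, the grid of the original
studies), applies the chosen analysis at `alpha = 0.05` two-sided, and
records rejection fractions with binomial standard errors.  Analysis
failures are excluded from the denominator and counted, since non-converged
fits have no principled rejection decision.  Independent seed substreams are
used per N (common random numbers available but off by default).

`required_replications` makes the raw curve monotone by isotonic regression
(Monte-Carlo noise produces small violations), interpolates the 0.80
crossing linearly in N, and rounds up to an integer; curves entirely above
or below the target are rendered censored ("≤4", "≥40") exactly as the
printed tables do.  The ceiling is a deliberate conservative choice: a
crossing of 34.1 replicates recommends 35.

`reproduce_table` sweeps the three published studies: the NB difference-test
table (T3), the Poisson difference/equivalence table with limits (1/2, 2)
(T4, degenerate rows rendered "-"), and the repeated-measures equivalence
table with limits (1/3, 3) (T5: quadratic time peaking at `mu` with
tolerance 47.96 days, Poisson-lognormal overdispersion `omega = 0.25`
realized as lognormal time random effects, AR1 `rho = 0.8` or independent
sampling at days −14..14, NB analysis of per-unit summed counts).

## What the generator does and does not establish

The synthetic scenarios are exactly the stated worlds of the original
studies: CRD, one additional variety at the comparator mean, GM mean
`theta*mu`, 1000 datasets per parameter combination.  Green tests establish
that the generator realizes the intended hierarchical law (moment
identities, zero fractions, distributional equivalences verified by
simulation) and that the testing layer has the advertised operating
characteristics (type-I error, coverage, required-N reproduction within the
stochastic interpolation tolerance of ±2 replications).  They do not
establish realism of any particular field system: real NTO counts bring
spatial correlation, measurement error, unbalanced designs and species
accumulation effects that are outside this model.

## Numerical notes and limitations

* Required-N entries from 1000-simulation curves carry interpolation noise
  of roughly ±1.5 replications where the grid is coarse (N = 30..40); the
  acceptance tests measure the table cells at 4000 simulations per N so the
  ±2 comparison reflects the pipeline rather than the noise.
* The NB profile CI relies on Nelder-Mead re-maximization per `theta`; warm
  starts keep it deterministic and fast, but the full T5 sweep at 1000
  simulations per cell is an hours-scale computation and is meant to be run
  explicitly via the CLI at a chosen scale.
* Reproducibility: a master seed spawns named substreams (effect draws vs
  response draws vs datasets), so the k-th dataset of a batch is stable
  across runs and adding varieties does not shift unrelated draws.
* Binary-family scenarios reuse the count linear predictor on the logit
  scale; the moment-matching helper is provided for calibrating
  logit-normal overdispersion, but the power studies replicated here are
  count-based.
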