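# ntosim

Simulation of non-target-organism (NTO) count and presence/absence data from
comparative field trials for environmental risk assessment of genetically
modified (GM) plants — together with the difference and equivalence tests
applied to such trials and a Monte-Carlo engine for prospective power
analysis.

## Who this is for

Before a GM field trial is sown, regulators expect a prospective power
analysis: how many replicates are needed to *detect* an ecologically relevant
effect on non-target arthropods (difference testing), or to *demonstrate*
that the GM variety stays within limits of concern relative to its
conventional comparator (equivalence testing, TOST)?  Field counts are
rarely Gaussian — they are overdispersed, often zero-inflated, blocked,
repeated in time and replicated across environments — so these questions are
best answered by simulating the trial and the analysis many times.  That is
what this package does.

## The model in brief

Counts per plot follow Poisson, overdispersed-Poisson (variance φμ),
negative binomial (variance μ + ωμ²) or Poisson-lognormal (same variance
function with ω = e^σ² − 1) laws; presence/absence counts follow binomial,
beta-binomial or binomial-logitnormal laws.  Any family can be zero-inflated
with a structural-zero probability δ, giving
P(Y=0) = δ + (1−δ)P_c(0).  All systematic and random effects enter on the
log scale (counts) or logit scale (probabilities):

    log μ = variety + block + trial/site/year effects + f_p(t) + v_t

with fixed effects for the GM plant, comparator and additional varieties,
normal draws for reference-variety populations (two-stage across trials),
optional genotype-by-environment draws, a constant/linear/quadratic time
pattern f_p(t) — the quadratic in peak form
f(t) = β_max − (t − β_opt)²/(2β_tol) — and time random effects v with
independence, compound-symmetry or AR1 correlation.

The inference layer provides the negative-binomial / Poisson
likelihood-ratio difference test (one mean per variety, common dispersion),
a quasi-Poisson deviance-scaled variant, log-transform ANOVA, a
profile-likelihood confidence interval for the GM/comparator mean ratio θ,
and TOST equivalence (CI wholly inside the limits of concern).  The power
engine sweeps replication grids, reports rejection fractions with
Monte-Carlo standard errors, and interpolates the replication needed for a
target power (default 0.80), rendered "≤4"/"≥40" when censored by the grid.

See `docs/methods.md` for assumptions, parameter conventions and numerical
choices.

## Worked example

A randomized-block trial comparing Bt maize (aphid mean 20/plant,
log scale 2.996) against its isoline (mean 10, log 2.303) and three
reference varieties drawn from N(2.303, 0.25), negative-binomial counts with
ω = 0.5, block variance 0.1 — `maize_aphids.toml`:

```toml
[distribution]
family = "negbin"
dispersion = 0.5

[design]
layout = "rcb"
replicates = 10
block_variance_count = 0.1

[[variety]]
name = "bt_maize"
role = "gm"
count_effect = 2.99573

[[variety]]
name = "isoline"
role = "comparator"
count_effect = 2.30259

[[variety]]
name = "ref"
role = "reference_population"
count_effect = {mean = 2.30259, variance = 0.25}
n_reference = 3
```

Simulate one dataset:

```
$ ntosim simulate maize_aphids.toml --seed 7 --n-datasets 1 --out sim_out
$ head -4 sim_out/dataset_0001.csv
trial,site,year,block,plot,variety,role,time,n,response,mu_true,delta_true
1,0,0,1,1,bt_maize,gm,0.0,1,38,20.964781600637675,0.0
1,0,0,1,2,isoline,comparator,0.0,1,2,10.482466070024588,0.0
1,0,0,1,3,ref1,reference,0.0,1,6,9.634388495907935,0.0
```

`mu_true` is the realized unit mean exp(variety effect + block effect): in
this draw the first block sits 0.047 above average on the log scale, so the
Bt mean is 20.96 rather than 20; the observed counts (38, 2, 6, …) scatter
around these means with negative-binomial noise.  A `manifest.json` records
the config hash, seed and output checksums for exact reproduction.

How much replication would this trial need for 80% power to detect the
twofold aphid increase?

```
$ ntosim power maize_aphids.toml --analysis negbin_lrt \
      --n-grid 4,6,8,10,15,20 --n-sims 200 --seed 7 --out pw_out
  N=  4: power=0.245 (se 0.030, failures 0)
  N=  6: power=0.395 (se 0.035, failures 0)
  N=  8: power=0.395 (se 0.035, failures 0)
  N= 10: power=0.510 (se 0.035, failures 0)
  N= 15: power=0.650 (se 0.034, failures 0)
  N= 20: power=0.775 (se 0.030, failures 0)
required N for power 0.8: ≥20
```

Even 20 blocks leave the likelihood-ratio difference test just under 80%
power here (the curve is censored at the grid maximum, hence "≥20") —
unsurprising for ω = 0.5: clumped counts are expensive.  The same command
with `--analysis equivalence --limits 0.5,2` answers the proof-of-safety
question instead, and `ntosim table --table T3` reproduces the full
required-replication sweep for the negative-binomial difference test.

The same machinery is available as a library:

```python
from ntosim import power
curve = power.estimate_power(
    lambda N: power.crd_count_config("negbin", 10.0, 2.0, N, 0.5),
    power.Analysis("negbin_lrt"), n_sims=1000, seed=1)
power.required_replications(curve)   # RequiredN(value=..., target=0.8)
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch at the original scale of
1000 simulated datasets per replication level, the headline
required-replication numbers of the underlying simulation studies: three
cells of the negative-binomial difference-test table, one Poisson
difference-test cell, and two Poisson TOST-equivalence cells with limits
(1/2, 2).

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It writes one JSON object per target id with the interpolated replication
number and the simulation count used (a few minutes on one CPU).
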