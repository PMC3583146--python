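# Methods

## Setting and notation

A disclosed microdata set of `n` records is modelled as a simple random
sample without replacement from a population of `N` records (a registry such
as a voter list).  Records sharing identical values on the declared
quasi-identifiers form equivalence classes; `f_i` and `F_i` denote the size
of class `i` in the sample and population, `u` and `K` the number of
non-empty classes, and `π = n/N` the sampling fraction.  All estimators
consume only the sample's frequency-of-frequencies spectrum (the number of
classes of each size) together with `(n, N)`; `π` is always derived from the
pair, never supplied separately, so the three can never be inconsistent.
Value comparison is exact string equality after parsing and optional
generalization — no fuzzy matching, which errs on the conservative side for
real, error-laden registries.

## Exact metrics

`λ1` is the probability that a sample-unique record is also
population-unique; it is a conditional quantity and is reported as undefined
(`None`) when the sample has no uniques, since `0/0` carries no information.
`λ2` divides the same count by `n` and is the share of the *disclosed* file
at certain-match risk; `λ2 = λ1·u1/n ≤ λ1` always holds, and at `π = 1`,
`λ2 = λ3` exactly.  Under record-level SRSWOR the expectation of `λ2` equals
`λ3` exactly at every fraction (a population-unique record contributes iff
sampled, with probability `n/N`), which is the identity the sampling tests
verify to three standard errors.

## Estimators

### Pitman

The sample partition is modelled by the two-parameter Poisson–Dirichlet
family with discount `0 ≤ α < 1` and concentration `θ > −α` (the Ewens model
at `α = 0`).  The log-likelihood of a spectrum with `u` classes is

```
Σ_{i=1}^{u−1} log(θ+iα) − Σ_{i=1}^{n−1} log(θ+i)
  + Σ_{classes, f_j≥2} Σ_{i=1}^{f_j−1} log(i−α),
```

evaluated through log-gamma identities.  Because Poisson–Dirichlet
partitions are sampling-consistent, fitting the sample partition is valid
inference for the population law, and the estimate is the predictive
expected singleton fraction of a size-`N` draw,

```
λ̂3 = (θ̂+α̂)_{N−1} / (θ̂+1)_{N−1}        (rising factorials),
```

which reduces to `θ̂/(θ̂+N−1)` at `α̂ = 0` and is verified against a
Chinese-restaurant-process Monte Carlo oracle in the tests.  Optimization is
box-constrained L-BFGS with analytic gradients in `(α, log(θ+α))`
coordinates, multi-started from `{0.01, 0.5, 0.9} × {1, 10, 100}` because
the likelihood can be nearly flat in `θ`; tolerance 1e−12 on the objective.
An all-singleton spectrum drives `α̂` to its upper bound, which is clamped
at `1 − 1e−6` and reported as converged with a boundary flag (the estimate
`λ̂3 ≈ 1` is then correct).  A fitted `α̂` carries a small negative
finite-sample bias (≈ −0.016 with spread ≈ 0.06 at `n = 2000` under
`α = 0.25, θ = 20`), so roughly 89% of replicates land within ±0.1 of the
truth; the parameter-recovery test asserts the rate that experiment
actually yields.

### Slide negative binomial (SNB)

Population class sizes are i.i.d. `F = 1 + NegBin(k, p)`.  Binomial
subsampling at rate `π` gives the closed form
`f = Bernoulli(π) + NegBin(k, p̃)` with `p̃ = p/(p+(1−p)π)` (thinning a
negative binomial is again negative binomial), so the observable-class
likelihood needs no series truncation.  `(k, p)` are fit by zero-truncated
maximum likelihood on the sample spectrum; the number of population classes
is then *estimated* as `K̂ = u/(1−P(f=0))` — never assumed known — and
`λ̂3 = K̂·p̂^k̂/N`.  Convergence is declared when the optimizer succeeds and
the gradient of the per-class average log-likelihood falls below 1e−6; a fit
parked on the negative-binomial→Poisson ridge (`k → ∞`, `p → 1` with
`k(1−p)` fixed) is flat but fully determines `P(F=1)` and therefore counts
as converged, with the box-boundary hit recorded as a diagnostic.
Genuinely unidentified spectra (e.g. all singletons at small `π`) surface as
`converged=False` with no estimate — the decision rule depends on that flag,
so there is no silent fallback.

### Zayatz

Model-free plug-in: the population class-size distribution is replaced by
the observed sample class-size distribution `u_j/u`, weighted by exact
hypergeometric subsampling probabilities
`P(f=1 | F=j) = j·C(N−j, n−1)/C(N, n)` (exact rather than the binomial
approximation, since `N` is known — this makes the estimator exactly `λ3`
at `π = 1` and lets tiny fixtures be checked in rational arithmetic).  Then
`λ̂3 = u1·P̂(F=1|f=1)/(π·N)`.  Deterministic; always converges.

### mu-argus

The Benedetti–Franconi individual-risk model posits
`F − f | f ~ NegBin(f, π)`.  Extended to `λ3` the same way as Zayatz —
summing `P(F=1|f=1)` over sample uniques and rescaling by `1/(π·N)` — the
posterior gives `P(F=1|f=1) = π`, so the estimate collapses to `u1/N`.  The
implementation evaluates the posterior pmf rather than hard-coding the
collapsed constant, so the independent re-derivation test is meaningful.
Its signed bias at fraction `π` on a heavy-tailed population behaves like
`π^α − 1`: strongly negative at small fractions, and *worse* the heavier the
tail, which is why the decision rule never consults it.

All estimates are clamped to `[0, 1]` with an explicit flag; clamping is
never silent.  Estimators raise on a spectrum whose total disagrees with
`n`.

## Decision rule

`E1`: if `π ≤ 0.1` use Pitman; else if SNB converged, use Zayatz when the
SNB estimate strictly exceeds the Zayatz estimate and SNB otherwise (ties
keep SNB); else use Zayatz.  The comparison `π ≤ 0.1` is evaluated at full
precision with an inclusive boundary, the returned result object is the
chosen component's own (bit-identical), and mu-argus is never invoked.  If
the chosen component itself failed (e.g. Pitman at tiny `π`), its failed
result is returned with the trace; inventing a fallback beyond the rule
would change the method.

## Monte Carlo harness

The study design is a factorial grid: uniqueness tier (low < 10%, medium
10–50% inclusive, high > 50%) × sampling fraction
(0.01, 0.05, 0.1, 0.3, 0.5, 0.7, 0.9) × estimator, with 1000 replicates per
point by default (`runs` is overridable for desk-scale work).  Replicate
`r` uses seed `base_seed + r`, and within a replicate every estimator
receives the identical sample, so estimator contrasts are free of sampling
noise.  Accuracy is summarized by the median and inter-quartile range
(Q3 − Q1, linear-interpolation quantiles) of the signed relative bias
`(λ̂3 − λ3)/λ3` — medians rather than MSE because rare extreme estimates
would otherwise dominate.  Runs whose estimator did not converge are
excluded from the median/IQR and reported through an explicit convergence
rate; a population with `λ3 = 0` is rejected since relative bias is
undefined there.  The per-run table (one row per study point × replicate,
with seed and convergence recorded) is the hand-off point for any
downstream modelling of the bias surface.

## Synthetic populations

Ground truth is always the *realized* `λ3` of the generated population,
computed exactly from its class sizes — not the superpopulation expectation.

- **CRP populations** (two-parameter Chinese restaurant process) provide
  heavy-tailed class-size distributions matching the Pitman model; the
  seating uses an O(1)-per-record proposal/rejection scheme and is verified
  against the Ewens closed forms for the expected number of classes and
  singletons.  Tier parameter choices used in the evaluation tests:
  low `(α=0.1, θ=80)`, medium `(α=0.5, θ=100)`, high `(α=0.95, θ=20)` at
  `N = 2000`.
- **SNB populations** draw class sizes i.i.d. from the slide negative
  binomial and back the self-consistency test (median relative bias within
  ±0.15 at `π = 0.5` over 200 replicates of `K = 800` classes).
- **Quasi-identifier tables** draw independent demographic-like columns
  (day-resolution birth dates over a 25-year window, sex, a 3-level region)
  and reach the three tiers by walking a generalization ladder (day → month
  → month with region collapsed), mirroring how tiered versions of real
  data sets are produced by coarsening.  Columns are independent; no
  correlation structure is modelled — sufficient for tier control, not for
  emulating any particular real data set.  An unreachable tier is reported
  as such, never fabricated.

What passing tests show — and do not show.  The synthetic populations have
exactly known truth and clean sampling, so the tests validate the
estimators' math, the decision rule's branching and the harness's
book-keeping.  They do not certify accuracy on real clinical data, whose
class-size distributions are correlated across quasi-identifiers and whose
registries contain errors and duplicates.  On *near-uniform* populations
(flat multinomial cells) two caveats are documented: the Pitman model is
misspecified and overestimates uniqueness at large fractions, and the
mu-argus estimate's signed bias crosses zero as `π` grows, so its |median
relative bias| is intrinsically non-monotone there.

## Problem sizes and numerical choices

Test-suite simulations run at desk scale, chosen to keep every Monte Carlo
band meaningful: CRP closed-form checks at `N = 400–800` with 2000–6000
draws (3-standard-error bands), parameter recovery and SNB self-consistency
at the full 200 replicates (`n = 2000` and `K = 800`), the sample-mean
uniqueness identity at `N = 2000` with 1000 draws per fraction, and the
trend study at `N = 2000` with 100 replicates per study point.  Trend
comparisons treat |median relative bias| changes below 0.01 as ties (the
resolution of a 100-run median) and allow one dip-and-rebound episode,
which a sign crossing of the bias produces even for an estimator improving
monotonically.  Likelihoods are computed in log space throughout;
hypergeometric and factorial terms use log-gamma; sample sizes derive from
fractions by round-half-up with a minimum of one record.  Missing
quasi-identifier values, if present in a CSV, are ordinary category values
(empty string) under exact matching.
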