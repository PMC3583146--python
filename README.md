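# uniqrisk

Population-uniqueness estimation and re-identification risk assessment for
sampled microdata.

## The problem

When a custodian discloses a clinical data set that is a *sample* of some
population (charts selected for abstraction, a survey, a public-use census
extract), the standard measure of linkage risk is **population uniqueness**:
the proportion of records in the population registry (for instance a voter
list) that are unique on the quasi-identifiers an adversary could know —
age, sex, postal code, dates.  With the registry in hand the exact metrics
are straightforward; without it, population uniqueness must be *estimated
from the disclosed sample alone*.  uniqrisk implements both modes for health
privacy researchers and disclosure-control practitioners.

## Metrics and estimators

Let `N`/`n` be population/sample sizes, `F_i`/`f_i` the equivalence-class
sizes (records identical on all quasi-identifiers), and `I` the indicator
function.  Exact metrics when both files are available:

- `λ1 = Σ I(f_i=1, F_i=1) / Σ I(f_i=1)` — P(population unique | sample unique)
- `λ2 = Σ I(f_i=1, F_i=1) / n` — share of the disclosed records at risk of a
  certain match
- `λ3 = Σ I(F_i=1) / N` — population uniqueness, the estimation target

Four sample-only estimators of `λ3` are implemented, all functions of the
sample's frequency-of-frequencies spectrum plus `(n, N)`:

- **Pitman** — maximum likelihood in the two-parameter Poisson–Dirichlet
  partition model (discount `α`, concentration `θ`; `α = 0` is the Ewens
  model), with `λ̂3 = (θ̂+α̂)_{N−1} / (θ̂+1)_{N−1}` (rising factorials).
- **SNB** — slide (shifted) negative binomial superpopulation law for class
  sizes, fit by zero-truncated maximum likelihood under binomial
  subsampling; the number of population classes is estimated, never assumed.
- **Zayatz** — model-free plug-in of the observed class-size distribution
  into exact hypergeometric subsampling probabilities.
- **mu-argus** — the Benedetti–Franconi individual-risk model (negative
  binomial posterior for `F` given `f`), extended to a `λ3` estimate.

The headline method is the **E1 decision rule**: Pitman when the sampling
fraction `π = n/N ≤ 0.1`; otherwise SNB, unless SNB fails to converge or
exceeds the Zayatz estimate, in which case Zayatz.  A Monte Carlo harness
evaluates all of this on synthetic populations with exactly known `λ3`,
reporting the median and inter-quartile range of the relative bias
`(λ̂3 − λ3)/λ3` per uniqueness tier, sampling fraction and estimator.

## Worked example

Estimate risk from a disclosed sample alone.  `sample.csv` holds 1500
records drawn (π = 0.3) from a synthetic population of 5000 whose true
uniqueness is λ3 = 0.066; the config declares the quasi-identifiers, the
population size and a 20% risk threshold:

```yaml
# cfg.yaml
quasi_identifiers: [dob, sex, region]
population_size: 5000
threshold: 0.20
seed: 1
```

```sh
uniqrisk assess sample.csv --config cfg.yaml
```

prints a JSON report; abridged:

```json
{
  "inputs": {"n": 1500, "N": 5000, "sampling_fraction": 0.3,
             "sample_classes": 1018, "sample_uniques": 651},
  "estimates": [
    {"estimator": "pitman",   "lambda3_hat": 0.2177, "converged": true},
    {"estimator": "snb",      "lambda3_hat": 0.0634, "converged": true},
    {"estimator": "zayatz",   "lambda3_hat": 0.2420, "converged": true},
    {"estimator": "mu_argus", "lambda3_hat": 0.1302, "converged": true}
  ],
  "e1": {"chosen_estimator": "snb", "lambda3_hat": 0.0634,
         "branch_path": [["pi<=0.1", false], ["snb_converged", true],
                         ["snb_estimate_gt_zayatz", false]]},
  "decision": "below_threshold"
}
```

Since π = 0.3 > 0.1 and the converged SNB estimate (0.063) does not exceed
Zayatz (0.242), E1 reports λ̂3 ≈ 0.063 — close to the true 0.066 and below
the 0.20 threshold, so the sample could be disclosed under that policy.
With the registry available, `uniqrisk truth sample.csv population.csv
--config cfg.yaml` reports the exact λ1/λ2/λ3 instead, and
`uniqrisk evaluate --synthetic --out-dir study/ --runs 100 --seed 1` runs
the full estimator-evaluation study and writes per-run and per-condition
relative-bias tables.

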