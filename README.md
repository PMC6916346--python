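# mixedintervals

Confidence, prediction, and tolerance intervals for linear mixed models
with variance components — one random factor, two nested or two crossed
random factors, balanced or unbalanced, with optional per-group
heterogeneous variances.

## Who this is for

Statisticians who need more than a confidence interval from a mixed
model: in assay validation and qualification, the range within which a
*single future measurement* will fall (accuracy), not just the mean bias
(trueness); in clinical or preclinical measurement studies, the range of
future individual responses accounting for random factors such as runs,
batches, surgeons or laboratories.  Standard mixed-model software
reports confidence intervals for means; prediction and tolerance
intervals for future observations under general designs are what this
package adds.

## The statistics

For the model `Y = Xβ + Zγ + ε` with `Var(Y) = V = ZGZ' + R` and
variance components `θ = (θ₁, …, θ_q)` (residual last), fitted by REML:

* **CI** for an estimable cell combination `l`:
  `lβ̂ ± t₁₋α/₂,k √(l Ĉ₁₁ l')`, with `Ĉ₁₁ = (X'V̂⁻¹X)⁻¹` and degrees of
  freedom `k` from the generalized Satterthwaite rule applied to
  `l Ĉ₁₁ l'` (delta method through θ).
* **PI** for one future observation:
  `lβ̂ ± t₁₋ψ/₂,r √(l Ĉ₁₁ l' + σ̂_T²)`, where `σ̂_T² = Σθ̂ᵢ` is the total
  variance and
  `r = 2 σ̂_T⁴ / Var(σ̂_T²)`, with `Var(σ̂_T²) = ΣᵢΣⱼ ϑ̂ᵢⱼ` summed over the
  covariance matrix `ϑ̂` of the variance components — the inverse
  observed Fisher information (inverse negative Hessian of the REML
  log-likelihood).  This works for any design, balanced or not, because
  it never assumes the components are independent.
* **TI** (two-sided, β-content): the z-based PI with `σ̂_T²` replaced by
  its modified-large-sample (Graybill–Wang) upper confidence bound on
  the expected-mean-square scale:
  `lβ̂ ± z₁₋ψ/₂ √(l Ĉ₁₁ l' + σ̂_T² + √(Σⱼ Hⱼ² kⱼ² EMSⱼ²))`, with
  `σ̂_T² = Σⱼ kⱼ EMSⱼ`, `Hⱼ = rⱼ/χ²_{α,rⱼ} − 1` and `rⱼ` the ANOVA df of
  mean square `j`.  Closed-form decompositions cover balanced one-way,
  nested and crossed designs and the unbalanced one-way; other
  unbalanced designs use quadratic-form synthesis of the EMS
  coefficients.

Fixed effects are always coded as cell means (one parameter per observed
level combination, no intercept), so each cell's estimate, SE and df
come straight out of the fit and contrasts are expressed through `l`.

## Worked example

Intervals for a balanced assay validation study (6 runs × 3 replicates,
one-way random model) computed directly from the fit summary — see
`examples/assay_balanced.py`:

```text
total variance sigma_T^2 = 0.001934
generalized Satterthwaite df for the PI = 12.478
95% CI            [0.946, 1.016]  (df = 5)
95% PI            [0.881, 1.081]  (df = 12.478)
95% TI (90% conf) [0.849, 1.113]
```

The CI says the mean reported concentration is within ±3.5% of truth;
the PI says a single future measurement will fall within roughly ±10%;
the TI guarantees 95% of future measurements stay within ±13% with 90%
confidence.  The other examples cover the unbalanced variant of the same
study, an orthopedic surgery application with heterogeneous variances
per technology, a full fit from raw data, and a Monte-Carlo check of
coverage:

```bash
python examples/fit_from_data.py
python examples/coverage_simulation.py
```

A thin CLI wraps the same machinery:

```bash
mixedintervals fixture --kind one_random --levels 6x3 --out assay.csv
mixedintervals intervals --data assay.csv --response y --random fa --all-cells
mixedintervals simulate --scenario one_random_high_residual --nsims 500 --seed 42
```

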