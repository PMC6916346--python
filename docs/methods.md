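# Methods

## Model and estimation

The package fits `Y = Xβ + Zγ + ε` with independent Gaussian random
effects and errors, `Var(Y) = V(θ) = Σₖ θₖ ZₖZₖ' + R(θ)`, where each Zₖ
is a membership indicator block (one per random term) and R is diagonal
with one residual variance, or one per heterogeneity group.  Fixed
effects use cell-means coding exclusively: X is an indicator of observed
fixed-level combinations (a single intercept cell if there are none), so
X has full column rank by construction, every cell has its own parameter,
and all contrasts are `l` vectors.  Level order is lexicographic in the
string labels, so `l` vectors are reproducible across runs; nested child
levels are keyed by the combined `parent:child` label so reused child
labels never alias.

Estimation is REML: the restricted log-likelihood
`ℓ_R(θ) = −½[log|V| + log|X'V⁻¹X| + y'Py]` (P the REML projection) is
maximized on the **variance scale** under box constraints `θ ≥ 0`.  The
variance scale matters because the covariance of θ̂ is consumed
downstream on that scale; a log transform would be friendlier to the
optimizer but would put the Hessian in the wrong parametrization.
L-BFGS-B with the analytic score
`∂ℓ_R/∂θₖ = −½[tr(PVₖ) − y'PVₖPy]` is followed by a projected-Newton
polish (finite-difference Hessian of the score) until the free-set
gradient norm is below 1e−6; an ANOVA-style restart is attempted if the
first pass fails.  The response is standardized internally and θ̂ scaled
back, which is exact by REML scale equivariance.  Residual components
are kept ≥ 1e−10 during optimization because V is singular when all
residual variances vanish; non-residual components may hit 0 exactly and
are then flagged as boundary estimates.

With heterogeneous variance groups (e.g. one technology far noisier than
another) every component, residual included, is split per group level;
a random term's block for group g is its indicator restricted to that
group's rows, so observations sharing a random level are correlated only
within their group, each with its own variance.

## Covariance of the variance components

`ϑ̂ = Var(θ̂)` is the inverse of the negative Hessian of ℓ_R at θ̂ (the
inverse observed Fisher information).  The Hessian is obtained by
central finite differences of the analytic score with relative step
`max(1e−4·θ̂ᵢ, 1e−8)` plus one Richardson extrapolation step (truncation
error O(h⁴)); this keeps the downstream degrees-of-freedom identities
accurate to ~1e−7 relative, verified against the closed-form one-way
information.  Components pinned at zero get one-sided differences and
degrade the quality flag.  When the full information is not positive
definite at a boundary, the boundary components are profiled out: the
interior block is inverted and boundary rows/columns set to zero
(`boundary-profiled` flag); a pseudo-inverse is the last resort and is
flagged loudly, since a non-PSD ϑ̂ can make interval variances
meaningless.  Cov(β̂, θ̂) is taken as zero (asymptotic independence) and
never estimated.

## Degrees of freedom

Everything runs through one rule: `df = 2·Variance²/Var(Variance)`,
evaluated at continuous (fractional) df in the t quantile.

* For the prediction interval, the variance is `σ̂_T² = Σθ̂ᵢ` and
  `Var(σ̂_T²) = ΣᵢΣⱼϑ̂ᵢⱼ` — no independence assumption on the components,
  which is what makes the construction design-agnostic (unbalanced
  designs and missing data only change the Hessian).
* For fixed-effect CIs, the variance is `lĈ₁₁l'` and its variance comes
  from the delta method: central-difference gradient of `lC₁₁(θ)l'` at
  θ̂, sandwiched with ϑ̂.  For a balanced one-way intercept this yields
  exactly A−1 (the intercept variance is proportional to the
  between-group mean square alone), matching what containment or
  Kenward–Roger degrees of freedom give in those balanced cases.
  Kenward–Roger itself (which also adjusts the covariance, not only the
  df) is deliberately not implemented; outputs label the df method.

On balanced one-way designs the PI reduces algebraically to the
effective-sample-size form `μ̂ ± t·σ̂_T√(1+1/N_e)` with
`N_e = A·n·σ̂_T²/(n·σ̂_α²+σ̂_ε²)`, and the information-based df equals
classical Satterthwaite on the independent mean squares; both identities
are asserted numerically to 1e−6 relative in the test suite.

## Tolerance intervals

The TI replaces `σ̂_T²` in the z-based PI by its Graybill–Wang
(modified-large-sample) upper confidence bound computed on the EMS
scale, where the mean squares are independent in balanced designs (the
variance components themselves generally are not):
`U = σ̂_T² + √(Σⱼ(Hⱼ kⱼ EMSⱼ)²)` with `σ̂_T² = Σⱼ kⱼ EMSⱼ` and
`Hⱼ = rⱼ/χ²_{α,rⱼ} − 1`.  The fixed-effect variance `lĈ₁₁l'` is kept
additively under the outer square root but excluded from the MLS
inflation (its EMS is ill-defined for general designs and it is
dominated by σ̂_T²).  As all rⱼ → ∞, Hⱼ → 0 and the TI collapses onto
the z-based PI, which in turn converges to the true normal quantiles.

EMS decompositions:

* closed forms for balanced one-way (`k = (1/n, 1−1/n)`, df
  `(A−1, A(n−1))`), balanced nested, balanced crossed, and unbalanced
  one-way (`c = (N − Σnᵢ²/N)/(A−1)` replacing n);
* synthesis for other designs.  Crossed terms use Type-III quadratic
  forms — contrasts of unweighted marginal cell means — because in an
  all-cells-filled two-factor layout they produce EMS rows with the
  balanced structure `σ_ε² + c·σ_ab² + c·B·σ_a²` and reduce exactly to
  the closed forms under balance; sequential projections (Henderson-III
  style), which coincide with the closed forms, are used for nested and
  one-way layouts.  The kⱼ then solve `Σⱼ kⱼ·coefⱼ(component) = 1` for
  every component — a triangular system whose last equation makes the
  residual coefficient complete the identity `Σⱼ kⱼ EMSⱼ = σ̂_T²`, which
  is checked to 1e−6 relative before any TI is produced (manual
  coefficient injection is available through the CLI for published
  decompositions one wants to reproduce verbatim).

Residual ANOVA df default to `N − rank([X Z])`, which equals the
familiar `A(n−1)`-type counts for balanced designs and handles fixed
effects beyond the intercept (e.g. 92 − 26 = 66 for a 23-surgeon,
4-slice group); an override is provided because published analyses
sometimes fix this count by hand.

## Paradox reporting

With very few levels in a random factor the CI can be wider than the PI:
the prediction has more variance but also more degrees of freedom, and
the smaller t quantile can win.  The library detects and reports this
condition (`detect_paradox`, CLI warning) and never "fixes" it.  Under
the generalized-Satterthwaite CI df used here it is concentrated at
two-level parent factors (55% of replicates at a 2×2×2 nested design in
the packaged simulation); with fixed-effect df methods that can collapse
toward 1 it appears across more designs.

## Synthetic data and simulations

`Scenario`/`generate_dataset` emulate intercept-plus-random-factor
studies: one random factor, two nested, or two crossed with interaction,
components chosen from two canonical mixes per structure (high residual:
e.g. 2/8; low residual: e.g. 8/2, all totalling 10) with intercept 25.
Draws are Gaussian with independent effects — no outliers, no skewness,
no missingness mechanisms, no correlated structures beyond the variance
components — so passing coverage here demonstrates correctness of the
interval machinery under the model, not robustness to model violation.
Randomness is counter-based (`SeedSequence([seed, scenario_key,
replicate])`), so any replicate reproduces in isolation.

Default Monte-Carlo sizes are desk-scale (a few hundred to 1000
replicates; the packaged acceptance check uses 1000 for the 10×10
one-random design and 300 for the nested paradox design) — enough for
3-MC-SE assertions around nominal levels; larger grids are available
through scenario configuration.  TI content is computed as the exact
normal content of each realized interval rather than by a second
simulation layer, removing one source of Monte-Carlo noise.

## Numerical choices and limitations

* Convergence: relative log-likelihood change < 1e−10 in L-BFGS-B and
  projected gradient norm < 1e−6 after polishing (both configurable);
  non-convergence raises, carrying the last iterate.
* Generalized inverses in the textbook formulas are realized as ordinary
  inverses — cell-means X is full rank; zero-variance components are
  excluded from the C₂₂ computation rather than inverting a singular G.
* t quantiles at fractional df use scipy's continuous t distribution.
* Degenerate inputs: sd = 0 gives a degenerate [mean, mean] interval;
  all-equal group means give a flagged zero boundary estimate; a random
  factor observed at a single level is rejected as inestimable.
* Only variance-component covariance structures are supported (no
  unstructured G, no serial correlation), fixed effects must be
  categorical, and all intervals are two-sided; one-sided and
  simultaneous intervals are out of scope.
* EBLUP-conditional intervals are provided with an explicit caveat: for
  formal conditional inference the realized random levels should be
  refitted as fixed effects.
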