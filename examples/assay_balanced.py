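"""Intervals for a balanced assay validation study from its fit summary.

An analytical method measured a reference sample in 6 runs with 3
replicates each (one-way random model: run variance + repeatability).
The raw data are not needed: the interval layer works directly from the
reported REML summary - the two variance components, the summed
covariance matrix of the components, and the intercept with its SE.
"""

from mixedintervals import (
    balanced_one_way,
    ci_from_summary,
    pi_from_summary,
    satterthwaite_df,
    ti_from_summary,
)

sigma_run, sigma_res = 0.000681, 0.001253  # between-run and residual variance
var_total = 5.995e-7  # Var(sigma_T^2): sum of the component covariance matrix
estimate, se = 0.981, 0.01353  # intercept (relative concentration) and its SE
A, n = 6, 3

sigma_t2 = sigma_run + sigma_res
df_pi = satterthwaite_df(sigma_t2, var_total)
print(f"total variance sigma_T^2 = {sigma_t2:.6f}")
print(f"generalized Satterthwaite df for the PI = {df_pi:.3f}")

ci = ci_from_summary(estimate, se, df=A - 1, alpha=0.05)
pi = pi_from_summary(estimate, se, sigma_t2, var_total, psi=0.05)
decomp = balanced_one_way(sigma_run, sigma_res, A, n, alpha=0.10)
ti = ti_from_summary(estimate, se, decomp, psi=0.05)

print(f"95% CI            [{ci.lower:.3f}, {ci.upper:.3f}]  (df = {ci.df:.0f})")
print(f"95% PI            [{pi.lower:.3f}, {pi.upper:.3f}]  (df = {pi.df:.3f})")
print(f"95% TI (90% conf) [{ti.lower:.3f}, {ti.upper:.3f}]")
print()
print("The CI brackets the mean bias of the method; the PI brackets a")
print("single future measurement; the TI covers 95% of future")
print("measurements with 90% confidence (MLS bound on the EMS scale).")
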