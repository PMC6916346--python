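"""Intervals for the same assay after removing three observations.

Dropping the first replicate of runs 1, 2 and 6 leaves group sizes
(2,2,3,3,3,2).  The one-way EMS coefficient is no longer the replicate
count n: it becomes c = (N - sum n_i^2 / N) / (A - 1) = 2.48, and the
tolerance interval uses the adapted decomposition with ANOVA df (5, 9).
"""

from mixedintervals import (
    pi_from_summary,
    satterthwaite_df,
    ti_from_summary,
    unbalanced_one_way,
)

sigma_run, sigma_res = 0.000575, 0.001594
var_total = 8.316e-7
estimate, se = 0.9822, 0.01441
sizes = (2, 2, 3, 3, 3, 2)

decomp = unbalanced_one_way(sizes, sigma_run, sigma_res, alpha=0.10)
coeff = decomp.terms[0].coeffs["a"]
print(f"EMS_A = sigma_e^2 + {coeff:.2f} sigma_run^2  (df {decomp.terms[0].r:.0f}, "
      f"{decomp.terms[1].r:.0f})")

sigma_t2 = sigma_run + sigma_res
df_pi = satterthwaite_df(sigma_t2, var_total)
pi = pi_from_summary(estimate, se, sigma_t2, var_total, psi=0.05)
ti = ti_from_summary(estimate, se, decomp, psi=0.05)
print(f"PI df = {df_pi:.5f}")
print(f"95% PI            [{pi.lower:.3f}, {pi.upper:.3f}]")
print(f"95% TI (90% conf) [{ti.lower:.3f}, {ti.upper:.3f}]")
print()
print("Both intervals are slightly wider than in the balanced case: three")
print("missing values raise the variances and lower the degrees of freedom.")
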