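"""Prediction and tolerance intervals for an orthopedic surgery study.

23 surgeons cut a simulated bone tumor at 4 slices with two technologies
(free hand vs navigated).  The response is the error of safe margin
(ESM, mm); values below -10 mean the tumor was not fully removed.  The
model has cell means for slice x technology, surgeon as a random factor,
and variance components estimated per technology (the navigated
technology is far less variable).  Here: the free-hand group at slice 1,
from the reported per-technology summary.
"""

from mixedintervals import (
    balanced_one_way,
    pi_from_summary,
    satterthwaite_df,
    ti_from_summary,
)

sigma_surgeon, sigma_res = 7.349, 18.074  # free-hand technology
var_total = 18.372  # Var(sigma_T^2) from the observed information
estimate, se = 0.114, 1.051  # predicted ESM at slice 1, free hand
A, n = 23, 4  # surgeons, slices per surgeon

sigma_t2 = sigma_surgeon + sigma_res
print(f"sigma_T^2 = {sigma_t2:.3f}, PI df = {satterthwaite_df(sigma_t2, var_total):.2f}")

pi = pi_from_summary(estimate, se, sigma_t2, var_total, psi=0.05)
print(f"prediction variance = {pi.variance_used:.3f}")
print(f"95% PI            [{pi.lower:.2f}, {pi.upper:.2f}]")

# residual ANOVA df within the group: (23-1)(4-1) = 66
decomp = balanced_one_way(sigma_surgeon, sigma_res, A, n, alpha=0.20, residual_df=66)
ti = ti_from_summary(estimate, se, decomp, psi=0.05)
print(f"95% TI (80% conf) [{ti.lower:.2f}, {ti.upper:.2f}]")
print()
print("95% of individual free-hand ESM values at slice 1 are expected in")
print("the PI on average; the TI guarantees that content with 80%")
print("confidence.  Both overlap -10: free-hand intralesional resection")
print("cannot be ruled out at this slice.")
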