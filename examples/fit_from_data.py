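"""Full pipeline on raw data: simulate, fit by REML, report intervals.

Builds a balanced one-way dataset (6 runs x 3 replicates) with known
variance components, fits the variance-component model by REML, and
prints the fitted components with their SEs and the three intervals for
the intercept cell.
"""

import numpy as np

import mixedintervals as mi

scenario = mi.Scenario(
    "one_random",
    variance_components=(0.0007, 0.0013),
    level_counts=(6, 3),
    mu=1.0,
    seed=5,
    n_sims=1,
)
data = mi.generate_dataset(scenario, 0)
print(data.head(4).to_string(index=False), "\n...")

spec = mi.ModelSpec(response="y", random_terms=["fa"])
design = mi.build_design(data, spec)
fit = mi.fit_reml(design, data["y"].to_numpy())

for label, est, se in zip(fit.theta_layout, fit.theta_hat, fit.theta_se):
    print(f"{label:>10s}: {est:.6f} (SE {se:.6f})")
tv = mi.total_variance(fit)
print(f"sigma_T^2 = {tv.sigmaT2:.6f}, PI df = {tv.df_r:.2f}")

ci = mi.confidence_interval(fit, "(Intercept)", alpha=0.05)
pi = mi.prediction_interval(fit, "(Intercept)", psi=0.05)
ti = mi.tolerance_interval(fit, "(Intercept)", psi=0.05, alpha=0.10)
print(f"95% CI            [{ci.lower:.4f}, {ci.upper:.4f}]  (df = {ci.df:.2f})")
print(f"95% PI            [{pi.lower:.4f}, {pi.upper:.4f}]  (df = {pi.df:.2f})")
print(f"95% TI (90% conf) [{ti.lower:.4f}, {ti.upper:.4f}]")
if mi.detect_paradox(ci, pi):
    print("note: CI wider than PI (few random levels)")
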