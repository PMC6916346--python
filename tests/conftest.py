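import numpy as np
import pandas as pd
import pytest

import mixedintervals as mi


def make_one_way(A=6, n=3, sigma_a2=0.5, sigma_e2=1.0, mu=10.0, seed=42):
    """Balanced one-way dataset with known generating parameters."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, np.sqrt(sigma_a2), A)
    y = mu + np.repeat(a, n) + rng.normal(0.0, np.sqrt(sigma_e2), A * n)
    data = pd.DataFrame(
        {"run": np.repeat([f"r{i:02d}" for i in range(A)], n), "y": y}
    )
    return data


def anova_one_way(y, A, n):
    """Closed-form balanced one-way ANOVA estimators (independent oracle)."""
    y = np.asarray(y, dtype=float).reshape(A, n)
    group_means = y.mean(axis=1)
    grand = y.mean()
    ms_a = n * np.sum((group_means - grand) ** 2) / (A - 1)
    ms_e = np.sum((y - group_means[:, None]) ** 2) / (A * (n - 1))
    return ms_a, ms_e, (ms_a - ms_e) / n, ms_e, grand


@pytest.fixture(scope="session")
def one_way_data():
    return make_one_way()


@pytest.fixture(scope="session")
def one_way_fit(one_way_data):
    spec = mi.ModelSpec(response="y", random_terms=["run"])
    design = mi.build_design(one_way_data, spec)
    return mi.fit_reml(design, one_way_data["y"].to_numpy())


@pytest.fixture(scope="session")
def nested_fit():
    sc = mi.Scenario(
        "nested", (5.0, 3.0, 2.0), (5, 5, 5), n_sims=1, seed=11
    )
    data = mi.generate_dataset(sc, 0)
    design = mi.build_design(data, sc.model_spec())
    return mi.fit_reml(design, data["y"].to_numpy())
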