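"""Monte-Carlo evaluation of interval coverage, content and confidence.

Datasets are simulated from Gaussian variance-component models with an
intercept-only fixed effect (mu = 25 by default): one random factor, two
nested random factors, or two crossed random factors with interaction,
each under a high-residual or low-residual mix of components that sums
to a total variance of 10.  Each replicate is fitted by REML and the
CI / PI / TI computed; metrics follow the usual definitions:

* CI coverage  - fraction of replicates whose CI contains the true mean;
* PI/TI content - normal probability content of the realized interval,
  Phi((U - mu)/sigma_T) - Phi((L - mu)/sigma_T), averaged over replicates
  (the exact content, not an extra layer of simulated draws);
* TI confidence - fraction of replicates whose content is at least the
  nominal prediction level;
* paradox frequency - fraction of replicates with CI wider than PI.

Randomness is a counter-based stream: replicate j of a scenario draws
from ``SeedSequence([seed, scenario_key, j])``, so scenarios parallelize
and single replicates reproduce independently of execution order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ModelSpec, build_design
from .intervals import (
    confidence_interval,
    detect_paradox,
    prediction_interval,
    tolerance_interval,
)
from .reml import RemlError, fit_reml

__all__ = [
    "Scenario",
    "CoverageReport",
    "TABLE_COMPONENTS",
    "generate_dataset",
    "run_scenario",
    "paradox_frequency",
]

# canonical component mixes (total variance 10): per structure,
# high-residual and low-residual regimes
TABLE_COMPONENTS: dict[str, dict[str, tuple[float, ...]]] = {
    "one_random": {"high_residual": (2.0, 8.0), "low_residual": (8.0, 2.0)},
    "nested": {"high_residual": (2.0, 2.0, 6.0), "low_residual": (5.0, 3.0, 2.0)},
    "crossed": {
        "high_residual": (1.0, 1.0, 2.0, 6.0),
        "low_residual": (4.0, 2.0, 2.0, 2.0),
    },
}

_N_COMPONENTS = {"one_random": 2, "nested": 3, "crossed": 4}


@dataclass
class Scenario:
    """One simulation cell: structure, components, design size, levels."""

    structure: str  # "one_random" | "nested" | "crossed"
    variance_components: tuple[float, ...]
    level_counts: tuple[int, ...]  # (A, n) or (A, B, n)
    mu: float = 25.0
    n_sims: int = 1000
    seed: int = 0
    psi: float = 0.05
    alphas: tuple[float, ...] = (0.2,)
    name: str | None = None

    def __post_init__(self) -> None:
        if self.structure not in _N_COMPONENTS:
            raise ValueError(f"unknown structure {self.structure!r}")
        if len(self.variance_components) != _N_COMPONENTS[self.structure]:
            raise ValueError(
                f"{self.structure} takes {_N_COMPONENTS[self.structure]} components"
            )
        if any(v < 0 for v in self.variance_components):
            raise ValueError("variance components must be nonnegative")
        expected_levels = 2 if self.structure == "one_random" else 3
        if len(self.level_counts) != expected_levels:
            raise ValueError(f"{self.structure} takes {expected_levels} level counts")
        if any(c < 2 for c in self.level_counts[:-1]) or self.level_counts[-1] < 1:
            raise ValueError("factor level counts must be >= 2")

    @property
    def sigma_t2(self) -> float:
        return float(sum(self.variance_components))

    def key(self) -> int:
        tag = f"{self.structure}|{self.variance_components}|{self.level_counts}|{self.mu}"
        return zlib.crc32(tag.encode())

    def model_spec(self) -> ModelSpec:
        if self.structure == "one_random":
            return ModelSpec(response="y", random_terms=["fa"])
        if self.structure == "nested":
            return ModelSpec(response="y", random_terms=["fa", "fb(fa)"])
        return ModelSpec(response="y", random_terms=["fa*fb"])


def _rng(scenario: Scenario, replicate_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([scenario.seed, scenario.key(), replicate_index])
    )


def generate_dataset(scenario: Scenario, replicate_index: int) -> pd.DataFrame:
    """Simulate one long-format dataset, reproducible from (seed, index)."""
    rng = _rng(scenario, replicate_index)
    mu = scenario.mu
    if scenario.structure == "one_random":
        sa2, se2 = scenario.variance_components
        A, n = scenario.level_counts
        a = rng.normal(0.0, np.sqrt(sa2), A)
        rows = [
            (f"a{i:03d}", mu + a[i] + e)
            for i in range(A)
            for e in rng.normal(0.0, np.sqrt(se2), n)
        ]
        return pd.DataFrame(rows, columns=["fa", "y"])
    if scenario.structure == "nested":
        sa2, sb2, se2 = scenario.variance_components
        A, B, n = scenario.level_counts
        a = rng.normal(0.0, np.sqrt(sa2), A)
        b = rng.normal(0.0, np.sqrt(sb2), (A, B))
        rows = [
            (f"a{i:03d}", f"b{j:03d}", mu + a[i] + b[i, j] + e)
            for i in range(A)
            for j in range(B)
            for e in rng.normal(0.0, np.sqrt(se2), n)
        ]
        return pd.DataFrame(rows, columns=["fa", "fb", "y"])
    sa2, sb2, sab2, se2 = scenario.variance_components
    A, B, n = scenario.level_counts
    a = rng.normal(0.0, np.sqrt(sa2), A)
    b = rng.normal(0.0, np.sqrt(sb2), B)
    ab = rng.normal(0.0, np.sqrt(sab2), (A, B))
    rows = [
        (f"a{i:03d}", f"b{j:03d}", mu + a[i] + b[j] + ab[i, j] + e)
        for i in range(A)
        for j in range(B)
        for e in rng.normal(0.0, np.sqrt(se2), n)
    ]
    return pd.DataFrame(rows, columns=["fa", "fb", "y"])


def _frequency_se(p: float, n: int) -> float:
    return float(np.sqrt(max(p * (1.0 - p), 0.0) / n)) if n else float("nan")


@dataclass
class CoverageReport:
    scenario: Scenario
    n_used: int
    n_failed: int
    ci_coverage: float
    pi_content_mean: float
    ti_content_mean: dict[float, float]
    ti_confidence: dict[float, float]
    paradox_freq: float
    mc_se: dict[str, float] = field(default_factory=dict)
    flagged: bool = False

    def as_row(self) -> dict:
        row = {
            "scenario": self.scenario.name or self.scenario.structure,
            "structure": self.scenario.structure,
            "levels": "x".join(map(str, self.scenario.level_counts)),
            "n_sims": self.scenario.n_sims,
            "n_used": self.n_used,
            "n_failed": self.n_failed,
            "ci_coverage": self.ci_coverage,
            "pi_content_mean": self.pi_content_mean,
            "paradox_freq": self.paradox_freq,
            "flagged": self.flagged,
        }
        for a, v in self.ti_content_mean.items():
            row[f"ti_content_{int(round((1 - a) * 100))}"] = v
        for a, v in self.ti_confidence.items():
            row[f"ti_confidence_{int(round((1 - a) * 100))}"] = v
        for k, v in self.mc_se.items():
            row[f"se_{k}"] = v
        return row


def _normal_content(lower: float, upper: float, mu: float, sigma_t: float) -> float:
    from scipy.stats import norm

    return float(norm.cdf((upper - mu) / sigma_t) - norm.cdf((lower - mu) / sigma_t))


def run_scenario(scenario: Scenario, progress: bool = False) -> CoverageReport:
    """Fit every simulated replicate by REML and aggregate interval metrics.

    Replicates whose fit fails to converge are excluded and counted; a
    failure rate above 5% flags the report.
    """
    spec = scenario.model_spec()
    mu, sigma_t = scenario.mu, float(np.sqrt(scenario.sigma_t2))
    ci_hits: list[bool] = []
    pi_contents: list[float] = []
    ti_contents: dict[float, list[float]] = {a: [] for a in scenario.alphas}
    paradoxes: list[bool] = []
    n_failed = 0
    for j in range(scenario.n_sims):
        data = generate_dataset(scenario, j)
        try:
            design = build_design(data, spec)
            fit = fit_reml(design, data["y"].to_numpy())
            ci = confidence_interval(fit, "(Intercept)", alpha=0.05)
            pi = prediction_interval(fit, "(Intercept)", psi=scenario.psi)
            tis = {
                a: tolerance_interval(fit, "(Intercept)", psi=scenario.psi, alpha=a)
                for a in scenario.alphas
            }
        except (RemlError, ValueError):
            n_failed += 1
            continue
        ci_hits.append(ci.lower <= mu <= ci.upper)
        pi_contents.append(_normal_content(pi.lower, pi.upper, mu, sigma_t))
        for a, ti in tis.items():
            ti_contents[a].append(_normal_content(ti.lower, ti.upper, mu, sigma_t))
        paradoxes.append(detect_paradox(ci, pi))
    n_used = len(ci_hits)
    if n_used == 0:
        raise RuntimeError("all replicates failed to fit")
    level = 1.0 - scenario.psi
    ci_cov = float(np.mean(ci_hits))
    pi_mean = float(np.mean(pi_contents))
    ti_mean = {a: float(np.mean(v)) for a, v in ti_contents.items()}
    ti_conf = {a: float(np.mean(np.asarray(v) >= level)) for a, v in ti_contents.items()}
    par = float(np.mean(paradoxes))
    mc_se = {
        "ci_coverage": _frequency_se(ci_cov, n_used),
        "pi_content_mean": float(np.std(pi_contents, ddof=1) / np.sqrt(n_used)),
        "paradox_freq": _frequency_se(par, n_used),
    }
    for a in scenario.alphas:
        tag = int(round((1 - a) * 100))
        mc_se[f"ti_content_{tag}"] = float(
            np.std(ti_contents[a], ddof=1) / np.sqrt(n_used)
        )
        mc_se[f"ti_confidence_{tag}"] = _frequency_se(ti_conf[a], n_used)
    return CoverageReport(
        scenario=scenario,
        n_used=n_used,
        n_failed=n_failed,
        ci_coverage=ci_cov,
        pi_content_mean=pi_mean,
        ti_content_mean=ti_mean,
        ti_confidence=ti_conf,
        paradox_freq=par,
        mc_se=mc_se,
        flagged=n_failed > 0.05 * scenario.n_sims,
    )


def paradox_frequency(report: CoverageReport) -> float:
    """Fraction of replicates whose CI came out wider than the PI."""
    return report.paradox_freq
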