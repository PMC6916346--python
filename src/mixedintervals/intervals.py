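"""Confidence, prediction and tolerance intervals.

Univariate forms
    CI:  xbar +/- t_{1-a/2, n-1} s / sqrt(n)
    PI:  xbar +/- t_{1-p/2, n-1} s sqrt(1 + 1/n)
    TI:  xbar +/- z_{1-p/2} s sqrt((1 + 1/n)(n-1)/chi2_{a, n-1})

Mixed-model forms, for an estimable cell combination l:
    CI:  l bhat +/- t_{1-a/2, k} sqrt(l C11 l')
    PI:  l bhat +/- t_{1-p/2, r} sqrt(l C11 l' + sigma_T^2)
    TI:  l bhat +/- z_{1-p/2} sqrt(l C11 l' + U)
where sigma_T^2 is the sum of the variance components (the variance of a
single future observation around its cell mean), U is the Graybill-Wang
(MLS) upper confidence bound on sigma_T^2 built from expected mean
squares, and the degrees of freedom come from the generalized
Satterthwaite rule df = 2 Variance^2 / Var(Variance): applied to
sigma_T^2 (with Var(sigma_T^2) = sum of all entries of the inverse
observed Fisher information) for the PI, and to l C11 l' (delta method
through theta) for the CI.  The t distribution is evaluated at
fractional degrees of freedom directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import ConfigurationError, DesignMatrices
from .ems import EMSDecomposition, decomposition_for_fit
from .reml import FittedModel, _profile_pieces

__all__ = [
    "IntervalResult",
    "TotalVariance",
    "univariate_ci",
    "univariate_pi",
    "univariate_ti",
    "satterthwaite_df",
    "total_variance",
    "satterthwaite_df_fixed",
    "confidence_interval",
    "conditional_interval",
    "prediction_interval",
    "tolerance_interval",
    "ci_from_summary",
    "pi_from_summary",
    "ti_from_summary",
    "detect_paradox",
]


@dataclass
class IntervalResult:
    estimate: float
    lower: float
    upper: float
    kind: str  # "CI" | "PI" | "TI"
    prediction_level: float | None = None  # 1 - psi
    confidence_level: float | None = None  # 1 - alpha
    df: float | None = None  # TI uses z, so None there
    variance_used: float = 0.0
    warnings: list[str] = field(default_factory=list)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "estimate": self.estimate,
            "lower": self.lower,
            "upper": self.upper,
            "prediction_level": self.prediction_level,
            "confidence_level": self.confidence_level,
            "df": self.df,
            "variance_used": self.variance_used,
            "warnings": list(self.warnings),
        }


@dataclass
class TotalVariance:
    """sigma_T^2, its estimated variance, and the implied df (2 v^2 / Var v)."""

    sigmaT2: float
    var_sigmaT2: float
    df_r: float
    group: str | None = None


def satterthwaite_df(variance: float, var_of_variance: float) -> float:
    """Generalized Satterthwaite rule: df = 2 Variance^2 / Var(Variance)."""
    if variance <= 0 or var_of_variance <= 0:
        raise ValueError("variance and its variance must be positive")
    return 2.0 * variance**2 / var_of_variance


# ---------------------------------------------------------------------------
# univariate intervals
# ---------------------------------------------------------------------------


def _check_levels(**levels: float) -> None:
    for name, v in levels.items():
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {v}")


def univariate_ci(mean: float, sd: float, n: int, alpha: float = 0.05) -> IntervalResult:
    _check_levels(alpha=alpha)
    if n < 2:
        raise ValueError("need n >= 2 observations")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    half = stats.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n)
    return IntervalResult(
        mean, mean - half, mean + half, "CI",
        confidence_level=1 - alpha, df=float(n - 1), variance_used=sd**2 / n,
    )


def univariate_pi(mean: float, sd: float, n: int, psi: float = 0.05) -> IntervalResult:
    _check_levels(psi=psi)
    if n < 2:
        raise ValueError("need n >= 2 observations")
    half = stats.t.ppf(1 - psi / 2, n - 1) * sd * np.sqrt(1.0 + 1.0 / n)
    return IntervalResult(
        mean, mean - half, mean + half, "PI",
        prediction_level=1 - psi, df=float(n - 1),
        variance_used=sd**2 * (1.0 + 1.0 / n),
    )


def univariate_ti(
    mean: float, sd: float, n: int, psi: float = 0.05, alpha: float = 0.10
) -> IntervalResult:
    _check_levels(psi=psi, alpha=alpha)
    if n < 2:
        raise ValueError("need n >= 2 observations")
    infl = (1.0 + 1.0 / n) * (n - 1) / stats.chi2.ppf(alpha, n - 1)
    half = stats.norm.ppf(1 - psi / 2) * sd * np.sqrt(infl)
    return IntervalResult(
        mean, mean - half, mean + half, "TI",
        prediction_level=1 - psi, confidence_level=1 - alpha,
        variance_used=sd**2 * infl,
    )


# ---------------------------------------------------------------------------
# mixed-model machinery
# ---------------------------------------------------------------------------


def _component_indices(design: DesignMatrices, group: str | None) -> np.ndarray:
    """Theta indices in scope for one variance group (all, if homogeneous)."""
    comp_groups = design.component_groups()
    if design.het_group is None:
        return np.arange(design.q)
    if group is None:
        raise ConfigurationError(
            "heterogeneous-variance fit: a variance group is required"
        )
    if group not in design.group_levels:
        raise ConfigurationError(f"unknown variance group {group!r}")
    idx = [i for i, g in enumerate(comp_groups) if g in (group, None)]
    return np.asarray(idx)


def infer_group(fit: FittedModel, l: np.ndarray) -> str | None:
    """Variance group implied by the cells l touches (None if homogeneous)."""
    design = fit.design
    if design.het_group is None:
        return None
    touched = {
        design.cell_groups[i]
        for i in np.flatnonzero(np.asarray(l, dtype=float))
        if i < len(design.cell_groups)
    }
    touched.discard(None)
    if len(touched) == 1:
        return touched.pop()
    raise ConfigurationError(
        "cannot infer the variance group from l; pass group= explicitly"
    )


def total_variance(fit: FittedModel, group: str | None = None) -> TotalVariance:
    """sigma_T^2 = sum of theta-hat (within the variance group) and its
    variance = sum of the corresponding block of Var(theta-hat)."""
    idx = _component_indices(fit.design, group)
    sigma = float(np.sum(fit.theta_hat[idx]))
    var = float(np.sum(fit.vartheta[np.ix_(idx, idx)]))
    if var <= 0:
        raise ValueError(
            "Var(sigma_T^2) <= 0 (degenerate information matrix); "
            "intervals cannot be formed"
        )
    return TotalVariance(sigma, var, satterthwaite_df(sigma, var), group)


def _l_vector(fit: FittedModel, l) -> np.ndarray:
    if isinstance(l, str):
        try:
            i = fit.design.cell_labels.index(l)
        except ValueError:
            raise ConfigurationError(f"unknown cell {l!r}") from None
        vec = np.zeros(fit.design.p)
        vec[i] = 1.0
        return vec
    vec = np.asarray(l, dtype=float)
    if vec.shape != (fit.design.p,):
        raise ConfigurationError(
            f"l has length {vec.size}, expected {fit.design.p} cells"
        )
    return vec


def _c11_at(theta: np.ndarray, design: DesignMatrices, y: np.ndarray) -> np.ndarray:
    *_, XtVX, _, _, _, _, _ = _profile_pieces(theta, design, y)
    return np.linalg.inv(XtVX)


def _delta_method_df(fit: FittedModel, func, value: float) -> float:
    """df for a variance that is a smooth function of theta, by the delta
    method: grad' vartheta grad with a central-difference gradient."""
    theta = fit.theta_hat
    scale = max(float(np.sum(theta)), 1e-8)
    grad = np.zeros(fit.design.q)
    for i in range(fit.design.q):
        h = max(1e-5 * theta[i], 1e-9 * max(scale, 1.0))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] = max(tm[i] - h, 0.0)
        grad[i] = (func(tp) - func(tm)) / (tp[i] - tm[i])
    var = float(grad @ fit.vartheta @ grad)
    if var <= 0:
        raise ValueError("variance of l C11 l' is not positive; df undefined")
    if np.allclose(grad, 0.0):
        raise ValueError("l C11 l' does not depend on theta; df undefined")
    return satterthwaite_df(value, var)


def satterthwaite_df_fixed(fit: FittedModel, l) -> float:
    """Generalized Satterthwaite df for the fixed-effect variance l C11 l'.

    Var(l C11 l') comes from the delta method through theta (gradient of
    l C11(theta) l' at theta-hat, sandwiched with Var(theta-hat)).  For a
    balanced one-way intercept this returns A - 1: the intercept variance
    is EMS_A / (A n), a multiple of a single mean square.
    """
    lv = _l_vector(fit, l)
    value = float(lv @ fit.C11 @ lv)
    return _delta_method_df(
        fit, lambda th: float(lv @ _c11_at(th, fit.design, fit.y) @ lv), value
    )


def confidence_interval(fit: FittedModel, l, alpha: float = 0.05) -> IntervalResult:
    """t-based CI for the cell combination l, df by generalized Satterthwaite."""
    _check_levels(alpha=alpha)
    lv = _l_vector(fit, l)
    est = float(lv @ fit.beta_hat)
    var = float(lv @ fit.C11 @ lv)
    df = satterthwaite_df_fixed(fit, lv)
    half = stats.t.ppf(1 - alpha / 2, df) * np.sqrt(var)
    res = IntervalResult(
        est, est - half, est + half, "CI",
        confidence_level=1 - alpha, df=df, variance_used=var,
    )
    res.warnings.extend(fit.vartheta_flags)
    return res


def conditional_interval(fit: FittedModel, l_nu, alpha: float = 0.05) -> IntervalResult:
    """Interval for a combination of fixed effects and EBLUPs, using the
    joint covariance C of (beta-hat, gamma-hat).

    EBLUP-conditional intervals are a descriptive device: predictions
    conditional on realized random levels are better handled by refitting
    with those levels as fixed effects; a warning records this caveat.
    """
    _check_levels(alpha=alpha)
    lv = np.asarray(l_nu, dtype=float)
    p, g = fit.design.p, fit.gamma_hat.size
    if lv.shape != (p + g,):
        raise ConfigurationError(f"l_nu has length {lv.size}, expected {p + g}")
    lb, lg = lv[:p], lv[p:]
    if not lg.any():
        return confidence_interval(fit, lb, alpha)
    est = float(lb @ fit.beta_hat + lg @ fit.gamma_hat)
    C = np.block([[fit.C11, fit.C21.T], [fit.C21, fit.C22]])
    var = float(lv @ C @ lv)
    tv = total_variance(fit) if fit.design.het_group is None else None
    df = tv.df_r if tv is not None else fit.design.n - fit.design.p
    half = stats.t.ppf(1 - alpha / 2, df) * np.sqrt(max(var, 0.0))
    res = IntervalResult(
        est, est - half, est + half, "CI",
        confidence_level=1 - alpha, df=df, variance_used=var,
    )
    res.warnings.append(
        "conditional on EBLUPs; treat realized random levels as fixed "
        "effects for formal conditional inference"
    )
    return res


def prediction_interval(
    fit: FittedModel, l, psi: float = 0.05, group: str | None = None
) -> IntervalResult:
    """PI for one future observation at the cell combination l.

    Variance = l C11 l' + sigma_T^2; df from the total variance via the
    generalized Satterthwaite rule.
    """
    _check_levels(psi=psi)
    lv = _l_vector(fit, l)
    if group is None and fit.design.het_group is not None:
        group = infer_group(fit, lv)
    tv = total_variance(fit, group)
    est = float(lv @ fit.beta_hat)
    var = float(lv @ fit.C11 @ lv) + tv.sigmaT2
    half = stats.t.ppf(1 - psi / 2, tv.df_r) * np.sqrt(var)
    res = IntervalResult(
        est, est - half, est + half, "PI",
        prediction_level=1 - psi, df=tv.df_r, variance_used=var,
    )
    res.warnings.extend(fit.vartheta_flags)
    return res


def tolerance_interval(
    fit: FittedModel,
    l,
    psi: float = 0.05,
    alpha: float = 0.10,
    decomp: EMSDecomposition | None = None,
    group: str | None = None,
) -> IntervalResult:
    """Two-sided beta-content TI via the MLS (Graybill-Wang) bound.

    The total variance inside the z-based PI formula is replaced by its
    MLS upper confidence bound built on the EMS decomposition; the
    fixed-effect variance l C11 l' is retained additively but does not
    enter the MLS inflation.
    """
    _check_levels(psi=psi, alpha=alpha)
    lv = _l_vector(fit, l)
    if group is None and fit.design.het_group is not None:
        group = infer_group(fit, lv)
    tv = total_variance(fit, group)
    if decomp is None:
        decomp = decomposition_for_fit(fit, alpha=alpha, group=group)
    elif abs(decomp.alpha - alpha) > 1e-12:
        decomp = decomp.with_alpha(alpha)
    decomp.check_identity(tv.sigmaT2, rtol=1e-6)
    est = float(lv @ fit.beta_hat)
    fixed_var = float(lv @ fit.C11 @ lv)
    var = fixed_var + decomp.mls_upper()
    half = stats.norm.ppf(1 - psi / 2) * np.sqrt(var)
    res = IntervalResult(
        est, est - half, est + half, "TI",
        prediction_level=1 - psi, confidence_level=1 - alpha, variance_used=var,
    )
    res.warnings.extend(fit.vartheta_flags)
    return res


def detect_paradox(ci: IntervalResult, pi: IntervalResult) -> bool:
    """True when the CI is wider than the PI.

    This can legitimately happen when a random factor has very few levels:
    the prediction gains degrees of freedom (smaller t quantile) faster
    than it gains variance.  The condition is reported, never 'fixed'.
    """
    return ci.width > pi.width


# ---------------------------------------------------------------------------
# summary-input mode: intervals from printed/reported model output
# ---------------------------------------------------------------------------


def ci_from_summary(estimate: float, se: float, df: float, alpha: float = 0.05) -> IntervalResult:
    """CI from a reported cell estimate, its SE and fixed-effect df."""
    _check_levels(alpha=alpha)
    half = stats.t.ppf(1 - alpha / 2, df) * se
    return IntervalResult(
        estimate, estimate - half, estimate + half, "CI",
        confidence_level=1 - alpha, df=float(df), variance_used=se**2,
    )


def pi_from_summary(
    estimate: float,
    se: float,
    sigma_t2: float,
    var_sigma_t2: float,
    psi: float = 0.05,
) -> IntervalResult:
    """PI from reported estimate, SE, total variance and Var(total variance)."""
    _check_levels(psi=psi)
    df = satterthwaite_df(sigma_t2, var_sigma_t2)
    var = se**2 + sigma_t2
    half = stats.t.ppf(1 - psi / 2, df) * np.sqrt(var)
    return IntervalResult(
        estimate, estimate - half, estimate + half, "PI",
        prediction_level=1 - psi, df=df, variance_used=var,
    )


def ti_from_summary(
    estimate: float,
    se: float,
    decomp: EMSDecomposition,
    psi: float = 0.05,
    alpha: float | None = None,
) -> IntervalResult:
    """MLS TI from a reported estimate, SE and an EMS decomposition."""
    if alpha is not None and abs(decomp.alpha - alpha) > 1e-12:
        decomp = decomp.with_alpha(alpha)
    _check_levels(psi=psi, alpha=decomp.alpha)
    var = se**2 + decomp.mls_upper()
    half = stats.norm.ppf(1 - psi / 2) * np.sqrt(var)
    return IntervalResult(
        estimate, estimate - half, estimate + half, "TI",
        prediction_level=1 - psi, confidence_level=1 - decomp.alpha,
        variance_used=var,
    )
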