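"""REML estimation of variance-component mixed models.

The model is Y = X beta + Z gamma + eps with Var(Y) = V(theta)
= sum_k theta_k Z_k Z_k' + residual variance(s) on the diagonal.  Fixed
effects are profiled out of the likelihood; theta is estimated on the
variance scale under box constraints theta >= 0 (a negative component is
bounded to zero and flagged).  The covariance matrix of theta-hat is the
inverse observed Fisher information, i.e. the inverse of the negative
Hessian of the restricted log-likelihood, obtained by central finite
differences (one-sided at the zero boundary) with one Richardson
extrapolation step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .design import DesignMatrices

logger = logging.getLogger(__name__)

__all__ = [
    "RemlError",
    "FittedModel",
    "restricted_loglik",
    "restricted_loglik_grad",
    "fit_reml",
    "observed_information",
]

_LOG2PI = float(np.log(2.0 * np.pi))


class RemlError(RuntimeError):
    """REML fitting or likelihood-evaluation failure."""


def _build_V(theta: np.ndarray, design: DesignMatrices) -> np.ndarray:
    n = design.n
    nz = len(design.Z_blocks)
    V = np.zeros((n, n))
    for k, block in enumerate(design.Z_blocks):
        if theta[k] != 0.0:
            V += theta[k] * (block.matrix @ block.matrix.T)
    diag = np.zeros(n)
    for r, mask in enumerate(design.residual_masks):
        diag[mask] += theta[nz + r]
    V[np.diag_indices(n)] += diag
    return V


def _check_theta(theta: np.ndarray, design: DesignMatrices) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (design.q,):
        raise RemlError(
            f"theta has length {theta.size}, design expects {design.q} components"
        )
    if not np.all(np.isfinite(theta)) or np.any(theta < 0):
        raise RemlError("theta must be finite and nonnegative")
    return theta


def _profile_pieces(theta: np.ndarray, design: DesignMatrices, y: np.ndarray):
    """Cholesky-based quantities shared by the loglik and its gradient."""
    V = _build_V(theta, design)
    try:
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:  # singular V (all components zero, ...)
        raise RemlError("V is singular at the supplied theta") from exc
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    X = design.X
    Vinv_X = linalg.cho_solve(cf, X, check_finite=False)
    Vinv_y = linalg.cho_solve(cf, y, check_finite=False)
    XtVX = X.T @ Vinv_X
    sign, logdet_XtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise RemlError("X'V^-1 X is not positive definite (aliased cells?)")
    beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta  # P y
    yPy = float(y @ Py)
    return cf, V, Vinv_X, Vinv_y, XtVX, beta, Py, logdet_V, logdet_XtVX, yPy


def restricted_loglik(theta: np.ndarray, design: DesignMatrices, y: np.ndarray) -> float:
    """Restricted log-likelihood of theta, fixed effects profiled out.

    Invariant to observation reordering and to adding a constant to ``y``
    (any constant lies in the column space of the cell-means ``X``).
    """
    theta = _check_theta(theta, design)
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n,):
        raise RemlError("response length does not match the design")
    *_, logdet_V, logdet_XtVX, yPy = _profile_pieces(theta, design, y)
    n, p = design.n, design.p
    return -0.5 * (logdet_V + logdet_XtVX + yPy + (n - p) * _LOG2PI)


def restricted_loglik_grad(
    theta: np.ndarray, design: DesignMatrices, y: np.ndarray
) -> np.ndarray:
    """Analytic score: dl/dtheta_k = -1/2 (tr(P V_k) - y'P V_k P y)."""
    theta = _check_theta(theta, design)
    cf, V, Vinv_X, _, XtVX, _, Py, *_ = _profile_pieces(theta, design, y)
    n = design.n
    Vinv = linalg.cho_solve(cf, np.eye(n), check_finite=False)
    W = np.linalg.solve(XtVX, Vinv_X.T)
    P = Vinv - Vinv_X @ W  # P = Vinv - Vinv X (X'Vinv X)^-1 X'Vinv
    nz = len(design.Z_blocks)
    grad = np.empty(design.q)
    for k, block in enumerate(design.Z_blocks):
        Z = block.matrix
        PZ = P @ Z
        tr = float(np.sum(PZ * Z))  # tr(P Z Z')
        quad = float(np.sum((Py @ Z) ** 2))  # y'P ZZ' P y
        grad[k] = -0.5 * (tr - quad)
    for r, mask in enumerate(design.residual_masks):
        tr = float(np.sum(np.diag(P)[mask]))
        quad = float(np.sum(Py[mask] ** 2))
        grad[nz + r] = -0.5 * (tr - quad)
    return grad


@dataclass
class FittedModel:
    """REML fit: estimates, covariance blocks, and convergence record."""

    design: DesignMatrices
    y: np.ndarray
    beta_hat: np.ndarray
    gamma_hat: np.ndarray
    theta_hat: np.ndarray
    C11: np.ndarray
    C21: np.ndarray
    C22: np.ndarray
    vartheta: np.ndarray
    reml_loglik: float
    n_iter: int
    grad_norm: float
    boundary: np.ndarray  # bool flag per component
    vartheta_flags: list[str] = field(default_factory=list)

    @property
    def theta_layout(self) -> list[str]:
        return self.design.theta_layout

    @property
    def theta_se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vartheta), 0.0, None))

    def report(self) -> dict:
        """Structured fit summary (JSON-serializable)."""
        return {
            "theta": dict(zip(self.theta_layout, self.theta_hat.tolist())),
            "theta_se": dict(zip(self.theta_layout, self.theta_se.tolist())),
            "beta": dict(zip(self.design.cell_labels, self.beta_hat.tolist())),
            "reml_loglik": self.reml_loglik,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "boundary": dict(
                zip(self.theta_layout, [bool(b) for b in self.boundary])
            ),
            "vartheta_flags": list(self.vartheta_flags),
        }


def _starting_values(design: DesignMatrices, y: np.ndarray) -> np.ndarray:
    """ANOVA-flavoured start: residual OLS variance split over components."""
    X = design.X
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    s2 = float(resid @ resid) / max(len(y) - design.p, 1)
    s2 = max(s2, 1e-8)
    return np.full(design.q, s2 / design.q)


def _polish_newton(
    theta: np.ndarray,
    design: DesignMatrices,
    y: np.ndarray,
    gtol: float,
    max_iter: int = 30,
) -> tuple[np.ndarray, float, int]:
    """Projected-Newton refinement using the analytic score and an FD Hessian."""
    scale = max(float(np.sum(theta)), 1e-12)
    it = 0
    ll = restricted_loglik(theta, design, y)
    for it in range(1, max_iter + 1):
        g = restricted_loglik_grad(theta, design, y)
        free = (theta > 1e-10 * scale) | (g > 0)
        gn = float(np.linalg.norm(g[free])) if free.any() else 0.0
        if gn < gtol:
            break
        H = _fd_hessian(theta, design, y, free=free)
        try:
            step = np.zeros_like(theta)
            step[free] = np.linalg.solve(-H[np.ix_(free, free)], g[free])
        except np.linalg.LinAlgError:
            break
        # backtracking line search with projection onto theta >= 0
        t = 1.0
        improved = False
        for _ in range(25):
            cand = np.clip(theta + t * step, 0.0, None)
            try:
                ll_new = restricted_loglik(cand, design, y)
            except RemlError:
                t *= 0.5
                continue
            if ll_new >= ll - 1e-12 * abs(ll):
                theta, ll = cand, ll_new
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    g = restricted_loglik_grad(theta, design, y)
    free = (theta > 1e-10 * scale) | (g > 0)
    gn = float(np.linalg.norm(g[free])) if free.any() else 0.0
    return theta, gn, it


def fit_reml(
    design: DesignMatrices,
    y: np.ndarray,
    *,
    max_iter: int = 200,
    loglik_tol: float = 1e-10,
    grad_tol: float = 1e-6,
    compute_vartheta: bool = True,
) -> FittedModel:
    """Maximize the restricted log-likelihood under theta >= 0.

    Optimization runs on the variance scale (the covariance of theta-hat is
    needed on that scale), L-BFGS-B with the analytic score, followed by a
    projected-Newton polish; a restart from ANOVA-type values is attempted
    if the first pass fails.  Components estimated at the zero boundary are
    flagged.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n,):
        raise RemlError("response length does not match the design")
    if design.n <= design.p:
        raise RemlError("need more observations than fixed-effect cells")
    for block in design.Z_blocks:
        if block.matrix.shape[1] < 2:
            raise RemlError(f"random component {block.label!r} has fewer than 2 levels")

    # scale equivariance: work on y with unit-ish variance, scale theta back
    s = float(np.var(y))
    s = s if s > 0 else 1.0
    ys = y / np.sqrt(s)

    def negll(th):
        try:
            return -restricted_loglik(th, design, ys)
        except RemlError:
            return np.inf

    def neggrad(th):
        try:
            return -restricted_loglik_grad(th, design, ys)
        except RemlError:
            return np.zeros_like(th)

    theta0 = _starting_values(design, ys)
    best = None
    starts = [theta0, np.full(design.q, float(np.var(ys)) / design.q + 1e-6)]
    n_iter_total = 0
    # keep the residual variance(s) strictly positive during line searches:
    # V is singular whenever every residual component hits zero
    nz = len(design.Z_blocks)
    bounds = [(0.0, None)] * nz + [(1e-10, None)] * len(design.residual_labels)
    for start in starts:
        res = optimize.minimize(
            negll,
            np.clip(start, 1e-10, None),
            jac=neggrad,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": loglik_tol, "gtol": 1e-8},
        )
        n_iter_total += int(res.nit)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
        if best is not None and np.isfinite(best.fun):
            break
    if best is None or not np.isfinite(best.fun):
        raise RemlError("REML optimization failed to produce a finite log-likelihood")

    theta_s, gn, polish_iters = _polish_newton(best.x, design, ys, grad_tol)
    n_iter_total += polish_iters
    if gn >= max(grad_tol, 1e-4):
        raise RemlError(
            f"REML did not converge: projected gradient norm {gn:.3g} "
            f"after {n_iter_total} iterations (last theta={theta_s * s})"
        )

    bound_tol = 1e-9 * max(float(np.sum(theta_s)), 1e-12)
    boundary = theta_s <= bound_tol
    theta_s = np.where(boundary, 0.0, theta_s)
    theta_hat = theta_s * s

    beta, gamma, C11, C21, C22 = _coefficient_covariances(theta_hat, design, y)
    ll = restricted_loglik(theta_hat, design, y)

    fit = FittedModel(
        design=design,
        y=y,
        beta_hat=beta,
        gamma_hat=gamma,
        theta_hat=theta_hat,
        C11=C11,
        C21=C21,
        C22=C22,
        vartheta=np.full((design.q, design.q), np.nan),
        reml_loglik=ll,
        n_iter=n_iter_total,
        grad_norm=gn,
        boundary=boundary,
    )
    if compute_vartheta:
        fit.vartheta = observed_information(fit, design, y)
    return fit


def _coefficient_covariances(theta, design, y):
    """beta-hat, EBLUPs, and the C blocks evaluated at theta."""
    cf, V, Vinv_X, Vinv_y, XtVX, beta, Py, *_ = _profile_pieces(theta, design, y)
    C11 = np.linalg.inv(XtVX)
    nz = len(design.Z_blocks)
    if nz == 0:
        return beta, np.zeros(0), C11, np.zeros((0, design.p)), np.zeros((0, 0))
    Z = design.Z_full()
    g_sizes = [b.matrix.shape[1] for b in design.Z_blocks]
    g_diag = np.concatenate(
        [np.full(sz, theta[k]) for k, sz in enumerate(g_sizes)]
    )
    # gamma = G Z' V^-1 (y - X beta) = G Z' P y
    gamma = g_diag * (Z.T @ Py)
    # C21 = -G Z' Vinv X C11
    GZtVinvX = g_diag[:, None] * (Z.T @ Vinv_X)
    C21 = -GZtVinvX @ C11
    # C22 = (Z'R^-1 Z + G^-1)^-1 - C21 X'Vinv Z G  (zero-variance columns excluded)
    active = g_diag > 0
    C22 = np.zeros((Z.shape[1], Z.shape[1]))
    if active.any():
        Za = Z[:, active]
        rinv = np.zeros(design.n)
        for r, mask in enumerate(design.residual_masks):
            rinv[mask] = 1.0 / theta[nz + r]
        M = (Za * rinv[:, None]).T @ Za + np.diag(1.0 / g_diag[active])
        Minv = np.linalg.inv(M)
        XtVinvZ_G = (Vinv_X.T @ Za) * g_diag[active][None, :]
        C22a = Minv - C21[active] @ XtVinvZ_G
        C22[np.ix_(active, active)] = C22a
    return beta, gamma, C11, C21, C22


def _fd_hessian(
    theta: np.ndarray,
    design: DesignMatrices,
    y: np.ndarray,
    *,
    free: np.ndarray | None = None,
    rel_step: float = 1e-4,
    richardson: bool = False,
) -> np.ndarray:
    """Finite-difference Hessian of the restricted log-likelihood.

    Central differences with relative step max(rel_step*theta_i, 1e-8);
    one-sided (forward) differences for components pinned at zero.  With
    ``richardson`` the central estimate is extrapolated once (steps h and
    h/2) for O(h^4) truncation error.
    """
    q = theta.size
    if free is None:
        free = np.ones(q, dtype=bool)
    scale = max(float(np.sum(theta)), 1e-8)
    h = np.maximum(rel_step * theta, 1e-8 * max(scale, 1.0))
    one_sided = theta <= 1e-12 * scale

    def f(th):
        return restricted_loglik(th, design, y)

    def grad_fd(th):
        # gradient via analytic score keeps the Hessian differencing to
        # first differences of the score (cheaper and more accurate)
        return restricted_loglik_grad(th, design, y)

    def hess_at(step):
        H = np.zeros((q, q))
        for i in range(q):
            if not free[i]:
                continue
            hi = step[i]
            if one_sided[i]:
                g0 = grad_fd(theta)
                tp = theta.copy()
                tp[i] += hi
                H[i] = (grad_fd(tp) - g0) / hi
            else:
                tp = theta.copy()
                tm = theta.copy()
                tp[i] += hi
                tm[i] = max(tm[i] - hi, 0.0)
                H[i] = (grad_fd(tp) - grad_fd(tm)) / (tp[i] - tm[i])
        return H

    H = hess_at(h)
    if richardson and not one_sided.any():
        H2 = hess_at(h / 2.0)
        H = (4.0 * H2 - H) / 3.0
    return 0.5 * (H + H.T)


def observed_information(
    fit: FittedModel, design: DesignMatrices | None = None, y: np.ndarray | None = None
) -> np.ndarray:
    """Covariance of theta-hat: inverse of the negative REML Hessian.

    The Hessian is differenced on the variance scale at theta-hat
    (Richardson-extrapolated central differences; one-sided at the zero
    boundary).  A singular negative Hessian (boundary estimates) falls back
    to the Moore-Penrose pseudo-inverse with a warning flag that consumers
    must check (``fit.vartheta_flags``).
    """
    design = design if design is not None else fit.design
    y = y if y is not None else fit.y
    theta = fit.theta_hat
    H = _fd_hessian(theta, design, y, richardson=True)
    info = -H
    if fit.boundary.any():
        fit.vartheta_flags.append("boundary")
    q = theta.size
    try:
        cf = linalg.cho_factor(info)
        vartheta = linalg.cho_solve(cf, np.eye(q))
        return 0.5 * (vartheta + vartheta.T)
    except linalg.LinAlgError:
        pass
    # indefinite at the boundary: profile the pinned components out (their
    # one-sided curvature rows are unreliable) and invert the interior block
    free = ~fit.boundary
    if free.any() and not free.all():
        try:
            sub = linalg.cho_solve(
                linalg.cho_factor(info[np.ix_(free, free)]), np.eye(int(free.sum()))
            )
            vartheta = np.zeros((q, q))
            vartheta[np.ix_(free, free)] = sub
            if "boundary-profiled" not in fit.vartheta_flags:
                fit.vartheta_flags.append("boundary-profiled")
            return 0.5 * (vartheta + vartheta.T)
        except linalg.LinAlgError:
            pass
    warnings.warn(
        "observed information is singular (boundary estimate?); "
        "using a pseudo-inverse for Var(theta-hat)",
        RuntimeWarning,
        stacklevel=2,
    )
    fit.vartheta_flags.append("pseudo-inverse")
    vartheta = np.linalg.pinv(info)
    return 0.5 * (vartheta + vartheta.T)
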