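"""Expected-mean-square decompositions of the total variance.

The modified-large-sample (MLS, Graybill-Wang) tolerance bound needs the
total variance written as sigma_T^2 = sum_j k_j * EMS_j, together with the
ANOVA degrees of freedom r_j of each mean square and the chi-square
inflation factors H_j = r_j / chi2(alpha, r_j) - 1.  Closed forms are
provided for balanced one-way, two nested and two crossed random factors
and for the unbalanced one-way design; other unbalanced designs go
through quadratic-form synthesis of the EMS coefficients.

For crossed terms the synthesis uses Type-III quadratic forms (contrasts
of unweighted marginal cell means): in a two-factor crossed layout with
all cells filled these give EMS rows of the familiar balanced pattern
sigma_e^2 + c*sigma_ab^2 + c*B*sigma_a^2 with a design-specific constant
c, and they reduce to the balanced closed forms for equal cell counts.
Nested and one-way terms use sequential (fitting-order) projections,
which coincide with the closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .design import DesignMatrices, ConfigurationError

__all__ = [
    "EMSTerm",
    "EMSDecomposition",
    "balanced_one_way",
    "balanced_nested",
    "balanced_crossed",
    "unbalanced_one_way",
    "synthesis_coefficients",
    "decomposition_for_fit",
]


def _H(alpha: float, r: float) -> float:
    """MLS inflation factor r / chi2_{alpha, r} - 1 (positive for alpha < 0.5)."""
    return float(r / stats.chi2.ppf(alpha, r) - 1.0)


@dataclass
class EMSTerm:
    label: str
    k: float  # coefficient of this EMS in sigma_T^2
    ems_value: float | None  # response^2; None until evaluated
    r: float  # ANOVA degrees of freedom
    H: float  # MLS inflation factor at the decomposition's alpha
    coeffs: dict[str, float] = field(default_factory=dict)  # EMS in components


@dataclass
class EMSDecomposition:
    """sigma_T^2 = sum_j k_j EMS_j with ANOVA df and MLS factors."""

    terms: list[EMSTerm]
    alpha: float

    @property
    def sigma_t2(self) -> float:
        return float(sum(t.k * t.ems_value for t in self.terms))

    def mls_margin(self) -> float:
        """sqrt(sum_j H_j^2 k_j^2 EMS_j^2): the MLS upper-bound excess."""
        return float(
            np.sqrt(sum((t.H * t.k * t.ems_value) ** 2 for t in self.terms))
        )

    def mls_upper(self) -> float:
        """Graybill-Wang upper confidence bound on sigma_T^2."""
        return self.sigma_t2 + self.mls_margin()

    def check_identity(self, sigma_t2: float, rtol: float = 1e-6) -> None:
        own = self.sigma_t2
        if abs(own - sigma_t2) > rtol * max(abs(sigma_t2), 1e-12):
            raise ValueError(
                f"EMS decomposition reproduces sigma_T^2={own:.6g}, "
                f"fit says {sigma_t2:.6g}"
            )

    def component_coefficient_sums(self) -> dict[str, float]:
        """Implied coefficient of each variance component across sum_j k_j EMS_j
        (each must equal 1 for a valid decomposition)."""
        out: dict[str, float] = {}
        for t in self.terms:
            for comp, c in t.coeffs.items():
                out[comp] = out.get(comp, 0.0) + t.k * c
        return out

    def with_alpha(self, alpha: float) -> "EMSDecomposition":
        terms = [replace(t, H=_H(alpha, t.r)) for t in self.terms]
        return EMSDecomposition(terms=terms, alpha=alpha)


def _mk(label, k, value, r, alpha, coeffs):
    return EMSTerm(label, float(k), value, float(r), _H(alpha, r), coeffs)


def balanced_one_way(
    sigma_a2: float,
    sigma_e2: float,
    A: int,
    n: int,
    alpha: float = 0.10,
    residual_df: float | None = None,
) -> EMSDecomposition:
    """EMS_A = sigma_e^2 + n sigma_a^2 (df A-1), EMS_E = sigma_e^2
    (df A(n-1) unless overridden); k = (1/n, 1-1/n)."""
    if A < 2 or n < 1:
        raise ValueError("need A >= 2 groups and n >= 1 replicates")
    ems_a = sigma_e2 + n * sigma_a2
    terms = [
        _mk("A", 1.0 / n, ems_a, A - 1, alpha, {"a": float(n), "e": 1.0}),
    ]
    if n > 1:
        r_e = residual_df if residual_df is not None else A * (n - 1)
        terms.append(_mk("E", 1.0 - 1.0 / n, sigma_e2, r_e, alpha, {"e": 1.0}))
    return EMSDecomposition(terms=terms, alpha=alpha)


def balanced_nested(
    sigma_a2: float,
    sigma_b2: float,
    sigma_e2: float,
    A: int,
    B: int,
    n: int,
    alpha: float = 0.10,
    residual_df: float | None = None,
) -> EMSDecomposition:
    """Two nested random factors (B within A), balanced with n replicates."""
    if B == 1:  # degenerate: collapses to one-way in A
        return balanced_one_way(sigma_a2 + sigma_b2, sigma_e2, A, n, alpha, residual_df)
    ems_a = sigma_e2 + n * sigma_b2 + n * B * sigma_a2
    ems_b = sigma_e2 + n * sigma_b2
    k_a = 1.0 / (n * B)
    k_b = 1.0 / n - 1.0 / (n * B)
    terms = [
        _mk("A", k_a, ems_a, A - 1, alpha, {"a": float(n * B), "b": float(n), "e": 1.0}),
        _mk("B(A)", k_b, ems_b, A * (B - 1), alpha, {"b": float(n), "e": 1.0}),
    ]
    if n > 1:
        r_e = residual_df if residual_df is not None else A * B * (n - 1)
        terms.append(_mk("E", 1.0 - 1.0 / n, sigma_e2, r_e, alpha, {"e": 1.0}))
    return EMSDecomposition(terms=terms, alpha=alpha)


def balanced_crossed(
    sigma_a2: float,
    sigma_b2: float,
    sigma_ab2: float,
    sigma_e2: float,
    A: int,
    B: int,
    n: int,
    alpha: float = 0.10,
    residual_df: float | None = None,
) -> EMSDecomposition:
    """Two crossed random factors with interaction, balanced, n replicates."""
    ems_a = sigma_e2 + n * sigma_ab2 + n * B * sigma_a2
    ems_b = sigma_e2 + n * sigma_ab2 + n * A * sigma_b2
    ems_ab = sigma_e2 + n * sigma_ab2
    k_a = 1.0 / (n * B)
    k_b = 1.0 / (n * A)
    k_ab = 1.0 / n - 1.0 / (n * A) - 1.0 / (n * B)
    terms = [
        _mk("A", k_a, ems_a, A - 1, alpha, {"a": float(n * B), "ab": float(n), "e": 1.0}),
        _mk("B", k_b, ems_b, B - 1, alpha, {"b": float(n * A), "ab": float(n), "e": 1.0}),
        _mk(
            "AB",
            k_ab,
            ems_ab,
            (A - 1) * (B - 1),
            alpha,
            {"ab": float(n), "e": 1.0},
        ),
    ]
    if n > 1:
        r_e = residual_df if residual_df is not None else A * B * (n - 1)
        terms.append(_mk("E", 1.0 - 1.0 / n, sigma_e2, r_e, alpha, {"e": 1.0}))
    return EMSDecomposition(terms=terms, alpha=alpha)


def unbalanced_one_way(
    group_sizes,
    sigma_a2: float,
    sigma_e2: float,
    alpha: float = 0.10,
    residual_df: float | None = None,
) -> EMSDecomposition:
    """One random factor with unequal group sizes.

    EMS_A = sigma_e^2 + c sigma_a^2 with c = (N - sum n_i^2 / N) / (A - 1);
    k = (1/c, 1 - 1/c); df = (A - 1, N - A unless overridden).
    """
    sizes = np.asarray(group_sizes, dtype=float)
    if sizes.size < 2 or np.any(sizes <= 0):
        raise ValueError("need >= 2 groups, all sizes positive")
    N = float(sizes.sum())
    A = sizes.size
    c = (N - float(np.sum(sizes**2)) / N) / (A - 1)
    ems_a = sigma_e2 + c * sigma_a2
    terms = [_mk("A", 1.0 / c, ems_a, A - 1, alpha, {"a": c, "e": 1.0})]
    r_e = residual_df if residual_df is not None else N - A
    if r_e > 0:
        terms.append(_mk("E", 1.0 - 1.0 / c, sigma_e2, r_e, alpha, {"e": 1.0}))
    return EMSDecomposition(terms=terms, alpha=alpha)


# ---------------------------------------------------------------------------
# quadratic-form synthesis for general designs
# ---------------------------------------------------------------------------


def _colspace(M: np.ndarray) -> tuple[np.ndarray, int]:
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    r = int((s > 1e-9 * (s[0] if s.size else 1.0)).sum())
    return U[:, :r], r


def _projector(M: np.ndarray) -> tuple[np.ndarray, int]:
    U, r = _colspace(M)
    return U @ U.T, r


def _crossed_cell_structure(design: DesignMatrices):
    """Row cell index and counts for a two-factor crossed random layout."""
    blocks = {b.label: b for b in design.Z_blocks}
    term = design.Z_blocks[0].term
    a_name, b_name = term.factors
    ab_label = [lab for lab in blocks if ":" in lab][0]
    ZA, ZB, ZAB = blocks[a_name].matrix, blocks[b_name].matrix, blocks[ab_label].matrix
    return ZA, ZB, ZAB, a_name, b_name, ab_label


def synthesis_coefficients(
    design: DesignMatrices,
    theta: np.ndarray | None = None,
    alpha: float = 0.10,
    residual_df: float | None = None,
) -> EMSDecomposition:
    """EMS coefficients for an arbitrary (possibly unbalanced) design.

    Coefficient of component v in EMS_j is tr(Q_j Z_v Z_v') / df_j for the
    term's quadratic form Q_j (normalized so the residual coefficient is 1).
    The k_j are then solved from the requirement that the implied
    coefficient of every variance component in sum_j k_j EMS_j equals 1
    (a triangular system; the residual k completes the identity).

    ``theta`` (layout order, residual last) fills in the EMS values; pass
    None for a coefficients-only decomposition.
    """
    if design.het_group is not None:
        raise ConfigurationError(
            "synthesis operates per variance group; pass a single-group design"
        )
    n = design.n
    one = np.ones((n, 1))
    X = design.X
    labels = [b.label for b in design.Z_blocks]
    Zs = {b.label: b.matrix for b in design.Z_blocks}
    kinds = {b.label: b.term.kind for b in design.Z_blocks}

    quads: list[tuple[str, np.ndarray, float]] = []  # (label, Q, df)
    if len(design.Z_blocks) == 3 and all(k == "crossed" for k in kinds.values()):
        ZA, ZB, ZAB, a_name, b_name, ab_label = _crossed_cell_structure(design)
        A, B = ZA.shape[1], ZB.shape[1]
        counts = (ZAB.T @ ZAB).diagonal()
        if np.any(counts == 0):
            raise ConfigurationError(
                "crossed synthesis requires every (A,B) cell to be observed"
            )
        # map ZAB columns to (i, j) level indices
        a_of_cell = np.argmax(ZAB.T @ ZA, axis=1)
        b_of_cell = np.argmax(ZAB.T @ ZB, axis=1)
        D_inv = np.diag(1.0 / counts)

        def type3(L, df):
            core = L @ D_inv @ L.T
            Q = ZAB @ D_inv @ L.T @ np.linalg.solve(core, L @ D_inv) @ ZAB.T
            return Q, df

        def margin_contrasts(nlev, of_cell, other_of_cell, nother):
            L = np.zeros((nlev - 1, ZAB.shape[1]))
            for i in range(nlev - 1):
                L[i, of_cell == i] = 1.0 / nother
                L[i, of_cell == nlev - 1] = -1.0 / nother
            return L

        LA = margin_contrasts(A, a_of_cell, b_of_cell, B)
        LB = margin_contrasts(B, b_of_cell, a_of_cell, A)
        LAB = np.zeros(((A - 1) * (B - 1), ZAB.shape[1]))
        kidx = 0
        for i in range(A - 1):
            for j in range(B - 1):
                for cell in range(ZAB.shape[1]):
                    ia, jb = a_of_cell[cell], b_of_cell[cell]
                    sgn = (1 if ia == i else -1 if ia == A - 1 else 0) * (
                        1 if jb == j else -1 if jb == B - 1 else 0
                    )
                    LAB[kidx, cell] += sgn
                kidx += 1
        quads.append((a_name, *type3(LA, A - 1)))
        quads.append((b_name, *type3(LB, B - 1)))
        quads.append((ab_label, *type3(LAB, (A - 1) * (B - 1))))
        full_rank = _projector(np.hstack([X, ZAB]))[1]
    else:
        # sequential (fitting-order) projections: one-way and nested layouts
        running = np.hstack([X, one]) if X.size else one
        P_prev, r_prev = _projector(running)
        for lab in labels:
            running = np.hstack([running, Zs[lab]])
            P_cur, r_cur = _projector(running)
            df = r_cur - r_prev
            if df <= 0:
                raise ConfigurationError(f"term {lab!r} adds no degrees of freedom")
            quads.append((lab, P_cur - P_prev, float(df)))
            P_prev, r_prev = P_cur, r_cur
        full_rank = r_prev

    # EMS rows: coefficient of each component in each term's EMS
    coef_rows: list[dict[str, float]] = []
    for lab, Q, df in quads:
        row = {"e": float(np.trace(Q)) / df}
        for v in labels:
            Zv = Zs[v]
            row[v] = float(np.sum((Q @ Zv) * Zv)) / df
        # normalize so the residual enters with coefficient 1
        row = {k: v / row["e"] for k, v in row.items()}
        coef_rows.append(row)
    r_resid = residual_df if residual_df is not None else n - full_rank
    coef_rows.append({"e": 1.0, **{v: 0.0 for v in labels}})
    term_labels = [lab for lab, _, _ in quads] + ["E"]
    dfs = [df for _, _, df in quads] + [float(r_resid)]

    # solve sum_j k_j coef_j(v) = 1 for every component v (incl. residual)
    comp_order = labels + ["e"]
    M = np.array([[coef_rows[j].get(v, 0.0) for j in range(len(coef_rows))] for v in comp_order])
    k_vec = np.linalg.solve(M, np.ones(len(comp_order)))

    values: list[float | None]
    if theta is not None:
        theta = np.asarray(theta, dtype=float)
        comp_vals = dict(zip(labels, theta[: len(labels)]))
        comp_vals["e"] = float(theta[-1])
        values = [
            float(sum(row.get(v, 0.0) * comp_vals[v] for v in comp_order))
            for row in coef_rows
        ]
    else:
        values = [None] * len(coef_rows)

    terms = [
        EMSTerm(lab, float(k), val, float(df), _H(alpha, df), row)
        for lab, k, val, df, row in zip(term_labels, k_vec, values, dfs, coef_rows)
    ]
    return EMSDecomposition(terms=terms, alpha=alpha)


def decomposition_for_fit(fit, alpha: float = 0.10, group: str | None = None,
                          residual_df: float | None = None) -> EMSDecomposition:
    """Build the EMS decomposition matching a fitted model's design.

    Balanced one-way / nested / crossed designs use the closed forms;
    the unbalanced one-way uses its closed form; anything else goes
    through :func:`synthesis_coefficients`.  For heterogeneous-variance
    fits the decomposition is built per ``group`` on that group's rows.
    """
    design = fit.design
    theta = fit.theta_hat
    if design.het_group is not None:
        if group is None:
            raise ConfigurationError("het-group fit: specify the variance group")
        return _group_decomposition(fit, group, alpha, residual_df)

    nz = len(design.Z_blocks)
    sigma_e2 = float(theta[-1])
    if nz == 1:
        Z = design.Z_blocks[0].matrix
        sizes = Z.sum(axis=0)
        A = Z.shape[1]
        # residual df: rows minus rank of [X Z] (matches A(n-1) when X is
        # the intercept and the design is balanced)
        r_e = residual_df
        if r_e is None:
            r_e = design.n - _projector(np.hstack([design.X, Z]))[1]
        if np.all(sizes == sizes[0]):
            return balanced_one_way(theta[0], sigma_e2, A, int(sizes[0]), alpha, r_e)
        return unbalanced_one_way(sizes, theta[0], sigma_e2, alpha, r_e)

    kinds = [b.term.kind for b in design.Z_blocks]
    if nz == 2 and kinds == ["simple", "nested"]:
        ZA, ZB = design.Z_blocks[0].matrix, design.Z_blocks[1].matrix
        A, AB = ZA.shape[1], ZB.shape[1]
        sizes_b = ZB.sum(axis=0)
        per_parent = (ZA.T @ ZB).sum(axis=1)  # children per parent (weighted)
        if AB % A == 0 and np.all(sizes_b == sizes_b[0]):
            B = AB // A
            counts_per_parent = np.count_nonzero(ZA.T @ ZB, axis=1)
            if np.all(counts_per_parent == B):
                return balanced_nested(
                    theta[0], theta[1], sigma_e2, A, B, int(sizes_b[0]), alpha, residual_df
                )
    if nz == 3 and all(k == "crossed" for k in kinds):
        ZA, ZB, ZAB, *_ = _crossed_cell_structure(design)
        counts = (ZAB.T @ ZAB).diagonal()
        A, B = ZA.shape[1], ZB.shape[1]
        if counts.size == A * B and np.all(counts == counts[0]):
            return balanced_crossed(
                theta[0], theta[1], theta[2], sigma_e2, A, B, int(counts[0]),
                alpha, residual_df,
            )
    return synthesis_coefficients(design, theta, alpha, residual_df)


def _group_decomposition(fit, group: str, alpha: float, residual_df: float | None):
    """One-way-per-group decomposition for heterogeneous-variance fits."""
    from .design import GROUP_SEP

    design = fit.design
    if group not in design.group_levels:
        raise ConfigurationError(f"unknown variance group {group!r}")
    gi = design.group_levels.index(group)
    rows = design.residual_masks[gi]
    blocks = [b for b in design.Z_blocks if b.group == group]
    if len(blocks) != 1:
        raise ConfigurationError(
            "per-group decompositions support one random term per group"
        )
    block = blocks[0]
    k = [b.label for b in design.Z_blocks].index(block.label)
    sigma_a2 = float(fit.theta_hat[k])
    nz = len(design.Z_blocks)
    sigma_e2 = float(fit.theta_hat[nz + gi])
    Zg = block.matrix[rows]
    Zg = Zg[:, Zg.sum(axis=0) > 0]
    sizes = Zg.sum(axis=0)
    A = Zg.shape[1]
    r_e = residual_df
    if r_e is None:
        Xg = design.X[rows]
        Xg = Xg[:, Xg.sum(axis=0) > 0]
        r_e = int(rows.sum()) - _projector(np.hstack([Xg, Zg]))[1]
    if np.all(sizes == sizes[0]):
        return balanced_one_way(sigma_a2, sigma_e2, A, int(sizes[0]), alpha, r_e)
    return unbalanced_one_way(sizes, sigma_a2, sigma_e2, alpha, r_e)
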