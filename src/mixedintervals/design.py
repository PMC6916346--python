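"""Model specification and design-matrix construction.

Fixed effects use cell-means coding: one indicator column per observed
combination of fixed-factor levels and no intercept (a single intercept
cell when there are no fixed factors).  Every estimable quantity is then
expressed through an ``l`` vector over cells, so the coding itself never
changes, and the degrees of freedom and standard error of each cell come
straight out of the fit.

Random terms are variance components only: each term contributes one
block of membership indicators ``Z_j`` and one variance parameter.  An
optional heterogeneity group splits every component (including the
residual) into one parameter per group level, with the component active
only on that group's rows.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "ModelSpec",
    "RandomTerm",
    "DesignMatrices",
    "parse_random_term",
    "build_design",
]

LABEL_SEP = ":"  # joins parent:child labels and crossed-cell labels
GROUP_SEP = "|"  # joins component label with heterogeneity-group level


class ConfigurationError(ValueError):
    """Invalid model specification or data/specification mismatch."""


@dataclass(frozen=True)
class RandomTerm:
    """One random term: a simple factor, ``child(parent)`` nesting, or an
    ``A*B`` crossed pair (which expands to components A, B and A:B)."""

    kind: str  # "simple" | "nested" | "crossed"
    factors: tuple[str, ...]

    def component_labels(self) -> list[str]:
        if self.kind == "simple":
            return [self.factors[0]]
        if self.kind == "nested":
            parent, child = self.factors
            return [f"{child}({parent})"]
        a, b = self.factors
        return [a, b, f"{a}{LABEL_SEP}{b}"]


_NESTED_RE = re.compile(r"^\s*([\w.\-]+)\s*\(\s*([\w.\-]+)\s*\)\s*$")
_CROSSED_RE = re.compile(r"^\s*([\w.\-]+)\s*\*\s*([\w.\-]+)\s*$")


def parse_random_term(text: str) -> RandomTerm:
    """Parse ``"A"``, ``"B(A)"`` (B nested within A) or ``"A*B"`` (crossed
    with interaction) into a :class:`RandomTerm`."""
    m = _NESTED_RE.match(text)
    if m:
        child, parent = m.group(1), m.group(2)
        return RandomTerm("nested", (parent, child))
    m = _CROSSED_RE.match(text)
    if m:
        return RandomTerm("crossed", (m.group(1), m.group(2)))
    name = text.strip()
    if not name or not re.match(r"^[\w.\-]+$", name):
        raise ConfigurationError(f"cannot parse random term {text!r}")
    return RandomTerm("simple", (name,))


@dataclass
class ModelSpec:
    """Declarative description of response, fixed cells and random terms."""

    response: str
    fixed_factors: list[str] = field(default_factory=list)
    random_terms: list[RandomTerm | str] = field(default_factory=list)
    het_group: str | None = None

    def __post_init__(self) -> None:
        self.random_terms = [
            parse_random_term(t) if isinstance(t, str) else t for t in self.random_terms
        ]


@dataclass
class ZBlock:
    """Membership-indicator block for one variance component."""

    label: str
    matrix: np.ndarray  # n x g, one 1 per row (within its het group)
    term: RandomTerm
    group: str | None = None  # het-group level, None when homogeneous
    level_labels: list[str] = field(default_factory=list)


@dataclass
class DesignMatrices:
    """Cell-means fixed design, random-indicator blocks and the theta layout.

    ``theta_layout`` orders the variance components: the Z-block variances
    first, then the residual variance(s) last.
    """

    X: np.ndarray
    cell_labels: list[str]
    Z_blocks: list[ZBlock]
    residual_labels: list[str]
    residual_masks: np.ndarray  # n_res x n boolean
    theta_layout: list[str]
    cell_counts: np.ndarray
    het_group: str | None = None
    group_levels: list[str] = field(default_factory=list)
    row_groups: np.ndarray | None = None  # index into group_levels per row
    cell_groups: list[str | None] = field(default_factory=list)
    spec: ModelSpec | None = None
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return len(self.theta_layout)

    def Z_full(self) -> np.ndarray:
        """Horizontal stack of all Z blocks (columns ordered as in theta)."""
        if not self.Z_blocks:
            return np.zeros((self.n, 0))
        return np.hstack([b.matrix for b in self.Z_blocks])

    def component_groups(self) -> list[str | None]:
        """Het-group level of each theta component (None = shared)."""
        out: list[str | None] = [b.group for b in self.Z_blocks]
        if self.het_group is None:
            out.append(None)
        else:
            out.extend(self.group_levels)
        return out


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((codes.size, n_levels))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


def _factor_codes(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    labels = sorted(values.astype(str).unique())
    lookup = {lab: i for i, lab in enumerate(labels)}
    codes = values.astype(str).map(lookup).to_numpy()
    return codes, labels


def _term_level_strings(term: RandomTerm, comp_label: str, data: pd.DataFrame) -> pd.Series:
    """String label of the random level each row belongs to, for one component."""
    if term.kind == "simple":
        return data[term.factors[0]].astype(str)
    if term.kind == "nested":
        parent, child = term.factors
        # child labels are interpreted within parent
        return data[parent].astype(str) + LABEL_SEP + data[child].astype(str)
    a, b = term.factors
    if comp_label == a:
        return data[a].astype(str)
    if comp_label == b:
        return data[b].astype(str)
    return data[a].astype(str) + LABEL_SEP + data[b].astype(str)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Build cell-means ``X``, random blocks ``Z_j`` and the theta layout.

    Rows with missing response or missing factor labels are dropped (count
    logged).  Column order is deterministic: lexicographic by level label.
    """
    if data is None or len(data) == 0:
        raise ConfigurationError("empty data")
    needed = [spec.response] + list(spec.fixed_factors)
    for term in spec.random_terms:
        needed.extend(term.factors)
    if spec.het_group:
        needed.append(spec.het_group)
    for col in dict.fromkeys(needed):
        if col not in data.columns:
            raise ConfigurationError(f"unknown column {col!r}")
    if not spec.random_terms:
        raise ConfigurationError("at least one random term is required")

    y = pd.to_numeric(data[spec.response], errors="coerce")
    keep = y.notna()
    factor_cols = [c for c in dict.fromkeys(needed) if c != spec.response]
    for col in factor_cols:
        keep &= data[col].notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing response or factor labels", n_dropped)
    data = data.loc[keep].reset_index(drop=True)
    if len(data) == 0:
        raise ConfigurationError("no usable rows after dropping missing values")

    # --- fixed cells ---------------------------------------------------
    if spec.fixed_factors:
        cells = data[spec.fixed_factors].astype(str).agg(LABEL_SEP.join, axis=1)
        codes, cell_labels = _factor_codes(cells)
    else:
        codes = np.zeros(len(data), dtype=int)
        cell_labels = ["(Intercept)"]
    X = _indicator(codes, len(cell_labels))
    cell_counts = X.sum(axis=0)

    # --- het grouping --------------------------------------------------
    het = spec.het_group
    if het is not None:
        row_groups, group_levels = _factor_codes(data[het])
        group_of_rows = np.asarray(row_groups)
    else:
        group_levels = []
        group_of_rows = None

    # map cells to het groups when the het column is itself a fixed factor
    cell_groups: list[str | None] = [None] * len(cell_labels)
    if het is not None and het in spec.fixed_factors:
        for c in range(len(cell_labels)):
            rows = codes == c
            g = np.unique(group_of_rows[rows])
            cell_groups[c] = group_levels[g[0]] if g.size == 1 else None

    # --- random blocks -------------------------------------------------
    Z_blocks: list[ZBlock] = []
    for term in spec.random_terms:
        for comp_label in term.component_labels():
            levels_all = _term_level_strings(term, comp_label, data)
            if het is None:
                lv_codes, lv_labels = _factor_codes(levels_all)
                if len(lv_labels) < 2:
                    raise ConfigurationError(
                        f"random component {comp_label!r} has a single level; "
                        "variance not estimable"
                    )
                Z_blocks.append(
                    ZBlock(comp_label, _indicator(lv_codes, len(lv_labels)), term, None, lv_labels)
                )
            else:
                for gi, glab in enumerate(group_levels):
                    rows = group_of_rows == gi
                    lv_codes, lv_labels = _factor_codes(levels_all[rows])
                    if len(lv_labels) < 2:
                        raise ConfigurationError(
                            f"random component {comp_label!r} has a single level "
                            f"within group {glab!r}; variance not estimable"
                        )
                    Z = np.zeros((len(data), len(lv_labels)))
                    Z[np.flatnonzero(rows), lv_codes] = 1.0
                    Z_blocks.append(
                        ZBlock(f"{comp_label}{GROUP_SEP}{glab}", Z, term, glab, lv_labels)
                    )

    # --- residual components -------------------------------------------
    if het is None:
        residual_labels = ["residual"]
        residual_masks = np.ones((1, len(data)), dtype=bool)
    else:
        residual_labels = [f"residual{GROUP_SEP}{g}" for g in group_levels]
        residual_masks = np.stack([group_of_rows == gi for gi in range(len(group_levels))])

    theta_layout = [b.label for b in Z_blocks] + residual_labels
    return DesignMatrices(
        X=X,
        cell_labels=cell_labels,
        Z_blocks=Z_blocks,
        residual_labels=residual_labels,
        residual_masks=residual_masks,
        theta_layout=theta_layout,
        cell_counts=cell_counts,
        het_group=het,
        group_levels=group_levels,
        row_groups=group_of_rows,
        cell_groups=cell_groups,
        spec=spec,
        n_dropped=n_dropped,
    )


def response_vector(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Numeric response aligned with :func:`build_design` row filtering."""
    y = pd.to_numeric(data[spec.response], errors="coerce")
    keep = y.notna()
    cols = list(spec.fixed_factors)
    for term in spec.random_terms:
        cols.extend(term.factors)
    if spec.het_group:
        cols.append(spec.het_group)
    for col in dict.fromkeys(cols):
        keep &= data[col].notna()
    return y.loc[keep].to_numpy(dtype=float)
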