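"""Covariate encoding with sum-to-zero categorical coding.

Categorical variables keep one reported coefficient per level, constrained
to sum to zero within each variable (and within each interaction family),
so the intercept is the mean for a person neutral on every predictor.
Internally each family is reparameterized onto an orthonormal sum-to-zero
basis (Helmert contrasts), which turns the constrained problem into an
unconstrained one; fitted coefficients are mapped back to the per-level
scale for reporting.  Numeric variables are z-scored over the estimation
sample unless declared otherwise; the scalers are stored and re-applied to
new data at predict time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import helmert

__all__ = [
    "Variable",
    "CovariateSchema",
    "EncodedDesign",
    "encode",
    "build_lag_covariates",
    "linear_predictor",
    "effect_span",
]


@dataclass(frozen=True)
class Variable:
    """One covariate: categorical with explicit levels, or numeric."""

    name: str
    kind: str  # "categorical" | "numeric"
    levels: tuple | None = None
    standardize: bool = True  # numeric only

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numeric"):
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical":
            if not self.levels:
                raise ValueError(f"categorical {self.name!r} needs levels")
        elif self.levels is not None:
            raise ValueError(f"numeric {self.name!r} must not declare levels")


@dataclass
class CovariateSchema:
    """Ordered covariate list, interaction pairs, and the partition into the
    segment-specific block (x tilde) and the common block (x star)."""

    variables: list[Variable]
    interactions: list[tuple[str, str]] = field(default_factory=list)
    segment_specific: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        byname = {v.name: v for v in self.variables}
        if len(byname) != len(self.variables):
            raise ValueError("duplicate variable names in schema")
        for a, b in self.interactions:
            for n in (a, b):
                if n not in byname:
                    raise ValueError(f"interaction names unknown variable {n!r}")
                if byname[n].kind != "categorical":
                    raise ValueError("interactions require categorical variables")
        for n in self.segment_specific:
            if n not in byname:
                raise ValueError(f"segment-specific unknown variable {n!r}")

    def variable(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise ValueError(f"variable {name!r} not in schema")


@dataclass
class EncodedDesign:
    """A reduced (unconstrained) design matrix plus the bookkeeping needed
    to report constrained per-level coefficients.

    ``report_matrix`` maps reduced coefficients to the reported scale
    (per-level for categorical families, identity for numerics); the rows of
    ``constraint`` select reported coefficients whose sum is constrained to
    zero.
    """

    X: np.ndarray
    colnames: list[str]
    report_matrix: np.ndarray
    report_names: list[str]
    constraint: np.ndarray
    constraint_families: list[str]
    scalers: dict[str, tuple[float, float]]
    seg_cols: np.ndarray
    common_cols: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def report_coefs(self, beta_reduced: np.ndarray) -> np.ndarray:
        return self.report_matrix @ np.asarray(beta_reduced, dtype=float)


def _dummies(values: pd.Series, var: Variable) -> np.ndarray:
    levels = list(var.levels)
    n = len(values)
    D = np.zeros((n, len(levels)))
    arr = values.to_numpy(dtype=object)
    missing = pd.isna(values).to_numpy()
    for i, v in enumerate(arr):
        if missing[i]:
            continue  # neutral row: all dummies zero (the categorical mean)
        try:
            D[i, levels.index(v)] = 1.0
        except ValueError:
            raise ValueError(
                f"variable {var.name!r} has unseen level {v!r}"
            ) from None
    return D


def _basis(n_levels: int) -> np.ndarray:
    # columns orthonormal and orthogonal to the ones vector
    return helmert(n_levels, full=False).T


def encode(
    schema: CovariateSchema,
    table: pd.DataFrame,
    scalers: dict[str, tuple[float, float]] | None = None,
) -> EncodedDesign:
    """Build the reduced design matrix for ``table``.

    Pass ``scalers`` (from a previous fit) to re-apply stored z-score
    parameters instead of re-estimating them.
    """
    for v in schema.variables:
        if v.name not in table.columns:
            raise ValueError(f"table is missing schema column {v.name!r}")
    reuse = scalers is not None
    out_scalers: dict[str, tuple[float, float]] = dict(scalers or {})

    cols: list[np.ndarray] = []
    colnames: list[str] = []
    report_blocks: list[np.ndarray] = []
    report_names: list[str] = []
    constraint_rows: list[np.ndarray] = []
    families: list[str] = []
    seg_mask: list[bool] = []
    dummy_cache: dict[str, np.ndarray] = {}

    def add_family(name, reduced, names_r, B, names_rep, seg):
        cols.append(reduced)
        colnames.extend(names_r)
        report_blocks.append(B)
        report_names.extend(names_rep)
        seg_mask.extend([seg] * reduced.shape[1])

    for var in schema.variables:
        seg = var.name in schema.segment_specific
        if var.kind == "numeric":
            x = table[var.name].to_numpy(dtype=float)
            if var.standardize:
                if reuse:
                    m, s = out_scalers[var.name]
                else:
                    m, s = float(np.mean(x)), float(np.std(x, ddof=1))
                    out_scalers[var.name] = (m, s)
                if s <= 0:
                    raise ValueError(f"numeric {var.name!r} has zero variance")
                x = (x - m) / s
            add_family(var.name, x[:, None], [var.name], np.eye(1), [var.name], seg)
        else:
            D = _dummies(table[var.name], var)
            dummy_cache[var.name] = D
            B = _basis(len(var.levels))
            names_r = [f"{var.name}.c{j + 1}" for j in range(B.shape[1])]
            names_rep = [f"{var.name}={lev}" for lev in var.levels]
            add_family(var.name, D @ B, names_r, B, names_rep, seg)
            constraint_rows.append((var.name, names_rep, [names_rep]))

    for a, b in schema.interactions:
        va, vb = schema.variable(a), schema.variable(b)
        Da, Db = dummy_cache[a], dummy_cache[b]
        Dab = np.einsum("ni,nj->nij", Da, Db).reshape(len(table), -1)
        B = np.kron(_basis(len(va.levels)), _basis(len(vb.levels)))
        fam = f"{a}:{b}"
        names_rep = [
            f"{a}={la}:{b}={lb}" for la in va.levels for lb in vb.levels
        ]
        names_r = [f"{fam}.c{j + 1}" for j in range(B.shape[1])]
        seg = a in schema.segment_specific and b in schema.segment_specific
        add_family(fam, Dab @ B, names_r, B, names_rep, seg)
        # one constraint group per slice: sums over b within each level of a
        # and over a within each level of b are all zero
        groups = [
            [f"{a}={la}:{b}={lb}" for lb in vb.levels] for la in va.levels
        ] + [[f"{a}={la}:{b}={lb}" for la in va.levels] for lb in vb.levels]
        constraint_rows.append((fam, names_rep, groups))

    X = np.hstack(cols) if cols else np.zeros((len(table), 0))
    p = X.shape[1]
    R = len(report_names)
    report_matrix = np.zeros((R, p))
    r0 = c0 = 0
    for B in report_blocks:
        rb, cb = B.shape
        report_matrix[r0 : r0 + rb, c0 : c0 + cb] = B
        r0, c0 = r0 + rb, c0 + cb

    crows: list[np.ndarray] = []
    for fam, _names, groups in constraint_rows:
        for g in groups:
            row = np.zeros(R)
            for nm in g:
                row[report_names.index(nm)] = 1.0
            crows.append(row)
            families.append(fam)
    constraint = np.vstack(crows) if crows else np.zeros((0, R))

    seg_arr = np.asarray(seg_mask, dtype=bool)
    return EncodedDesign(
        X=X,
        colnames=colnames,
        report_matrix=report_matrix,
        report_names=report_names,
        constraint=constraint,
        constraint_families=families,
        scalers=out_scalers,
        seg_cols=np.nonzero(seg_arr)[0],
        common_cols=np.nonzero(~seg_arr)[0],
    )


def build_lag_covariates(
    table: pd.DataFrame, max_lag: int, person_col: str = "person_id",
    trial_col: str = "trial", censor_col: str = "censored",
) -> tuple[pd.DataFrame, list[Variable]]:
    """Add loss-experience lag variables.

    ``loss_lag{j}`` is "yes" when trial t - j of the same person ended on a
    loss card, "no" otherwise; the first j trials of a person get a missing
    value, which :func:`encode` turns into the neutral all-zero dummy row.
    Trials must be strictly increasing within person.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    df = table.copy()
    for pid, grp in df.groupby(person_col, sort=False):
        t = grp[trial_col].to_numpy()
        if len(np.unique(t)) != len(t) or np.any(np.diff(t) <= 0):
            raise ValueError(
                f"trials of person {pid!r} are not strictly increasing"
            )
    variables = []
    grouped = df.groupby(person_col, sort=False)[censor_col]
    for j in range(1, max_lag + 1):
        name = f"loss_lag{j}"
        shifted = grouped.shift(j)
        df[name] = shifted.map({1: "yes", 0: "no", 1.0: "yes", 0.0: "no"})
        variables.append(Variable(name, "categorical", ("yes", "no")))
    return df, variables


def linear_predictor(
    alpha_s: float,
    beta_common: np.ndarray,
    x_common: np.ndarray,
    beta_seg: np.ndarray | None = None,
    x_seg: np.ndarray | None = None,
) -> float:
    """eta = alpha_s + x_tilde' beta_tilde_s + x_star' beta_star.

    With an empty segment-specific block this is the common-coefficient
    linear predictor alpha_s + x' beta.
    """
    beta_common = np.asarray(beta_common, dtype=float)
    x_common = np.asarray(x_common, dtype=float)
    if x_common.shape != beta_common.shape:
        raise ValueError("common block dimension mismatch")
    eta = alpha_s + float(x_common @ beta_common)
    if beta_seg is not None or x_seg is not None:
        beta_seg = np.asarray(beta_seg, dtype=float)
        x_seg = np.asarray(x_seg, dtype=float)
        if x_seg.shape != beta_seg.shape:
            raise ValueError("segment block dimension mismatch")
        eta += float(x_seg @ beta_seg)
    return eta


def effect_span(
    coefs: dict[str, float],
    schema: CovariateSchema,
    variable: str,
    conditioning: dict[str, object] | None = None,
) -> float:
    """Total effect of a two-level variable on the eta (cards) scale.

    The span is the difference in eta between the variable's two levels,
    adding interaction coefficients for every interacting variable fixed by
    ``conditioning``.  Interacting variables left free average out under the
    sum-to-zero constraint.  Under that constraint a two-level main effect
    (b, -b) spans 2|b|.
    """
    var = schema.variable(variable)
    if var.kind != "categorical" or len(var.levels) != 2:
        raise ValueError("effect_span requires a two-level categorical variable")
    conditioning = conditioning or {}
    l1, l2 = var.levels

    def key(a, la, b, lb):
        return f"{a}={la}:{b}={lb}"

    d = coefs[f"{variable}={l1}"] - coefs[f"{variable}={l2}"]
    for a, b in schema.interactions:
        if variable == a and b in conditioning:
            lv = conditioning[b]
            d += coefs[key(a, l1, b, lv)] - coefs[key(a, l2, b, lv)]
        elif variable == b and a in conditioning:
            lv = conditioning[a]
            d += coefs[key(a, lv, b, l1)] - coefs[key(a, lv, b, l2)]
    return abs(d)
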