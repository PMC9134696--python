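"""Multivariable logistic model of CHE occurrence with diagnostics.

The model is the standard binary logistic regression

    logit(p_i) = log[p_i / (1 - p_i)] = beta_0 + beta' X_i

fitted by maximum likelihood (iteratively reweighted least squares), with
Wald odds ratios and 95% confidence intervals, the Hosmer-Lemeshow decile
goodness-of-fit test, and variance inflation factors as the collinearity
diagnostic.  The default design mirrors the household-survey covariates:
householder age (numeric), region (ref East), economic quintile (ref
poorest), household-size class (ref single-person), labour participation,
member aged 65+, disabled member, outpatient use in the past month,
inpatient use in the past year, five chronic-disease indicators, and
insurance type (ref URRBMI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    HosmerLemeshowError,
    RankDeficiencyError,
    SeparationError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Design specification
# ---------------------------------------------------------------------------

YESNO = ("No", "Yes")


@dataclass(frozen=True)
class Term:
    """One model term: a numeric column or a categorical with a reference level."""

    column: str
    kind: str  # "numeric" | "categorical"
    levels: tuple = ()
    reference: object = None

    def column_names(self):
        if self.kind == "numeric":
            return [self.column]
        return [f"{self.column}[{lv}]" for lv in self.levels if lv != self.reference]


@dataclass(frozen=True)
class DesignSpec:
    """Ordered model terms with reference levels."""

    terms: tuple

    def column_names(self):
        names = ["const"]
        for t in self.terms:
            names.extend(t.column_names())
        return names


def _binary(column: str) -> Term:
    return Term(column, "categorical", YESNO, "No")


DISEASE_COLUMNS = (
    "heart_disease",
    "stroke",
    "malignant_tumour",
    "chronic_lung_disease",
    "diabetes",
)


def default_design_spec(extended: bool = False) -> DesignSpec:
    """The fitted model's terms; ``extended`` adds the descriptive-only
    covariates (sex, marital status, residence, education, self-rated health)."""
    terms = [
        Term("age", "numeric"),
        Term("region", "categorical", ("East", "Central", "West"), "East"),
        Term("economic_level", "categorical", (1, 2, 3, 4, 5), 1),
        Term("size_class", "categorical", ("1", "2", "3+"), "1"),
        _binary("labour"),
        _binary("member_65"),
        _binary("disabled"),
        _binary("outpatient"),
        _binary("inpatient"),
        *[_binary(c) for c in DISEASE_COLUMNS],
        Term(
            "insurance",
            "categorical",
            ("URRBMI", "UEBMI", "NRCMS", "URBMI", "Other"),
            "URRBMI",
        ),
    ]
    if extended:
        terms.extend(
            [
                Term("sex", "categorical", ("Female", "Male"), "Female"),
                Term("marital", "categorical", ("Single", "Married"), "Single"),
                Term("residence", "categorical", ("Rural", "Urban"), "Rural"),
                Term(
                    "education",
                    "categorical",
                    ("Illiterate", "Primary school", "Junior high school and above"),
                    "Illiterate",
                ),
                Term("self_rated_health", "categorical", ("Good", "Bad"), "Good"),
            ]
        )
    return DesignSpec(tuple(terms))


def build_design_matrix(records: pd.DataFrame, outcome, spec: DesignSpec):
    """Dummy-code ``records`` per ``spec``.

    Returns ``(y, X, columns)`` with an intercept column first and dummy
    columns named ``column[level]`` in spec order.  Raises on categories not
    declared in the spec, naming the household and term.
    """
    n = len(records)
    y = np.asarray(outcome, dtype=float)
    if y.shape[0] != n:
        raise ValidationError("outcome length does not match records")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("outcome must be coded 0/1")
    cols = [np.ones(n)]
    names = ["const"]
    for term in spec.terms:
        if term.column not in records.columns:
            raise ValidationError(f"records lack model column {term.column!r}")
        values = records[term.column]
        if term.kind == "numeric":
            cols.append(values.to_numpy(dtype=float))
            names.append(term.column)
            continue
        known = values.isin(term.levels)
        if not known.all():
            bad = records.loc[~known, ["household_id", term.column]].iloc[0]
            raise ValidationError(
                f"household {bad['household_id']!r}: unseen category "
                f"{bad[term.column]!r} for term {term.column!r}"
            )
        for level in term.levels:
            if level == term.reference:
                continue
            cols.append((values == level).to_numpy(dtype=float))
            names.append(f"{term.column}[{level}]")
    X = np.column_stack(cols)
    return y, X, names


# ---------------------------------------------------------------------------
# Maximum-likelihood fit (IRLS)
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    """Fitted logistic model: coefficients, Wald inference, fit diagnostics."""

    columns: list
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray = field(repr=False)
    converged: bool
    n_iter: int
    log_likelihood: float
    fitted: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)
    design: np.ndarray = field(repr=False)

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.beta)

    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.columns)


def _log_likelihood(y, eta):
    # sum y*eta - log(1 + e^eta), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    outcome,
    design,
    columns=None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> LogisticFit:
    """Fit by IRLS with step-halving.

    Convergence: max |score| < ``score_tol`` or relative log-likelihood change
    < ``ll_tol``; hard cap ``max_iter``.  Standard errors come from the inverse
    observed information.  Rank-deficient designs raise
    :class:`RankDeficiencyError` naming the collinear columns; diverging
    coefficients with fitted probabilities pinned to 0/1 raise
    :class:`SeparationError`.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if columns is None:
        columns = [f"x{j}" for j in range(p)]
    if n <= p:
        raise ValidationError("need more observations than design columns")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("outcome must be coded 0/1")

    # rank check via QR; a near-zero R diagonal marks the column that became
    # linearly dependent on its predecessors
    _, R = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(R))
    scale = np.max(diag) if diag.size else 0.0
    if scale == 0.0 or np.any(diag < 1e-10 * scale):
        bad = [columns[j] for j in range(p) if diag[j] < 1e-10 * scale]
        raise RankDeficiencyError(bad or columns)

    beta = np.zeros(p)
    eta = X @ beta
    ll = _log_likelihood(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        info = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix: probabilities pinned to 0/1 "
                "(perfect separation)"
            ) from None
        # step-halving to guarantee likelihood ascent
        new_ll = -np.inf
        for _h in range(30):
            cand = beta + step
            eta_c = X @ cand
            new_ll = _log_likelihood(y, eta_c)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        beta, eta = beta + step, X @ (beta + step)
        if np.max(np.abs(beta)) > 30.0:
            raise SeparationError(
                "diverging coefficient (|beta| > 30): perfect separation suspected"
            )
        if abs(new_ll - ll) < ll_tol * (abs(ll) + 1e-12):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    ll = _log_likelihood(y, eta)
    if ll > -1e-6:
        # a binomial likelihood can only approach 1 when the data are
        # perfectly separated and the MLE diverges
        raise SeparationError("log-likelihood at machine zero: perfect separation")
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise SeparationError("information matrix not invertible at the optimum") from None
    se = np.sqrt(np.diag(cov))
    return LogisticFit(
        columns=list(columns),
        beta=beta,
        se=se,
        cov=cov,
        converged=converged,
        n_iter=it,
        log_likelihood=_log_likelihood(y, eta),
        fitted=mu,
        outcome=y,
        design=X,
    )


def odds_ratios(fit: LogisticFit, confidence: float = 0.95) -> pd.DataFrame:
    """Per-term OR with Wald confidence interval and two-sided Wald p-value."""
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    wald = fit.beta / fit.se
    return pd.DataFrame(
        {
            "term": fit.columns,
            "coef": fit.beta,
            "se": fit.se,
            "or": np.exp(fit.beta),
            "ci_lower": np.exp(fit.beta - z * fit.se),
            "ci_upper": np.exp(fit.beta + z * fit.se),
            "p_value": 2.0 * stats.norm.sf(np.abs(wald)),
        }
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def hosmer_lemeshow(outcome, fitted_probabilities, groups: int = 10):
    """Hosmer-Lemeshow goodness-of-fit test on fitted-probability deciles.

    Households are sorted by fitted probability and split into ``groups``
    near-equal groups; ties never straddle a boundary (group sizes then deviate
    from n/groups as needed).  Statistic: sum over groups of
    (O1-E1)^2/E1 + (O0-E0)^2/E0, df = groups - 2, upper-tail chi-square p.
    """
    y = np.asarray(outcome, dtype=float)
    p = np.asarray(fitted_probabilities, dtype=float)
    n = y.size
    if groups < 3:
        raise ValidationError("need at least 3 groups")
    if n < groups:
        raise ValidationError("need at least as many observations as groups")
    order = np.argsort(p, kind="mergesort")
    ps, ys = p[order], y[order]

    edges = [0]
    for g in range(1, groups):
        e = round(g * n / groups)
        e = max(e, edges[-1])
        while 0 < e < n and ps[e] == ps[e - 1]:
            e += 1  # keep ties together
        if e > edges[-1]:
            edges.append(e)
    edges.append(n)
    edges = sorted(set(edges))

    stat = 0.0
    n_groups = 0
    for a, b in zip(edges[:-1], edges[1:]):
        if a == b:
            continue
        n_groups += 1
        o1 = ys[a:b].sum()
        e1 = ps[a:b].sum()
        e0 = (b - a) - e1
        if e1 <= 0 or e0 <= 0:
            raise HosmerLemeshowError(
                "a group has zero expected events or non-events; use fewer groups"
            )
        stat += (o1 - e1) ** 2 / e1 + ((b - a - o1) - e0) ** 2 / e0
    df = n_groups - 2
    if df < 1:
        raise HosmerLemeshowError("too few distinct groups for the test; use fewer groups")
    return float(stat), int(df), float(stats.chi2.sf(stat, df))


def vif(design, columns=None) -> pd.Series:
    """Variance inflation factor per non-intercept design column.

    VIF_j = 1 / (1 - R^2_j) from the least-squares regression of column j on
    the remaining non-intercept columns (plus an intercept).  Exact linear
    dependence is reported as ``inf`` rather than raised.
    """
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if columns is None:
        columns = [f"x{j}" for j in range(p)]
    keep = [j for j, c in enumerate(columns) if c != "const"]
    if len(keep) < 2:
        raise ValidationError("need at least two non-intercept columns for VIF")
    out = {}
    ones = np.ones((n, 1))
    for j in keep:
        others = [k for k in keep if k != j]
        A = np.hstack([ones, X[:, others]])
        xj = X[:, j]
        coef, _, _, _ = np.linalg.lstsq(A, xj, rcond=None)
        resid = xj - A @ coef
        tss = np.sum((xj - xj.mean()) ** 2)
        if tss <= 0:
            out[columns[j]] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / tss
        out[columns[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_by_term(design, columns) -> pd.Series:
    """Aggregate per-dummy VIFs to one value per model term (max within term)."""
    per_col = vif(design, columns)
    grouped = {}
    for name, value in per_col.items():
        term = name.split("[", 1)[0]
        grouped[term] = max(grouped.get(term, 0.0), float(value))
    return pd.Series(grouped)
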