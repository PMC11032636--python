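"""Item-level evaluation engine: correlations and stepped robust regressions.

Behavioural outcomes (zRT, accuracy, corrected hit probability) are
modelled by three-step hierarchical OLS: a block of lexical/semantic
control covariates enters first, the semantic-size rating second, and form
typicality third, so typicality is only credited with variance that
nothing else can claim.  Coefficient uncertainty uses
heteroskedasticity-consistent (sandwich) standard errors, HC2 by default;
each increment's significance is a robust Wald chi-square test on the
newly added block (the natural companion to robust fitting; it is not the
classical hierarchical F on ΔR²).  ΔR² is reported on unadjusted R²
(adjusted R² can decrease between steps and is tabulated alongside).

Predictors are mean-centred by default, which changes only the intercept.
Rows with missing values on the outcome or any predictor are removed
listwise, with the count logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "StepSpec",
    "CoefficientEstimate",
    "StepResult",
    "RegressionFit",
    "CorrelationMatrix",
    "zero_order_correlations",
    "fit_design",
    "robust_covariance",
    "fit_hierarchical",
    "split_by_category",
]

ROBUST_TYPES = ("HC0", "HC1", "HC2", "HC3")


@dataclass
class StepSpec:
    """Ordered predictor blocks, the outcome name, and fitting options."""

    blocks: tuple[tuple[str, ...], ...]
    dv: str
    robust_type: str = "HC2"
    center_predictors: bool = True
    standardize_dv: bool = False

    def __post_init__(self) -> None:
        self.blocks = tuple(tuple(b) for b in self.blocks)
        if self.robust_type not in ROBUST_TYPES:
            raise ValueError(f"robust_type must be one of {ROBUST_TYPES}")
        flat = [name for block in self.blocks for name in block]
        if len(flat) != len(set(flat)):
            raise ValueError("predictor blocks must be disjoint")
        if self.dv in flat:
            raise ValueError("dependent variable cannot appear among predictors")

    @property
    def all_predictors(self) -> tuple[str, ...]:
        return tuple(name for block in self.blocks for name in block)


@dataclass
class CoefficientEstimate:
    name: str
    estimate: float
    se_robust: float
    t: float
    p: float


@dataclass
class StepResult:
    step: int
    coefficients: list[CoefficientEstimate]
    r2: float
    adj_r2: float
    delta_r2: float | None = None  # vs previous step, on unadjusted R2
    delta_chi2: float | None = None
    delta_df: int | None = None
    delta_p: float | None = None
    n: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"name": c.name, "estimate": c.estimate, "se": c.se_robust,
                 "t": c.t, "p": c.p}
                for c in self.coefficients
            ]
        )


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def zero_order_correlations(
    table: pd.DataFrame, variables: Sequence[str]
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with two-sided p-values.

    A zero-variance variable yields NaN entries (flagged, not fatal);
    pairs with fewer than 3 complete cases likewise.
    """
    variables = list(variables)
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=int)
    data = table[variables]
    for i in range(k):
        counts[i, i] = int(data.iloc[:, i].notna().sum())
    for i in range(k):
        for j in range(i + 1, k):
            pair = data.iloc[:, [i, j]].dropna()
            counts[i, j] = counts[j, i] = len(pair)
            if len(pair) < 3 or pair.iloc[:, 0].std() == 0 or pair.iloc[:, 1].std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rij, pij = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    idx = pd.Index(variables)
    return CorrelationMatrix(
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(counts, index=idx, columns=idx),
    )


@dataclass
class RegressionFit:
    """OLS fit that keeps its design matrix, residuals and hat diagonals,
    which is everything a sandwich covariance needs."""

    names: tuple[str, ...]  # "(Intercept)" first
    X: np.ndarray
    y: np.ndarray
    params: np.ndarray
    residuals: np.ndarray
    rss: float
    tss: float
    n: int
    p: int
    hat: np.ndarray

    @property
    def r2(self) -> float:
        return 1.0 - self.rss / self.tss if self.tss > 0 else 1.0

    @property
    def adj_r2(self) -> float:
        return 1.0 - (1.0 - self.r2) * (self.n - 1) / (self.n - self.p)


def fit_design(
    X: np.ndarray, y: np.ndarray, names: Sequence[str] | None = None,
    add_intercept: bool = True,
) -> RegressionFit:
    """QR-based OLS on an explicit design (intercept prepended by default)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["(Intercept)"] + names
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} observations cannot identify p={p} parameters")
    q, rmat = np.linalg.qr(X)
    rdiag = np.abs(np.diag(rmat))
    if rdiag.min() < 1e-10 * rdiag.max():
        raise np.linalg.LinAlgError(
            "collinear predictor block; prune collinear columns first"
        )
    params = np.linalg.solve(rmat, q.T @ y)
    fitted = X @ params
    resid = y - fitted
    hat = np.sum(q**2, axis=1)
    return RegressionFit(
        names=tuple(names), X=X, y=y, params=params, residuals=resid,
        rss=float(resid @ resid), tss=float(np.sum((y - y.mean()) ** 2)),
        n=n, p=p, hat=hat,
    )


def robust_covariance(fit: RegressionFit, robust_type: str = "HC2") -> np.ndarray:
    """Heteroskedasticity-consistent covariance of the coefficient vector.

    Sandwich estimator ``(X'X)^-1 X' diag(w e_i^2) X (X'X)^-1`` with
    weights w = 1 (HC0), n/(n-p) (HC1), 1/(1-h_i) (HC2), 1/(1-h_i)^2
    (HC3), where h_i are the hat-matrix diagonals.  HC2/HC3 refuse
    observations with leverage 1 (the weight would be infinite).
    """
    if robust_type not in ROBUST_TYPES:
        raise ValueError(f"robust_type must be one of {ROBUST_TYPES}")
    e2 = fit.residuals**2
    if robust_type == "HC1":  # literally the degrees-of-freedom-scaled HC0
        return robust_covariance(fit, "HC0") * (fit.n / (fit.n - fit.p))
    if robust_type == "HC0":
        w = np.ones(fit.n)
    else:
        lev = np.where(np.isclose(fit.hat, 1.0, atol=1e-12))[0]
        if lev.size:
            raise ValueError(
                f"observation(s) {lev.tolist()} have leverage 1; "
                f"{robust_type} weights are undefined"
            )
        w = 1.0 / (1.0 - fit.hat)
        if robust_type == "HC3":
            w = w**2
    xtx_inv = np.linalg.inv(fit.X.T @ fit.X)
    meat = fit.X.T @ (fit.X * (w * e2)[:, None])
    return xtx_inv @ meat @ xtx_inv


def _wald_block(fit: RegressionFit, cov: np.ndarray, idx: Sequence[int]) -> tuple[float, int, float]:
    """Robust Wald chi-square that the coefficients at ``idx`` are all zero."""
    idx = np.asarray(idx, dtype=int)
    beta = fit.params[idx]
    sub = cov[np.ix_(idx, idx)]
    chi2 = float(beta @ np.linalg.solve(sub, beta))
    df = len(idx)
    return chi2, df, float(stats.chi2.sf(chi2, df))


def fit_hierarchical(table: pd.DataFrame, spec: StepSpec) -> list[StepResult]:
    """Fit the cumulative models Step k = blocks 1..k and report each step.

    Complete cases only (listwise deletion over the outcome and every block
    member, count logged).  Per step: robust coefficient table, R2 and
    adjusted R2, ΔR² on unadjusted R², and a robust Wald test of the newly
    added block.
    """
    needed = [spec.dv, *spec.all_predictors]
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise KeyError(f"table lacks column(s): {missing_cols}")
    data = table[needed].dropna()
    n_dropped = len(table) - len(data)
    if n_dropped:
        logger.info("listwise deletion removed %d of %d rows", n_dropped, len(table))

    y = data[spec.dv].to_numpy(dtype=float)
    if spec.standardize_dv:
        sd = y.std(ddof=0)
        if sd == 0:
            raise ValueError("cannot standardize a constant outcome")
        y = (y - y.mean()) / sd

    preds = data[list(spec.all_predictors)].astype(float)
    if spec.center_predictors:
        preds = preds - preds.mean()

    results: list[StepResult] = []
    prev_r2: float | None = None
    cum_names: list[str] = []
    for step_no, block in enumerate(spec.blocks, start=1):
        cum_names.extend(block)
        fit = fit_design(preds[cum_names].to_numpy(), y, names=cum_names)
        cov = robust_covariance(fit, spec.robust_type)
        se = np.sqrt(np.diag(cov))
        tvals = fit.params / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), fit.n - fit.p)
        coefs = [
            CoefficientEstimate(name, float(b), float(s), float(t), float(pv))
            for name, b, s, t, pv in zip(fit.names, fit.params, se, tvals, pvals)
        ]
        res = StepResult(
            step=step_no, coefficients=coefs, r2=fit.r2, adj_r2=fit.adj_r2, n=fit.n
        )
        if prev_r2 is not None:
            res.delta_r2 = fit.r2 - prev_r2
            block_idx = [fit.names.index(name) for name in block]
            res.delta_chi2, res.delta_df, res.delta_p = _wald_block(fit, cov, block_idx)
        prev_r2 = fit.r2
        results.append(res)
    return results


def split_by_category(
    table: pd.DataFrame, column: str, values: Sequence[str]
) -> dict[str, pd.DataFrame]:
    """Disjoint sub-tables by category value; absent values give empty tables."""
    if column not in table.columns:
        raise KeyError(f"table lacks column {column!r}")
    out: dict[str, pd.DataFrame] = {}
    for value in values:
        sub = table[table[column] == value]
        if sub.empty:
            logger.warning("category %r: no rows", value)
        out[str(value)] = sub.copy()
        logger.info("category %r: %d rows", value, len(sub))
    return out
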