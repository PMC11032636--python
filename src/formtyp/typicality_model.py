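"""Best-subset size model and form-typicality scores.

The modelling chain is: prune exactly collinear feature columns, select the
subset of form variables minimizing Mallow's Cp, refit ordinary least
squares on the winner, and z-transform the fitted values.  A word's
z-scored fitted size is its *form typicality*: positive values mean the
word's surface form looks like the forms of large-referent words.

Cp convention
-------------
``Cp = RSS_p / sigma2_full + 2 p - n`` with the intercept always included
and counted in ``p``, and ``sigma2_full`` the residual variance of the
model containing every candidate column.  Under this convention the full
model satisfies ``Cp = p`` exactly, which the tests assert.  Lower Cp is
better; ties go to the smaller subset, then to lexicographically earlier
column sets, so the selection is deterministic.

The search is an exact branch-and-bound over include/exclude decisions:
the incumbent is seeded with forward/backward stepwise passes, branching
prefers the candidate whose exclusion raises RSS most, and nodes are
fathomed with a bound combining the union model's RSS with per-candidate
drop-one increments (see ``_CpSearch``).  Residual sums of squares come
from solves on the centered Gram matrix, so node cost is independent of
the sample size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PruningResult",
    "OLSFit",
    "SubsetModel",
    "TypicalityScores",
    "find_linear_combos",
    "fit_ols",
    "best_subset_cp",
    "compute_typicality",
]


@dataclass
class PruningResult:
    removed_columns: tuple[str, ...]
    retained_columns: tuple[str, ...]
    rank: int


def find_linear_combos(
    matrix: pd.DataFrame, tol: float = 1e-8, assume_intercept: bool = False
) -> PruningResult:
    """Identify columns that are exact linear combinations of earlier ones.

    Columns are scanned left to right; a column lying (to relative
    tolerance ``tol``) in the span of the previously retained columns is
    removed, so later-ordered columns are removed first and the retained
    matrix has full column rank.

    With ``assume_intercept=True`` the constant vector is placed in the
    basis first, so affine dependencies (e.g. indicator groups that sum to
    one) are also removed and the retained columns stay full rank *after*
    an intercept is added.  The default matches the matrix-only semantics
    of the usual collinearity screens.
    """
    if matrix.shape[1] < 1:
        raise ValueError("matrix must have at least one column")
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    basis: list[np.ndarray] = []
    if assume_intercept:
        basis.append(np.full(n, 1.0 / np.sqrt(n)))
    removed: list[str] = []
    retained: list[str] = []
    for j, name in enumerate(matrix.columns):
        v = X[:, j].copy()
        norm0 = np.linalg.norm(v)
        if norm0 == 0.0:
            removed.append(name)
            continue
        for q in basis:
            v -= (q @ v) * q
        # second Gram-Schmidt pass for numerical safety
        for q in basis:
            v -= (q @ v) * q
        if np.linalg.norm(v) <= tol * norm0:
            removed.append(name)
        else:
            retained.append(name)
            basis.append(v / np.linalg.norm(v))
    rank = len(retained)
    return PruningResult(tuple(removed), tuple(retained), rank)


@dataclass
class OLSFit:
    """Least-squares fit with an intercept."""

    columns: tuple[str, ...]
    intercept: float
    slopes: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    rss: float
    tss: float
    n: int
    p: int  # parameter count including the intercept

    @property
    def r2(self) -> float:
        return 1.0 - self.rss / self.tss if self.tss > 0 else 1.0

    @property
    def adj_r2(self) -> float:
        if self.n <= self.p:
            return float("nan")
        return 1.0 - (1.0 - self.r2) * (self.n - 1) / (self.n - self.p)

    @property
    def sigma2(self) -> float:
        return self.rss / (self.n - self.p)


def fit_ols(X: pd.DataFrame | np.ndarray, y: np.ndarray) -> OLSFit:
    """Ordinary least squares with an intercept (full-rank design required)."""
    if isinstance(X, pd.DataFrame):
        columns = tuple(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        columns = tuple(f"x{j}" for j in range(Xv.shape[1]))
    y = np.asarray(y, dtype=float)
    n, m = Xv.shape
    p = m + 1
    if n <= p:
        raise ValueError(f"n={n} observations cannot identify p={p} parameters")
    design = np.column_stack([np.ones(n), Xv])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p:
        raise np.linalg.LinAlgError(
            "design is rank deficient; prune collinear columns first"
        )
    fitted = design @ coef
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    return OLSFit(columns, float(coef[0]), coef[1:], fitted, resid, rss, tss, n, p)


@dataclass
class SubsetModel:
    """Selected feature subset, its OLS fit, and standardization constants."""

    selected: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    cp: float
    adj_r2: float
    sigma2_full: float
    n: int
    p: int  # selected size + intercept
    fitted_mean: float
    fitted_sd: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.selected if c not in X.columns]
        if missing:
            raise KeyError(f"feature matrix lacks selected column(s): {missing}")
        beta = np.array([self.coefficients[c] for c in self.selected])
        return self.intercept + X[list(self.selected)].to_numpy(dtype=float) @ beta

    def to_json(self) -> str:
        payload = {
            "selected": list(self.selected),
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "cp": self.cp,
            "adj_r2": self.adj_r2,
            "sigma2_full": self.sigma2_full,
            "n": self.n,
            "p": self.p,
            "fitted_mean": self.fitted_mean,
            "fitted_sd": self.fitted_sd,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SubsetModel":
        d = json.loads(text)
        return cls(
            selected=tuple(d["selected"]),
            intercept=d["intercept"],
            coefficients=dict(d["coefficients"]),
            cp=d["cp"],
            adj_r2=d["adj_r2"],
            sigma2_full=d["sigma2_full"],
            n=d["n"],
            p=d["p"],
            fitted_mean=d["fitted_mean"],
            fitted_sd=d["fitted_sd"],
        )


class _CpSearch:
    """Exact Cp minimization over subsets of the centered Gram matrix.

    Fathoming combines two valid lower-bound pieces for a node with
    forced-in set F and undecided candidates C (union U = F u C):

    * every completion S satisfies RSS(S) >= RSS(U) and pays the intercept
      plus 2|F| penalty;
    * deciding each candidate costs extra: including c pays 2, while
      excluding c raises RSS by at least its drop-one increment
      delta_c = beta_c^2 / (G_U^-1)_cc (and dropping a set raises RSS by at
      least the largest individual increment).  Minimizing
      ``2 (j - 1) + delta_(j)`` over the descending-sorted deltas (or
      paying 2|C| to keep everything) bounds that decision cost from
      below.

    Candidates are branched include-first in decreasing delta order, so the
    exclude branch (where the union shrinks) tightens quickly.
    """

    TIE_TOL = 1e-9

    def __init__(self, G: np.ndarray, g: np.ndarray, yty: float, sigma2: float,
                 n: int, max_features: int):
        self.G, self.g, self.yty = G, g, yty
        self.sigma2, self.n = sigma2, n
        self.m = G.shape[0]
        self.max_features = max_features
        self.best_cp = np.inf
        self.best: tuple[int, ...] = ()
        self.nodes = 0

    def rss(self, idx: tuple[int, ...]) -> float:
        if not idx:
            return self.yty
        ii = np.array(idx)
        sub = self.G[np.ix_(ii, ii)]
        try:
            sol = np.linalg.solve(sub, self.g[ii])
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(sub, self.g[ii], rcond=None)[0]
        return max(self.yty - float(self.g[ii] @ sol), 0.0)

    def cp(self, idx: tuple[int, ...]) -> float:
        return self.rss(idx) / self.sigma2 + 2 * (len(idx) + 1) - self.n

    def offer(self, idx: tuple[int, ...]) -> None:
        if not idx:
            return
        cand = self.cp(idx)
        if cand < self.best_cp - self.TIE_TOL:
            self.best_cp, self.best = cand, tuple(sorted(idx))
        elif abs(cand - self.best_cp) <= self.TIE_TOL:
            key = (len(idx), tuple(sorted(idx)))
            if key < (len(self.best), self.best):
                self.best_cp, self.best = min(self.best_cp, cand), tuple(sorted(idx))

    def stepwise_incumbent(self) -> None:
        # forward pass, offering the best greedy model of each size
        current: list[int] = []
        remaining = list(range(self.m))
        while remaining and len(current) < self.max_features:
            _, j = min((self.rss(tuple(current + [k])), k) for k in remaining)
            current.append(j)
            remaining.remove(j)
            self.offer(tuple(current))
        # backward pass from the largest admissible model
        current = list(range(self.m)) if self.m <= self.max_features else current
        while len(current) > 1:
            _, j = min(
                (self.rss(tuple(k for k in current if k != cand)), cand)
                for cand in current
            )
            current.remove(j)
            self.offer(tuple(current))

    def _decision_cost(self, deltas: list[float], capacity: int) -> float:
        """Lower bound on the extra Cp any completion pays for deciding the
        candidates with the given drop-one increments; ``capacity`` is how
        many more variables may still be included."""
        if not deltas:
            return 0.0
        deltas = sorted(deltas, reverse=True)
        best = 2.0 * len(deltas) if len(deltas) <= capacity else np.inf
        for j, d in enumerate(deltas):  # j vars kept before the 1st exclusion
            if j > capacity:
                break
            best = min(best, 2.0 * j + d)
        return best

    def search(self, forced: tuple[int, ...], candidates: tuple[int, ...],
               union: tuple[int, ...], union_rss: float,
               inv: np.ndarray, beta: np.ndarray) -> None:
        """DFS over include/exclude decisions.  ``inv`` and ``beta`` are the
        Gram inverse and coefficients of the *union* model (forced +
        candidates), maintained by rank-one downdates on exclusion.
        Subsets are offered to the incumbent only at leaves: the node bound
        covers every interior completion, including the forced set itself.
        """
        self.nodes += 1
        base = union_rss / self.sigma2 + 2 * (len(forced) + 1) - self.n
        if base > self.best_cp + self.TIE_TOL:
            return
        if not candidates or len(forced) >= self.max_features:
            self.offer(forced)
            return
        pos = {v: k for k, v in enumerate(union)}
        deltas = {}
        for c in candidates:
            k = pos[c]
            d = inv[k, k]
            deltas[c] = (beta[k] ** 2 / d) / self.sigma2 if d > 0 else 0.0
        capacity = self.max_features - len(forced)
        extra = self._decision_cost(list(deltas.values()), capacity)
        if base + extra > self.best_cp + self.TIE_TOL:
            return
        # branch on the candidate whose exclusion hurts most
        c = max(candidates, key=lambda k: deltas[k])
        rest = tuple(k for k in candidates if k != c)
        # include branch first: union unchanged
        self.search(forced + (c,), rest, union, union_rss, inv, beta)
        # exclude branch: Schur downdate of the union inverse
        k = pos[c]
        keep = [i for i in range(len(union)) if i != k]
        col = inv[keep, k]
        d = inv[k, k]
        inv_new = inv[np.ix_(keep, keep)] - np.outer(col, col) / d
        beta_new = beta[keep] - col * (beta[k] / d)
        rss_new = union_rss + beta[k] ** 2 / d if d > 0 else self.rss(forced + rest)
        union_new = tuple(v for v in union if v != c)
        self.search(forced, rest, union_new, rss_new, inv_new, beta_new)


def best_subset_cp(
    X: pd.DataFrame,
    y: np.ndarray,
    max_features: int | None = None,
    method: str = "auto",
) -> SubsetModel:
    """Select the Cp-minimizing subset of columns of ``X`` for predicting ``y``.

    ``method`` is ``"auto"`` (branch-and-bound, exact), ``"exhaustive"``
    (plain enumeration, allowed up to 15 columns), or
    ``"branch_and_bound"``.  All methods return the same model; the
    enumeration exists as a readable reference path for small problems.
    """
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if max_features is None or max_features > m:
        max_features = m
    if max_features < 1:
        raise ValueError("max_features must be >= 1")

    full = fit_ols(X, y)  # raises on rank deficiency or n <= p
    if full.rss <= 1e-12 * max(full.tss, 1.0):
        raise ValueError(
            "full model fits perfectly (sigma2_full = 0); Cp is undefined -- "
            "check that the response contains noise"
        )
    sigma2 = full.sigma2

    Xv = X.to_numpy(dtype=float)
    Xc = Xv - Xv.mean(axis=0)
    yc = y - y.mean()
    G = Xc.T @ Xc
    g = Xc.T @ yc
    yty = float(yc @ yc)

    search = _CpSearch(G, g, yty, sigma2, n, max_features)
    if method == "exhaustive" or (method == "auto" and m <= 12):
        if m > 15:
            raise ValueError("exhaustive enumeration limited to 15 columns")
        for k in range(1, max_features + 1):
            for idx in combinations(range(m), k):
                search.offer(idx)
    elif method in {"auto", "branch_and_bound"}:
        # branch in decreasing full-model |t| so good models appear early
        t = np.abs(full.slopes) / np.sqrt(
            np.maximum(np.diag(np.linalg.inv(G)), 1e-300) * sigma2
        )
        order = tuple(int(i) for i in np.argsort(-t))
        search.stepwise_incumbent()
        ii = np.array(order)
        inv_root = np.linalg.inv(G[np.ix_(ii, ii)])
        beta_root = inv_root @ g[ii]
        rss_root = max(yty - float(g[ii] @ beta_root), 0.0)
        search.search((), order, order, rss_root, inv_root, beta_root)
    else:
        raise ValueError(f"unknown method {method!r}")

    names = tuple(X.columns[i] for i in search.best)
    refit = fit_ols(X[list(names)], y)
    fitted = refit.fitted
    return SubsetModel(
        selected=names,
        intercept=refit.intercept,
        coefficients={c: float(b) for c, b in zip(names, refit.slopes)},
        cp=float(search.best_cp),
        adj_r2=refit.adj_r2,
        sigma2_full=sigma2,
        n=n,
        p=len(names) + 1,
        fitted_mean=float(fitted.mean()),
        fitted_sd=float(fitted.std(ddof=0)),
    )


@dataclass
class TypicalityScores:
    """Raw fitted sizes and their z-transform for a set of words."""

    words: tuple[str, ...]
    fitted: np.ndarray
    z: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fitted_size": self.fitted, "typicality_z": self.z},
            index=pd.Index(self.words, name="word"),
        )


def compute_typicality(model: SubsetModel, X: pd.DataFrame) -> TypicalityScores:
    """Score words: fitted size under the model, z-scored with the *fitting*
    set's mean and SD (stored on the model), so new words are comparable."""
    if model.fitted_sd <= 0:
        raise ValueError("degenerate model: fitted values have zero spread")
    fitted = model.predict(X)
    z = (fitted - model.fitted_mean) / model.fitted_sd
    words = tuple(str(w) for w in X.index)
    return TypicalityScores(words, fitted, z)
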