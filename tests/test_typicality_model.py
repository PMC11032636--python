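"""Pruning, Cp subset selection, OLS and typicality scoring."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from formtyp.synthetic_data import DEFAULT_SIZE_COEFFICIENTS, DEFAULT_SIZE_INTERCEPT
from formtyp.typicality_model import (
    SubsetModel,
    best_subset_cp,
    compute_typicality,
    find_linear_combos,
    fit_ols,
)


def exhaustive_cp_oracle(X: pd.DataFrame, y: np.ndarray):
    """Independent enumeration of every non-empty subset, minimizing
    Cp = RSS/sigma2_full + 2p - n with ties to smaller, earlier subsets."""
    n, m = X.shape
    Xv = X.to_numpy(float)
    ones = np.ones((n, 1))
    full_res = np.linalg.lstsq(np.hstack([ones, Xv]), y, rcond=None)
    rss_full = float(np.sum((y - np.hstack([ones, Xv]) @ full_res[0]) ** 2))
    sigma2 = rss_full / (n - m - 1)
    best = (np.inf, np.inf, ())
    for k in range(1, m + 1):
        for idx in combinations(range(m), k):
            design = np.hstack([ones, Xv[:, idx]])
            coef = np.linalg.lstsq(design, y, rcond=None)[0]
            rss = float(np.sum((y - design @ coef) ** 2))
            cp = rss / sigma2 + 2 * (k + 1) - n
            key = (round(cp, 9), k, idx)
            if key < best:
                best = key
    return best[2], best[0]


class TestFindLinearCombos:
    def test_constructed_dependency_removed(self, rng):
        c1 = rng.standard_normal(40)
        c2 = rng.standard_normal(40)
        X = pd.DataFrame({"c1": c1, "c2": c2, "c3": c1 + c2})
        result = find_linear_combos(X)
        assert result.removed_columns == ("c3",)
        assert result.rank == 2

    def test_full_rank_matrix_untouched(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 5)), columns=list("abcde"))
        result = find_linear_combos(X)
        assert result.removed_columns == ()
        assert result.retained_columns == tuple("abcde")

    def test_zero_column_removed(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(20), "z": np.zeros(20)})
        assert find_linear_combos(X).removed_columns == ("z",)

    def test_removed_count_matches_rank_oracle(self, small_study):
        feats = small_study.features
        result = find_linear_combos(feats)
        rank = np.linalg.matrix_rank(feats.to_numpy())
        assert rank < 60  # the partition identities force deficiency
        assert len(result.removed_columns) == 60 - rank
        retained = feats[list(result.retained_columns)].to_numpy()
        assert np.linalg.matrix_rank(retained) == retained.shape[1]

    def test_intercept_mode_leaves_affine_full_rank(self, small_study):
        feats = small_study.features
        result = find_linear_combos(feats, assume_intercept=True)
        retained = feats[list(result.retained_columns)].to_numpy()
        design = np.column_stack([np.ones(len(retained)), retained])
        assert np.linalg.matrix_rank(design) == design.shape[1]


class TestFitOls:
    def test_perfect_fit(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
        y = 1.0 + 2.0 * X["a"].to_numpy() - 3.0 * X["b"].to_numpy()
        fit = fit_ols(X, y)
        assert np.allclose(fit.residuals, 0, atol=1e-10)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_orthogonal_response_gives_zero_slopes(self):
        X = pd.DataFrame({"x": [-2.0, -1.0, 0.0, 1.0, 2.0]})
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # orthogonal to centered x
        fit = fit_ols(X, y)
        assert fit.slopes[0] == pytest.approx(0.0, abs=1e-12)
        assert fit.adj_r2 <= 0

    def test_five_point_hand_calculation(self):
        # x = 1..5, y = (2,4,5,4,5): slope 0.6, intercept 2.2, RSS 2.4
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        y = np.array([2.0, 4.0, 5.0, 4.0, 5.0])
        fit = fit_ols(X, y)
        assert fit.slopes[0] == pytest.approx(0.6)
        assert fit.intercept == pytest.approx(2.2)
        assert fit.rss == pytest.approx(2.4)

    def test_underdetermined_raises(self, rng):
        X = pd.DataFrame(rng.standard_normal((3, 3)))
        with pytest.raises(ValueError):
            fit_ols(X, np.zeros(3))


class TestBestSubsetCp:
    def test_full_model_cp_equals_p(self, rng):
        # algebraic identity: RSS_full/sigma2_full = n - p_full, so the
        # full subset scores Cp = p; with every feature strongly needed it
        # is also the winner
        n, m = 80, 5
        X = pd.DataFrame(rng.standard_normal((n, m)),
                         columns=[f"x{j}" for j in range(m)])
        y = X.to_numpy() @ np.array([3.0, -2.0, 1.5, 1.0, -1.0]) \
            + 0.1 * rng.standard_normal(n)
        model = best_subset_cp(X, y)
        assert len(model.selected) == m
        assert model.cp == pytest.approx(m + 1, abs=1e-8)

    @pytest.mark.parametrize("method", ["exhaustive", "branch_and_bound"])
    def test_eight_feature_problem_matches_enumeration(self, method, rng):
        n, m = 70, 8
        X = pd.DataFrame(rng.standard_normal((n, m)),
                         columns=[f"x{j}" for j in range(m)])
        beta = np.array([2.0, -1.0, 0.0, 0.0, 0.5, 0.0, 0.0, 0.0])
        y = X.to_numpy() @ beta + rng.standard_normal(n)
        oracle_idx, oracle_cp = exhaustive_cp_oracle(X, y)
        model = best_subset_cp(X, y, method=method)
        assert model.selected == tuple(X.columns[i] for i in oracle_idx)
        assert model.cp == pytest.approx(oracle_cp, abs=1e-6)

    def test_randomized_oracle_equivalence(self):
        rng = np.random.default_rng(404)
        for _ in range(25):
            n = int(rng.integers(40, 90))
            m = int(rng.integers(3, 11))
            X = pd.DataFrame(rng.standard_normal((n, m)),
                             columns=[f"x{j}" for j in range(m)])
            beta = rng.standard_normal(m) * (rng.random(m) < 0.5)
            y = X.to_numpy() @ beta + rng.standard_normal(n)
            oracle_idx, oracle_cp = exhaustive_cp_oracle(X, y)
            model = best_subset_cp(X, y, method="branch_and_bound")
            assert model.selected == tuple(X.columns[i] for i in oracle_idx)
            assert model.cp == pytest.approx(oracle_cp, abs=1e-6)

    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(7)
        n = 500
        X = pd.DataFrame(rng.standard_normal((n, 8)),
                         columns=[f"x{j}" for j in range(8)])
        y = 2.0 * X["x0"].to_numpy() - 1.0 * X["x1"].to_numpy() \
            + 0.01 * rng.standard_normal(n)
        model = best_subset_cp(X, y)
        assert {"x0", "x1"} <= set(model.selected)
        assert model.coefficients["x0"] == pytest.approx(2.0, abs=0.05)
        assert model.coefficients["x1"] == pytest.approx(-1.0, abs=0.05)

    def test_nested_rss_monotone(self, rng):
        n, m = 60, 6
        X = pd.DataFrame(rng.standard_normal((n, m)),
                         columns=[f"x{j}" for j in range(m)])
        y = X["x0"].to_numpy() + rng.standard_normal(n)
        cols = list(X.columns)
        last = np.inf
        for k in range(1, m + 1):
            fit = fit_ols(X[cols[:k]], y)
            assert fit.rss <= last + 1e-9
            last = fit.rss

    def test_perfect_fit_is_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=["a", "b"])
        y = X["a"].to_numpy() * 2.0
        with pytest.raises(ValueError, match="noise"):
            best_subset_cp(X, y)

    def test_rank_deficiency_points_to_pruning(self, rng):
        a = rng.standard_normal(30)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(np.linalg.LinAlgError, match="prune"):
            best_subset_cp(X, a + rng.standard_normal(30))


def _toy_model(**kw):
    defaults = dict(
        selected=("n_syllables",),
        intercept=3.0,
        coefficients={"n_syllables": 0.361},
        cp=2.0, adj_r2=0.2, sigma2_full=1.0, n=100, p=2,
        fitted_mean=3.7, fitted_sd=0.4,
    )
    defaults.update(kw)
    return SubsetModel(**defaults)


class TestComputeTypicality:
    def test_z_has_mean_zero_sd_one(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(200)},
                         index=[f"w{i}" for i in range(200)])
        y = 1.0 + 0.5 * X["a"].to_numpy() + 0.3 * rng.standard_normal(200)
        model = best_subset_cp(X, y)
        scores = compute_typicality(model, X)
        assert abs(scores.z.mean()) < 1e-10
        assert abs(scores.z.std(ddof=0) - 1.0) < 1e-10

    def test_syllable_coefficient_moves_fitted_value(self):
        """Two words identical except one extra syllable differ by the
        planted per-syllable slope, +0.361 Likert units."""
        coefs = dict(DEFAULT_SIZE_COEFFICIENTS)
        model = _toy_model(
            selected=tuple(coefs), coefficients=coefs,
            intercept=DEFAULT_SIZE_INTERCEPT, p=len(coefs) + 1,
        )
        base = {name: 1.0 for name in coefs}
        plus = dict(base, n_syllables=2.0)
        X = pd.DataFrame([base, plus], index=["short", "long"])
        scores = compute_typicality(model, X)
        assert scores.fitted[1] - scores.fitted[0] == pytest.approx(0.361)

    def test_ordering_of_z_matches_fitted(self, rng):
        X = pd.DataFrame({"n_syllables": rng.integers(1, 5, 50).astype(float)},
                         index=[f"w{i}" for i in range(50)])
        scores = compute_typicality(_toy_model(), X)
        assert (np.argsort(scores.z) == np.argsort(scores.fitted)).all()

    def test_constant_fitted_vector_is_error(self):
        X = pd.DataFrame({"n_syllables": np.ones(10)})
        with pytest.raises(ValueError, match="zero spread"):
            compute_typicality(_toy_model(fitted_sd=0.0), X)

    def test_new_words_reuse_stored_standardization(self):
        model = _toy_model()
        X_new = pd.DataFrame({"n_syllables": [4.0]}, index=["newword"])
        scores = compute_typicality(model, X_new)
        expected = (3.0 + 0.361 * 4.0 - model.fitted_mean) / model.fitted_sd
        assert scores.z[0] == pytest.approx(expected)

    def test_affine_rescaling_of_response_leaves_z_unchanged(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(150),
                          "b": rng.standard_normal(150)},
                         index=[f"w{i}" for i in range(150)])
        y = 2.0 + X["a"].to_numpy() + 0.5 * rng.standard_normal(150)
        m1 = best_subset_cp(X, y)
        m2 = best_subset_cp(X, 10.0 + 3.0 * y)
        assert m1.selected == m2.selected
        z1 = compute_typicality(m1, X).z
        z2 = compute_typicality(m2, X).z
        assert np.allclose(z1, z2, atol=1e-8)


def test_model_json_roundtrip_scores_identically(rng):
    X = pd.DataFrame({"a": rng.standard_normal(100),
                      "b": rng.standard_normal(100)},
                     index=[f"w{i}" for i in range(100)])
    y = X["a"].to_numpy() - X["b"].to_numpy() + 0.5 * rng.standard_normal(100)
    model = best_subset_cp(X, y)
    clone = SubsetModel.from_json(model.to_json())
    assert clone.to_json() == model.to_json()
    assert np.array_equal(compute_typicality(clone, X).z,
                          compute_typicality(model, X).z)
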