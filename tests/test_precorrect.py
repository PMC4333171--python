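"""Relationship matrix and mixed-model pre-correction."""

import numpy as np
import pandas as pd
import pytest

from gpimpute.precorrect import (
    build_design,
    build_numerator_relationship,
    fit_mixed_model,
)
from gpimpute.simulate import Pedigree, simulate_population


def pedigree_from_rows(rows):
    return Pedigree(
        pd.DataFrame(
            rows, columns=["individual_id", "sire_id", "dam_id", "generation", "family_id", "cage_id"]
        )
    )


def kinship_oracle(pedigree: Pedigree) -> np.ndarray:
    """Naive recursive-kinship oracle: A_ij = 2 f(i,j), A_ii = 1 + f(s_i, d_i)."""
    parents = pedigree.parent_indices()
    n = len(pedigree)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            s, d = parents[i]
            return 0.5 * (1.0 + f(s, d))
        if i < j:
            i, j = j, i
        s, d = parents[i]  # i is the younger individual
        return 0.5 * (f(s, j) + f(d, j))

    A = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            A[i, j] = 2.0 * f(i, j) if i != j else 1.0 + f(*map(int, parents[i]))
    return A


class TestNumeratorRelationship:
    def test_unrelated_founders_give_identity(self):
        ped = pedigree_from_rows([("a", "", "", 0, None, None), ("b", "", "", 0, None, None)])
        np.testing.assert_array_equal(build_numerator_relationship(ped), np.eye(2))

    def test_nuclear_family_relationships(self):
        ped = pedigree_from_rows(
            [
                ("s", "", "", 0, None, None),
                ("d", "", "", 0, None, None),
                ("o1", "s", "d", 1, "f", "c"),
                ("o2", "s", "d", 1, "f", "c"),
            ]
        )
        A = build_numerator_relationship(ped)
        assert A[0, 2] == A[1, 2] == 0.5  # parent-offspring
        assert A[2, 3] == 0.5  # full sibs
        assert A[2, 2] == A[3, 3] == 1.0  # non-inbred offspring

    def test_full_sib_mating_gives_inbred_offspring(self):
        ped = pedigree_from_rows(
            [
                ("s", "", "", 0, None, None),
                ("d", "", "", 0, None, None),
                ("o1", "s", "d", 1, None, None),
                ("o2", "s", "d", 1, None, None),
                ("x", "o1", "o2", 2, None, None),
            ]
        )
        A = build_numerator_relationship(ped)
        assert A[4, 4] == pytest.approx(1.25)  # F = 0.25

    def test_matches_recursive_oracle_on_simulated_pedigree(self, small_map):
        pop = simulate_population(
            small_map, n_strains=4, n_families=20, litter_size=6,
            n_generations=3, n_intermediate=16, seed=9,
        )
        assert len(pop.pedigree) <= 200
        A = build_numerator_relationship(pop.pedigree)
        np.testing.assert_allclose(A, kinship_oracle(pop.pedigree), atol=1e-12)

    def test_cyclic_pedigree_rejected(self):
        with pytest.raises(ValueError):
            pedigree_from_rows(
                [("a", "b", "", 0, None, None), ("b", "a", "", 0, None, None)]
            )


def _fixed_effects_data(rng, n):
    phen = pd.DataFrame(
        {
            "individual_id": [f"i{k}" for k in range(n)],
            "age": rng.integers(6, 11, n),
            "gender": rng.integers(0, 2, n),
            "month": rng.integers(1, 5, n),
            "cage_density": rng.integers(2, 9, n),
            "cage_id": [f"c{k % 10}" for k in range(n)],
        }
    )
    y = (
        3.0
        + 0.5 * phen["age"]
        + 1.5 * phen["gender"]
        + 0.2 * phen["month"]
        + rng.normal(0, 1, n)
    )
    phen["trait"] = y
    return phen


class TestFitMixedModel:
    def test_collapses_to_ols_without_random_variance(self):
        rng = np.random.default_rng(0)
        phen = _fixed_effects_data(rng, 200)
        y, X, W, _ = build_design(phen, "trait")
        corrected = fit_mixed_model(y, X, W, np.eye(200))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(corrected.y_star, y - X @ beta_ols, atol=1e-6)
        assert corrected.variance_components["sigma_c2"] == 0.0
        assert abs(corrected.y_star.mean()) < 1e-8

    def test_single_individual_gives_centered_response(self):
        # degenerate design: intercept only, one cage, identity A
        y = np.array([4.0, 6.0, 5.0])
        X = np.ones((3, 1))
        W = np.ones((3, 1))
        corrected = fit_mixed_model(y, X, W, np.eye(3))
        assert corrected.theta_hat[0] + corrected.c_hat[0] == pytest.approx(5.0, abs=1e-6)
        np.testing.assert_allclose(corrected.y_star, y - 5.0, atol=1e-6)

    def test_reml_recovers_variance_components(self, small_map):
        """sigma_u2, sigma_c2, sigma_e2 = (2, 1, 3) within 35% over 20 seeds."""
        pop = simulate_population(
            small_map, n_strains=6, n_families=30, litter_size=10,
            n_generations=3, seed=1,
        )
        A = build_numerator_relationship(pop.pedigree)
        last = pop.pedigree.table["generation"].max()
        rows = np.flatnonzero((pop.pedigree.table["generation"] == last).to_numpy())
        A_sub = A[np.ix_(rows, rows)]
        n = len(rows)
        # cages assigned independently of family here, so the cage and
        # additive components are separately identifiable
        cages = np.random.default_rng(99).integers(0, 30, n)
        W = pd.get_dummies(pd.Series(cages)).to_numpy(float)
        L = np.linalg.cholesky(A_sub + 1e-8 * np.eye(n))
        su2, sc2, se2 = 2.0, 1.0, 3.0
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            u = L @ rng.normal(0, np.sqrt(su2), n)
            c = W @ rng.normal(0, np.sqrt(sc2), W.shape[1])
            y = 10.0 + u + c + rng.normal(0, np.sqrt(se2), n)
            fit = fit_mixed_model(y, np.ones((n, 1)), W, A_sub)
            estimates.append(
                [fit.variance_components[k] for k in ("sigma_u2", "sigma_c2", "sigma_e2")]
            )
        mean = np.mean(estimates, axis=0)
        np.testing.assert_allclose(mean, [su2, sc2, se2], rtol=0.35)

    def test_solutions_satisfy_henderson_equations(self):
        rng = np.random.default_rng(4)
        phen = _fixed_effects_data(rng, 120)
        y, X, W, _ = build_design(phen, "trait")
        A = np.eye(120) * 1.0
        A[:60, :60] += 0.2  # some relatedness structure
        np.fill_diagonal(A, 1.2)
        # add genuine cage and genetic variance so REML stays off the boundary
        L = np.linalg.cholesky(A)
        y = y + L @ rng.normal(0, 1.2, 120) + W @ rng.normal(0, 1.0, W.shape[1])
        corrected = fit_mixed_model(y, X, W, A)
        vc = corrected.variance_components
        # rebuild Henderson's MME at the REML estimates, with u on A's support
        gu = max(vc["sigma_u2"], 1e-10) / vc["sigma_e2"]
        gc_ = max(vc["sigma_c2"], 1e-10) / vc["sigma_e2"]
        Z = np.eye(120)
        Ainv = np.linalg.inv(A)
        top = [X.T @ X, X.T @ W, X.T @ Z]
        mid = [W.T @ X, W.T @ W + np.eye(W.shape[1]) / gc_, W.T @ Z]
        bot = [Z.T @ X, Z.T @ W, Z.T @ Z + Ainv / gu]
        lhs = np.block([top, mid, bot])
        rhs = np.concatenate([X.T @ y, W.T @ y, Z.T @ y])
        sol = np.linalg.solve(lhs, rhs)
        p, q = X.shape[1], W.shape[1]
        np.testing.assert_allclose(sol[:p], corrected.theta_hat, atol=1e-6)
        np.testing.assert_allclose(sol[p : p + q], corrected.c_hat, atol=1e-6)
        resid = lhs @ sol - rhs
        assert np.linalg.norm(resid) < 1e-8 * max(np.linalg.norm(rhs), 1.0)

    def test_y_star_invariant_to_fixed_effect_coding(self):
        rng = np.random.default_rng(5)
        phen = _fixed_effects_data(rng, 150)
        y, X, W, _ = build_design(phen, "trait")
        A = np.eye(150)
        A[:75, :75] += 0.3  # informative relatedness: unique REML optimum
        np.fill_diagonal(A, 1.3)
        L = np.linalg.cholesky(A)
        y = y + L @ rng.normal(0, 1.0, 150) + W @ rng.normal(0, 0.8, W.shape[1])
        fit1 = fit_mixed_model(y, X, W, A)
        # sum-to-zero contrast for the same column space
        C = np.eye(X.shape[1])
        C[0, 1:] = -0.5
        fit2 = fit_mixed_model(y, X @ C, W, A)
        np.testing.assert_allclose(fit1.y_star, fit2.y_star, atol=1e-8)
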