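"""Pedigree relationships and mixed-model phenotype pre-correction.

The trait is pre-corrected with the animal model

    y = X theta + W c + Z u + e,
    u ~ N(0, A sigma_u^2),  c ~ N(0, I sigma_c^2),  e ~ N(0, I sigma_e^2),

where ``X`` carries fixed effects of age, gender, month and cage density,
``W`` is the cage incidence, and ``A`` is the pedigree numerator
relationship matrix. Variance components are estimated by REML (direct
maximization of the restricted likelihood over variance ratios, with the
residual variance profiled out); fixed effects and cage BLUPs are the
mixed-model-equation solutions at the REML estimates. The corrected
response is

    y* = y - X theta_hat - W c_hat,

which deliberately retains all genetic signal (additive, dominance,
epistasis) for the downstream prediction models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .simulate import Pedigree

__all__ = [
    "CorrectedPhenotype",
    "MixedModelError",
    "build_numerator_relationship",
    "build_design",
    "fit_mixed_model",
    "precorrect_phenotypes",
]


class MixedModelError(RuntimeError):
    """REML failed to converge; carries the optimizer trajectory."""

    def __init__(self, message: str, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


def build_numerator_relationship(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix A by the tabular method.

    Uses the recursions a_ij = 0.5 (a_{i,sire(j)} + a_{i,dam(j)}) for i < j
    and a_jj = 1 + 0.5 a_{sire(j),dam(j)}; unknown parents contribute 0.
    Requires (and the Pedigree type guarantees) parents-before-offspring
    ordering, which also excludes cycles.
    """
    parents = pedigree.parent_indices()
    n = len(pedigree)
    A = np.zeros((n, n))
    for j in range(n):
        s, d = parents[j]
        row = np.zeros(j)
        if s >= 0:
            row += 0.5 * A[s, :j]
        if d >= 0:
            row += 0.5 * A[d, :j]
        A[j, :j] = row
        A[:j, j] = row
        A[j, j] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def build_design(
    phenotypes: pd.DataFrame,
    trait: str,
    numeric_covariates: tuple[str, ...] = ("age", "cage_density"),
    categorical_covariates: tuple[str, ...] = ("gender", "month"),
    cage_column: str = "cage_id",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Response y, fixed design X (intercept + treatment coding), cage incidence W."""
    df = phenotypes.dropna(subset=[trait]).reset_index(drop=True)
    y = df[trait].to_numpy(dtype=float)
    blocks = [np.ones((len(df), 1))]
    names = ["intercept"]
    for c in numeric_covariates:
        if c in df:
            blocks.append(df[c].to_numpy(dtype=float)[:, None])
            names.append(c)
    for c in categorical_covariates:
        if c in df:
            dummies = pd.get_dummies(df[c].astype("category"), prefix=c, drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns)
    X = np.hstack(blocks)
    # drop exactly collinear columns so X has full column rank
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * max(np.abs(np.diag(r)).max(), 1.0)
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    cage = pd.get_dummies(df[cage_column].astype(str))
    W = cage.to_numpy(dtype=float)
    return y, X, W, names


@dataclass
class CorrectedPhenotype:
    """Pre-corrected response y* and the mixed-model solutions behind it."""

    individual_ids: list[str]
    y_star: np.ndarray
    theta_hat: np.ndarray
    c_hat: np.ndarray
    variance_components: dict[str, float] = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.y_star, index=self.individual_ids, name="y_star")


def _reml_neg_loglik(log_gammas, y, X, G, C):
    gu, gc = np.exp(log_gammas)
    n, p = X.shape
    H = np.eye(n) + gu * G + gc * C
    try:
        L = linalg.cholesky(H, lower=True)
    except linalg.LinAlgError:
        return np.inf
    logdet_H = 2.0 * np.sum(np.log(np.diag(L)))
    Hi_y = linalg.cho_solve((L, True), y)
    Hi_X = linalg.cho_solve((L, True), X)
    XtHiX = X.T @ Hi_X
    sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtHiX, X.T @ Hi_y)
    resid_quad = y @ Hi_y - (X.T @ Hi_y) @ beta
    if resid_quad <= 0:
        return np.inf
    sigma_e2 = resid_quad / (n - p)
    return 0.5 * (logdet_H + logdet_XtHiX + (n - p) * (np.log(sigma_e2) + 1.0))


def fit_mixed_model(
    y: np.ndarray,
    X: np.ndarray,
    W: np.ndarray,
    A_sub: np.ndarray,
    individual_ids: list[str] | None = None,
    max_iter: int = 400,
) -> CorrectedPhenotype:
    """REML fit of the animal model and computation of y*.

    ``A_sub`` is the relationship matrix restricted to the phenotyped
    individuals (i.e. Z A Z' with Z a selection matrix). The restricted
    likelihood is maximized over the variance ratios (sigma_u^2/sigma_e^2,
    sigma_c^2/sigma_e^2) on the log scale with sigma_e^2 profiled out;
    estimates hitting the search boundary raise a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    G = np.asarray(A_sub, dtype=float)
    C = W @ W.T
    bounds = [(-12.0, 8.0), (-12.0, 8.0)]
    trajectory: list[tuple[np.ndarray, float]] = []

    def objective(lg):
        val = _reml_neg_loglik(lg, y, X, G, C)
        trajectory.append((np.array(lg), val))
        return val

    res = optimize.minimize(
        objective,
        x0=np.array([-1.0, -1.0]),
        method="Nelder-Mead",
        bounds=bounds,
        options={"maxiter": max_iter, "xatol": 1e-8, "fatol": 1e-12},
    )
    if not res.success:
        raise MixedModelError(f"REML did not converge: {res.message}", trajectory)
    lg = res.x
    if np.any(np.abs(lg - np.array(bounds)[:, 0]) < 1e-6) or np.any(
        np.abs(lg - np.array(bounds)[:, 1]) < 1e-6
    ):
        warnings.warn("variance ratio estimate pinned at the search boundary")
    gu, gc = np.exp(lg)
    # a ratio at the lower search boundary is a zero variance component:
    # snap it so the model collapses exactly (e.g. to OLS when both vanish)
    gu = 0.0 if gu < 1e-5 else gu
    gc = 0.0 if gc < 1e-5 else gc
    p = X.shape[1]
    H = np.eye(n) + gu * G + gc * C
    L = linalg.cholesky(H, lower=True)
    Hi_y = linalg.cho_solve((L, True), y)
    Hi_X = linalg.cho_solve((L, True), X)
    XtHiX = X.T @ Hi_X
    theta = np.linalg.solve(XtHiX, X.T @ Hi_y)
    resid_quad = y @ Hi_y - (X.T @ Hi_y) @ theta
    sigma_e2 = float(resid_quad / (n - p))
    sigma_u2 = float(gu * sigma_e2)
    sigma_c2 = float(gc * sigma_e2)
    # cage BLUP: c_hat = gamma_c W' H^{-1} (y - X theta)
    Hi_r = linalg.cho_solve((L, True), y - X @ theta)
    c_hat = gc * (W.T @ Hi_r)
    y_star = y - X @ theta - W @ c_hat
    return CorrectedPhenotype(
        individual_ids=list(individual_ids) if individual_ids is not None else list(map(str, range(n))),
        y_star=y_star,
        theta_hat=theta,
        c_hat=c_hat,
        variance_components={
            "sigma_u2": sigma_u2,
            "sigma_c2": sigma_c2,
            "sigma_e2": sigma_e2,
            "reml_neg_loglik": float(res.fun),
        },
    )


def precorrect_phenotypes(
    phenotypes: pd.DataFrame, pedigree: Pedigree, trait: str
) -> CorrectedPhenotype:
    """Convenience wrapper: design matrices + A + REML fit for one trait."""
    y, X, W, _ = build_design(phenotypes, trait)
    df = phenotypes.dropna(subset=[trait]).reset_index(drop=True)
    ids = [str(i) for i in df["individual_id"]]
    A = build_numerator_relationship(pedigree)
    pos = {iid: i for i, iid in enumerate(pedigree.ids)}
    rows = np.array([pos[i] for i in ids])
    A_sub = A[np.ix_(rows, rows)]
    return fit_mixed_model(y, X, W, A_sub, individual_ids=ids)
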