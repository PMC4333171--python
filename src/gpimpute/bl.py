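"""Bayesian LASSO whole-genome regression via Gibbs sampling.

The model is y = mu + X beta + e with Gaussian likelihood and a
double-exponential (Laplace) prior on each marker effect, represented as a
scale mixture of Gaussians:

    beta_j | tau_j^2, sigma_e^2 ~ N(0, tau_j^2 sigma_e^2)
    tau_j^2 | lambda^2          ~ Exp(lambda^2 / 2)
    sigma_e^2                   ~ scaled-inv-chi^2(df, S)
    lambda^2                    ~ Gamma(shape alpha1, rate alpha2)

with default hyperparameters S = df = 1, alpha1 = 1.2, alpha2 = 1e-5.
The Gibbs sweep updates mu and each beta_j from their Gaussian full
conditionals, 1/tau_j^2 from an inverse-Gaussian, sigma_e^2 from a scaled
inverse chi-square and lambda^2 from a Gamma. Marker covariates are
centered (not standardized) and an intercept is always included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BLPriors",
    "ChainSettings",
    "BLPosterior",
    "beta_conditional_moments",
    "fit_bl",
    "predict_bl",
]


def beta_conditional_moments(
    xj: np.ndarray, residual_without_j: np.ndarray, ss_j: float, tau2_j: float, sigma_e2: float
) -> tuple[float, float]:
    """Mean and variance of the Gaussian full conditional of one marker effect.

    Given the residual with marker j's contribution added back, the
    conditional is N(x_j'e / (x_j'x_j + 1/tau_j^2),
    sigma_e^2 / (x_j'x_j + 1/tau_j^2)).
    """
    prec = ss_j + 1.0 / tau2_j
    return float(xj @ residual_without_j) / prec, sigma_e2 / prec


@dataclass(frozen=True)
class BLPriors:
    scale: float = 1.0  # S of the scaled-inv-chi^2 on sigma_e^2
    df: float = 1.0
    alpha1: float = 1.2  # Gamma shape on lambda^2
    alpha2: float = 1e-5  # Gamma rate on lambda^2

    def __post_init__(self) -> None:
        if min(self.scale, self.df, self.alpha1, self.alpha2) <= 0:
            raise ValueError("all prior parameters must be positive")


@dataclass(frozen=True)
class ChainSettings:
    """Test-scale default 6,000/1,000; the full-scale run uses 70,000/5,000."""

    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class BLPosterior:
    """Posterior summaries and thinned samples of a fitted Bayesian LASSO."""

    beta_mean: np.ndarray
    beta_sd: np.ndarray
    mu_mean: float
    sigma_e2_mean: float
    lambda2_mean: float
    column_centers: np.ndarray
    kept_columns: np.ndarray
    settings: ChainSettings
    samples: dict[str, np.ndarray] = field(default_factory=dict)  # thinned traces
    log_posterior_trace: np.ndarray | None = None


def _log_posterior(y_resid, beta, tau2, sigma_e2, lam2, priors: BLPriors) -> float:
    n, p = len(y_resid), len(beta)
    ll = -0.5 * n * np.log(sigma_e2) - 0.5 * (y_resid @ y_resid) / sigma_e2
    lp_beta = -0.5 * np.sum(np.log(tau2)) - 0.5 * p * np.log(sigma_e2) - 0.5 * np.sum(
        beta**2 / tau2
    ) / sigma_e2
    lp_tau = p * np.log(lam2 / 2.0) - (lam2 / 2.0) * np.sum(tau2)
    lp_sig = -(1 + priors.df / 2.0) * np.log(sigma_e2) - priors.df * priors.scale / (
        2.0 * sigma_e2
    )
    lp_lam = (priors.alpha1 - 1.0) * np.log(lam2) - priors.alpha2 * lam2
    return float(ll + lp_beta + lp_tau + lp_sig + lp_lam)


def fit_bl(
    y: np.ndarray,
    X: np.ndarray,
    priors: BLPriors | None = None,
    settings: ChainSettings | None = None,
    fixed_tau2: float | None = None,
) -> BLPosterior:
    """Fit the Bayesian LASSO to a complete genotype matrix.

    ``fixed_tau2`` freezes every tau_j^2 at a constant (and skips the
    lambda^2 update), which turns the prior into a fixed Gaussian — the
    ridge-regression limit used for validation.
    """
    priors = priors or BLPriors()
    settings = settings or ChainSettings()
    rng = np.random.default_rng(settings.seed)

    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p_all = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.isnan(X).any():
        raise ValueError("X must be complete (impute or drop missing entries first)")

    centers = X.mean(axis=0)
    Xc = X - centers
    ss = np.einsum("ij,ij->j", Xc, Xc)
    keep = ss > 1e-12
    if not keep.all():
        warnings.warn(f"dropping {np.count_nonzero(~keep)} constant marker columns")
    Xc = Xc[:, keep]
    ss = ss[keep]
    p = Xc.shape[1]

    # initial state
    mu = float(y.mean())
    beta = np.zeros(p)
    tau2 = np.full(p, fixed_tau2 if fixed_tau2 is not None else 1.0)
    sigma_e2 = float(y.var()) or 1.0
    lam2 = 1.0
    e = y - mu  # running residual

    n_kept = (settings.n_iter - settings.burn_in) // settings.thin
    beta_sum = np.zeros(p)
    beta_sq_sum = np.zeros(p)
    mu_sum = 0.0
    sig_samples = np.empty(n_kept)
    lam_samples = np.empty(n_kept)
    logpost = np.empty(n_kept)
    kept = 0

    for it in range(settings.n_iter):
        # intercept
        e += mu
        mu = rng.normal(e.mean(), np.sqrt(sigma_e2 / n))
        e -= mu
        # marker effects, sequentially
        for j in range(p):
            xj = Xc[:, j]
            e += xj * beta[j]
            mean, var = beta_conditional_moments(xj, e, ss[j], tau2[j], sigma_e2)
            beta[j] = rng.normal(mean, np.sqrt(var))
            e -= xj * beta[j]
        if fixed_tau2 is None:
            # 1/tau_j^2 ~ IG(sqrt(lambda^2 sigma_e^2 / beta_j^2), lambda^2)
            babs = np.maximum(np.abs(beta), 1e-10)
            ig_mean = np.sqrt(lam2 * sigma_e2) / babs
            inv_tau2 = rng.wald(ig_mean, lam2)
            tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)
            lam2 = rng.gamma(p + priors.alpha1, 1.0 / (np.sum(tau2) / 2.0 + priors.alpha2))
        # sigma_e^2 ~ scaled-inv-chi^2
        df_post = n + p + priors.df
        scale_post = e @ e + np.sum(beta**2 / tau2) + priors.df * priors.scale
        sigma_e2 = scale_post / rng.chisquare(df_post)
        if not np.isfinite(sigma_e2) or not np.all(np.isfinite(beta)):
            raise FloatingPointError(f"divergent chain at iteration {it}")
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            beta_sum += beta
            beta_sq_sum += beta**2
            mu_sum += mu
            sig_samples[kept] = sigma_e2
            lam_samples[kept] = lam2
            logpost[kept] = _log_posterior(e, beta, tau2, sigma_e2, lam2, priors)
            kept += 1

    beta_mean = beta_sum / kept
    beta_var = np.maximum(beta_sq_sum / kept - beta_mean**2, 0.0)
    return BLPosterior(
        beta_mean=beta_mean,
        beta_sd=np.sqrt(beta_var),
        mu_mean=mu_sum / kept,
        sigma_e2_mean=float(sig_samples[:kept].mean()),
        lambda2_mean=float(lam_samples[:kept].mean()),
        column_centers=centers,
        kept_columns=np.flatnonzero(keep),
        settings=settings,
        samples={"sigma_e2": sig_samples[:kept], "lambda2": lam_samples[:kept]},
        log_posterior_trace=logpost[:kept],
    )


def predict_bl(posterior: BLPosterior, X_new: np.ndarray) -> np.ndarray:
    """Posterior-mean predictions mu_hat + X_new beta_hat (training centering)."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != len(posterior.column_centers):
        raise ValueError(
            f"expected {len(posterior.column_centers)} marker columns, got {X_new.shape[1]}"
        )
    Xc = (X_new - posterior.column_centers)[:, posterior.kept_columns]
    return posterior.mu_mean + Xc @ posterior.beta_mean
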