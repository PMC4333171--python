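"""Bayesian-regularized feed-forward networks (Levenberg-Marquardt training).

A single-hidden-layer network with tangent-sigmoid hidden units and a
linear output,

    y_hat = sum_k w_k tanh(sum_j w_kj x_j + b_k) + b2,

is trained to minimize the regularized objective

    F = gamma * E_D + alpha * E_w,

where E_D is the sum of squared residuals, E_w the sum of squared weights
and biases, and (alpha, gamma) are updated between epochs by the evidence
framework: with lambda_i the nonzero eigenvalues of J'J (J the Jacobian of
the network outputs),

    n_eff  = sum_i gamma lambda_i / (gamma lambda_i + alpha)
    alpha  = n_eff / (2 E_w)
    gamma  = (n - n_eff) / (2 E_D).

Each epoch performs one accepted Levenberg-Marquardt step on F (damping mu
divided by 10 on acceptance, multiplied by 10 on rejection). The normal
equations are solved through a Woodbury identity on the n x n matrix JJ',
so networks with many more parameters than observations stay cheap.
Inputs are min-max scaled to [-1, 1] per column and the target is
standardized for training; an ensemble of random restarts (default 20) is
trained and predictions are the ensemble average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkArchitecture",
    "TrainedNetwork",
    "TrainedEnsemble",
    "train_brann",
    "predict_brann",
    "forward",
    "objective_and_gradient",
]

MU_INIT = 0.005
MU_FACTOR = 10.0
MU_MAX = 1e10
ALPHA_INIT = 0.01
ALPHA_MAX = 1e6
EVIDENCE_WARMUP = 3  # LM-only epochs before the first (alpha, gamma) update
NEFF_GAP_FLOOR = 0.02  # floor on (n - n_eff)/n in the gamma update


@dataclass(frozen=True)
class NetworkArchitecture:
    """5 tanh hidden neurons and one linear output by default."""

    n_inputs: int
    n_hidden: int = 5

    @property
    def n_parameters(self) -> int:
        # input->hidden weights + hidden biases + hidden->output + output bias
        return self.n_hidden * (self.n_inputs + 1) + self.n_hidden + 1


def _unpack(params: np.ndarray, arch: NetworkArchitecture):
    s, R = arch.n_hidden, arch.n_inputs
    W1 = params[: s * R].reshape(s, R)
    b1 = params[s * R : s * R + s]
    w2 = params[s * R + s : s * R + 2 * s]
    b2 = params[-1]
    return W1, b1, w2, b2


def forward(params: np.ndarray, arch: NetworkArchitecture, X: np.ndarray) -> np.ndarray:
    """Network output for (already scaled) inputs X."""
    W1, b1, w2, b2 = _unpack(params, arch)
    return np.tanh(X @ W1.T + b1) @ w2 + b2


def _jacobian(params: np.ndarray, arch: NetworkArchitecture, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(outputs, J) with J[i, q] = d y_hat_i / d w_q."""
    W1, b1, w2, b2 = _unpack(params, arch)
    n = X.shape[0]
    s, R = arch.n_hidden, arch.n_inputs
    Z = X @ W1.T + b1
    Hh = np.tanh(Z)
    out = Hh @ w2 + b2
    dH = (1.0 - Hh**2) * w2  # n x s
    J = np.empty((n, arch.n_parameters))
    J[:, : s * R] = (dH[:, :, None] * X[:, None, :]).reshape(n, s * R)
    J[:, s * R : s * R + s] = dH
    J[:, s * R + s : s * R + 2 * s] = Hh
    J[:, -1] = 1.0
    return out, J


def objective_and_gradient(
    params: np.ndarray,
    arch: NetworkArchitecture,
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    gamma: float,
) -> tuple[float, np.ndarray]:
    """F = gamma E_D + alpha E_w and its exact gradient (for LM and testing)."""
    out, J = _jacobian(params, arch, X)
    r = y - out
    F = gamma * float(r @ r) + alpha * float(params @ params)
    grad = -2.0 * gamma * (J.T @ r) + 2.0 * alpha * params
    return F, grad


@dataclass
class TrainedNetwork:
    params: np.ndarray
    alpha: float
    gamma: float
    n_effective: float
    objective_trace: list[float]
    training_correlation: float
    converged: bool = True


@dataclass
class TrainedEnsemble:
    """Restart ensemble; predictions average the member networks."""

    arch: NetworkArchitecture
    networks: list[TrainedNetwork]
    x_min: np.ndarray
    x_max: np.ndarray
    y_mean: float
    y_std: float
    seeds: list[int] = field(default_factory=list)
    training_predictions: np.ndarray | None = None


def _scale_X(X, x_min, x_max):
    span = np.where(x_max > x_min, x_max - x_min, 1.0)
    return 2.0 * (X - x_min) / span - 1.0


def _train_single(
    Xs: np.ndarray,
    ys: np.ndarray,
    arch: NetworkArchitecture,
    epochs: int,
    rng: np.random.Generator,
) -> TrainedNetwork:
    n = len(ys)
    P = arch.n_parameters
    w = rng.uniform(-0.5, 0.5, size=P) / np.sqrt(max(arch.n_inputs, 1))
    alpha, gamma = ALPHA_INIT, 1.0
    mu = MU_INIT
    trace: list[float] = []
    n_eff = float(min(n, P))
    for _epoch in range(epochs):
        out, J = _jacobian(w, arch, Xs)
        r = ys - out
        E_D = float(r @ r)
        E_w = float(w @ w)
        F = gamma * E_D + alpha * E_w
        g = -2.0 * gamma * (J.T @ r) + 2.0 * alpha * w
        B = J @ J.T  # n x n
        accepted = False
        while mu <= MU_MAX:
            c = 2.0 * alpha + mu
            # delta = -(cI + 2 gamma J'J)^{-1} g via Woodbury
            Jg = J @ g
            A = (2.0 * gamma / c) * B
            A[np.diag_indices_from(A)] += 1.0
            try:
                inner = np.linalg.solve(A, Jg)
            except np.linalg.LinAlgError:
                mu *= MU_FACTOR
                continue
            delta = -(g / c - (2.0 * gamma / (c * c)) * (J.T @ inner))
            w_try = w + delta
            out_try = forward(w_try, arch, Xs)
            r_try = ys - out_try
            F_try = gamma * float(r_try @ r_try) + alpha * float(w_try @ w_try)
            if np.isfinite(F_try) and F_try < F:
                w = w_try
                mu = max(mu / MU_FACTOR, 1e-20)
                accepted = True
                break
            mu *= MU_FACTOR
        trace.append(F)
        if not accepted:
            break  # damping exhausted: stationary for this objective
        if _epoch < EVIDENCE_WARMUP:
            continue  # let LM move off the random start before re-estimating
        # evidence updates on the accepted state
        out, J = _jacobian(w, arch, Xs)
        r = ys - out
        E_D = float(r @ r)
        E_w = float(w @ w)
        lam = np.linalg.eigvalsh(J @ J.T)
        lam = np.clip(lam, 0.0, None)
        n_eff = float(np.sum(gamma * lam / (gamma * lam + alpha)))
        # floors/caps keep the coupled updates away from the degenerate
        # fixed point alpha -> inf, gamma -> 0 reachable when P > n
        alpha = min(n_eff / (2.0 * max(E_w, 1e-8)), ALPHA_MAX)
        gamma = max(n - n_eff, NEFF_GAP_FLOOR * n) / (2.0 * max(E_D, 1e-8))
    out = forward(w, arch, Xs)
    finite = np.all(np.isfinite(out)) and np.all(np.isfinite(w))
    corr = float(np.corrcoef(out, ys)[0, 1]) if finite and out.std() > 0 else np.nan
    return TrainedNetwork(
        params=w,
        alpha=alpha,
        gamma=gamma,
        n_effective=n_eff,
        objective_trace=trace,
        training_correlation=corr,
        converged=bool(finite),
    )


def train_brann(
    X: np.ndarray,
    y: np.ndarray,
    arch: NetworkArchitecture | None = None,
    epochs: int = 30,
    restarts: int = 20,
    seed: int = 0,
) -> TrainedEnsemble:
    """Train the restart ensemble on genotype codes X and response y.

    Restarts differ only in their seeded weight initialization; a restart
    that ends in a non-finite state is excluded from the ensemble with a
    warning rather than aborting the run.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if epochs < 1 or restarts < 1:
        raise ValueError("epochs and restarts must be >= 1")
    arch = arch or NetworkArchitecture(n_inputs=X.shape[1])
    if arch.n_inputs != X.shape[1]:
        raise ValueError("architecture input count does not match X")
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    y_mean, y_std = float(y.mean()), float(y.std()) or 1.0
    Xs = _scale_X(X, x_min, x_max)
    ys = (y - y_mean) / y_std

    master = np.random.default_rng(seed)
    seeds = [int(s) for s in master.integers(2**31, size=restarts)]
    networks: list[TrainedNetwork] = []
    for s in seeds:
        net = _train_single(Xs, ys, arch, epochs, np.random.default_rng(s))
        if net.converged:
            networks.append(net)
        else:
            warnings.warn(f"excluding non-finite restart (seed {s})")
    if not networks:
        raise RuntimeError("all restarts diverged")
    ensemble = TrainedEnsemble(
        arch=arch,
        networks=networks,
        x_min=x_min,
        x_max=x_max,
        y_mean=y_mean,
        y_std=y_std,
        seeds=seeds,
    )
    ensemble.training_predictions = predict_brann(ensemble, X)
    return ensemble


def predict_brann(ensemble: TrainedEnsemble, X_new: np.ndarray) -> np.ndarray:
    """Average forward pass over restarts, back-transformed to trait scale."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[1] != ensemble.arch.n_inputs:
        raise ValueError("feature mismatch with the trained ensemble")
    Xs = _scale_X(X_new, ensemble.x_min, ensemble.x_max)
    preds = np.mean([forward(net.params, ensemble.arch, Xs) for net in ensemble.networks], axis=0)
    return preds * ensemble.y_std + ensemble.y_mean
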