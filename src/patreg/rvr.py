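"""Relevance vector regression (RVR) by sparse Bayesian evidence maximization.

The regressor places an independent zero-mean Gaussian prior with
precision ``alpha_i`` on each basis weight and a Gaussian likelihood with
noise variance ``sigma2``; hyperparameters are re-estimated by the
classical fixed-point scheme:

    Sigma = (diag(alpha) + Phi' Phi / sigma2)^-1
    mu    = Sigma Phi' y / sigma2
    g_i   = 1 - alpha_i Sigma_ii
    alpha_i <- g_i / mu_i^2
    sigma2  <- ||y - Phi mu||^2 / (n - sum_i g_i)

Basis functions whose precision diverges are pruned; the surviving
training points are the *relevance vectors*.  The basis is a kernel
(RBF by default) evaluated at the training points, plus an optional bias
column.

Features are standardized to zero mean / unit SD using training
statistics only.  The RBF width defaults to the median heuristic
``gamma = 1 / (d * median^2)`` with ``median`` the median pairwise
Euclidean distance of the standardized training features — the one
substantive hyperparameter of the model, kept configurable and recorded
on the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, spatial

_JITTER = 1e-10


@dataclass(frozen=True)
class KernelConfig:
    """Kernel for the RVR design matrix.

    ``gamma=None`` with an RBF kernel requests the median heuristic at
    fit time.
    """

    kind: str = "rbf"
    gamma: float | None = None
    include_bias: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("rbf", "linear"):
            raise ValueError(f"kernel kind must be rbf or linear, got {self.kind!r}")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("rbf gamma must be positive")


@dataclass
class RVRModel:
    """Fitted relevance vector regression model."""

    kernel: KernelConfig
    gamma: float | None                # resolved width actually used
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    X_train: np.ndarray                # standardized training design points
    relevance_idx: np.ndarray          # indices into X_train rows (bias excluded)
    mu: np.ndarray                     # posterior weight means, aligned w/ active basis
    alpha: np.ndarray
    sigma2: float
    has_bias_term: bool                # bias column survived pruning
    bias_weight: float
    converged: bool
    n_iter: int
    intercept_only: bool = False
    fallback_value: float = 0.0
    evidence_history: list = field(default_factory=list, repr=False)

    @property
    def n_relevance_vectors(self) -> int:
        return int(len(self.relevance_idx))


def _pairwise_sq_dists(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    d = spatial.distance.cdist(X, Y, metric="sqeuclidean")
    return np.maximum(d, 0.0)


def kernel_matrix(
    X: np.ndarray,
    Y: np.ndarray,
    cfg: KernelConfig,
    gamma: float | None = None,
) -> np.ndarray:
    """Design block K[i, j] = k(X_i, Y_j); appends a bias column if configured.

    Inputs are assumed already standardized.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if cfg.kind == "rbf":
        g = gamma if gamma is not None else cfg.gamma
        if g is None:
            raise ValueError("rbf kernel needs a resolved gamma")
        K = np.exp(-g * _pairwise_sq_dists(X, Y))
    else:
        K = X @ Y.T
    if cfg.include_bias:
        K = np.hstack([K, np.ones((K.shape[0], 1))])
    return K


def median_heuristic_gamma(X_std: np.ndarray) -> float:
    """gamma = 1 / (d * median^2) over pairwise distances of standardized rows."""
    d = X_std.shape[1]
    if X_std.shape[0] < 2:
        return 1.0 / max(d, 1)
    dists = spatial.distance.pdist(X_std)
    med = float(np.median(dists))
    if med <= 0:
        med = 1.0
    return 1.0 / (d * med * med)


def _standardize_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def _log_evidence(Phi, y, alpha, sigma2):
    """Marginal log-likelihood log N(y | 0, sigma2 I + Phi A^-1 Phi')."""
    n = len(y)
    M = Phi.shape[1]
    A_inv = 1.0 / alpha
    B = np.eye(M) * sigma2 + (Phi * A_inv).T @ Phi  # sigma2*A + Phi'Phi scaled
    # use Woodbury: C = s2 I + Phi A^-1 Phi'
    # log|C| = n log s2 + log|I + Phi A^-1 Phi'/s2|
    H = np.eye(M) + (Phi * A_inv).T @ Phi / sigma2
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf
    logdet_C = n * np.log(sigma2) + logdet_H
    # y' C^-1 y = (y'y - y'Phi (A s2 + Phi'Phi)^-1 Phi'y) / s2
    G = np.diag(alpha) * sigma2 + Phi.T @ Phi
    try:
        w = linalg.solve(G, Phi.T @ y, assume_a="pos")
    except linalg.LinAlgError:
        w = np.linalg.lstsq(G, Phi.T @ y, rcond=None)[0]
    quad = (y @ y - y @ (Phi @ w)) / sigma2
    return -0.5 * (n * np.log(2 * np.pi) + logdet_C + quad)


def posterior_weights(
    Phi: np.ndarray,
    y: np.ndarray,
    alpha: np.ndarray,
    sigma2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior weight mean and covariance diagonal at fixed hyperparameters.

    ``mu = Sigma Phi' y / sigma2`` with
    ``Sigma = (diag(alpha) + Phi'Phi / sigma2)^-1``.  When all alphas share
    one value ``a``, ``mu`` coincides with the ridge solution
    ``(Phi'Phi + a sigma2 I)^-1 Phi' y``.
    """
    alpha = np.asarray(alpha, dtype=float)
    G = Phi.T @ Phi / sigma2 + np.diag(alpha) + _JITTER * np.eye(len(alpha))
    Pty = Phi.T @ y
    try:
        cf = linalg.cho_factor(G, lower=True)
        mu = linalg.cho_solve(cf, Pty) / sigma2
        Sigma_diag = np.diag(linalg.cho_solve(cf, np.eye(len(alpha))))
    except linalg.LinAlgError:
        Sigma = np.linalg.pinv(G)
        mu = Sigma @ Pty / sigma2
        Sigma_diag = np.diag(Sigma)
    return mu, Sigma_diag


def fit_rvr(
    X: np.ndarray,
    y: np.ndarray,
    cfg: KernelConfig = KernelConfig(),
    tol: float = 1e-3,
    max_iter: int = 500,
    alpha_prune: float = 1e9,
    gamma: float | None = None,
    track_evidence: bool = False,
) -> RVRModel:
    """Fit RVR on (X, y) by iterating the evidence fixed-point updates.

    Stops when ``max |delta log alpha| < tol`` or at ``max_iter``.  If every
    basis function is pruned — typical of data with no predictive signal —
    the model degrades to an intercept-only predictor of ``mean(y)`` and is
    flagged ``intercept_only``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, d = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 training samples, got {n}")
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")

    mean, sd = _standardize_params(X)
    Xs = (X - mean) / sd
    if cfg.kind == "rbf" and gamma is None:
        gamma = cfg.gamma if cfg.gamma is not None else median_heuristic_gamma(Xs)

    Phi_full = kernel_matrix(Xs, Xs, cfg, gamma=gamma)  # n x M
    M = Phi_full.shape[1]
    active = np.arange(M)
    alpha = np.full(M, 1.0 / n**2)
    var_y = float(np.var(y))
    sigma2 = 0.1 * var_y if var_y > 0 else 1e-6
    sigma2_floor = max(1e-12, 1e-9 * var_y)

    mu = np.zeros(M)
    converged = False
    history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        Phi = Phi_full[:, active]
        a = alpha[active]
        mu_a, Sigma_diag = posterior_weights(Phi, y, a, sigma2)

        g = 1.0 - a * Sigma_diag
        g = np.clip(g, 1e-12, None)
        mu2 = mu_a**2
        new_alpha = np.where(mu2 > 0, g / np.maximum(mu2, 1e-300), np.inf)

        resid = y - Phi @ mu_a
        denom = n - g.sum()
        if denom <= 1e-6:
            denom = 1e-6
        new_sigma2 = max(float(resid @ resid) / denom, sigma2_floor)

        keep = new_alpha < alpha_prune
        if not keep.any():
            fallback = float(y.mean())
            return RVRModel(
                kernel=cfg, gamma=gamma, feature_mean=mean, feature_sd=sd,
                X_train=Xs, relevance_idx=np.array([], dtype=int),
                mu=np.array([]), alpha=np.array([]), sigma2=new_sigma2,
                has_bias_term=False, bias_weight=fallback,
                converged=True, n_iter=it, intercept_only=True,
                fallback_value=fallback, evidence_history=history,
            )

        delta = np.abs(np.log(new_alpha[keep]) - np.log(a[keep]))
        alpha_new_full = np.full(M, np.inf)
        alpha_new_full[active] = new_alpha
        mu_full = np.zeros(M)
        mu_full[active] = mu_a

        active = active[keep]
        alpha = alpha_new_full
        mu = mu_full
        sigma2 = new_sigma2

        if track_evidence:
            history.append(
                _log_evidence(Phi_full[:, active], y, alpha[active], sigma2)
            )
        if delta.max() < tol:
            converged = True
            break

    bias_idx = M - 1 if cfg.include_bias else None
    has_bias = bias_idx is not None and bias_idx in active
    rv_mask = active != bias_idx if bias_idx is not None else np.ones(len(active), bool)
    rv_idx = active[rv_mask]
    mu_active = mu[active]
    return RVRModel(
        kernel=cfg, gamma=gamma, feature_mean=mean, feature_sd=sd,
        X_train=Xs, relevance_idx=rv_idx,
        mu=mu_active[rv_mask], alpha=alpha[active][rv_mask], sigma2=sigma2,
        has_bias_term=has_bias,
        bias_weight=float(mu[bias_idx]) if has_bias else 0.0,
        converged=converged, n_iter=it, evidence_history=history,
    )


def predict(
    model: RVRModel,
    X_new: np.ndarray,
    return_std: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Predict targets for new samples with a fitted model.

    ``f(x) = sum_{i in RV} mu_i k(x, x_i) + bias``; inputs are standardized
    with the training statistics.  With ``return_std`` the predictive SD
    ``sqrt(sigma2)`` is returned alongside (weight-posterior covariance is
    not stored, so this is the noise floor only).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError("feature dimension mismatch with training data")
    Xs = (X_new - model.feature_mean) / model.feature_sd
    if model.intercept_only or model.n_relevance_vectors == 0:
        pred = np.full(X_new.shape[0], model.fallback_value + (model.bias_weight if model.has_bias_term else 0.0))
        if model.intercept_only:
            pred = np.full(X_new.shape[0], model.fallback_value)
    else:
        rv_cfg = KernelConfig(kind=model.kernel.kind, gamma=model.gamma, include_bias=False)
        K = kernel_matrix(Xs, model.X_train[model.relevance_idx], rv_cfg, gamma=model.gamma)
        pred = K @ model.mu + (model.bias_weight if model.has_bias_term else 0.0)
    if return_std:
        return pred, np.full(len(pred), np.sqrt(model.sigma2))
    return pred


def mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, float).ravel()
    y_pred = np.asarray(y_pred, float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    return float(np.mean((y_true - y_pred) ** 2))
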