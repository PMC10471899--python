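"""Penalized beta regression of differential-expression P-values on gene-set membership.

The response is the vector Y of per-gene P-values, modeled as beta-distributed
with gene-specific mean mu_i and a shared precision phi (shape parameters
p_i = mu_i * phi, q_i = (1 - mu_i) * phi).  The mean is linked to term
membership through g(mu) = X beta, with a logit link by default, so the
coefficient beta_j measures how strongly membership in term j pulls P-values
away from the uniform null (mu = 1/2 at beta = 0).  Estimation minimizes

    -log L(beta, phi | Y, X) + lambda * ||beta||_1
        + psi * sum_{i,j} (beta_i - beta_j)^2 g_ij

where g_ij is a term-term similarity in [0, 1].  The double sum runs over all
ordered pairs, so each unordered pair is counted twice; psi values are only
comparable across implementations that use the same convention.  The L1 term
is handled by a proximal (soft-threshold) step so exact zeros are attainable;
phi is optimized on the log scale to enforce positivity.  lambda and psi are
chosen by cross-validation on held-out unpenalized log-likelihood.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln, logit

from .genesets import MembershipMatrix, SimilarityMatrix

__all__ = [
    "ResponseVector",
    "ModelConfig",
    "EnrichmentFit",
    "CrossValidationResult",
    "clamp_pvalues",
    "link_forward",
    "link_inverse",
    "beta_log_likelihood",
    "soft_threshold",
    "fusion_penalty",
    "objective",
    "fit",
    "cross_validate",
]


class FitDivergenceError(RuntimeError):
    """Raised when the optimizer encounters a non-finite objective."""


@dataclass(frozen=True)
class ResponseVector:
    """Per-gene P-values, clamped strictly inside (0, 1), with gene labels."""

    values: np.ndarray
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.shape[0] != len(self.gene_ids):
            raise ValueError("response length must match the number of gene labels")
        if not ((v > 0) & (v < 1)).all():
            bad = np.flatnonzero(~((v > 0) & (v < 1)))
            raise ValueError(
                f"response values must lie strictly in (0, 1); offending genes: "
                f"{[self.gene_ids[i] for i in bad[:5]]}"
            )
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the penalized beta-regression fit.

    lambda_ : weight of the L1 (sparsity) penalty on beta, >= 0.
    psi : weight of the network-fusion penalty, >= 0.
    link : link function for the mean; only "logit" is implemented.
    epsilon : boundary clamp applied to P-values before fitting.
    step_size : initial proximal-gradient step; adapted during the run
        (halved whenever a step would increase the objective).
    max_epochs, tol : stopping rule — converged when the relative objective
        change drops below tol.
    batch_size : optional mini-batch size for the likelihood gradient;
        None means full-batch.
    include_intercept : add an unpenalized intercept to the linear predictor.
    """

    lambda_: float = 0.0
    psi: float = 0.0
    link: str = "logit"
    epsilon: float = 1e-6
    step_size: float = 0.05
    max_epochs: int = 2000
    tol: float = 1e-6
    batch_size: int | None = None
    seed: int = 0
    include_intercept: bool = False

    def __post_init__(self) -> None:
        if self.lambda_ < 0 or self.psi < 0:
            raise ValueError("penalty weights must be non-negative")
        if not (0 < self.epsilon < 0.5):
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.tol <= 0 or self.step_size <= 0:
            raise ValueError("tol and step_size must be positive")
        if self.link != "logit":
            raise NotImplementedError(f"link {self.link!r} not implemented")


@dataclass(frozen=True)
class EnrichmentFit:
    """Result of a penalized beta-regression fit."""

    beta: np.ndarray
    phi: float
    intercept: float
    term_ids: tuple[str, ...]
    fitted_means: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    config: ModelConfig

    @property
    def shape_p(self) -> np.ndarray:
        """Per-gene first beta shape parameter mu_i * phi."""
        return self.fitted_means * self.phi

    @property
    def shape_q(self) -> np.ndarray:
        """Per-gene second beta shape parameter (1 - mu_i) * phi."""
        return (1.0 - self.fitted_means) * self.phi

    def coefficients(self) -> pd.Series:
        return pd.Series(self.beta, index=list(self.term_ids), name="beta")


def clamp_pvalues(raw, gene_ids, epsilon: float = 1e-6) -> ResponseVector:
    """Clamp raw P-values in [0, 1] into [epsilon, 1 - epsilon].

    The beta density is undefined at the boundaries, so exact 0/1 values
    (common after numeric underflow in upstream DE tests) are pulled in.
    """
    v = np.asarray(raw, dtype=float)
    gene_ids = tuple(gene_ids)
    bad = np.flatnonzero(~((v >= 0) & (v <= 1)))
    if bad.size:
        raise ValueError(
            f"raw P-values outside [0, 1] for genes {[gene_ids[i] for i in bad[:5]]}"
        )
    return ResponseVector(values=np.clip(v, epsilon, 1.0 - epsilon), gene_ids=gene_ids)


def link_forward(mu) -> np.ndarray:
    """Logit link: log(mu / (1 - mu)); requires mu strictly in (0, 1)."""
    mu = np.asarray(mu, dtype=float)
    if not ((mu > 0) & (mu < 1)).all():
        raise ValueError("link_forward requires inputs strictly in (0, 1)")
    return logit(mu)


def link_inverse(eta) -> np.ndarray:
    """Inverse logit (logistic): 1 / (1 + exp(-eta))."""
    return expit(np.asarray(eta, dtype=float))


def beta_log_likelihood(y, mu, phi: float) -> float:
    """Beta log-likelihood of responses y under means mu and shared precision phi.

    Sum over genes of log Beta(y_i; p_i, q_i) with p_i = mu_i*phi and
    q_i = (1-mu_i)*phi.
    """
    y = np.asarray(y.values if isinstance(y, ResponseVector) else y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have the same length")
    if not ((y > 0) & (y < 1)).all():
        raise ValueError("responses must lie strictly in (0, 1)")
    if not ((mu > 0) & (mu < 1)).all():
        raise ValueError("means must lie strictly in (0, 1)")
    if phi <= 0:
        raise ValueError("phi must be positive")
    p = mu * phi
    q = (1.0 - mu) * phi
    return float(
        np.sum(gammaln(p + q) - gammaln(p) - gammaln(q)
               + (p - 1.0) * np.log(y) + (q - 1.0) * np.log1p(-y))
    )


def soft_threshold(x, threshold: float) -> np.ndarray:
    """Proximal operator of the L1 norm: shrink toward zero by ``threshold``."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - threshold, 0.0)


def fusion_penalty(beta, similarity) -> float:
    """Network-fusion penalty sum_{i,j} (beta_i - beta_j)^2 g_ij over ordered pairs."""
    beta = np.asarray(beta, dtype=float)
    g = similarity.values if isinstance(similarity, SimilarityMatrix) else np.asarray(similarity)
    # ordered-pair double sum == 2 beta' L beta for symmetric g (diagonal cancels)
    row = g.sum(axis=1)
    return float(2.0 * (beta @ (row * beta) - beta @ (g @ beta)))


def objective(beta, phi: float, y, X, G, config: ModelConfig,
              intercept: float = 0.0) -> float:
    """Full objective: negative beta log-likelihood plus L1 and fusion penalties."""
    beta = np.asarray(beta, dtype=float)
    if not (np.isfinite(beta).all() and np.isfinite(phi) and phi > 0):
        raise FitDivergenceError("non-finite or non-positive parameters")
    x = X.values if isinstance(X, MembershipMatrix) else np.asarray(X, dtype=float)
    eta = x @ beta + intercept
    mu = expit(eta)
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    nll = -beta_log_likelihood(y, mu, phi)
    pen = config.lambda_ * float(np.abs(beta).sum()) + config.psi * fusion_penalty(beta, G)
    return nll + pen


def _loglik_grads(y: np.ndarray, x: np.ndarray, beta: np.ndarray, phi: float,
                  intercept: float) -> tuple[np.ndarray, float, float]:
    """Gradients of the log-likelihood w.r.t. beta, intercept and theta=log(phi)."""
    eta = x @ beta + intercept
    mu = expit(eta)
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    p = mu * phi
    q = (1.0 - mu) * phi
    logy = np.log(y)
    log1my = np.log1p(-y)
    # d loglik / d eta_i = phi * mu(1-mu) * [log(y/(1-y)) - psi(p) + psi(q)]
    score_eta = phi * mu * (1.0 - mu) * (logy - log1my - digamma(p) + digamma(q))
    grad_beta = x.T @ score_eta
    grad_intercept = float(score_eta.sum())
    # d loglik / d phi, then chain through theta = log(phi)
    dphi = (digamma(phi) - mu * digamma(p) - (1.0 - mu) * digamma(q)
            + mu * logy + (1.0 - mu) * log1my)
    grad_theta = float(phi * dphi.sum())
    return grad_beta, grad_intercept, grad_theta


def fit(y: ResponseVector, X: MembershipMatrix, G: SimilarityMatrix | None,
        config: ModelConfig | None = None) -> EnrichmentFit:
    """Fit the penalized beta regression by proximal gradient descent.

    Full-batch by default; with ``config.batch_size`` set, likelihood gradients
    are estimated on shuffled mini-batches (rescaled to the full-data scale)
    while the penalties and the once-per-epoch objective use all genes.  Steps
    that would increase the full objective are rejected and the step size is
    halved, so the recorded objective trace is non-increasing.  Reproducible
    given ``config.seed``.
    """
    config = config or ModelConfig()
    x = X.values
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 genes")
    col = x.sum(axis=0)
    if not (col > 0).any():
        raise ValueError("membership matrix has no nonzero column")
    yv = np.asarray(y.values, dtype=float)
    if len(y) != n or tuple(y.gene_ids) != tuple(X.gene_ids):
        raise ValueError("response and membership matrix gene labels differ")
    if G is None:
        g = np.zeros((k, k))
    else:
        if tuple(G.term_ids) != tuple(X.term_ids):
            raise ValueError("similarity and membership matrix term labels differ")
        g = G.values.copy()
    np.fill_diagonal(g, 0.0)
    lap = np.diag(g.sum(axis=1)) - g  # graph Laplacian of the similarity weights

    rng = np.random.default_rng(config.seed)
    beta = np.zeros(k)
    theta = 0.0  # log(phi), phi = 1 initially
    intercept = 0.0
    step = config.step_size

    def full_objective(b, th, b0):
        return objective(b, float(np.exp(th)), yv, x, g, config, intercept=b0)

    obj = full_objective(beta, theta, intercept)
    if not np.isfinite(obj):
        raise FitDivergenceError("objective not finite at initialization")
    trace = [obj]
    converged = False

    for epoch in range(config.max_epochs):
        if config.batch_size is None or config.batch_size >= n:
            batches = [np.arange(n)]
        else:
            order = rng.permutation(n)
            batches = np.array_split(order, int(np.ceil(n / config.batch_size)))

        new_beta, new_theta, new_intercept = beta, theta, intercept
        for idx in batches:
            phi = float(np.exp(new_theta))
            gb, gi, gt = _loglik_grads(yv[idx], x[idx], new_beta, phi, new_intercept)
            scale = n / len(idx)
            # smooth part of the objective: -loglik + fusion
            grad_beta = -scale * gb + config.psi * 4.0 * (lap @ new_beta)
            cand = soft_threshold(new_beta - step * grad_beta, step * config.lambda_)
            new_theta = new_theta + step * scale * gt / n  # theta step kept O(1)
            if config.include_intercept:
                new_intercept = new_intercept + step * scale * gi / n
            new_beta = cand

        try:
            new_obj = full_objective(new_beta, new_theta, new_intercept)
        except FitDivergenceError as err:
            raise FitDivergenceError(
                f"divergence at epoch {epoch}: {err}; try a smaller step_size"
            ) from err
        if not np.isfinite(new_obj):
            raise FitDivergenceError(
                f"objective became non-finite at epoch {epoch}; try a smaller step_size"
            )

        if new_obj > obj:
            # reject uphill move; retry the epoch with a smaller step
            step *= 0.5
            trace.append(obj)
            if step < 1e-14:
                converged = True
                break
            continue
        rel_change = abs(obj - new_obj) / max(1.0, abs(obj))
        beta, theta, intercept, obj = new_beta, new_theta, new_intercept, new_obj
        trace.append(obj)
        step *= 1.1  # cautiously re-grow after a successful epoch
        if rel_change < config.tol:
            converged = True
            break

    phi = float(np.exp(theta))
    mu = np.clip(expit(x @ beta + intercept), 1e-12, 1.0 - 1e-12)
    return EnrichmentFit(
        beta=beta,
        phi=phi,
        intercept=float(intercept),
        term_ids=tuple(X.term_ids),
        fitted_means=mu,
        objective_trace=np.asarray(trace),
        converged=converged,
        config=config,
    )


@dataclass(frozen=True)
class CrossValidationResult:
    """Selected regularization weights plus the full grid-score table."""

    lambda_: float
    psi: float
    table: pd.DataFrame  # columns: lambda, psi, mean_heldout_loglik, fold scores

    @property
    def best(self) -> tuple[float, float]:
        return (self.lambda_, self.psi)


def cross_validate(y: ResponseVector, X: MembershipMatrix, G: SimilarityMatrix | None,
                   lambda_grid=None, psi_grid=None, n_folds: int = 5,
                   seed: int = 0, config: ModelConfig | None = None) -> CrossValidationResult:
    """Select (lambda, psi) by K-fold cross-validation over genes.

    Genes are partitioned into ``n_folds`` disjoint folds by a seeded shuffle.
    Each grid cell is scored by the mean per-gene held-out unpenalized
    log-likelihood, averaged over folds; the best cell wins, with ties broken
    toward the smallest lambda, then the smallest psi (prefer sparsity).
    """
    from sklearn.model_selection import KFold

    if lambda_grid is None:
        lambda_grid = np.concatenate([[0.0], np.logspace(-4, 1, 7)])
    if psi_grid is None:
        psi_grid = np.concatenate([[0.0], np.logspace(-4, 1, 7)])
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    psi_grid = np.asarray(psi_grid, dtype=float)
    if lambda_grid.size == 0 or psi_grid.size == 0:
        raise ValueError("grids must be non-empty")
    n = len(y)
    if not (2 <= n_folds <= n):
        raise ValueError("need 2 <= n_folds <= number of genes")
    base = config or ModelConfig()

    splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(splitter.split(np.arange(n)))
    for _, test_idx in folds:
        if len(test_idx) < 2:
            raise ValueError("a fold has fewer than 2 genes; reduce n_folds")

    rows = []
    best: tuple[float, float] | None = None
    best_score = -np.inf
    for lam, psi in itertools.product(sorted(lambda_grid), sorted(psi_grid)):
        cfg = replace(base, lambda_=float(lam), psi=float(psi))
        fold_scores = []
        for train_idx, test_idx in folds:
            ytr = ResponseVector(values=y.values[train_idx],
                                 gene_ids=tuple(y.gene_ids[i] for i in train_idx))
            xtr = MembershipMatrix(values=X.values[train_idx],
                                   gene_ids=tuple(X.gene_ids[i] for i in train_idx),
                                   term_ids=X.term_ids)
            res = fit(ytr, xtr, G, cfg)
            eta = X.values[test_idx] @ res.beta + res.intercept
            mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
            ll = beta_log_likelihood(y.values[test_idx], mu, res.phi)
            fold_scores.append(ll / len(test_idx))
        mean_score = float(np.mean(fold_scores))
        rows.append({"lambda": float(lam), "psi": float(psi),
                     "mean_heldout_loglik": mean_score,
                     **{f"fold_{i}": s for i, s in enumerate(fold_scores)}})
        if mean_score > best_score:  # strict: earlier (smaller lam, psi) wins ties
            best_score = mean_score
            best = (float(lam), float(psi))
    assert best is not None
    return CrossValidationResult(lambda_=best[0], psi=best[1], table=pd.DataFrame(rows))
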