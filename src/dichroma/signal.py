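"""Phylogenetic signal of a scalar trait: Pagel's lambda with bootstrap CI.

The trait (here, per-species dichromatism) is modelled as multivariate
normal with mean mu * 1 and covariance sigma^2 * C_lambda, where C is the
Brownian-motion covariance of the tree (C_ij = depth of the most recent
common ancestor of tips i and j) and C_lambda multiplies its off-diagonal
elements by lambda in [0, 1]. lambda = 1 recovers pure Brownian motion,
lambda = 0 removes all phylogenetic covariance (independent tips with
variances equal to their root-to-tip depths). mu and sigma^2 are profiled
out analytically (GLS / ML), and lambda is found by bounded scalar
optimization of the profile likelihood. The confidence interval comes from
a parametric bootstrap: simulate from the fitted model, re-estimate lambda,
take percentile bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .trees import as_tree_index

__all__ = ["LambdaEstimate", "pagel_lambda"]


@dataclass
class LambdaEstimate:
    """Maximum-likelihood Pagel's lambda with parametric-bootstrap CI."""

    lambda_hat: float
    loglik: float
    mu: float
    sigma2: float
    ci_low: float | None = None
    ci_high: float | None = None
    R_boot: int = 0
    boot_values: np.ndarray | None = field(default=None, repr=False)


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _profile_loglik(y: np.ndarray, C: np.ndarray, lam: float):
    """ML profile log-likelihood of lambda, with mu and sigma^2 profiled."""
    n = y.size
    Cl = _lambda_cov(C, lam)
    try:
        L = linalg.cholesky(Cl, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(f"covariance not positive definite at lambda={lam}") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    z = linalg.solve_triangular(L, np.column_stack([y, np.ones(n)]), lower=True)
    zy, z1 = z[:, 0], z[:, 1]
    mu = float(zy @ z1) / float(z1 @ z1)
    r = zy - mu * z1
    sigma2 = float(r @ r) / n
    if sigma2 <= 0:
        raise ValueError("trait has zero variance; lambda is undefined")
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, mu, sigma2, L


def _fit_lambda(y: np.ndarray, C: np.ndarray, xatol: float = 1e-6):
    res = optimize.minimize_scalar(
        lambda lam: -_profile_loglik(y, C, lam)[0],
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": xatol},
    )
    # bounded search can stop short of a boundary optimum; compare explicitly
    candidates = [0.0, 1.0, float(res.x)]
    lls = [_profile_loglik(y, C, lam)[0] for lam in candidates]
    best = int(np.argmax(lls))
    return candidates[best], lls[best]


def pagel_lambda(tree, trait, R_boot: int = 0, seed=None, ci_level: float = 0.95) -> LambdaEstimate:
    """Estimate Pagel's lambda for a per-species scalar trait.

    Parameters
    ----------
    tree
        Tree / Newick / TreeIndex.
    trait
        Scalar value per tip: array in tip order or pandas Series indexed
        by species id.
    R_boot
        Parametric-bootstrap replicates for the CI (0 skips the CI).
    seed
        Seed for the bootstrap simulations.
    ci_level
        Two-sided percentile CI coverage (default 95%).
    """
    index = as_tree_index(tree)
    if index.n_tips < 4:
        raise ValueError("need at least 4 tips to estimate lambda")
    y = index.align_traits(trait).reshape(-1)
    C = index.mrca_matrix()

    lam_hat, ll = _fit_lambda(y, C)
    _, mu, sigma2, _ = _profile_loglik(y, C, lam_hat)
    est = LambdaEstimate(lambda_hat=lam_hat, loglik=ll, mu=mu, sigma2=sigma2)

    if R_boot > 0:
        rng = np.random.default_rng(seed)
        Lhat = linalg.cholesky(_lambda_cov(C, lam_hat), lower=True)
        boots = np.empty(R_boot)
        for r in range(R_boot):
            ystar = mu + np.sqrt(sigma2) * (Lhat @ rng.standard_normal(y.size))
            boots[r] = _fit_lambda(ystar, C)[0]
        alpha = (1.0 - ci_level) / 2.0
        est.ci_low = float(np.quantile(boots, alpha))
        est.ci_high = float(np.quantile(boots, 1 - alpha))
        est.R_boot = R_boot
        est.boot_values = boots
    return est
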