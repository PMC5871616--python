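"""Single-random-intercept generalized linear mixed models.

Maximum (marginal) likelihood for models of the form

    g(E[y_ij | u_i]) = x_ij' beta + u_i,    u_i ~ N(0, sigma^2)

with a Bernoulli response and logit link, or a negative-binomial (NB2)
response and log link with dispersion ``alpha`` (Var = mu + alpha mu^2).
The per-group integral over ``u`` is evaluated with Gauss-Hermite quadrature
(default 25 nodes), and the marginal log-likelihood is maximized with
L-BFGS-B over ``(beta, sigma[, log alpha])``. Standard errors come from the
inverse of a finite-difference Hessian at the optimum.

This is deliberately small: one random intercept, two families — exactly the
model class needed for the tactic, survival and recruitment analyses. A
variance estimate on the boundary (sigma ~ 0) is reported as 0 with a
``boundary`` flag rather than an error, and quasi-complete separation is
flagged via diverging coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = ["GLMMResult", "fit_glmm"]

_SEPARATION_BOUND = 15.0  # |logit coefficient| beyond this flags separation
_BOUNDARY_SIGMA = 1e-3


@dataclass
class GLMMResult:
    """Fitted mixed model: fixed effects, variance component, likelihood."""

    family: str
    names: list[str]
    beta: np.ndarray
    sigma: float
    alpha: float | None  # NB2 dispersion, None for binomial
    loglik: float
    cov_beta: np.ndarray
    se_beta: np.ndarray
    n_obs: int
    n_groups: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def sigma2(self) -> float:
        return self.sigma**2

    @property
    def n_params(self) -> int:
        extra = 1 if self.family == "binomial" else 2
        return len(self.beta) + extra

    def coef_table(self, level: float = 0.95) -> dict[str, dict[str, float]]:
        """Wald estimates, CIs, z and p per fixed effect (link scale)."""
        z = stats.norm.ppf(0.5 + level / 2)
        table = {}
        for i, name in enumerate(self.names):
            est, se = float(self.beta[i]), float(self.se_beta[i])
            zval = est / se if se > 0 else np.inf
            table[name] = {
                "estimate": est,
                "ci_low": est - z * se,
                "ci_high": est + z * se,
                "z": zval,
                "p": float(2 * stats.norm.sf(abs(zval))),
            }
        return table


def _bernoulli_logpmf(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # log f = y*eta - log(1 + exp(eta)), stable via logaddexp
    return y * eta - np.logaddexp(0.0, eta)


def _nb2_logpmf(y: np.ndarray, eta: np.ndarray, alpha: float) -> np.ndarray:
    mu = np.exp(eta)
    size = 1.0 / alpha
    return (
        special.gammaln(y + size)
        - special.gammaln(size)
        - special.gammaln(y + 1.0)
        + size * np.log(size / (size + mu))
        + y * np.log(mu / (size + mu))
    )


def _marginal_loglik(
    params: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    family: str,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> float:
    p = X.shape[1]
    beta = params[:p]
    sigma = params[p]
    eta0 = X @ beta
    # row x node linear predictor offsets: sqrt(2) * sigma * node
    offsets = np.sqrt(2.0) * sigma * nodes
    eta = eta0[:, None] + offsets[None, :]
    if family == "binomial":
        logp = _bernoulli_logpmf(y[:, None], eta)
    elif family == "negative_binomial":
        alpha = np.exp(params[p + 1])
        logp = _nb2_logpmf(y[:, None], eta, alpha)
    else:  # pragma: no cover - guarded in fit_glmm
        raise ValueError(family)
    # sum log-density within groups, then integrate over nodes
    group_logp = np.zeros((n_groups, nodes.size))
    np.add.at(group_logp, group_idx, logp)
    ll = special.logsumexp(group_logp + log_weights[None, :], axis=1)
    return float(ll.sum())


def _start_values(y, X, family):
    """Cheap fixed-effects start: IRLS-free ridge-regularized Newton steps."""
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(25):
        eta = X @ beta
        if family == "binomial":
            mu = special.expit(eta)
            W = np.clip(mu * (1 - mu), 1e-10, None)
        else:
            mu = np.exp(np.clip(eta, -30, 30))
            W = np.clip(mu, 1e-10, None)
        z = eta + (y - mu) / W
        XtW = X.T * W
        try:
            new = np.linalg.solve(XtW @ X + 1e-8 * np.eye(p), XtW @ z)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(new)):
            break
        if np.max(np.abs(new - beta)) < 1e-8:
            beta = new
            break
        beta = np.clip(new, -_SEPARATION_BOUND - 5, _SEPARATION_BOUND + 5)
    return beta


def fit_glmm(
    y,
    X,
    groups,
    family: str = "binomial",
    names: list[str] | None = None,
    n_quad: int = 25,
) -> GLMMResult:
    """Fit a GLMM with one random intercept by marginal maximum likelihood.

    Parameters
    ----------
    y, X : response vector and fixed-effects design matrix (with intercept).
    groups : grouping labels for the random intercept (one level per group).
    family : ``"binomial"`` (Bernoulli, logit) or ``"negative_binomial"``
        (NB2, log link; dispersion estimated, Poisson limit flagged).
    names : optional column names for the coefficient table.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if family not in ("binomial", "negative_binomial"):
        raise ValueError(f"unsupported family {family!r}")
    _, group_idx = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = int(group_idx.max()) + 1
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_weights = np.log(weights) - 0.5 * np.log(np.pi)

    beta0 = _start_values(y, X, family)
    x0 = np.concatenate([beta0, [0.5]])
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * p + [(0.0, 50.0)]
    if family == "negative_binomial":
        x0 = np.concatenate([x0, [np.log(0.5)]])
        bounds.append((np.log(1e-6), np.log(1e3)))

    def nll(params):
        val = _marginal_loglik(params, y, X, group_idx, n_groups, family, nodes, log_weights)
        return -val if np.isfinite(val) else 1e12

    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
    params = res.x
    beta = params[:p]
    sigma = float(params[p])
    alpha = float(np.exp(params[p + 1])) if family == "negative_binomial" else None

    flags: list[str] = []
    if not res.success:
        flags.append("non_convergence")
    if sigma < _BOUNDARY_SIGMA:
        flags.append("boundary")
        sigma = 0.0
    if np.any(np.abs(beta) > _SEPARATION_BOUND):
        flags.append("separation")
    if alpha is not None and alpha < 1e-4:
        flags.append("poisson_limit")

    # finite-difference Hessian of the negative loglik for Wald SEs
    cov_beta, se_beta = _wald_cov(nll, params, p, flags)

    return GLMMResult(
        family=family,
        names=list(names),
        beta=beta,
        sigma=sigma,
        alpha=alpha,
        loglik=float(-res.fun),
        cov_beta=cov_beta,
        se_beta=se_beta,
        n_obs=n,
        n_groups=n_groups,
        converged=bool(res.success),
        flags=flags,
    )


def _wald_cov(nll, params, p, flags):
    k = len(params)
    h = np.maximum(1e-5, 1e-5 * np.abs(params))
    H = np.zeros((k, k))
    f0 = nll(params)
    # central second differences on the full parameter vector
    fp = np.zeros(k)
    fm = np.zeros(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h[i]
        fp[i] = nll(params + e)
        fm[i] = nll(params - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = nll(params + ei + ej)
            fmm = nll(params - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm) / (
                2 * h[i] * h[j]
            )
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov)[:p] <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        if "unstable_hessian" not in flags:
            flags.append("unstable_hessian")
    cov_beta = cov[:p, :p]
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    return cov_beta, se
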