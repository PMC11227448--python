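"""Two-limit Tobit regression by maximum likelihood.

The observed response y_i in [0, 1] (a DEA efficiency score) is modelled
through a latent Gaussian variable

    y*_i = x_i beta + eps_i,   eps_i ~ N(0, sigma^2),

censored below at L = 0 and above at U = 1: y_i = L when y*_i <= L, y_i = U
when y*_i >= U, and y_i = y*_i otherwise.  The log-likelihood sums the
Gaussian density over interior observations and the corresponding normal
tail probabilities over the censored ones; tails are evaluated with
``log_ndtr`` for numerical stability.

Estimation maximizes the likelihood over (beta, log sigma) by BFGS with the
analytic score, initialized from least squares.  Standard errors come from
the inverse observed information (numerically differentiated analytic
gradient on the (beta, sigma) scale); the pseudo-R^2 is the squared Pearson
correlation between the linear predictor and the observed response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr, ndtr

_LOG_2PI = np.log(2.0 * np.pi)

#: driver taxonomy used for report tables
DRIVER_GROUPS = {
    "const": "/",
    "pop_density": "socio-economic",
    "n_lulc": "socio-economic",
    "slope_pct": "natural",
    "elev_m": "natural",
    "natura_share": "political",
    "road_density": "technological",
    "dist_heritage_m": "cultural",
}


@dataclass
class TobitFit:
    """Fitted two-limit Tobit model."""

    beta: np.ndarray
    sigma: float
    se: np.ndarray  # SEs for (beta..., sigma)
    loglik: float
    pseudo_r2: float
    names: list[str]
    n_obs: int
    n_lower: int
    n_upper: int
    converged: bool
    vif: pd.Series | None = None

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se[:-1]

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * (1.0 - ndtr(np.abs(self.z)))


def _split(y: np.ndarray, lower: float, upper: float):
    at_l = y <= lower
    at_u = y >= upper
    mid = ~(at_l | at_u)
    return at_l, mid, at_u


def loglik_two_limit(
    beta: np.ndarray,
    sigma: float,
    y: np.ndarray,
    X: np.ndarray,
    lower: float = 0.0,
    upper: float = 1.0,
) -> float:
    """Two-limit Tobit log-likelihood at (beta, sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    xb = X @ beta
    at_l, mid, at_u = _split(y, lower, upper)
    ll = 0.0
    if mid.any():
        z = (y[mid] - xb[mid]) / sigma
        ll += float(np.sum(-np.log(sigma) - 0.5 * _LOG_2PI - 0.5 * z**2))
    if at_l.any():
        ll += float(np.sum(log_ndtr((lower - xb[at_l]) / sigma)))
    if at_u.any():
        ll += float(np.sum(log_ndtr((xb[at_u] - upper) / sigma)))
    return ll


def _score_two_limit(beta, sigma, y, X, lower=0.0, upper=1.0):
    """Analytic gradient of the log-likelihood w.r.t. (beta, sigma)."""
    xb = X @ beta
    at_l, mid, at_u = _split(y, lower, upper)
    g_beta = np.zeros(X.shape[1])
    g_sigma = 0.0
    if mid.any():
        z = (y[mid] - xb[mid]) / sigma
        g_beta += X[mid].T @ z / sigma
        g_sigma += float(np.sum((z**2 - 1.0) / sigma))
    if at_l.any():
        a = (lower - xb[at_l]) / sigma
        # phi(a)/Phi(a), computed in log space
        ratio = np.exp(-0.5 * _LOG_2PI - 0.5 * a**2 - log_ndtr(a))
        g_beta += -X[at_l].T @ ratio / sigma
        g_sigma += float(np.sum(-a * ratio / sigma))
    if at_u.any():
        b = (xb[at_u] - upper) / sigma
        ratio = np.exp(-0.5 * _LOG_2PI - 0.5 * b**2 - log_ndtr(b))
        g_beta += X[at_u].T @ ratio / sigma
        g_sigma += float(np.sum(-b * ratio / sigma))
    return g_beta, g_sigma


def _check_design(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name offending columns via QR pivoting
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[j] for j in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient (collinear columns: {bad or 'unknown'})")


def fit_two_limit_tobit(
    y,
    X,
    names: list[str] | None = None,
    lower: float = 0.0,
    upper: float = 1.0,
    compute_vif: bool = True,
) -> TobitFit:
    """Maximum-likelihood fit of the two-limit Tobit model.

    ``X`` must include the constant column.  Raises when the design is rank
    deficient, when every observation is censored at a single limit, or when
    the optimizer fails to improve the likelihood.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if n <= k:
        raise ValueError(f"need more observations ({n}) than parameters ({k})")
    if np.any(y < lower - 1e-12) or np.any(y > upper + 1e-12):
        raise ValueError("responses outside the censoring limits")
    _check_design(X, list(names))
    at_l, mid, at_u = _split(y, lower, upper)
    if not mid.any():
        raise ValueError(
            "all observations censored "
            f"({int(at_l.sum())} at lower, {int(at_u.sum())} at upper limit); "
            "two-limit Tobit cannot be identified"
        )

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sigma0 = max(float(np.std(resid)), 1e-3)
    theta0 = np.concatenate([beta0, [np.log(sigma0)]])
    ll0 = loglik_two_limit(beta0, sigma0, y, X, lower, upper)

    def negll(theta):
        return -loglik_two_limit(theta[:-1], np.exp(theta[-1]), y, X, lower, upper)

    def grad(theta):
        sigma = np.exp(theta[-1])
        gb, gs = _score_two_limit(theta[:-1], sigma, y, X, lower, upper)
        return -np.concatenate([gb, [gs * sigma]])  # chain rule for log sigma

    res = optimize.minimize(negll, theta0, jac=grad, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-8})
    beta_hat = res.x[:-1]
    sigma_hat = float(np.exp(res.x[-1]))
    ll = -float(res.fun)
    if ll < ll0 - 1e-6:
        raise RuntimeError(
            f"Tobit optimizer failed to improve the likelihood ({ll:.4f} < {ll0:.4f}): "
            f"{res.message}"
        )

    # observed information on the (beta, sigma) scale
    se = _information_se(beta_hat, sigma_hat, y, X, lower, upper)
    pr2 = pseudo_r2_from_values(X @ beta_hat, y)
    vif_s = vif(X, names) if compute_vif and k > 2 else None
    return TobitFit(
        beta=beta_hat,
        sigma=sigma_hat,
        se=se,
        loglik=ll,
        pseudo_r2=pr2,
        names=list(names),
        n_obs=n,
        n_lower=int(at_l.sum()),
        n_upper=int(at_u.sum()),
        converged=bool(res.success),
        vif=vif_s,
    )


def _information_se(beta, sigma, y, X, lower, upper) -> np.ndarray:
    """SEs from the inverse observed information, with the Hessian obtained
    by central differences of the analytic score."""
    k = len(beta)
    theta = np.concatenate([beta, [sigma]])

    def score(t):
        gb, gs = _score_two_limit(t[:-1], t[-1], y, X, lower, upper)
        return np.concatenate([gb, [gs]])

    H = np.zeros((k + 1, k + 1))
    for j in range(k + 1):
        h = 1e-6 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (score(tp) - score(tm)) / (2.0 * h)
    H = 0.5 * (H + H.T)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise RuntimeError("observed information is singular") from exc
    d = np.diag(cov).copy()
    if np.any(d <= 0):
        raise RuntimeError("observed information is not positive definite")
    return np.sqrt(d)


def pseudo_r2_from_values(fitted: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation between fitted (latent) and observed values."""
    fitted = np.asarray(fitted, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(fitted) == 0 or np.std(y) == 0:
        raise ValueError("pseudo-R^2 undefined: constant fitted or observed values")
    r = np.corrcoef(fitted, y)[0, 1]
    return float(r**2)


def pseudo_r2(fit: TobitFit, y, X) -> float:
    return pseudo_r2_from_values(np.atleast_2d(np.asarray(X, float)) @ fit.beta, y)


def vif(X, names: list[str] | None = None) -> pd.Series:
    """Variance inflation factors, excluding the constant from the report.

    VIF_j = 1 / (1 - R^2_j) from regressing column j on the other covariates
    (with constant).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    _check_design(X, list(names))
    const_cols = [j for j in range(k) if np.all(X[:, j] == X[0, j])]
    out = {}
    for j in range(k):
        if j in const_cols:
            continue
        others = [c for c in range(k) if c != j]
        if not any(c in const_cols for c in others):
            Z = np.column_stack([X[:, others], np.ones(n)])
        else:
            Z = X[:, others]
        coef, *_ = np.linalg.lstsq(Z, X[:, j], rcond=None)
        resid = X[:, j] - Z @ coef
        ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[names[j]] = 1.0 / max(1.0 - r2, 1e-12)
    return pd.Series(out, name="vif")


def driver_table(fit: TobitFit, groups: dict[str, str] | None = None) -> pd.DataFrame:
    """Coefficient table: covariate, driver group, coefficient, SE, z, p, stars."""
    groups = groups or DRIVER_GROUPS
    unknown = [nm for nm in fit.names if nm not in groups]
    if unknown:
        raise ValueError(f"unknown covariate names (no driver group): {unknown}")

    def stars(p: float) -> str:
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""

    rows = []
    for j, nm in enumerate(fit.names):
        p = float(fit.p_values[j])
        rows.append(
            {
                "covariate": nm,
                "group": groups[nm],
                "coefficient": float(fit.beta[j]),
                "std_error": float(fit.se[j]),
                "z": float(fit.z[j]),
                "p_value": p,
                "sig": stars(p),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")
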