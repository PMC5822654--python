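"""Baseline OLS and the network autocorrelation (spatial lag) model.

The baseline is ordinary least squares with school-cluster-robust standard
errors.  The network model adds dependence through the friendship weight
matrix W:

    y = rho * W y + X beta + eps,      eps ~ N(0, sigma^2 I),

fitted by maximum likelihood.  The log-likelihood concentrates beta and
sigma^2 out, leaving a one-dimensional profile in the network-dependence
parameter rho:

    l_p(rho) = const - (n/2) log sigmahat^2(rho) + sum_i log|1 - rho lambda_i|,

where sigmahat^2(rho) = RSS(rho)/n from regressing (I - rho W) y on X and
lambda_i are the eigenvalues of W (complex moduli for a directed W).  rho is
found by bounded scalar optimisation over the feasible interval; the
asymptotic covariance of (rho, beta, sigma^2) comes from the negative
inverse numerical Hessian of the full log-likelihood at the optimum.

Model fit is compared by AIC = 2k - 2 loglik, counting intercept, slopes,
sigma^2 and (network model only) rho, so the network model carries exactly
one extra parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .network import WeightMatrix

__all__ = [
    "OLSFit",
    "NetworkFit",
    "fit_ols",
    "profile_loglik",
    "fit_network_model",
    "model_aic",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class OLSFit:
    beta: np.ndarray
    se: np.ndarray  # cluster-robust
    vcov_cluster: np.ndarray
    residuals: np.ndarray
    loglik: float
    aic: float
    n: int
    k: int  # parameter count incl. sigma^2
    names: list[str] = field(default_factory=list)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        zq = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.beta - zq * self.se, self.beta + zq * self.se])


@dataclass
class NetworkFit:
    rho: float
    beta: np.ndarray
    sigma2: float
    loglik: float
    aic: float
    vcov: np.ndarray  # asymptotic covariance of (rho, beta_0..beta_p)
    se_rho: float
    se_beta: np.ndarray
    feasible_interval: tuple[float, float]
    converged: bool
    n: int
    k: int
    names: list[str] = field(default_factory=list)

    def params(self) -> np.ndarray:
        """(rho, beta) stacked, matching the leading block of ``vcov``."""
        return np.concatenate([[self.rho], self.beta])

    def rho_conf_int(self, level: float = 0.95) -> tuple[float, float]:
        zq = stats.norm.ppf(0.5 + level / 2)
        return self.rho - zq * self.se_rho, self.rho + zq * self.se_rho

    def beta_conf_int(self, level: float = 0.95) -> np.ndarray:
        zq = stats.norm.ppf(0.5 + level / 2)
        return np.column_stack([self.beta - zq * self.se_beta, self.beta + zq * self.se_beta])


def _check_design(X: np.ndarray, names: list[str] | None) -> list[str]:
    names = names or [f"x{j}" for j in range(X.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the collinearity
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return names


def gaussian_loglik(resid: np.ndarray) -> float:
    """Profiled Gaussian log-likelihood with sigma^2 = RSS/n."""
    n = resid.size
    s2 = float(resid @ resid) / n
    return -0.5 * n * (_LOG2PI + np.log(s2) + 1.0)


def fit_ols(
    y: np.ndarray,
    X: np.ndarray,
    cluster_ids: np.ndarray,
    names: list[str] | None = None,
) -> OLSFit:
    """OLS with cluster-robust (sandwich) standard errors by school.

    The sandwich uses the standard small-sample factor
    G/(G-1) * (n-1)/(n-k).  The reported log-likelihood is the Gaussian
    maximum (sigma^2 = RSS/n) and AIC counts sigma^2 as a parameter.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    names = _check_design(X, names)
    if len(np.unique(cluster_ids)) < 2:
        raise ValueError("need at least two clusters")
    res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": cluster_ids})
    n, p = X.shape
    k = p + 1  # + sigma^2
    ll = gaussian_loglik(res.resid)
    return OLSFit(
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        vcov_cluster=np.asarray(res.cov_params()),
        residuals=np.asarray(res.resid),
        loglik=ll,
        aic=2 * k - 2 * ll,
        n=n,
        k=k,
        names=names,
    )


def _rss_beta(z: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    r = z - X @ beta
    return float(r @ r), beta


def profile_loglik(
    rho: float,
    y: np.ndarray,
    X: np.ndarray,
    W: WeightMatrix | np.ndarray,
    eigenvalues: np.ndarray | None = None,
) -> float:
    """Concentrated log-likelihood of the lag model at rho.

    The Jacobian term uses sum_i log|1 - rho lambda_i| over all eigenvalues
    of W (complex moduli for directed W); at rho = 0 this reduces exactly to
    the OLS Gaussian log-likelihood.
    """
    w = W.w if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)
    if eigenvalues is None:
        eigenvalues = W.eigenvalues() if isinstance(W, WeightMatrix) else np.linalg.eigvals(w)
    moduli = np.abs(1.0 - rho * eigenvalues)
    if np.any(moduli < 1e-12):
        raise ValueError(f"I - rho*W is singular at rho={rho}")
    n = y.size
    z = y - rho * (w @ y)
    rss, _ = _rss_beta(z, X)
    s2 = rss / n
    return -0.5 * n * (_LOG2PI + np.log(s2) + 1.0) + float(np.sum(np.log(moduli)))


def _full_loglik(theta: np.ndarray, y, X, w, eigenvalues) -> float:
    """Unconcentrated log-likelihood at theta = (rho, beta..., sigma2)."""
    rho, sigma2 = theta[0], theta[-1]
    beta = theta[1:-1]
    if sigma2 <= 0:
        return -np.inf
    moduli = np.abs(1.0 - rho * eigenvalues)
    if np.any(moduli < 1e-12):
        return -np.inf
    n = y.size
    r = y - rho * (w @ y) - X @ beta
    return (
        -0.5 * n * (_LOG2PI + np.log(sigma2))
        - 0.5 * float(r @ r) / sigma2
        + float(np.sum(np.log(moduli)))
    )


def _numerical_hessian(f, theta: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar f at theta."""
    p = theta.size
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f(theta) + f(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(theta + ei + ej) - f(theta + ei - ej) - f(theta - ei + ej) + f(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def fit_network_model(
    y: np.ndarray,
    X: np.ndarray,
    W: WeightMatrix,
    names: list[str] | None = None,
    rho_fixed: float | None = None,
    compute_vcov: bool = True,
    xatol: float = 1e-8,
) -> NetworkFit:
    """Maximum-likelihood fit of y = rho W y + X beta + eps.

    rho is found by Brent bounded search of the profile log-likelihood over
    the feasible interval of W intersected with (-0.999, 0.999); beta and
    sigma^2 follow in closed form.  ``rho_fixed`` skips the search (e.g. 0
    for the nested OLS model).  A solution at the interval boundary is
    reported with ``converged=False``, never silently.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    names = _check_design(X, names)
    if not W.standardised:
        raise ValueError("W must be row-standardised")
    n, p = X.shape
    lam = W.eigenvalues()
    lo, hi = W.feasible_interval()

    boundary = False
    if rho_fixed is not None:
        rho_hat = float(rho_fixed)
    else:
        res = optimize.minimize_scalar(
            lambda r: -profile_loglik(r, y, X, W.w, lam),
            bounds=(lo + 1e-6, hi - 1e-6),
            method="bounded",
            options={"xatol": xatol},
        )
        if not res.success:
            raise RuntimeError(f"rho optimisation failed: {res.message}")
        rho_hat = float(res.x)
        boundary = min(rho_hat - lo, hi - rho_hat) < 1e-4

    z = y - rho_hat * (W.w @ y)
    rss, beta_hat = _rss_beta(z, X)
    sigma2 = rss / n
    ll = profile_loglik(rho_hat, y, X, W.w, lam)
    k = p + 2  # beta (incl. intercept), sigma^2, rho

    vcov = np.full((p + 1, p + 1), np.nan)
    se_rho = np.nan
    se_beta = np.full(p, np.nan)
    if compute_vcov:
        theta = np.concatenate([[rho_hat], beta_hat, [sigma2]])
        H = _numerical_hessian(lambda t: _full_loglik(t, y, X, W.w, lam), theta)
        try:
            full_vcov = np.linalg.inv(-H)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("Hessian of the log-likelihood is singular") from exc
        vcov = full_vcov[: p + 1, : p + 1]
        diag = np.diag(vcov)
        if np.any(diag < 0):
            raise RuntimeError("negative variance from the Hessian; model did not converge")
        se_rho = float(np.sqrt(diag[0]))
        se_beta = np.sqrt(diag[1:])

    return NetworkFit(
        rho=rho_hat,
        beta=beta_hat,
        sigma2=sigma2,
        loglik=ll,
        aic=2 * k - 2 * ll,
        vcov=vcov,
        se_rho=se_rho,
        se_beta=se_beta,
        feasible_interval=(lo, hi),
        converged=not boundary,
        n=n,
        k=k,
        names=names,
    )


def model_aic(fit: OLSFit | NetworkFit) -> float:
    """AIC = 2k - 2 loglik with k counting all estimated parameters."""
    if not np.isfinite(fit.loglik):
        raise ValueError("log-likelihood is not finite")
    return 2 * fit.k - 2 * fit.loglik


def fits_table(
    ols: OLSFit, net: NetworkFit, level: float = 0.95
) -> pd.DataFrame:
    """Side-by-side coefficient table (baseline vs network model)."""
    rows = []
    ci_o = ols.conf_int(level)
    for j, name in enumerate(ols.names):
        rows.append(
            {"model": "baseline_ols", "term": name, "coefficient": ols.beta[j],
             "ci_low": ci_o[j, 0], "ci_high": ci_o[j, 1]}
        )
    rows.append({"model": "baseline_ols", "term": "AIC", "coefficient": ols.aic,
                 "ci_low": np.nan, "ci_high": np.nan})
    ci_n = net.beta_conf_int(level)
    for j, name in enumerate(net.names):
        rows.append(
            {"model": "network", "term": name, "coefficient": net.beta[j],
             "ci_low": ci_n[j, 0], "ci_high": ci_n[j, 1]}
        )
    r_lo, r_hi = net.rho_conf_int(level)
    rows.append({"model": "network", "term": "network_dependence", "coefficient": net.rho,
                 "ci_low": r_lo, "ci_high": r_hi})
    rows.append({"model": "network", "term": "AIC", "coefficient": net.aic,
                 "ci_low": np.nan, "ci_high": np.nan})
    return pd.DataFrame(rows)
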