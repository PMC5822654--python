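"""Direct / indirect ("spillover") / total impact decomposition.

In the network autocorrelation model a unit change in covariate k for every
child propagates through the friendship network: the equilibrium effect is
beta_k * M with M = (I - rho W)^{-1}.  Summarising in the usual averaged
form:

    direct_k   = beta_k * mean(diag M)          (effect on the child's own outcome)
    total_k    = beta_k * mean(row sums of M)   (effect summed over everyone)
    indirect_k = total_k - direct_k             (spillover onto friends of friends ...)

For a row-stochastic W with no zero rows the total has the closed form
beta_k / (1 - rho).  Confidence intervals follow the simulation approach:
draw parameter vectors from the multivariate normal at the ML estimates
with the fit's asymptotic covariance, recompute the impacts per draw, and
take the 2.5 and 97.5 percentiles of 200 draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import NetworkFit
from .network import WeightMatrix

__all__ = ["ImpactSummary", "impact_point_estimates", "impact_intervals", "impact_factors"]


@dataclass
class ImpactSummary:
    names: list[str]
    direct: np.ndarray
    indirect: np.ndarray
    total: np.ndarray
    direct_ci: np.ndarray | None = None  # (k, 2)
    indirect_ci: np.ndarray | None = None
    total_ci: np.ndarray | None = None
    n_sims: int = 0
    seed: int | None = None
    n_infeasible: int = 0
    n_zero_rows: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"term": self.names, "direct": self.direct, "indirect": self.indirect, "total": self.total}
        )
        if self.total_ci is not None:
            for label, ci in [
                ("direct", self.direct_ci), ("indirect", self.indirect_ci), ("total", self.total_ci)
            ]:
                df[f"{label}_ci_low"] = ci[:, 0]
                df[f"{label}_ci_high"] = ci[:, 1]
        return df


def impact_factors(rho: float, W: WeightMatrix) -> tuple[float, float]:
    """(mean diagonal, mean row sum) of M = (I - rho W)^{-1}.

    Computed per school block when W is block-diagonal (exact and cheap),
    else by one dense inverse.  Zero-weight rows contribute their M row
    (a unit diagonal) to the averages as-is.
    """
    n = W.n
    diag_sum = 0.0
    row_sum = 0.0
    if W.is_block_diagonal():
        for _, idx in W.blocks():
            m = np.linalg.inv(np.eye(idx.size) - rho * W.w[np.ix_(idx, idx)])
            diag_sum += float(np.trace(m))
            row_sum += float(m.sum())
    else:
        m = np.linalg.inv(np.eye(n) - rho * W.w)
        diag_sum = float(np.trace(m))
        row_sum = float(m.sum())
    return diag_sum / n, row_sum / n


def _covariate_index(fit: NetworkFit, covariates: list[str] | None) -> list[int]:
    if covariates is None:
        # skip the leading intercept by convention
        return list(range(1, fit.beta.size))
    return [fit.names.index(c) for c in covariates]


def impact_point_estimates(
    fit: NetworkFit, W: WeightMatrix, covariates: list[str] | None = None
) -> ImpactSummary:
    """Point impacts per covariate (default: every non-intercept term)."""
    if not fit.converged:
        raise ValueError("network fit did not converge; impacts undefined")
    if not W.standardised:
        raise ValueError("W must be row-standardised")
    lo, hi = W.feasible_interval()
    if not lo < fit.rho < hi:
        raise ValueError("rho outside the feasible interval; (I - rho W) singular")
    d_factor, t_factor = impact_factors(fit.rho, W)
    idx = _covariate_index(fit, covariates)
    beta = fit.beta[idx]
    direct = beta * d_factor
    total = beta * t_factor
    return ImpactSummary(
        names=[fit.names[j] for j in idx],
        direct=direct,
        indirect=total - direct,
        total=total,
        n_zero_rows=int(np.sum(W.row_sums() == 0)),
    )


def impact_intervals(
    fit: NetworkFit,
    W: WeightMatrix,
    n_sims: int = 200,
    seed: int = 0,
    covariates: list[str] | None = None,
    level: float = 0.95,
) -> ImpactSummary:
    """Impacts with percentile CIs from ``n_sims`` draws of (rho, beta).

    Draws come from the multivariate normal at the estimates with the fit's
    asymptotic covariance; draws with rho outside the feasible interval are
    discarded and counted (an error if they exceed half).
    """
    summary = impact_point_estimates(fit, W, covariates)
    vcov = fit.vcov
    if vcov is None or not np.all(np.isfinite(vcov)):
        raise ValueError("fit has no finite (rho, beta) covariance")
    # symmetrise and guard tiny negative eigenvalues from numerical Hessians
    vcov = 0.5 * (vcov + vcov.T)
    eigval, eigvec = np.linalg.eigh(vcov)
    if np.any(eigval < -1e-8 * max(eigval.max(), 1.0)):
        raise ValueError("(rho, beta) covariance is not positive semi-definite")
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))

    rng = np.random.default_rng(seed)
    mean = fit.params()
    draws = mean + rng.standard_normal((n_sims, mean.size)) @ root.T
    lo, hi = W.feasible_interval()
    feasible = (draws[:, 0] > lo) & (draws[:, 0] < hi)
    n_bad = int(n_sims - feasible.sum())
    if n_bad > n_sims / 2:
        raise ValueError(
            f"{n_bad}/{n_sims} draws had infeasible rho; the model likely fits poorly"
        )
    idx = _covariate_index(fit, covariates)
    kept = draws[feasible]
    direct = np.empty((kept.shape[0], len(idx)))
    total = np.empty_like(direct)
    for s, row in enumerate(kept):
        d_factor, t_factor = impact_factors(row[0], W)
        b = row[1:][np.asarray(idx)]
        direct[s] = b * d_factor
        total[s] = b * t_factor
    indirect = total - direct

    q = [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)]
    summary.direct_ci = np.percentile(direct, q, axis=0).T
    summary.indirect_ci = np.percentile(indirect, q, axis=0).T
    summary.total_ci = np.percentile(total, q, axis=0).T
    summary.n_sims = n_sims
    summary.seed = seed
    summary.n_infeasible = n_bad
    return summary
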