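"""Multiple imputation by chained equations and Rubin's-rules pooling.

Missing covariates and accelerometer outcomes are multiply imputed by
"regression switching": each modelled variable is imputed in turn from a
linear regression on all the others (with the child's school entered as
categorical indicators), cycling a fixed number of times per completed
dataset.  Draws propagate both parameter uncertainty (a Bayesian draw of
the regression coefficients and residual variance) and residual noise.
Ordinal questionnaire items are drawn the same way then rounded and bounded
to their 0-3 range; the 0-12 activity participation score is imputed
passively, i.e. recomputed as the item sum in every completed dataset.
Imputation is run separately per sex stratum.

Downstream fits run once per completed dataset and are pooled with Rubin's
rules: pooled estimate = mean, total variance = within + (1 + 1/m) between,
with Rubin's small-sample degrees of freedom for the t-based CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ImputedStack",
    "PooledFit",
    "chained_imputation",
    "passive_score",
    "pool_rubin",
]

ITEM_COLS = ["item1", "item2", "item3", "item4"]


@dataclass
class ImputedStack:
    m: int
    datasets: list[pd.DataFrame]
    n_cycles: int
    seed: int
    imputed_mask: pd.DataFrame  # True where a cell was imputed


@dataclass
class PooledFit:
    names: list[str]
    estimate: np.ndarray  # qbar
    within: np.ndarray  # Wbar (diagonal)
    between: np.ndarray  # B (diagonal)
    total_variance: np.ndarray  # T = Wbar + (1+1/m) B
    df: np.ndarray
    ci: np.ndarray  # (p, 2)
    m: int
    vcov: np.ndarray | None = None  # pooled full covariance matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.estimate,
                "se": np.sqrt(self.total_variance),
                "ci_low": self.ci[:, 0],
                "ci_high": self.ci[:, 1],
                "df": self.df,
            }
        )


def passive_score(items: pd.DataFrame) -> pd.Series:
    """Activity participation score = sum of the four 0-3 items.

    Items outside [0, 3] are clipped (can only arise from imputation noise);
    the score itself is never imputed directly.
    """
    clipped = items[ITEM_COLS].clip(0, 3)
    return clipped.sum(axis=1)


def _bayes_linear_draw(
    X: np.ndarray, y: np.ndarray, X_mis: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw imputations from the posterior predictive of a normal-linear
    regression (non-informative prior)."""
    n, p = X.shape
    xtx = X.T @ X + 1e-8 * np.eye(p)  # tiny ridge guards near-collinearity
    xtx_inv = np.linalg.inv(xtx)
    beta_hat = xtx_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2_star = float(resid @ resid) / rng.chisquare(dof)
    beta_star = rng.multivariate_normal(beta_hat, sigma2_star * xtx_inv, method="cholesky")
    return X_mis @ beta_star + rng.normal(0.0, np.sqrt(sigma2_star), size=X_mis.shape[0])


def _impute_stratum(
    data: pd.DataFrame,
    variables: list[str],
    predictors: list[str],
    school_col: str,
    m: int,
    n_cycles: int,
    rng: np.random.Generator,
    ordinal: dict[str, tuple[float, float]],
    pmm: bool,
) -> list[pd.DataFrame]:
    miss = {v: data[v].isna().to_numpy() for v in variables}
    for v in variables:
        if miss[v].all():
            raise ValueError(f"variable {v!r} is 100% missing; cannot impute")
    school_dummies = pd.get_dummies(data[school_col], drop_first=True, dtype=float)

    out = []
    for _ in range(m):
        work = data.copy()
        # initialise missing cells from the observed marginal
        for v in variables:
            obs = work.loc[~miss[v], v].to_numpy()
            if miss[v].any():
                work.loc[miss[v], v] = rng.choice(obs, size=int(miss[v].sum()), replace=True)
        for _cycle in range(n_cycles):
            for v in variables:
                if not miss[v].any():
                    continue
                others = [u for u in variables if u != v] + predictors
                Xfull = np.column_stack(
                    [np.ones(len(work))]
                    + [work[u].to_numpy(dtype=float) for u in others]
                    + ([school_dummies.to_numpy()] if school_dummies.shape[1] else [])
                )
                obs_idx = ~miss[v]
                draws = _bayes_linear_draw(
                    Xfull[obs_idx], work.loc[obs_idx, v].to_numpy(dtype=float),
                    Xfull[miss[v]], rng,
                )
                if pmm:
                    # predictive-mean matching: borrow the nearest observed value
                    obs_vals = work.loc[obs_idx, v].to_numpy(dtype=float)
                    order = np.argsort(obs_vals)
                    pos = np.searchsorted(obs_vals[order], draws).clip(0, obs_vals.size - 1)
                    draws = obs_vals[order][pos]
                if v in ordinal:
                    lo, hi = ordinal[v]
                    draws = np.clip(np.round(draws), lo, hi)
                work.loc[miss[v], v] = draws
        if set(ITEM_COLS) <= set(work.columns) and "activity_score" in work.columns:
            work["activity_score"] = passive_score(work)
        out.append(work)
    return out


def chained_imputation(
    data: pd.DataFrame,
    variables: list[str] | None = None,
    m: int = 20,
    n_cycles: int = 20,
    seed: int = 0,
    school_col: str = "school_id",
    stratify_col: str | None = "sex",
    predictors: list[str] | None = None,
    pmm: bool = False,
) -> ImputedStack:
    """Create ``m`` completed datasets by chained-equation imputation.

    ``variables`` are the modelled (imputable) columns, defaulting to every
    numeric column with at least one missing value except the passive
    activity score.  The variable ordering within a cycle is fixed:
    covariates, items, outcomes (the order given).  Observed cells are never
    altered.
    """
    if m < 1 or n_cycles < 1:
        raise ValueError("m and n_cycles must be >= 1")
    if variables is None:
        order = ["bmi_z", "imd"] + ITEM_COLS + ["mean_mvpa", "mean_sedentary"]
        variables = [v for v in order if v in data.columns and data[v].isna().any()]
    missing_elsewhere = [
        v for v in variables if v not in data.columns
    ]
    if missing_elsewhere:
        raise ValueError(f"variables not in data: {missing_elsewhere}")
    predictors = [] if predictors is None else predictors
    ordinal = {c: (0.0, 3.0) for c in ITEM_COLS if c in variables}

    rng = np.random.default_rng(seed)
    if stratify_col is not None and stratify_col in data.columns:
        strata = sorted(data[stratify_col].dropna().unique())
        per_stratum = {}
        for s in strata:
            sub = data[data[stratify_col] == s]
            per_stratum[s] = _impute_stratum(
                sub, variables, predictors, school_col, m, n_cycles, rng, ordinal, pmm
            )
        datasets = [
            pd.concat([per_stratum[s][i] for s in strata]).loc[data.index]
            for i in range(m)
        ]
    else:
        datasets = _impute_stratum(
            data, variables, predictors, school_col, m, n_cycles, rng, ordinal, pmm
        )

    mask = pd.DataFrame(False, index=data.index, columns=data.columns)
    for v in variables:
        mask[v] = data[v].isna()
    if "activity_score" in data.columns:
        mask["activity_score"] = data["activity_score"].isna()
    return ImputedStack(m=m, datasets=datasets, n_cycles=n_cycles, seed=seed, imputed_mask=mask)


def pool_rubin(
    estimates: np.ndarray,
    vcovs: np.ndarray | list[np.ndarray],
    names: list[str] | None = None,
    level: float = 0.95,
) -> PooledFit:
    """Pool per-dataset estimates with Rubin's rules.

    ``estimates`` is (m, p); ``vcovs`` is (m, p, p) full covariance matrices
    or (m, p) variance rows.  Degrees of freedom use Rubin's small-sample
    formula df = (m-1)(1 + Wbar/((1+1/m)B))^2, infinite when B = 0.
    """
    est = np.asarray(estimates, dtype=float)
    if est.ndim != 2 or est.shape[0] < 2:
        raise ValueError("need an (m, p) array of estimates with m >= 2")
    m, p = est.shape
    V = np.asarray(vcovs, dtype=float)
    if V.shape == (m, p):
        V = np.stack([np.diag(v) for v in V])
    if V.shape != (m, p, p):
        raise ValueError("vcovs must be (m, p, p) or (m, p); parameter lists must match")
    names = names or [f"p{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("names length must match the parameter count")

    qbar = est.mean(axis=0)
    wbar_mat = V.mean(axis=0)
    dev = est - qbar
    b_mat = dev.T @ dev / (m - 1)
    t_mat = wbar_mat + (1 + 1 / m) * b_mat

    wbar = np.diag(wbar_mat)
    b = np.diag(b_mat)
    t = np.diag(t_mat)
    with np.errstate(divide="ignore"):
        r = (1 + 1 / m) * b / wbar
        df = np.where(b > 0, (m - 1) * (1 + 1 / r) ** 2, np.inf)
    q = np.where(np.isfinite(df), stats.t.ppf(0.5 + level / 2, np.clip(df, 1, None)),
                 stats.norm.ppf(0.5 + level / 2))
    half = q * np.sqrt(t)
    ci = np.column_stack([qbar - half, qbar + half])
    return PooledFit(
        names=list(names), estimate=qbar, within=wbar, between=b,
        total_variance=t, df=df, ci=ci, m=m, vcov=t_mat,
    )
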