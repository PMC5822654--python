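"""End-to-end study pipeline.

Orchestrates: simulate or ingest -> accelerometer reduction -> per-sex
network construction -> Moran diagnostics -> baseline OLS -> network
autocorrelation model -> impact decomposition -> (when data are
incomplete) multiple imputation wrapping the fits with Rubin pooling ->
model-comparison outputs.  Nominations are never imputed, so the network
is fixed across imputations.  Every artefact is written with a manifest
recording the configuration and seeds; identical inputs and seeds give
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import accelerometry, impacts, imputation, models, moran
from .network import (
    FriendshipNetwork,
    WeightMatrix,
    build_weight_matrix,
    filter_same_sex,
    match_nominations,
    prune_isolates,
)
from .synthetic import COVARIATES, SimulationConfig, generate_study

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StratumResult", "run_study", "export_network", "analyse_stratum"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    outdir: str | Path
    sim: SimulationConfig | None = None
    roster_path: str | Path | None = None
    nominations_path: str | Path | None = None
    epochs_path: str | Path | None = None
    strata: tuple[str, ...] = ("F", "M")
    outcomes: tuple[str, ...] = ("mean_mvpa", "mean_sedentary")
    covariates: tuple[str, ...] = tuple(COVARIATES)
    centre_outcome: bool = True
    m: int = 20
    n_cycles: int = 20
    n_perm: int = 999
    n_sims: int = 200
    seed: int = 0
    overwrite: bool = False

    def validate(self) -> None:
        if self.sim is None and (self.roster_path is None or self.nominations_path is None):
            raise ValueError("provide either a simulation config or roster+nominations paths")
        for name in ("m", "n_cycles", "n_sims"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")


@dataclass
class StratumResult:
    stratum: str
    outcome: str
    n: int
    moran_raw: moran.MoranResult
    ols: models.OLSFit
    moran_residual: moran.MoranResult
    net: models.NetworkFit
    impact: impacts.ImpactSummary | None
    pooled: imputation.PooledFit | None = None
    moran_residual_mi: dict | None = None
    aic_baseline: float = float("nan")
    aic_network: float = float("nan")


def _design(df: pd.DataFrame, covariates: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates])
    return X, ["const"] + list(covariates)


def build_stratum_network(
    roster: pd.DataFrame, nominations: pd.DataFrame, stratum: str
) -> tuple[FriendshipNetwork, WeightMatrix, dict]:
    """Match -> same-sex filter -> isolate pruning -> row-standardised W."""
    net_all, match_report = match_nominations(nominations, roster)
    per_sex, sex_report = filter_same_sex(net_all)
    if stratum not in per_sex:
        raise ValueError(f"no children of sex {stratum!r}")
    pruned, prune_report = prune_isolates(per_sex[stratum])
    W = build_weight_matrix(pruned, standardise=True)
    reports = {
        "n_nominated": match_report.n_nominated,
        "n_matched": match_report.n_matched,
        "n_opposite_sex_removed": sex_report.n_removed,
        "fraction_opposite_sex": sex_report.fraction_removed,
        "n_isolates_removed": prune_report.n_removed,
    }
    return pruned, W, reports


def analyse_stratum(
    data: pd.DataFrame,
    W: WeightMatrix,
    outcome: str,
    covariates: tuple[str, ...],
    centre_outcome: bool = True,
    n_perm: int = 999,
    n_sims: int = 200,
    seed: int = 0,
    stratum: str = "",
    compute_impacts: bool = True,
) -> StratumResult:
    """Complete-data analysis of one sex stratum and one outcome."""
    df = data.set_index("child_id").loc[W.ids]
    y = df[outcome].to_numpy(dtype=float)
    if centre_outcome:
        y = y - y.mean()
    X, names = _design(df, covariates)
    schools = df["school_id"].to_numpy()

    m_raw = moran.morans_i_test(y, W, n_perm=n_perm, seed=seed)
    ols = models.fit_ols(y, X, schools, names=names)
    m_res = moran.morans_i_test(ols.residuals, W, n_perm=n_perm, seed=seed + 1)
    net = models.fit_network_model(y, X, W, names=names)
    imp = impacts.impact_intervals(net, W, n_sims=n_sims, seed=seed + 2) if compute_impacts else None
    return StratumResult(
        stratum=stratum,
        outcome=outcome,
        n=len(df),
        moran_raw=m_raw,
        ols=ols,
        moran_residual=m_res,
        net=net,
        impact=imp,
        aic_baseline=ols.aic,
        aic_network=net.aic,
    )


def analyse_stratum_mi(
    stack: imputation.ImputedStack,
    W: WeightMatrix,
    outcome: str,
    covariates: tuple[str, ...],
    centre_outcome: bool = True,
    n_perm: int = 999,
    n_sims: int = 200,
    seed: int = 0,
    stratum: str = "",
) -> StratumResult:
    """Run the stratum analysis on every completed dataset and pool.

    The pooled (rho, beta) and their Rubin total covariance feed a single
    impact-interval computation; the residual Moran's I is summarised as the
    median across imputations plus the fraction significant at 0.05.
    """
    fits: list[models.NetworkFit] = []
    moran_is: list[float] = []
    moran_ps: list[float] = []
    aic_ols: list[float] = []
    aic_net: list[float] = []
    last = None
    for i, ds in enumerate(stack.datasets):
        res = analyse_stratum(
            ds, W, outcome, covariates, centre_outcome=centre_outcome,
            n_perm=n_perm, seed=seed + 10 * i, stratum=stratum, compute_impacts=False,
        )
        fits.append(res.net)
        moran_is.append(res.moran_residual.I)
        moran_ps.append(res.moran_residual.p_value)
        aic_ols.append(res.ols.aic)
        aic_net.append(res.net.aic)
        last = res

    est = np.stack([f.params() for f in fits])
    vcovs = np.stack([f.vcov for f in fits])
    names = ["network_dependence"] + fits[0].names
    pooled = imputation.pool_rubin(est, vcovs, names=names)

    # impacts at the pooled estimates with the pooled covariance
    pooled_fit = dataclasses.replace(
        fits[0],
        rho=float(pooled.estimate[0]),
        beta=pooled.estimate[1:],
        vcov=pooled.vcov,
        se_rho=float(np.sqrt(pooled.total_variance[0])),
        se_beta=np.sqrt(pooled.total_variance[1:]),
    )
    imp = impacts.impact_intervals(pooled_fit, W, n_sims=n_sims, seed=seed + 1)

    result = dataclasses.replace(
        last,
        net=pooled_fit,
        impact=imp,
        pooled=pooled,
        moran_residual_mi={
            "median_I": float(np.median(moran_is)),
            "fraction_significant": float(np.mean(np.asarray(moran_ps) < 0.05)),
            "m": stack.m,
        },
        aic_baseline=float(np.mean(aic_ols)),
        aic_network=float(np.mean(aic_net)),
    )
    return result


def export_network(
    network: FriendshipNetwork, summaries: pd.DataFrame, outdir: str | Path, prefix: str = "network"
) -> None:
    """GraphML + node/edge CSVs with activity attributes for plotting."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = network.graph.copy()
    lookup = summaries.set_index("child_id")
    node_rows = []
    for node in g.nodes:
        attrs = g.nodes[node]
        for col in ("mean_mvpa", "mean_sedentary"):
            if node in lookup.index and col in lookup.columns and pd.notna(lookup.at[node, col]):
                g.nodes[node][col] = float(lookup.at[node, col])
            else:
                logger.info("node %s has no %s summary; attribute omitted", node, col)
        node_rows.append({"child_id": node, **g.nodes[node]})
    nx.write_graphml(g, outdir / f"{prefix}.graphml")
    pd.DataFrame(node_rows).to_csv(outdir / f"{prefix}_nodes.csv", index=False)
    edges = pd.DataFrame(
        [
            {
                "source": u,
                "target": v,
                "school": g.nodes[u]["school"],
                "sex": g.nodes[u]["sex"],
            }
            for u, v in g.edges
        ]
    )
    edges.to_csv(outdir / f"{prefix}_edges.csv", index=False)


def _result_json(res: StratumResult) -> dict:
    out = {
        "stratum": res.stratum,
        "outcome": res.outcome,
        "n": res.n,
        "moran_raw": {"I": res.moran_raw.I, "p_value": res.moran_raw.p_value},
        "moran_residual": {"I": res.moran_residual.I, "p_value": res.moran_residual.p_value},
        "ols": {
            "terms": res.ols.names,
            "beta": res.ols.beta.tolist(),
            "se": res.ols.se.tolist(),
            "aic": res.aic_baseline,
        },
        "network": {
            "rho": res.net.rho,
            "rho_se": res.net.se_rho,
            "rho_ci": list(res.net.rho_conf_int()),
            "terms": res.net.names,
            "beta": res.net.beta.tolist(),
            "beta_se": res.net.se_beta.tolist(),
            "aic": res.aic_network,
            "converged": res.net.converged,
        },
        "aic_improvement": res.aic_baseline - res.aic_network,
        "impacts": res.impact.to_frame().to_dict(orient="records"),
    }
    if res.moran_residual_mi is not None:
        out["moran_residual_mi"] = res.moran_residual_mi
    if res.pooled is not None:
        out["pooled"] = res.pooled.to_frame().to_dict(orient="records")
    return out


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artefacts.

    Returns the result bundle (also written as JSON files under
    ``config.outdir``).
    """
    config.validate()
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not config.overwrite:
        raise FileExistsError(f"{outdir} is not empty; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------ inputs
    if config.sim is not None:
        study = generate_study(config.sim)
        roster = study.observed
        nominations = study.nominations
        epochs = None
    else:
        roster = pd.read_csv(config.roster_path)
        nominations = pd.read_csv(config.nominations_path)
        epochs = pd.read_csv(config.epochs_path) if config.epochs_path else None

    if epochs is not None:
        day_summ, child_summ = accelerometry.process_epochs(epochs)
        day_summ.to_csv(outdir / "day_summaries.csv", index=False)
        child_summ.to_csv(outdir / "child_summaries.csv", index=False)
        roster = roster.drop(columns=["mean_mvpa", "mean_sedentary"], errors="ignore").merge(
            child_summ[["child_id", "mean_mvpa", "mean_sedentary"]], on="child_id", how="left"
        )

    # ------------------------------------------------- per-stratum loops
    results: dict[str, dict] = {}
    bundle_results = []
    for s_idx, stratum in enumerate(config.strata):
        sub = roster[roster["sex"] == stratum].reset_index(drop=True)
        network, W, reports = build_stratum_network(roster, nominations, stratum)
        in_net = sub[sub["child_id"].isin(W.ids)].reset_index(drop=True)

        export_network(network, in_net, outdir, prefix=f"network_{stratum}")
        W.to_triplets().to_csv(outdir / f"weight_matrix_{stratum}.csv", index=False)
        pd.DataFrame({"child_id": W.ids}).to_csv(outdir / f"node_order_{stratum}.csv", index=False)

        model_cols = list(config.covariates) + [
            c for c in ("bmi_z", "imd") if c not in config.covariates
        ] + list(config.outcomes)
        has_missing = in_net[model_cols].isna().any().any()
        stack = None
        if has_missing:
            stack = imputation.chained_imputation(
                in_net, m=config.m, n_cycles=config.n_cycles,
                seed=config.seed + 1000 + s_idx, stratify_col=None,
            )

        for o_idx, outcome in enumerate(config.outcomes):
            seed = config.seed + 100 * s_idx + 10 * o_idx
            if has_missing:
                res = analyse_stratum_mi(
                    stack, W, outcome, config.covariates,
                    centre_outcome=config.centre_outcome,
                    n_perm=config.n_perm, n_sims=config.n_sims,
                    seed=seed, stratum=stratum,
                )
                scatter_data = stack.datasets[0]
            else:
                res = analyse_stratum(
                    in_net, W, outcome, config.covariates,
                    centre_outcome=config.centre_outcome,
                    n_perm=config.n_perm, n_sims=config.n_sims,
                    seed=seed, stratum=stratum,
                )
                scatter_data = in_net
            key = f"{stratum}_{outcome}"
            results[key] = _result_json(res)
            results[key]["network_reports"] = reports
            bundle_results.append(res)

            y = scatter_data.set_index("child_id").loc[W.ids, outcome].to_numpy(dtype=float)
            moran.moran_scatter(y, W).to_csv(outdir / f"moran_scatter_{key}.csv", index=False)
            models.fits_table(res.ols, res.net).to_csv(outdir / f"fits_table_{key}.csv", index=False)
            res.impact.to_frame().to_csv(outdir / f"impacts_table_{key}.csv", index=False)

    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)

    manifest = {
        "config": _config_dict(config),
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True).encode()
        ).hexdigest(),
        "n_children": int(len(roster)),
        "strata": list(config.strata),
        "outcomes": list(config.outcomes),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"results": results, "manifest": manifest, "stratum_results": bundle_results}


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("outdir", "roster_path", "nominations_path", "epochs_path"):
        if d[key] is not None:
            d[key] = str(d[key])
    return d
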