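"""Synthetic cohort generator for school friendship-network activity studies.

Emulates the data structure of a cross-sectional cohort of ~1200 children
aged 8-9 in ~47 primary schools: a roster with covariates (BMI z-score, area
deprivation, a 0-12 activity participation score built from four 0-3 items),
friend nominations (up to 4, within school, ~90% same-sex), 10-second epoch
accelerometer count series, and activity outcomes (mean daily MVPA and
sedentary minutes) generated from the network autocorrelation model

    y = rho * W y + X beta + u + eps,

with school random intercepts u and iid Gaussian eps, solved exactly via the
reduced form y = (I - rho W)^{-1} (X beta + u + eps).  Missingness is
missing-at-random, driven by sex and the school's leave-one-out mean
outcome, never by the deleted value itself.

All generation is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import WeightMatrix, build_weight_matrix, filter_same_sex, match_nominations

__all__ = [
    "SimulationConfig",
    "ActivityProfile",
    "EpochSeries",
    "SyntheticStudy",
    "generate_roster",
    "generate_nominations",
    "generate_outcomes",
    "apply_missingness",
    "generate_epoch_series",
    "generate_study",
    "study_weight_matrix",
    "write_study",
]

ITEM_COLS = ["item1", "item2", "item3", "item4"]
#: covariate order matching the ``beta`` coefficient vectors
COVARIATES = ["imd", "bmi_z", "activity_score"]


def _default_missing_rates() -> dict[str, float]:
    # spans the reported per-variable range, 0.5% (BMI z) to 18% (sedentary)
    return {
        "bmi_z": 0.005,
        "imd": 0.03,
        "item1": 0.02,
        "item2": 0.02,
        "item3": 0.02,
        "item4": 0.02,
        "mean_mvpa": 0.14,
        "mean_sedentary": 0.18,
    }


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic study.

    Defaults reproduce the shape of the motivating cohort: 47 schools,
    ~26 children per school, 55% girls, nominations of 2-4 friends with 90%
    same-sex ties.  MVPA outcomes use rho = 0.20, slopes (per covariate
    unit) for IMD, BMI z and activity score near the motivating cohort's reported boys' MVPA
    model, and residual SD 15.5 min/day; sedentary-time outcomes use
    rho = 0.14 and residual SD 37 min/day.
    """

    n_schools: int = 47
    children_per_school: int | tuple[int, int] = (18, 34)
    p_female: float = 0.55
    max_nominations: int = 4
    p_same_sex_tie: float = 0.90
    rho: float = 0.20
    beta: tuple[float, ...] = (-14.76, -0.004, -2.64, 2.45)  # intercept, IMD, BMI z, activity
    sigma: float = 15.5
    rho_sedentary: float = 0.14
    beta_sedentary: tuple[float, ...] = (21.0, 0.15, 2.0, -3.85)
    sigma_sedentary: float = 37.0
    school_sd: float = 5.0
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)
    seed: int = 0

    def validate(self) -> None:
        if self.n_schools <= 0:
            raise ValueError("n_schools must be positive")
        for name in ("p_female", "p_same_sex_tie"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if not abs(self.rho) < 1 or not abs(self.rho_sedentary) < 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma <= 0 or self.sigma_sedentary <= 0:
            raise ValueError("sigma must be positive")
        if self.max_nominations < 1:
            raise ValueError("max_nominations must be >= 1")
        for var, r in self.missing_rates.items():
            if not 0.0 <= r < 1.0:
                raise ValueError(f"missing rate for {var!r} must be in [0, 1)")


@dataclass
class EpochSeries:
    """One child-day of accelerometer counts at 10-s epochs."""

    child_id: str
    day_id: int
    weekend: bool
    counts: np.ndarray


@dataclass
class ActivityProfile:
    """Target day structure for the epoch generator.

    ``nonwear_blocks`` plants exact-zero runs of the given length (minutes)
    at the given start minute of every day, so non-wear detection rules are
    exercised; the intensity mix fixes the expected proportion of worn
    epochs in each band.
    """

    n_days: int = 5
    n_weekend_days: int = 2
    day_minutes: int = 840  # 14 h on-body window
    nonwear_blocks: tuple[tuple[int, int], ...] = ()  # (start_min, duration_min)
    sedentary_frac: float = 0.62
    light_frac: float = 0.30
    mvpa_frac: float = 0.08


@dataclass
class SyntheticStudy:
    roster: pd.DataFrame  # complete (pre-missingness) records incl. outcomes
    observed: pd.DataFrame  # roster with MAR missingness applied
    nominations: pd.DataFrame
    missing_mask: pd.DataFrame
    epoch_series: list[EpochSeries]
    truth: dict


def generate_roster(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the child roster: ids, school, sex and covariates.

    BMI z ~ N(0.3, 1); IMD ~ Gamma with mean 15 and SD 10 (right-skewed, as
    deprivation indices are); four activity items uniform on {0,1,2,3} whose
    sum is the 0-12 activity participation score.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sizes = config.children_per_school
    if isinstance(sizes, tuple):
        n_per = rng.integers(sizes[0], sizes[1] + 1, size=config.n_schools)
    else:
        n_per = np.full(config.n_schools, int(sizes))
    rows = []
    k = 0
    for s, n_s in enumerate(n_per):
        school = f"s{s:02d}"
        for _ in range(int(n_s)):
            rows.append({"child_id": f"c{k:04d}", "school_id": school})
            k += 1
    roster = pd.DataFrame(rows)
    n = len(roster)
    roster["sex"] = np.where(rng.random(n) < config.p_female, "F", "M")
    roster["bmi_z"] = rng.normal(0.3, 1.0, size=n)
    # Gamma(shape, scale): mean 15, SD 10 -> shape 2.25, scale 20/3
    roster["imd"] = rng.gamma(2.25, 15.0 / 2.25, size=n)
    for col in ITEM_COLS:
        roster[col] = rng.integers(0, 4, size=n)
    roster["activity_score"] = roster[ITEM_COLS].sum(axis=1)
    return roster


def generate_nominations(
    roster: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw friend nominations: 2 to ``max_nominations`` distinct schoolmates
    per child (never self), each tie same-sex with probability
    ``p_same_sex_tie``.  Children in a school of size 1 emit none.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    lo = min(2, config.max_nominations)
    rows = []
    for _, group in roster.groupby("school_id", sort=True):
        ids = group["child_id"].to_numpy()
        sexes = group["sex"].to_numpy()
        for i, child in enumerate(ids):
            same = [j for j in range(len(ids)) if j != i and sexes[j] == sexes[i]]
            other = [j for j in range(len(ids)) if j != i and sexes[j] != sexes[i]]
            n_nom = int(rng.integers(lo, config.max_nominations + 1))
            n_nom = min(n_nom, len(same) + len(other))
            rank = 0
            for _ in range(n_nom):
                want_same = rng.random() < config.p_same_sex_tie
                pool = same if (want_same and same) or not other else other
                if not pool:
                    break
                j = pool.pop(int(rng.integers(len(pool))))
                rank += 1
                rows.append({"nominator_id": child, "rank": rank, "nominee_id": ids[j]})
    return pd.DataFrame(rows, columns=["nominator_id", "rank", "nominee_id"])


def generate_outcomes(
    W: WeightMatrix,
    X: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    rho: float | None = None,
    beta: tuple[float, ...] | None = None,
    sigma: float | None = None,
    school_sd: float | None = None,
) -> np.ndarray:
    """Draw outcomes from the network-lag model via its exact reduced form.

    Solves (I - rho W) y = X beta + u + eps with a dense linear solve (never
    a truncated series).  ``rho`` must lie in the feasible interval of W.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    rho = config.rho if rho is None else rho
    beta = np.asarray(config.beta if beta is None else beta, dtype=float)
    sigma = config.sigma if sigma is None else sigma
    school_sd = config.school_sd if school_sd is None else school_sd

    X = np.asarray(X, dtype=float)
    if X.shape[0] != W.n:
        raise ValueError("X rows must match W dimension")
    if X.shape[1] != beta.size:
        raise ValueError("beta length must match X columns")
    lo, hi = W.feasible_interval()
    if not lo < rho < hi:
        raise ValueError(f"rho={rho} outside feasible interval ({lo:.4f}, {hi:.4f}) of W")

    schools = pd.Series(W.schools)
    u_school = {s: rng.normal(0.0, school_sd) if school_sd > 0 else 0.0 for s in schools.unique()}
    u = schools.map(u_school).to_numpy(dtype=float)
    eps = rng.normal(0.0, sigma, size=W.n)
    rhs = X @ beta + u + eps
    return np.linalg.solve(np.eye(W.n) - rho * W.w, rhs)


def apply_missingness(
    data: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    driver_col: str = "mean_mvpa",
    mode: str = "mar",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delete entries missing-at-random at the configured per-variable rates.

    The missingness probability for child i is the target rate tilted by a
    logistic score in sex and the school's leave-one-out mean of
    ``driver_col`` (both fully observed drivers), normalised so the realised
    rate matches the target in expectation.  ``mode="mcar"`` drops the
    tilt so every cell is deleted completely at random at the target rate.
    Returns (data with NaNs, boolean mask of deleted cells).
    """
    config.validate()
    if mode not in ("mar", "mcar"):
        raise ValueError("mode must be 'mar' or 'mcar'")
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    out = data.copy()
    mask = pd.DataFrame(False, index=data.index, columns=data.columns)

    female = (data["sex"] == "F").to_numpy(dtype=float)
    if mode == "mcar":
        female = np.zeros(len(data))
    if driver_col in data.columns and mode == "mar":
        v = data[driver_col].to_numpy(dtype=float)
        grp = data.groupby("school_id")[driver_col]
        s_sum = grp.transform("sum").to_numpy()
        s_n = grp.transform("count").to_numpy()
        loo = np.where(s_n > 1, (s_sum - v) / np.maximum(s_n - 1, 1), 0.0)
        sd = loo.std()
        z = (loo - loo.mean()) / sd if sd > 0 else np.zeros_like(loo)
    else:
        z = np.zeros(len(data))
    score = np.exp(0.4 * female - 0.3 * z)

    for var, rate in config.missing_rates.items():
        if var not in data.columns or rate <= 0:
            continue
        if rate >= 1:
            raise ValueError(f"missing rate for {var!r} must be < 1")
        p = np.clip(rate * score / score.mean(), 0.0, 0.99)
        hit = rng.random(len(data)) < p
        if hit.any():
            out.loc[hit, var] = np.nan
            mask.loc[hit, var] = True
    if set(ITEM_COLS) <= set(out.columns) and "activity_score" in out.columns:
        # the score is a derived sum: missing whenever any item is missing
        item_missing = out[ITEM_COLS].isna().any(axis=1)
        if item_missing.any():
            out.loc[item_missing, "activity_score"] = np.nan
            mask.loc[item_missing, "activity_score"] = True
    return out, mask


def generate_epoch_series(
    profile: ActivityProfile,
    seed: int | np.random.Generator,
    child_id: str = "c0000",
) -> list[EpochSeries]:
    """Generate per-day 10-s epoch count series for one child.

    Worn epochs draw an intensity band from the profile's mix and then a
    count within that band (counts per 10 s: sedentary 0-16, light 17-382,
    MVPA 383-1500, matching child cut points of 100/2296 counts per minute
    scaled to 10-s epochs).  Non-wear blocks are planted verbatim as zeros.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_epoch = profile.day_minutes * 6
    probs = np.array([profile.sedentary_frac, profile.light_frac, profile.mvpa_frac], dtype=float)
    probs = probs / probs.sum()
    days: list[EpochSeries] = []
    for d in range(profile.n_days):
        band = rng.choice(3, size=n_epoch, p=probs)
        counts = np.empty(n_epoch, dtype=int)
        sed = band == 0
        counts[sed] = rng.integers(0, 17, size=sed.sum())
        light = band == 1
        counts[light] = rng.integers(17, 383, size=light.sum())
        mvpa = band == 2
        counts[mvpa] = rng.integers(383, 1501, size=mvpa.sum())
        for start_min, dur_min in profile.nonwear_blocks:
            counts[start_min * 6 : (start_min + dur_min) * 6] = 0
        weekend = d >= profile.n_days - profile.n_weekend_days
        days.append(EpochSeries(child_id=child_id, day_id=d, weekend=weekend, counts=counts))
    return days


def study_weight_matrix(
    roster: pd.DataFrame, nominations: pd.DataFrame, standardise: bool = True
) -> WeightMatrix:
    """Same-sex weight matrix over the *full* roster (isolates kept as zero
    rows), used to generate outcomes for every child."""
    net, _ = match_nominations(nominations, roster)
    per_sex, _ = filter_same_sex(net)
    info = roster.set_index("child_id")
    order = sorted(roster["child_id"], key=lambda c: (info.at[c, "school_id"], c))
    n = len(order)
    pos = {c: i for i, c in enumerate(order)}
    w = np.zeros((n, n))
    for net_s in per_sex.values():
        for u, v in net_s.graph.edges:
            w[pos[u], pos[v]] = 1.0
    wm = WeightMatrix(w, order, info.loc[order, "school_id"].to_numpy())
    return wm.standardise() if standardise else wm


def design_matrix(roster: pd.DataFrame) -> np.ndarray:
    """Intercept + (IMD, BMI z, activity score), matching ``beta`` order."""
    X = roster[COVARIATES].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(roster)), X])


def generate_study(config: SimulationConfig, include_epochs: bool = False) -> SyntheticStudy:
    """Generate a full synthetic study: roster, nominations, network-lag
    outcomes for MVPA and sedentary time, optional epoch series, and a
    MAR-degraded observed copy."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(6)]

    roster = generate_roster(config, rngs[0])
    nominations = generate_nominations(roster, config, rngs[1])
    W = study_weight_matrix(roster, nominations)
    # regenerate design in W's node order
    roster = roster.set_index("child_id").loc[W.ids].reset_index()
    X = design_matrix(roster)
    roster["mean_mvpa"] = generate_outcomes(W, X, config, rngs[2])
    roster["mean_sedentary"] = generate_outcomes(
        W,
        X,
        config,
        rngs[3],
        rho=config.rho_sedentary,
        beta=config.beta_sedentary,
        sigma=config.sigma_sedentary,
    )

    epoch_series: list[EpochSeries] = []
    if include_epochs:
        for row in roster.itertuples():
            day_min = 840
            mvpa = float(np.clip(row.mean_mvpa, 5, day_min * 0.4))
            sed_frac = float(np.clip(row.mean_sedentary / day_min, 0.2, 0.85))
            mvpa_frac = mvpa / day_min
            light = max(1.0 - sed_frac - mvpa_frac, 0.05)
            profile = ActivityProfile(
                sedentary_frac=sed_frac, light_frac=light, mvpa_frac=mvpa_frac
            )
            epoch_series.extend(generate_epoch_series(profile, rngs[4], child_id=row.child_id))

    observed, mask = apply_missingness(roster, config, rngs[5])
    truth = dataclasses.asdict(config)
    return SyntheticStudy(
        roster=roster,
        observed=observed,
        nominations=nominations,
        missing_mask=mask,
        epoch_series=epoch_series,
        truth=truth,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write roster.csv, nominations.csv, epochs.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.observed.to_csv(outdir / "roster.csv", index=False)
    study.nominations.to_csv(outdir / "nominations.csv", index=False)
    if study.epoch_series:
        frames = []
        for es in study.epoch_series:
            frames.append(
                pd.DataFrame(
                    {
                        "child_id": es.child_id,
                        "day_id": es.day_id,
                        "weekend": int(es.weekend),
                        "epoch_index": np.arange(len(es.counts)),
                        "counts": es.counts,
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(outdir / "epochs.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=2, sort_keys=True)
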