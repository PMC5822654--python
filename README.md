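# friendnet

Network autocorrelation analysis of children's accelerometer-measured
physical activity within school friendship networks.

## The problem

Children's moderate-to-vigorous physical activity (MVPA) and sedentary time
cluster within friendship groups: a child's activity resembles the average
activity of the friends they nominate. Ordinary regression ignores this
dependence, which biases coefficients and confidence intervals. `friendnet`
is a library for epidemiologists and activity researchers analysing cohorts
in which children in each school name up to four close friends, wear a
waist accelerometer for several days, and report covariates (BMI z-score,
area deprivation (IMD), a 0–12 activity participation score).

At its core is the **network autocorrelation model** (network effect /
spatial lag model), fitted by maximum likelihood per sex stratum:

```
y = ρ W y + X β + ε,      ε ~ N(0, σ² I)
```

where `W` is the directed friend-nomination adjacency matrix,
row-standardised so each non-zero row sums to 1 (so `Wy` is the mean
outcome of a child's friends) and `ρ` is the network dependence. Around the
model the package provides:

* **synthetic cohort generation** — rosters, same-sex-homophilous friend
  nominations, 10-s epoch accelerometer counts, outcomes drawn from the lag
  model's exact reduced form `y = (I − ρW)⁻¹(Xβ + u + ε)`, and
  missing-at-random gaps — so the whole pipeline runs with no data download;
* **accelerometry reduction** — non-wear detection (≥60 min of zeros with
  ≤2 min interruptions), child cut-point classification (sedentary ≤100 cpm,
  MVPA ≥2296 cpm, rescaled to 10-s epochs), 500-min valid days, 3-day valid
  children;
* **network construction** — nomination matching, opposite-sex tie removal,
  isolate pruning, row-standardised `W`;
* **Moran's I** diagnostics with permutation inference, on raw outcomes and
  model residuals;
* baseline **OLS with school-cluster-robust errors** vs the ML lag fit,
  compared by AIC;
* **direct / indirect / total impacts** from `M = (I − ρ̂W)⁻¹` with
  percentile CIs from 200 parameter draws;
* **multiple imputation** (chained equations with passive score imputation)
  and **Rubin's-rules pooling** of every downstream estimate.

## Worked example

```python
import friendnet as fn
from friendnet.experiments import simulate_lag_dataset

names = ["const", "imd", "bmi_z", "activity_score"]
_, y, X, W, cfg = simulate_lag_dataset(seed=12, rho=0.20)   # 600 children, 24 schools

ols = fn.fit_ols(y, X, W.schools, names=names)
net = fn.fit_network_model(y, X, W, names=names)
print(f"rho = {net.rho:.3f} (95% CI {net.rho_conf_int()[0]:.3f} to {net.rho_conf_int()[1]:.3f})")
print(f"AIC: baseline {ols.aic:.1f} vs network {net.aic:.1f}")
print(fn.impact_intervals(net, W, n_sims=200, seed=4).to_frame().round(3))
```

prints

```
rho = 0.122 (95% CI 0.022 to 0.222)
AIC: baseline 4961.9 vs network 4958.3
             term  direct  indirect  total  ...
              imd  -0.243    -0.033 -0.277  ...
            bmi_z  -2.088    -0.287 -2.375  ...
   activity_score   2.578     0.354  2.931  ...
```

The fitted network dependence (`rho`) is this replicate's estimate of the
generating value 0.20; the network model's lower AIC says the friendship
term improves fit. Each covariate's `total` impact splits into the child's
own (`direct`) effect and the spillover (`indirect`) transmitted to friends
through `(I − ρW)⁻¹`; for a row-stochastic `W`, `total = β/(1 − ρ)`.

The `examples/` directory has one short script per capability (simulation,
accelerometry, network + Moran, model fit, impacts, imputation, full
pipeline); each prints its numbers with a note on what they mean. A thin
CLI (`friendnet simulate|process-accel|build-network|diagnose|run`) wraps
the same functions for batch use.

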