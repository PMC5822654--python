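"""Fit the baseline OLS and the network autocorrelation model.

Compares cluster-robust OLS with the spatial-lag ML fit on one simulated
stratum and prints coefficients, the network dependence and the AIC gain.
"""

import numpy as np

import friendnet as fn
from friendnet.experiments import simulate_lag_dataset

names = ["const", "imd", "bmi_z", "activity_score"]
_, y, X, W, cfg = simulate_lag_dataset(seed=12, rho=0.20)

ols = fn.fit_ols(y, X, W.schools, names=names)
net = fn.fit_network_model(y, X, W, names=names)

print(f"n = {net.n} children, true rho = {cfg.rho}, true beta = {cfg.beta}")
for j, name in enumerate(names):
    print(f"  {name:>15}: OLS {ols.beta[j]:7.3f} (se {ols.se[j]:.3f})   "
          f"network {net.beta[j]:7.3f} (se {net.se_beta[j]:.3f})")
lo, hi = net.rho_conf_int()
print(f"network dependence rho = {net.rho:.3f} (95% CI {lo:.3f} to {hi:.3f})")
print(f"AIC: baseline {ols.aic:.1f} vs network {net.aic:.1f} "
      f"(improvement {ols.aic - net.aic:.1f})")
print(f"residual Moran's I after the lag term: "
      f"{fn.morans_i(y - net.rho * (W.w @ y) - X @ net.beta, W):.3f}")

# The lag model should recover rho near 0.20, leave little residual
# autocorrelation, and beat the baseline AIC because the outcomes really
# do propagate through the friendship network.
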