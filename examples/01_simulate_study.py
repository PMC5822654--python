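"""Generate a small synthetic cohort and inspect its structure.

Draws a 6-school study with network-autocorrelated MVPA/sedentary outcomes
and missing-at-random gaps, then prints its basic shape.
"""

import friendnet as fn

cfg = fn.SimulationConfig(n_schools=6, children_per_school=25, seed=1)
study = fn.generate_study(cfg)

roster = study.roster
print(f"children: {len(roster)} in {roster['school_id'].nunique()} schools")
print(f"girls: {(roster['sex'] == 'F').mean():.0%}")
print(f"nominations: {len(study.nominations)} "
      f"(median {study.nominations.groupby('nominator_id').size().median():.0f} per child)")
print(f"mean MVPA {roster['mean_mvpa'].mean():.1f} min/day, "
      f"mean sedentary {roster['mean_sedentary'].mean():.1f} min/day")
print("missing fractions:")
print(study.observed[["bmi_z", "imd", "mean_mvpa", "mean_sedentary"]].isna().mean().round(3))

# The outcomes were generated from y = rho*W*y + X*beta + u + eps with
# rho = 0.20, so friends' activity levels are positively correlated; the
# missing fractions mirror the per-variable rates in the configuration.
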