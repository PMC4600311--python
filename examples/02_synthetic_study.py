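"""Generate a synthetic small-area mortality study with known ground truth.

The scenario emulates municipality-level data: a 20x20 lattice of units
with log-uniform population sizes, 18 five-year age bands, five 4-year
periods, contiguous language regions, urban status for the largest units,
a CAR-distributed spatial log-risk field, and Poisson death counts whose
mean is expected count x SMR.
"""

import numpy as np

from smrmap import simulate_study

study = simulate_study(seed=1)

print("units:", study.graph.n_units, "| periods:", study.population.periods)
print("person-years per unit-period: min %.0f, median %.0f, max %.0f" % (
    study.population.values.sum(axis=2).min(),
    np.median(study.population.values.sum(axis=2)),
    study.population.values.sum(axis=2).max(),
))
print("total deaths:", int(study.deaths.values.sum()))
print("language counts:", study.covariates["language"].value_counts().to_dict())
print("urban units:", (study.covariates["urbanisation"] == "urban").sum())
print("true period SMR ratios:", np.round(np.exp(study.truth.beta_period), 3))
print("true urban ratio: %.2f | true spatial SD: %.2f" % (
    np.exp(study.truth.beta_urban[1]), study.truth.sigma_phi))
# the spatial field sums to zero over the (connected) map by construction
print("sum of phi over the map: %.2e" % study.truth.phi.sum())
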