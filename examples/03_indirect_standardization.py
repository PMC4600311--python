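"""Indirect age standardization: reference rates, expected counts, raw SMRs.

Nationwide per-band rates pooled over all periods are applied to each
unit's person-years; the closure identity (total expected = total observed
when the rates come from the same data) is what makes period SMR ratios
interpretable as temporal trends.
"""

import numpy as np

from smrmap import (
    CorrectionFactors,
    aggregate_age_groups,
    apply_coding_correction,
    compute_expected,
    compute_reference_rates,
    raw_smr,
    simulate_study,
)

study = simulate_study(seed=1)

# a coding-change correction (values are study-specific user input; the
# wildcard applies one factor to pre-1995-style periods only)
factors = CorrectionFactors({("*", "1969-1972"): 0.93, ("*", "1979-1982"): 0.93,
                             ("*", "1989-1992"): 0.93})
deaths = apply_coding_correction(study.deaths, factors)
print("deaths before/after correction: %d -> %d" % (
    study.deaths.values.sum(), deaths.values.sum()))

rates = compute_reference_rates(deaths, study.population)
print("reference rate per 100,000 PY: 0-4 band %.1f, 60-64 band %.1f, 85+ band %.1f"
      % (rates[0] * 1e5, rates[12] * 1e5, rates[-1] * 1e5))

expected = compute_expected(study.population, rates)
grouped = aggregate_age_groups(deaths)
print("closure: total expected %.4f vs observed %d" % (
    expected.values.sum(), grouped.values.sum()))

smr, defined = raw_smr(grouped, expected)
print("defined raw-SMR cells: %d of %d" % (defined.sum(), defined.size))
print("raw SMR spread (75+ group): 5%%..95%% = %.2f..%.2f — noisy, needs smoothing"
      % tuple(np.nanquantile(smr[:, :, 2][defined[:, :, 2]], [0.05, 0.95])))
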