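"""Coding correction, period aggregation, and indirect age standardization.

Indirect standardization: nationwide age-specific mortality rates, pooled
over all periods and computed on 5-year bands, are applied to each unit's
person-years to give expected death counts per (unit, period, coarse age
group).  The ratio observed/expected is the standardized mortality ratio
(SMR).  When the reference rates come from the same data, total expected
equals total observed exactly (the closure identity of the method).
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .tables import (
    COARSE_AGE_GROUPS,
    DEFAULT_AGE_GROUP_MAP,
    ExpectedCounts,
    GroupedDeaths,
    MortalityTable,
    PopulationTable,
)

__all__ = [
    "CorrectionFactors",
    "aggregate_periods",
    "apply_coding_correction",
    "compute_reference_rates",
    "compute_expected",
    "aggregate_age_groups",
    "raw_smr",
]

logger = logging.getLogger(__name__)

WILDCARD = "*"


@dataclass
class CorrectionFactors:
    """Multiplicative corrections for cause-of-death coding changes.

    Keyed by (age band or group, period or era); either key may be the
    wildcard ``"*"``.  Lookup order: exact, (band, *), (*, period), (*, *);
    unresolved cells default to 1.0 with a logged warning.  The actual
    factor values are study-specific user input.
    """

    factors: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[tuple[str, str], float] = {}
        for (age, period), f in self.factors.items():
            f = float(f)
            if f <= 0:
                raise ValueError(
                    f"nonpositive correction factor {f} for ({age!r}, {period!r})"
                )
            clean[(str(age), str(period))] = f
        self.factors = clean
        self._warned = False

    def factor_for(self, age_band: str, period: str) -> float:
        for key in (
            (age_band, period),
            (age_band, WILDCARD),
            (WILDCARD, period),
            (WILDCARD, WILDCARD),
        ):
            if key in self.factors:
                return self.factors[key]
        if not self._warned:
            logger.warning(
                "no correction factor for (%s, %s); defaulting to 1.0",
                age_band,
                period,
            )
            self._warned = True
        return 1.0

    @classmethod
    def read_csv(cls, path) -> "CorrectionFactors":
        """Delimited file with header (age_band_or_group, period_or_era, factor)."""
        factors: dict[tuple[str, str], float] = {}
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or len(header) < 3:
                raise ValueError("correction-factor file needs a 3-column header")
            for row in reader:
                if not row or not "".join(row).strip():
                    continue
                factors[(row[0].strip(), row[1].strip())] = float(row[2])
        return cls(factors)


def aggregate_periods(
    annual_deaths: MortalityTable,
    period_windows: Sequence[tuple[int, int]],
) -> MortalityTable:
    """Sum annual counts into multi-year periods; years outside all windows drop.

    ``annual_deaths`` must be keyed by calendar-year period labels.  The
    default study design uses five 4-year windows around census years.
    """
    windows = [(int(a), int(b)) for a, b in period_windows]
    for a, b in windows:
        if a > b:
            raise ValueError(f"window {a}-{b} has start > end")
    for k, (a, b) in enumerate(windows):
        for a2, b2 in windows[k + 1 :]:
            if a <= b2 and a2 <= b:
                raise ValueError(
                    f"overlapping period windows {a}-{b} and {a2}-{b2}"
                )
    try:
        years = [int(p) for p in annual_deaths.periods]
    except ValueError:
        raise ValueError("annual table periods must be calendar years") from None

    labels = tuple(f"{a}-{b}" for a, b in windows)
    u, _, nb = annual_deaths.shape
    out = np.zeros((u, len(windows), nb))
    for yi, year in enumerate(years):
        for wi, (a, b) in enumerate(windows):
            if a <= year <= b:
                out[:, wi, :] += annual_deaths.values[:, yi, :]
                break
    return MortalityTable(out, annual_deaths.units, labels, annual_deaths.ages)


def apply_coding_correction(
    deaths: MortalityTable,
    factors: CorrectionFactors,
    round_counts: bool = True,
) -> MortalityTable:
    """Multiply each cell by its correction factor.

    With ``round_counts`` (default) the corrected value is rounded
    half-to-even to an integer at the (unit, period, band) level so the
    count likelihood sees integers; pass ``False`` to keep the fractional
    pipeline for sensitivity analysis.
    """
    out = deaths.values.copy()
    for pi, period in enumerate(deaths.periods):
        for bi, band in enumerate(deaths.ages):
            out[:, pi, bi] *= factors.factor_for(band, period)
    if round_counts:
        # pre-round at 1e-9 so float fuzz (e.g. 10 x 0.85 = 8.500000000000001)
        # cannot flip the half-to-even result
        out = np.round(np.round(out, 9))
    return MortalityTable(out, deaths.units, deaths.periods, deaths.ages)


def compute_reference_rates(
    deaths: MortalityTable, population: PopulationTable
) -> np.ndarray:
    """Nationwide per-band rates pooled over ALL units and periods.

    rate(band) = total deaths / total person-years; bands with zero
    person-years get rate 0 by convention so expected counts stay defined.
    """
    deaths.require_same_index(population, "deaths and person-years")
    d = deaths.values.sum(axis=(0, 1))
    py = population.values.sum(axis=(0, 1))
    return np.divide(d, py, out=np.zeros_like(d), where=py > 0)


def compute_expected(
    population: PopulationTable,
    rates: Mapping[str, float] | Sequence[float],
    age_group_map: Mapping[str, str] = DEFAULT_AGE_GROUP_MAP,
    groups: Sequence[str] = COARSE_AGE_GROUPS,
) -> ExpectedCounts:
    """Expected deaths per (unit, period, coarse group) = sum_b PY_b x rate_b."""
    bands = population.age_bands
    if isinstance(rates, Mapping):
        rate_arr = np.array([float(rates[b]) for b in bands])
    else:
        rate_arr = np.asarray(rates, dtype=float)
        if rate_arr.shape != (len(bands),):
            raise ValueError("rates length must match age bands")
    unmapped = [b for b in bands if b not in age_group_map]
    if unmapped:
        raise ValueError(f"age bands without a coarse group: {unmapped}")
    bad = [b for b in bands if age_group_map[b] not in groups]
    if bad:
        raise ValueError(f"bands mapped to undeclared groups: {bad}")
    u, p, _ = population.shape
    out = np.zeros((u, p, len(groups)))
    gidx = {g: k for k, g in enumerate(groups)}
    per_band = population.values * rate_arr[np.newaxis, np.newaxis, :]
    for bi, band in enumerate(bands):
        out[:, :, gidx[age_group_map[band]]] += per_band[:, :, bi]
    return ExpectedCounts(out, population.units, population.periods, tuple(groups))


def aggregate_age_groups(
    deaths: MortalityTable,
    age_group_map: Mapping[str, str] = DEFAULT_AGE_GROUP_MAP,
    groups: Sequence[str] = COARSE_AGE_GROUPS,
) -> GroupedDeaths:
    """Observed deaths summed from 5-year bands into the coarse groups."""
    unmapped = [b for b in deaths.age_bands if b not in age_group_map]
    if unmapped:
        raise ValueError(f"age bands without a coarse group: {unmapped}")
    u, p, _ = deaths.shape
    out = np.zeros((u, p, len(groups)))
    gidx = {g: k for k, g in enumerate(groups)}
    for bi, band in enumerate(deaths.age_bands):
        out[:, :, gidx[age_group_map[band]]] += deaths.values[:, :, bi]
    return GroupedDeaths(out, deaths.units, deaths.periods, tuple(groups))


def raw_smr(
    observed: GroupedDeaths, expected: ExpectedCounts
) -> tuple[np.ndarray, np.ndarray]:
    """Unsmoothed SMR = observed/expected per cell.

    Returns ``(smr, defined)``: cells with expected = 0 are NaN in ``smr``
    and False in ``defined`` — flagged, never silently dropped.
    """
    observed.require_same_index(expected, "observed and expected")
    defined = expected.values > 0
    smr = np.full(expected.values.shape, np.nan)
    np.divide(observed.values, expected.values, out=smr, where=defined)
    return smr, defined
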