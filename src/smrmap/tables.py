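"""Dense count/person-year cubes indexed by (unit, period, age).

The whole analysis runs on three-axis arrays: spatial unit x calendar period
x age stratum.  Age strata are either the 5-year bands used for indirect
standardization (0-4 ... 85+) or the three coarse groups the models are
fitted on (<55, 55-74, 75+).  Tables round-trip to tidy delimited text
(columns unit_id, period, age_band/age_group, value).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AGE_BANDS_5Y",
    "COARSE_AGE_GROUPS",
    "DEFAULT_AGE_GROUP_MAP",
    "PopulationTable",
    "MortalityTable",
    "ExpectedCounts",
    "GroupedDeaths",
]

#: 18 five-year age bands, open-ended at 85+.
AGE_BANDS_5Y: tuple[str, ...] = tuple(
    f"{a}-{a + 4}" for a in range(0, 85, 5)
) + ("85+",)

#: The three coarse age groups the models are fitted on, separately.
COARSE_AGE_GROUPS: tuple[str, ...] = ("<55", "55-74", "75+")


def _band_lower(band: str) -> int:
    band = band.strip()
    if band.startswith("<"):
        return -1  # open lower group sorts first
    return int(band.rstrip("+").split("-")[0])


def _coarse_group_for(band: str) -> str:
    lo = _band_lower(band)
    if lo < 55:
        return "<55"
    if lo < 75:
        return "55-74"
    return "75+"


#: Default 5-year band -> coarse group mapping.
DEFAULT_AGE_GROUP_MAP: dict[str, str] = {
    b: _coarse_group_for(b) for b in AGE_BANDS_5Y
}


@dataclass
class _Cube:
    """Dense nonnegative array over units x periods x age strata."""

    values: np.ndarray = field(repr=False)
    units: tuple[str, ...]
    periods: tuple[str, ...]
    ages: tuple[str, ...]

    AGE_COLUMN = "age_band"
    VALUE_COLUMN = "value"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.units = tuple(str(u) for u in self.units)
        self.periods = tuple(str(p) for p in self.periods)
        self.ages = tuple(str(a) for a in self.ages)
        expected_shape = (len(self.units), len(self.periods), len(self.ages))
        if self.values.shape != expected_shape:
            raise ValueError(
                f"values shape {self.values.shape} != index shape {expected_shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite cell values")
        if np.any(self.values < 0):
            raise ValueError("negative cell values")

    # -- index helpers ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def unit_index(self) -> dict[str, int]:
        return {u: i for i, u in enumerate(self.units)}

    def same_index(self, other: "_Cube") -> bool:
        return (
            self.units == other.units
            and self.periods == other.periods
            and self.ages == other.ages
        )

    def require_same_index(self, other: "_Cube", what: str = "tables") -> None:
        if not self.same_index(other):
            raise ValueError(f"mismatched indices between {what}")

    def with_values(self, values: np.ndarray) -> "_Cube":
        return replace(self, values=np.asarray(values, dtype=float))

    # -- tidy-frame round trip -------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.units, self.periods, self.ages],
            names=["unit_id", "period", self.AGE_COLUMN],
        )
        return pd.DataFrame(
            {self.VALUE_COLUMN: self.values.reshape(-1)}, index=idx
        ).reset_index()

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        units: Sequence[str] | None = None,
        periods: Sequence[str] | None = None,
        ages: Sequence[str] | None = None,
    ):
        """Build a dense cube from a tidy frame; absent cells become 0."""
        df = frame.copy()
        needed = {"unit_id", "period", cls.AGE_COLUMN, cls.VALUE_COLUMN}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        for col in ("unit_id", "period", cls.AGE_COLUMN):
            df[col] = df[col].astype(str)
        units = tuple(units) if units is not None else tuple(
            sorted(df["unit_id"].unique())
        )
        periods = tuple(str(p) for p in periods) if periods is not None else tuple(
            sorted(df["period"].unique())
        )
        ages = tuple(ages) if ages is not None else tuple(
            sorted(df[cls.AGE_COLUMN].unique(), key=_band_lower)
        )
        pivot = (
            df.set_index(["unit_id", "period", cls.AGE_COLUMN])[cls.VALUE_COLUMN]
            .reindex(
                pd.MultiIndex.from_product([units, periods, ages]),
                fill_value=0.0,
            )
            .to_numpy()
            .reshape(len(units), len(periods), len(ages))
        )
        return cls(pivot, units, periods, ages)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, **kwargs):
        return cls.from_frame(pd.read_csv(path), **kwargs)


@dataclass
class PopulationTable(_Cube):
    """Person-years at risk by (unit, period, 5-year age band)."""

    VALUE_COLUMN = "person_years"

    @property
    def person_years(self) -> np.ndarray:
        return self.values

    @property
    def age_bands(self) -> tuple[str, ...]:
        return self.ages


@dataclass
class MortalityTable(_Cube):
    """Death counts by (unit, period, 5-year age band).

    Counts are integers before any coding-change correction and may be
    fractional afterwards (until re-rounded).
    """

    VALUE_COLUMN = "deaths"

    @property
    def deaths(self) -> np.ndarray:
        return self.values

    @property
    def age_bands(self) -> tuple[str, ...]:
        return self.ages

    def check_against_population(self, population: PopulationTable) -> None:
        """Deaths must vanish wherever person-years vanish."""
        self.require_same_index(population, "deaths and person-years")
        bad = (population.values == 0) & (self.values > 0)
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} cells have deaths > 0 with person_years = 0"
            )


@dataclass
class ExpectedCounts(_Cube):
    """Indirectly standardized expected deaths by (unit, period, coarse group)."""

    AGE_COLUMN = "age_group"
    VALUE_COLUMN = "expected"

    @property
    def age_groups(self) -> tuple[str, ...]:
        return self.ages


@dataclass
class GroupedDeaths(_Cube):
    """Observed deaths aggregated to the coarse age groups."""

    AGE_COLUMN = "age_group"
    VALUE_COLUMN = "deaths"

    @property
    def age_groups(self) -> tuple[str, ...]:
        return self.ages


def covariates_frame(units: Sequence) -> pd.DataFrame:
    """Tidy per-unit covariate frame from SpatialUnit records."""
    df = pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "name": [u.name for u in units],
            "language": [u.language for u in units],
            "urbanisation": [u.urbanisation for u in units],
        }
    ).set_index("unit_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate unit_id in covariates")
    return df.sort_index()


def align_covariates(covariates: pd.DataFrame, unit_ids: Sequence[str]) -> pd.DataFrame:
    """Reindex a covariate frame to graph unit order, rejecting gaps."""
    missing = [u for u in unit_ids if u not in covariates.index]
    if missing:
        raise ValueError(f"units without covariates: {missing[:5]}")
    out = covariates.loc[list(unit_ids)]
    for col in ("language", "urbanisation"):
        if col not in out.columns:
            raise ValueError(f"covariates lack required column {col!r}")
        if out[col].isna().any():
            raise ValueError(f"missing values in covariate {col!r}")
    return out
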