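"""Demographic table containers indexed by single age, gender, and calendar year.

The universal container is :class:`AgeGenderYearTable`: a dense rectangular
array of one value (a rate, prevalence, count, or life expectancy) per
(age, gender, year) cell. Gender is always the pair ``("male", "female")``.
Grouped inputs (five-year mortality bands, survey age groups) are held in
:class:`GroupedTable` and expanded to single ages before use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENDERS = ("male", "female")


class SchemaError(ValueError):
    """Input table violates the declared layout (columns, overlap, duplicates)."""


class CoverageError(ValueError):
    """A required (age, gender, year) cell has no value."""


@dataclass
class AgeGenderYearTable:
    """Value per (age, gender, year), stored as a dense (n_age, 2, n_year) array.

    Parameters
    ----------
    values : ndarray, shape (n_age, 2, n_year)
        Axis 1 follows :data:`GENDERS` order (male, female).
    ages, years : 1-D integer arrays
        Contiguous, strictly increasing index ranges.
    """

    values: np.ndarray
    ages: np.ndarray
    years: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.ages), len(GENDERS), len(self.years))
        if self.values.shape != expected:
            raise SchemaError(
                f"values shape {self.values.shape} != (ages, genders, years) {expected}"
            )
        for name, idx in (("ages", self.ages), ("years", self.years)):
            if len(idx) > 1 and not np.all(np.diff(idx) == 1):
                raise SchemaError(f"{name} must be contiguous and increasing")

    # ------------------------------------------------------------------ builders
    @classmethod
    def constant(cls, value: float, ages, years) -> "AgeGenderYearTable":
        ages = np.asarray(ages, dtype=int)
        years = np.asarray(years, dtype=int)
        return cls(np.full((len(ages), 2, len(years)), float(value)), ages, years)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str = "value") -> "AgeGenderYearTable":
        """Build from a long-format frame with columns age, gender, year, value."""
        required = {"age", "gender", "year", value_col}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"missing columns: {sorted(missing)}")
        bad = set(df["gender"].unique()) - set(GENDERS)
        if bad:
            raise SchemaError(f"unknown gender labels: {sorted(bad)}")
        ages = np.arange(df["age"].min(), df["age"].max() + 1)
        years = np.arange(df["year"].min(), df["year"].max() + 1)
        pivot = df.set_index(["age", "gender", "year"])[value_col]
        if pivot.index.has_duplicates:
            raise SchemaError("duplicate (age, gender, year) rows")
        full = pd.MultiIndex.from_product([ages, GENDERS, years], names=["age", "gender", "year"])
        try:
            pivot = pivot.reindex(full)
        except Exception as exc:  # pragma: no cover - defensive
            raise SchemaError(str(exc)) from exc
        if pivot.isna().any():
            missing_ix = pivot.index[pivot.isna()][0]
            raise CoverageError(f"missing value at {missing_ix}")
        values = pivot.to_numpy().reshape(len(ages), 2, len(years))
        return cls(values, ages, years)

    def to_frame(self, value_col: str = "value") -> pd.DataFrame:
        idx = pd.MultiIndex.from_product(
            [self.ages, GENDERS, self.years], names=["age", "gender", "year"]
        )
        return pd.DataFrame({value_col: self.values.reshape(-1)}, index=idx).reset_index()

    # ------------------------------------------------------------------ access
    def loc(self, age: int, gender: str, year: int) -> float:
        return float(
            self.values[
                int(age) - int(self.ages[0]),
                GENDERS.index(gender),
                int(year) - int(self.years[0]),
            ]
        )

    def gender_slice(self, gender: str) -> np.ndarray:
        """(n_age, n_year) view for one gender."""
        return self.values[:, GENDERS.index(gender), :]

    def year_slice(self, year: int) -> np.ndarray:
        """(n_age, 2) view for one calendar year."""
        return self.values[:, :, int(year) - int(self.years[0])]

    def _check_aligned(self, other: "AgeGenderYearTable") -> None:
        if not (np.array_equal(self.ages, other.ages) and np.array_equal(self.years, other.years)):
            raise SchemaError("tables are not on a common (age, year) index")

    def _binop(self, other, op) -> "AgeGenderYearTable":
        if isinstance(other, AgeGenderYearTable):
            self._check_aligned(other)
            other = other.values
        return AgeGenderYearTable(op(self.values, other), self.ages, self.years)

    def __mul__(self, other):
        return self._binop(other, np.multiply)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binop(other, np.divide)

    def __add__(self, other):
        return self._binop(other, np.add)

    def __sub__(self, other):
        return self._binop(other, np.subtract)

    def copy(self) -> "AgeGenderYearTable":
        return AgeGenderYearTable(self.values.copy(), self.ages.copy(), self.years.copy())

    def clip(self, lo: float, hi: float) -> "AgeGenderYearTable":
        return AgeGenderYearTable(np.clip(self.values, lo, hi), self.ages, self.years)


@dataclass
class GroupedTable:
    """Value per closed age interval [age_lo, age_hi], gender, and optional year.

    ``data`` columns: age_lo, age_hi, gender, value, and optionally year.
    Groups must be non-overlapping within each (gender, year).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"age_lo", "age_hi", "gender", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise SchemaError("grouped table is empty")
        if (self.data["age_lo"] > self.data["age_hi"]).any():
            raise SchemaError("age_lo > age_hi in some group")
        keys = ["gender"] + (["year"] if "year" in self.data.columns else [])
        for _, sub in self.data.groupby(keys):
            sub = sub.sort_values("age_lo")
            if (sub["age_lo"].to_numpy()[1:] <= sub["age_hi"].to_numpy()[:-1]).any():
                raise SchemaError("overlapping age groups")

    @property
    def has_year(self) -> bool:
        return "year" in self.data.columns

    def groups(self, gender: str, year: int | None = None) -> pd.DataFrame:
        sub = self.data[self.data["gender"] == gender]
        if self.has_year:
            if year is None:
                raise SchemaError("year required for a year-indexed grouped table")
            sub = sub[sub["year"] == year]
        if len(sub) == 0:
            raise CoverageError(f"no groups for gender={gender}, year={year}")
        return sub.sort_values("age_lo")


def read_table_csv(path) -> pd.DataFrame:
    """Read a delimited input table (comma-separated, header row, UTF-8)."""
    return pd.read_csv(path)


def write_table_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
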