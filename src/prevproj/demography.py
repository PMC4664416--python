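"""Demographic bookkeeping on single-year age × sex grids.

Everything in the pipeline flows through one tidy currency: a value per
(year, sex, age) cell, where age runs over adult single years 20..100 and
100 means "100 and above".  This module holds that container
(:class:`AgeSexTable`), the population frame with entrants and net
migration, cohort-component advancement, and population-weighted band
aggregation for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("prevproj")

SEXES: tuple[str, str] = ("female", "male")
AGE_MIN: int = 20
AGE_MAX: int = 100  # open-ended top bin: 100 and above
AGES: np.ndarray = np.arange(AGE_MIN, AGE_MAX + 1)
N_AGES: int = AGES.size

#: value ranges by table role; counts and ratios are unbounded above
ROLE_RANGES: dict[str, tuple[float, float]] = {
    "count": (0.0, np.inf),
    "proportion": (0.0, 1.0),
    "risk": (0.0, 1.0),
    "ratio": (0.0, np.inf),
    "signed": (-np.inf, np.inf),
}

#: reporting bands matching the published age layout; None = open above
DEFAULT_BANDS: tuple[tuple[int, int | None], ...] = ((20, 44), (45, 64), (65, None))


class TableFormatError(ValueError):
    """Input file does not have the expected tidy columns."""


class TableValidationError(ValueError):
    """A table violates a role range, duplicates a key, or has age gaps."""


class CoverageError(KeyError):
    """An operation needs a (year, sex, age) cell that is missing."""


def sex_index(sex: str) -> int:
    try:
        return SEXES.index(sex)
    except ValueError:
        raise TableValidationError(f"unknown sex code {sex!r}; expected one of {SEXES}") from None


@dataclass
class AgeSexTable:
    """Values on a (year, sex, age) grid.

    Parameters
    ----------
    years
        Sorted calendar years present.
    values
        Array of shape ``(len(years), 2, 81)`` indexed ``[year, sex, age-20]``
        with ``NaN`` marking cells absent from the source data.
    role
        One of ``count``, ``proportion``, ``risk``, ``ratio``; fixes the
        admissible value range.
    """

    years: np.ndarray
    values: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.years.size, len(SEXES), N_AGES):
            raise TableValidationError(
                f"values shape {self.values.shape} does not match "
                f"({self.years.size}, {len(SEXES)}, {N_AGES})"
            )
        if self.role not in ROLE_RANGES:
            raise TableValidationError(f"unknown role {self.role!r}")
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_frame(cls, df: pd.DataFrame, role: str) -> "AgeSexTable":
        """Build from a tidy frame with columns year, sex, age, value."""
        missing = {"year", "sex", "age", "value"} - set(df.columns)
        if missing:
            raise TableFormatError(f"missing column(s): {sorted(missing)}")
        df = df.copy()
        dup = df.duplicated(subset=["year", "sex", "age"])
        if dup.any():
            row = df[dup].iloc[0]
            raise TableValidationError(
                f"duplicated key (year={row['year']}, sex={row['sex']}, age={row['age']})"
            )
        ages = df["age"].to_numpy()
        if (ages < AGE_MIN).any() or (ages > AGE_MAX).any():
            bad = df[(ages < AGE_MIN) | (ages > AGE_MAX)].iloc[0]
            raise TableValidationError(
                f"age {bad['age']} outside [{AGE_MIN}, {AGE_MAX}] "
                f"(year={bad['year']}, sex={bad['sex']})"
            )
        years = np.sort(df["year"].unique()).astype(int)
        values = np.full((years.size, len(SEXES), N_AGES), np.nan)
        sex_codes = df["sex"].astype(str)
        bad_sex = ~sex_codes.isin(SEXES)
        if bad_sex.any():
            raise TableValidationError(
                f"unknown sex code {sex_codes[bad_sex].iloc[0]!r}; expected one of {SEXES}"
            )
        yi = np.searchsorted(years, df["year"].to_numpy(dtype=int))
        si = sex_codes.map({s: k for k, s in enumerate(SEXES)}).to_numpy(dtype=int)
        ai = df["age"].to_numpy(dtype=int) - AGE_MIN
        values[yi, si, ai] = df["value"].to_numpy(dtype=float)
        return cls(years, values, role)

    @classmethod
    def read_csv(cls, path: str | Path, role: str) -> "AgeSexTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        return cls.from_frame(pd.read_csv(path), role)

    @classmethod
    def from_grid(cls, years: Iterable[int], values: np.ndarray, role: str) -> "AgeSexTable":
        return cls(np.asarray(list(years), dtype=int), np.asarray(values, dtype=float), role)

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        lo, hi = ROLE_RANGES[self.role]
        finite = self.values[~np.isnan(self.values)]
        if finite.size and ((finite < lo).any() or (finite > hi).any()):
            iy, isex, ia = [idx[0] for idx in np.nonzero(
                (~np.isnan(self.values)) & ((self.values < lo) | (self.values > hi))
            )]
            raise TableValidationError(
                f"value {self.values[iy, isex, ia]} out of [{lo}, {hi}] for role "
                f"{self.role!r} at (year={self.years[iy]}, sex={SEXES[isex]}, age={AGE_MIN + ia})"
            )
        # ages present per (year, sex) must be gap-free
        for iy, year in enumerate(self.years):
            for isex, sex in enumerate(SEXES):
                present = ~np.isnan(self.values[iy, isex])
                if present.any():
                    first, last = np.flatnonzero(present)[[0, -1]]
                    if not present[first : last + 1].all():
                        gap = first + np.flatnonzero(~present[first : last + 1])[0]
                        raise TableValidationError(
                            f"age axis has a gap at age {AGE_MIN + gap} "
                            f"(year={year}, sex={sex})"
                        )

    # -- access --------------------------------------------------------

    def year_index(self, year: int) -> int:
        hits = np.nonzero(self.years == year)[0]
        if hits.size == 0:
            raise CoverageError(f"year {year} not in table (role={self.role})")
        return int(hits[0])

    def has_year(self, year: int) -> bool:
        return bool((self.years == year).any())

    def at(self, year: int) -> np.ndarray:
        """Return the (2, 81) sex × age grid for ``year`` (a copy)."""
        return self.values[self.year_index(year)].copy()

    def require_full(self, year: int) -> np.ndarray:
        grid = self.at(year)
        if np.isnan(grid).any():
            isex, ia = [idx[0] for idx in np.nonzero(np.isnan(grid))]
            raise CoverageError(
                f"missing value at (year={year}, sex={SEXES[isex]}, age={AGE_MIN + ia}) "
                f"in {self.role} table"
            )
        return grid

    # -- export --------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for iy, year in enumerate(self.years):
            for isex, sex in enumerate(SEXES):
                for ia, age in enumerate(AGES):
                    v = self.values[iy, isex, ia]
                    if not np.isnan(v):
                        recs.append((int(year), sex, int(age), float(v)))
        return pd.DataFrame(recs, columns=["year", "sex", "age", "value"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def __len__(self) -> int:
        return int((~np.isnan(self.values)).sum())


def read_agesex_csv(path: str | Path, role: str) -> AgeSexTable:
    """Read and validate a tidy ``year,sex,age,value`` CSV for the given role."""
    return AgeSexTable.read_csv(path, role)


# MortalitySchedule is an AgeSexTable with role "risk": m(year, sex, age) is
# the one-year death probability in the total population.
MortalitySchedule = AgeSexTable


@dataclass
class PopulationFrame:
    """Start-of-year person counts plus entrants and net migration.

    ``counts`` holds N(year, sex, age); ``entrants`` gives the cohort
    reaching the minimum age at the start of each year; ``migration`` holds
    signed net flows added at the start of the year they join.
    """

    counts: AgeSexTable
    entrants: dict[int, np.ndarray] = field(default_factory=dict)
    migration: AgeSexTable | None = None

    def __post_init__(self) -> None:
        if self.counts.role != "count":
            raise TableValidationError("population counts must have role 'count'")
        self.entrants = {int(y): np.asarray(e, dtype=float) for y, e in self.entrants.items()}

    @classmethod
    def closed(cls, base_year: int, base_counts: np.ndarray) -> "PopulationFrame":
        """A closed cohort: base-year counts, no entrants, no migration."""
        return cls(AgeSexTable.from_grid([base_year], base_counts[None, :, :], "count"))

    @classmethod
    def from_counts(cls, counts: AgeSexTable, mort: MortalitySchedule) -> "PopulationFrame":
        """Recover entrants and net migration from an observed/forecast count table.

        Entrants are the age-20 rows; migration for later years is the residual
        of the advancement identity, so re-advancing reproduces ``counts``
        exactly.
        """
        entrants: dict[int, np.ndarray] = {}
        mig_values = np.zeros((counts.years.size, len(SEXES), N_AGES))
        mig_values[:] = 0.0
        for iy, year in enumerate(counts.years):
            grid = counts.require_full(int(year))
            entrants[int(year)] = grid[:, 0].copy()
            if iy > 0 and counts.years[iy - 1] == year - 1:
                prev = counts.require_full(int(year) - 1)
                m = mort.require_full(int(year) - 1)
                surv = prev * (1.0 - m)
                expected = np.zeros_like(prev)
                expected[:, 1:] = surv[:, :-1]
                expected[:, -1] += surv[:, -1]
                mig_values[iy, :, 1:] = grid[:, 1:] - expected[:, 1:]
        migration = AgeSexTable.from_grid(counts.years, mig_values, "signed")
        return cls(counts, entrants, migration)

    def entrants_at(self, year: int) -> np.ndarray:
        return self.entrants.get(int(year), np.zeros(len(SEXES)))

    def migration_at(self, year: int) -> np.ndarray:
        if self.migration is not None and self.migration.has_year(year):
            grid = self.migration.at(year)
            return np.nan_to_num(grid)
        return np.zeros((len(SEXES), N_AGES))

    def scaled(self, k: float) -> "PopulationFrame":
        """Uniformly rescale counts, entrants and migration by ``k``."""
        counts = AgeSexTable.from_grid(self.counts.years, self.counts.values * k, "count")
        entrants = {y: e * k for y, e in self.entrants.items()}
        migration = None
        if self.migration is not None:
            migration = AgeSexTable.from_grid(
                self.migration.years, self.migration.values * k, "signed"
            )
        return PopulationFrame(counts, entrants, migration)


def advance_counts(
    counts: np.ndarray,
    m: np.ndarray,
    entrants: np.ndarray | None = None,
    migration: np.ndarray | None = None,
) -> np.ndarray:
    """One cohort-component step on a (2, 81) count grid.

    Survivors of age a move to a+1; the top bin absorbs survivors of both 99
    and 100; the youngest bin is refilled by entrants; net migration is added
    to the cohorts it joins.
    """
    if np.isnan(m).any() or np.isnan(counts).any():
        isex, ia = [idx[0] for idx in np.nonzero(np.isnan(m) | np.isnan(counts))]
        raise CoverageError(f"missing mortality/count at (sex={SEXES[isex]}, age={AGE_MIN + ia})")
    surv = counts * (1.0 - m)
    nxt = np.zeros_like(counts)
    nxt[:, 1:] = surv[:, :-1]
    nxt[:, -1] += surv[:, -1]
    nxt[:, 0] = 0.0 if entrants is None else entrants
    if migration is not None:
        nxt = nxt + migration
    return nxt


def advance_cohorts(pop: PopulationFrame, mort: MortalitySchedule, year: int) -> PopulationFrame:
    """Advance the frame from ``year`` to ``year + 1``.

    Returns a new frame whose count table includes the projected year,
    satisfying N(year+1, s, a+1) = N(year, s, a)·(1 − m(year, s, a)) +
    M(year+1, s, a+1) with the 100+ bin absorbing and entrants at age 20.
    """
    grid = pop.counts.require_full(year)
    m = mort.require_full(year)
    nxt = advance_counts(grid, m, pop.entrants_at(year + 1), pop.migration_at(year + 1))
    if (nxt < 0).any():
        logger.warning("negative counts after migration in year %d; clamping to 0", year + 1)
        nxt = np.clip(nxt, 0.0, None)
    if pop.counts.has_year(year + 1):
        years = pop.counts.years
        values = pop.counts.values.copy()
        values[pop.counts.year_index(year + 1)] = nxt
    else:
        years = np.append(pop.counts.years, year + 1)
        values = np.concatenate([pop.counts.values, nxt[None, :, :]], axis=0)
        order = np.argsort(years)
        years, values = years[order], values[order]
    return PopulationFrame(AgeSexTable.from_grid(years, values, "count"), pop.entrants, pop.migration)


def band_label(lo: int, hi: int | None) -> str:
    return f"{lo}+" if hi is None or hi >= AGE_MAX else f"{lo}-{hi}"


def band_aggregate(
    table: AgeSexTable,
    pop: PopulationFrame,
    bands: Sequence[tuple[int, int | None]] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Population-weighted band means of a proportion table.

    Bands are closed on both ends; a band with upper bound ``None`` is open
    above (absorbs through 100+).  Output is tidy with an ``age_band`` column.
    """
    recs = []
    for year in table.years:
        vals = table.at(int(year))
        weights = pop.counts.require_full(int(year))
        for isex, sex in enumerate(SEXES):
            for lo, hi in bands:
                hi_eff = AGE_MAX if hi is None else hi
                sel = (AGES >= lo) & (AGES <= hi_eff)
                if not sel.any():
                    raise TableValidationError(f"empty band [{lo}, {hi}]")
                v, w = vals[isex, sel], weights[isex, sel]
                ok = ~np.isnan(v)
                if not ok.any() or w[ok].sum() <= 0:
                    raise TableValidationError(
                        f"band [{lo}, {hi}] has no data or zero weight (year={year}, sex={sex})"
                    )
                recs.append(
                    (int(year), sex, band_label(lo, hi), float(np.average(v[ok], weights=w[ok])))
                )
    return pd.DataFrame(recs, columns=["year", "sex", "age_band", "value"])
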