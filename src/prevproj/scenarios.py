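"""Year-by-year scenario projection of prevalence and case counts.

A scenario fixes two levers over the forecast horizon: a uniform annual
multiplicative trend on age/sex-specific incidence, and whether the relative
mortality of diabetes keeps declining or is frozen at its base-year value.
The four canonical scenarios are:

    A  constant incidence, relative mortality keeps declining (1.6%/yr)
    B  incidence +1%/yr,   relative mortality keeps declining
    C  incidence −1%/yr,   relative mortality keeps declining
    D  constant incidence, relative mortality frozen

The projection advances every (sex, birth-cohort) cell with the closed-form
prevalence recurrence while the population advances by cohort-component
bookkeeping; because the recurrence works on proportions, results are
invariant to the overall population scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    ExcessMortalityModel,
    IncidenceSurface,
    PrevalenceState,
    diabetic_death_risk,
    forward_prevalence_step,
)
from .demography import (
    AGE_MIN,
    AGES,
    DEFAULT_BANDS,
    N_AGES,
    SEXES,
    AgeSexTable,
    MortalitySchedule,
    PopulationFrame,
    advance_counts,
    band_label,
)

#: canonical scenario definitions: (incidence trend, mortality trend)
SCENARIO_TABLE: dict[str, tuple[float, str]] = {
    "A": (0.0, "declining"),
    "B": (+0.01, "declining"),
    "C": (-0.01, "declining"),
    "D": (0.0, "constant"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the scenario table: what incidence and rr do after base year."""

    name: str
    incidence_trend: float
    mortality_trend: str  # "declining" | "constant"
    horizon_end: int
    base_year: int = 2013

    def __post_init__(self) -> None:
        if abs(self.incidence_trend) >= 1:
            raise ValueError("|incidence_trend| must be < 1")
        if self.mortality_trend not in ("declining", "constant"):
            raise ValueError(f"unknown mortality_trend {self.mortality_trend!r}")
        if self.horizon_end <= self.base_year:
            raise ValueError("horizon_end must be after base_year")


def build_scenario(
    name: str | None = None,
    incidence_trend: float | None = None,
    mortality_trend: str | None = None,
    horizon_end: int = 2050,
    base_year: int = 2013,
) -> ScenarioSpec:
    """Construct a named (A–D) or custom scenario."""
    if name is not None and name.upper() in SCENARIO_TABLE:
        trend, mort = SCENARIO_TABLE[name.upper()]
        if incidence_trend is not None:
            trend = incidence_trend
        if mortality_trend is not None:
            mort = mortality_trend
        return ScenarioSpec(name.upper(), trend, mort, horizon_end, base_year)
    if incidence_trend is None or mortality_trend is None:
        raise ValueError(
            f"unknown scenario {name!r}: give a name in {sorted(SCENARIO_TABLE)} "
            "or both incidence_trend and mortality_trend"
        )
    return ScenarioSpec(name or "custom", incidence_trend, mortality_trend, horizon_end, base_year)


def fill_incidence_edges(grid: np.ndarray) -> np.ndarray:
    """Nearest-fill NaN cells along the age axis (per sex).

    Back-calculated surfaces have no age-20 or 100+ cells; projections need
    a full grid, so edge ages borrow the nearest estimated age.
    """
    out = np.asarray(grid, dtype=float).copy()
    for isex in range(out.shape[0]):
        row = out[isex]
        ok = np.flatnonzero(~np.isnan(row))
        if ok.size == 0:
            raise ValueError(f"incidence surface empty for sex {SEXES[isex]}")
        nearest = ok[np.argmin(np.abs(np.arange(row.size)[:, None] - ok[None, :]), axis=1)]
        out[isex] = row[nearest]
    return out


@dataclass
class ProjectionResult:
    """Full annual series of a projection run."""

    years: np.ndarray              # base_year .. horizon_end
    prevalence: np.ndarray         # (T, 2, 81) end-of-year cohort prevalence
    population: np.ndarray         # (T, 2, 81) start-of-year counts
    spec: ScenarioSpec

    def _iy(self, year: int) -> int:
        hits = np.nonzero(self.years == year)[0]
        if hits.size == 0:
            raise KeyError(f"year {year} not in projection")
        return int(hits[0])

    def cases_grid(self, year: int) -> np.ndarray:
        iy = self._iy(year)
        return self.prevalence[iy] * self.population[iy]

    def total_cases(self, year: int, sex: str | None = None) -> float:
        grid = self.cases_grid(year)
        return float(grid.sum() if sex is None else grid[SEXES.index(sex)].sum())

    def total_prevalence_pct(self, year: int, sex: str | None = None) -> float:
        iy = self._iy(year)
        n = self.population[iy]
        cases = self.prevalence[iy] * n
        if sex is not None:
            isex = SEXES.index(sex)
            n, cases = n[isex], cases[isex]
        return float(100.0 * cases.sum() / n.sum())

    def share_aged_65_plus(self, year: int) -> float:
        grid = self.cases_grid(year)
        sel = AGES >= 65
        return float(grid[:, sel].sum() / grid.sum())

    def prevalence_table(self) -> AgeSexTable:
        return AgeSexTable.from_grid(self.years, self.prevalence, "proportion")

    def population_table(self) -> AgeSexTable:
        return AgeSexTable.from_grid(self.years, self.population, "count")

    def annual_frame(self) -> pd.DataFrame:
        recs = []
        for year in self.years:
            y = int(year)
            for sex in (None, *SEXES):
                recs.append(
                    (
                        y,
                        "all" if sex is None else sex,
                        self.total_prevalence_pct(y, sex),
                        self.total_cases(y, sex),
                        self.share_aged_65_plus(y) if sex is None else np.nan,
                    )
                )
        return pd.DataFrame(
            recs, columns=["year", "sex", "prevalence_pct", "cases", "share_65_plus"]
        )


def project(
    base: PrevalenceState,
    inc0: IncidenceSurface | np.ndarray,
    em: ExcessMortalityModel,
    pop: PopulationFrame,
    mort: MortalitySchedule,
    spec: ScenarioSpec,
    migrant_prevalence: str = "cohort",
) -> ProjectionResult:
    """Project prevalence and population from base year to the horizon.

    The step into calendar year y uses the total-population death risk of
    year y−1, the relative mortality at y (frozen at the base year when the
    scenario says so), and the base-year incidence surface scaled by
    (1 + trend)^(y − base_year), clamped to [0, 1].  All rates are indexed
    by the cohort's starting age; the incidence surface by attained age.
    Cohorts age one bin per year with the 100+ bin absorbing; entrant
    cohorts receive the base-year age-20 prevalence scaled by the cumulative
    incidence-trend factor; migrants carry the prevalence of the cohort they
    join (or zero when ``migrant_prevalence="none"``).
    """
    if migrant_prevalence not in ("cohort", "none"):
        raise ValueError(f"unknown migrant_prevalence {migrant_prevalence!r}")
    y0, y1 = spec.base_year, spec.horizon_end
    if base.year != y0:
        raise ValueError(f"base prevalence is for {base.year}, scenario base year is {y0}")
    if isinstance(inc0, AgeSexTable):
        grid = inc0.at(y0) if inc0.has_year(y0) else inc0.values[-1].copy()
    else:
        grid = np.asarray(inc0, dtype=float)
    inc_grid = fill_incidence_edges(grid)
    inc_grid = np.clip(inc_grid, 0.0, 1.0)  # negative back-calculated cells clamp to 0

    T = y1 - y0 + 1
    prevalence = np.empty((T, len(SEXES), N_AGES))
    population = np.empty_like(prevalence)
    p = np.nan_to_num(base.p, nan=0.0)
    n = pop.counts.require_full(y0)
    prevalence[0], population[0] = p, n

    for t in range(1, T):
        y = y0 + t
        m = mort.require_full(y - 1)
        rr = em.as_grid(y if spec.mortality_trend == "declining" else y0)
        m1, m0 = diabetic_death_risk(m, p, rr, em.reference)
        trend_factor = (1.0 + spec.incidence_trend) ** t
        i_attained = np.clip(inc_grid * trend_factor, 0.0, 1.0)
        # incidence seen by a cohort starting at age a is the attained-age
        # a+1 cell; cohorts already in the top bin reuse its cell
        i_start = np.empty_like(i_attained)
        i_start[:, :-1] = i_attained[:, 1:]
        i_start[:, -1] = i_attained[:, -1]
        p_end = forward_prevalence_step(p, m, m1, i_start)  # by starting age

        surv = n * (1.0 - m)
        p_next = np.empty_like(p)
        p_next[:, 1:] = p_end[:, :-1]
        pooled_w = surv[:, -2] + surv[:, -1]
        p_next[:, -1] = np.where(
            pooled_w > 0,
            (p_end[:, -2] * surv[:, -2] + p_end[:, -1] * surv[:, -1]) / np.where(pooled_w > 0, pooled_w, 1.0),
            0.5 * (p_end[:, -2] + p_end[:, -1]),
        )
        p_next[:, 0] = np.clip(base.p[:, 0] * trend_factor, 0.0, 1.0)

        mig = pop.migration_at(y)
        n_next = np.clip(advance_counts(n, m, pop.entrants_at(y), mig), 0.0, None)
        if migrant_prevalence == "none":
            inflow = np.clip(mig, 0.0, None)
            with np.errstate(invalid="ignore", divide="ignore"):
                dilution = np.where(n_next > 0, (n_next - inflow) / n_next, 1.0)
            p_next = p_next * np.clip(dilution, 0.0, 1.0)

        p, n = np.clip(p_next, 0.0, 1.0), n_next
        prevalence[t], population[t] = p, n

    return ProjectionResult(np.arange(y0, y1 + 1), prevalence, population, spec)


def summarize(
    result: ProjectionResult,
    bands: tuple[tuple[int, int | None], ...] = DEFAULT_BANDS,
) -> tuple[dict, pd.DataFrame]:
    """Headline figures plus the tidy annual series.

    The headline dict carries final-year prevalence and case counts (all,
    women, men), the ≥65 case share at base and horizon, and banded
    final-year prevalence in the published three-band layout.
    """
    y0, y1 = int(result.years[0]), int(result.years[-1])
    iy = result._iy(y1)
    headline: dict = {
        "base_year": y0,
        "horizon_year": y1,
        "scenario": result.spec.name,
        "prevalence_pct": {
            "all": result.total_prevalence_pct(y1),
            "female": result.total_prevalence_pct(y1, "female"),
            "male": result.total_prevalence_pct(y1, "male"),
        },
        "cases": {
            "all": result.total_cases(y1),
            "female": result.total_cases(y1, "female"),
            "male": result.total_cases(y1, "male"),
        },
        "share_65_plus": {
            "base": result.share_aged_65_plus(y0),
            "horizon": result.share_aged_65_plus(y1),
        },
    }
    banded: dict[str, dict[str, float]] = {}
    n, p = result.population[iy], result.prevalence[iy]
    for isex, sex in enumerate(SEXES):
        banded[sex] = {}
        for lo, hi in bands:
            sel = (AGES >= lo) & (AGES <= (N_AGES + AGE_MIN - 1 if hi is None else hi))
            banded[sex][band_label(lo, hi)] = float(
                np.average(p[isex, sel], weights=np.maximum(n[isex, sel], 1e-300))
            )
    headline["banded_prevalence"] = banded
    return headline, result.annual_frame()
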