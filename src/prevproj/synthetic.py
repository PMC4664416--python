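"""Synthetic country generator and individual-level microsimulation oracle.

No registry or national-forecast inputs ship with this package, so testing
and demonstration run on a synthetic country that reproduces the
*statistical shape* of the real inputs: an adult (20–100+) population with
a stable-population age pyramid and slow entrant growth, Gompertz-like
age/sex death risks with a secular improvement, a logistic-in-age diabetes
prevalence surface calibrated to published three-band 2007 values, a
log-linear-in-age incidence surface whose level is solved so the
population-average incidence matches the published 2013 sex totals
(3.3 / 5.5 per 1000), and a relative mortality of diabetes that declines
with age and by 1.6% per year.

Ground truth is self-consistent by construction: the baseline prevalence
series is generated *forward* from the incidence surface through the same
recurrence the estimator inverts, so incidence recovery is a genuine
inverse-problem test.  The microsimulation follows individuals with the
identical within-year event order (death first, at m1 for prevalent cases
and m0 otherwise; incidence among the year's survivors), making the
deterministic recurrence its exact expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import (
    ExcessMortalityModel,
    IncidenceSurface,
    PrevalenceState,
    diabetic_death_risk,
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
    advance_cohorts,
)
from .scenarios import ProjectionResult, ScenarioSpec, build_scenario, project

#: published three-band prevalence at the first baseline year (women, men)
#: used as calibration anchors for the age-logistic prevalence curve
BAND_ANCHORS_START = {
    "female": (0.012, 0.046, 0.117),
    "male": (0.015, 0.074, 0.160),
}
#: published 2013 sex-specific incidence totals (per person per year)
INCIDENCE_ANCHORS = {"female": 0.0033, "male": 0.0055}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic country; defaults are the study conditions."""

    seed: int = 42
    n_individuals: int = 200_000
    baseline_start: int = 2007
    base_year: int = 2013
    horizon_end: int = 2050

    # demography: entrant cohort per sex and its annual growth; migration off
    entrant_size: float = 60_000.0
    entrant_growth: float = 0.005
    migration_rate: float = 0.0

    # Gompertz all-cause mortality m(a) = level·exp(slope·(a−20)), capped,
    # improving by a constant factor per calendar year
    mort_level: tuple[float, float] = (4.0e-4, 6.0e-4)  # female, male at age 20
    mort_slope: float = 0.09
    mort_cap: float = 0.7
    mort_improvement: float = 0.010

    # incidence: log-linear in age, level solved against INCIDENCE_ANCHORS,
    # then multiplied by inc_level_scale (0 turns incidence off entirely)
    inc_slope: float = 0.06
    inc_cap: float = 0.05
    inc_level_scale: float = 1.0

    # relative mortality of diabetes: declining in age, trending down in time
    rr_excess_at_20: float = 2.5
    rr_age_decay: float = 0.03
    rr_annual_decline: float = 0.016
    rr_convention: str = "excess"
    rr_reference: str = "vs_nondiabetic"

    nonpharm_share: float = 0.226


@dataclass
class SyntheticCountry:
    """The full generated input set plus its ground truth."""

    spec: SyntheticSpec
    population: PopulationFrame
    mortality: MortalitySchedule
    prevalence: AgeSexTable          # baseline series, generated forward
    incidence: IncidenceSurface      # ground-truth surface, attained-age indexed
    excess_mortality: ExcessMortalityModel
    params: dict = field(default_factory=dict)

    def base_state(self) -> PrevalenceState:
        return PrevalenceState(self.spec.base_year, self.prevalence.at(self.spec.base_year))

    def closed_population(self) -> PopulationFrame:
        """Base-year counts with no entrants or migration (closed cohort)."""
        return PopulationFrame.closed(
            self.spec.base_year, self.population.counts.require_full(self.spec.base_year)
        )


def _mortality_grid(spec: SyntheticSpec, year: int) -> np.ndarray:
    improve = (1.0 - spec.mort_improvement) ** (year - spec.baseline_start)
    grid = np.empty((len(SEXES), N_AGES))
    for isex in range(len(SEXES)):
        grid[isex] = np.minimum(
            spec.mort_level[isex] * np.exp(spec.mort_slope * (AGES - AGE_MIN)) * improve,
            spec.mort_cap,
        )
    return grid


def _rr0_grid(spec: SyntheticSpec) -> np.ndarray:
    rr = 1.0 + spec.rr_excess_at_20 * np.exp(-spec.rr_age_decay * (AGES - AGE_MIN))
    return np.tile(rr, (len(SEXES), 1))


def _logistic(ages: np.ndarray, level: float, midpoint: float, scale: float) -> np.ndarray:
    return level / (1.0 + np.exp(-(ages - midpoint) / scale))


def _fit_prevalence_curve(weights: np.ndarray, anchors: tuple[float, ...]) -> np.ndarray:
    """Fit an age-logistic to the three banded anchors under given weights."""
    sels = [
        (AGES >= lo) & (AGES <= (AGES[-1] if hi is None else hi)) for lo, hi in DEFAULT_BANDS
    ]

    def banded(params: np.ndarray) -> np.ndarray:
        curve = _logistic(AGES.astype(float), *params)
        return np.array([np.average(curve[s], weights=weights[s]) for s in sels])

    fit = least_squares(
        lambda q: banded(q) - np.asarray(anchors),
        x0=np.array([0.18, 72.0, 14.0]),
        bounds=([0.01, 40.0, 3.0], [0.8, 100.0, 40.0]),
    )
    return _logistic(AGES.astype(float), *fit.x)


def generate_country(spec: SyntheticSpec = SyntheticSpec()) -> SyntheticCountry:
    """Build the deterministic synthetic country for ``spec``.

    The output is bit-identical for identical specs (no randomness is used
    here; the seed feeds :func:`microsimulate`).  The baseline prevalence
    series is produced by running the forward recurrence from the fitted
    start-year curve under the ground-truth incidence surface.
    """
    y_start, y_base, y_end = spec.baseline_start, spec.base_year, spec.horizon_end
    years = np.arange(y_start, y_end + 1)

    mort_values = np.stack([_mortality_grid(spec, int(y)) for y in years])
    if (mort_values >= 1.0).any():
        raise ValueError("mortality parameters produce death risks >= 1")
    mortality = AgeSexTable.from_grid(years, mort_values, "risk")

    # stable-population start: each age is the entrant cohort of its birth
    # year carried through survival and entrant growth
    m0_grid = mort_values[0]
    n_start = np.empty((len(SEXES), N_AGES))
    for isex in range(len(SEXES)):
        surv = np.concatenate([[1.0], np.cumprod(1.0 - m0_grid[isex, :-1])])
        n_start[isex] = spec.entrant_size * surv * (1.0 + spec.entrant_growth) ** (-(AGES - AGE_MIN))
    pop = PopulationFrame(
        AgeSexTable.from_grid([y_start], n_start[None], "count"),
        entrants={
            int(y): np.full(len(SEXES), spec.entrant_size * (1.0 + spec.entrant_growth) ** (int(y) - y_start))
            for y in years
        },
    )
    for y in years[:-1]:
        pop = advance_cohorts(pop, mortality, int(y))

    # prevalence curve at the start year, calibrated to the banded anchors
    p_start = np.stack(
        [
            _fit_prevalence_curve(n_start[isex], BAND_ANCHORS_START[sex])
            for isex, sex in enumerate(SEXES)
        ]
    )
    p_start = np.clip(p_start, 0.0, 1.0)

    em = ExcessMortalityModel(
        rr0=_rr0_grid(spec),
        base_year=y_start,
        annual_decline=spec.rr_annual_decline,
        convention=spec.rr_convention,
        reference=spec.rr_reference,
    )

    # incidence level per sex solved so the diabetes-free-weighted mean at the
    # start year equals the published sex totals
    inc_shape = np.exp(spec.inc_slope * (AGES - 60.0))
    inc_grid = np.empty((len(SEXES), N_AGES))
    for isex, sex in enumerate(SEXES):
        w = n_start[isex] * (1.0 - p_start[isex])
        level = spec.inc_level_scale * INCIDENCE_ANCHORS[sex] / np.average(inc_shape, weights=w)
        inc_grid[isex] = np.minimum(level * inc_shape, spec.inc_cap)
    if (inc_grid < 0).any() or (inc_grid > 1).any():
        raise ValueError("incidence parameters produce risks outside [0, 1]")
    incidence = AgeSexTable.from_grid([y_base], inc_grid[None], "risk")

    # baseline prevalence generated forward through the recurrence itself
    baseline_run = project(
        PrevalenceState(y_start, p_start),
        inc_grid,
        em,
        pop,
        mortality,
        ScenarioSpec("baseline", 0.0, "declining", horizon_end=y_base, base_year=y_start),
    )
    prevalence = AgeSexTable.from_grid(
        np.arange(y_start, y_base + 1), baseline_run.prevalence, "proportion"
    )

    params = {
        "spec": asdict(spec),
        "prevalence_anchors_start_year": BAND_ANCHORS_START,
        "incidence_anchors": INCIDENCE_ANCHORS,
    }
    return SyntheticCountry(spec, pop, mortality, prevalence, incidence, em, params)


@dataclass
class MicrosimResult:
    """Annual aggregates of the individual-level simulation."""

    counts: pd.DataFrame  # year, sex, n_alive, n_diabetic, n_deaths, n_new_cases

    def prevalence(self, year: int, sex: str | None = None) -> float:
        df = self.counts[self.counts["year"] == year]
        if sex is not None:
            df = df[df["sex"] == sex]
        return float(df["n_diabetic"].sum() / df["n_alive"].sum())

    def n_alive(self, year: int) -> int:
        return int(self.counts[self.counts["year"] == year]["n_alive"].sum())


def microsimulate(
    spec: SyntheticSpec,
    scenario: ScenarioSpec | None = None,
    country: SyntheticCountry | None = None,
    closed: bool = True,
) -> MicrosimResult:
    """Simulate individuals year by year as a stochastic oracle.

    Individuals are drawn from the base-year population with diabetes status
    Bernoulli at the cohort prevalence.  Each year, prevalent cases die with
    probability m1 and others with m0 (split from the total-population risk
    using the deterministic cohort prevalence, so the cohort's overall death
    risk is exactly m); disease-free survivors convert with the
    scenario-scaled incidence; everyone then ages one year (100+ absorbing).
    ``closed=True`` (default) runs the base-year cohort with no entrants.
    """
    if spec.n_individuals < 1:
        raise ValueError("need at least one simulated individual")
    if country is None:
        country = generate_country(spec)
    if scenario is None:
        scenario = build_scenario("A", horizon_end=spec.horizon_end, base_year=spec.base_year)
    rng = np.random.default_rng(spec.seed)
    y0, y1 = scenario.base_year, scenario.horizon_end

    pop_frame = country.closed_population() if closed else country.population
    det = project(
        country.base_state(),
        country.incidence,
        country.excess_mortality,
        pop_frame,
        country.mortality,
        scenario,
    )

    n_grid = country.population.counts.require_full(y0)
    probs = (n_grid / n_grid.sum()).ravel()
    cells = rng.choice(probs.size, size=spec.n_individuals, p=probs)
    sex_idx = cells // N_AGES
    age_idx = cells % N_AGES
    base_p = country.base_state().p
    diabetic = rng.random(spec.n_individuals) < base_p[sex_idx, age_idx]
    alive = np.ones(spec.n_individuals, dtype=bool)

    inc_grid = np.clip(
        country.incidence.at(y0)
        if country.incidence.has_year(y0)
        else country.incidence.values[-1],
        0.0,
        1.0,
    )

    def snapshot(year: int) -> list[tuple]:
        rows = []
        for isex, sex in enumerate(SEXES):
            sel = alive & (sex_idx == isex)
            rows.append((year, sex, int(sel.sum()), int((sel & diabetic).sum()), 0, 0))
        return rows

    records = snapshot(y0)
    for t in range(1, y1 - y0 + 1):
        y = y0 + t
        m = country.mortality.require_full(y - 1)
        rr = country.excess_mortality.as_grid(
            y if scenario.mortality_trend == "declining" else y0
        )
        p_det = det.prevalence[t - 1]  # cohort prevalence by starting age
        m1, m0 = diabetic_death_risk(m, p_det, rr, country.excess_mortality.reference)
        i_att = np.clip(inc_grid * (1.0 + scenario.incidence_trend) ** t, 0.0, 1.0)
        i_start = np.empty_like(i_att)
        i_start[:, :-1] = i_att[:, 1:]
        i_start[:, -1] = i_att[:, -1]

        u_death = rng.random(spec.n_individuals)
        risk = np.where(diabetic, m1[sex_idx, age_idx], m0[sex_idx, age_idx])
        dies = alive & (u_death < risk)
        alive = alive & ~dies
        u_inc = rng.random(spec.n_individuals)
        converts = alive & ~diabetic & (u_inc < i_start[sex_idx, age_idx])
        diabetic = diabetic | converts
        age_idx = np.minimum(age_idx + 1, N_AGES - 1)

        for (yy, sex, n_alive, n_diab, _, _) in snapshot(y):
            isex = SEXES.index(sex)
            records.append(
                (
                    yy,
                    sex,
                    n_alive,
                    n_diab,
                    int((dies & (sex_idx == isex)).sum()),
                    int((converts & (sex_idx == isex)).sum()),
                )
            )

    counts = pd.DataFrame(
        records, columns=["year", "sex", "n_alive", "n_diabetic", "n_deaths", "n_new_cases"]
    )
    return MicrosimResult(counts)
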