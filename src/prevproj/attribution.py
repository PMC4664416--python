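"""Counterfactual decomposition of a projected case increase, and the
incidence decline required to hold prevalence flat.

The drivers of a growing case count — a larger population, an older
population, and better relative survival with the disease — are not
mutually exclusive, so there is no unique additive split.  The approach
here is sequential counterfactual substitution: starting from the full
projection, undo one driver at a time (rescale the horizon-year population
total back to the base-year total; replace the horizon-year age/sex
composition by the base-year composition; freeze the relative-mortality
trend) and attribute to each driver the drop in horizon-year cases its
substitution causes.  Whatever increase survives all substitutions is the
residual (dominated by falling general-population mortality, which the
substitutions deliberately leave untouched).  Components sum to the total
increase exactly, by construction.  Because the split depends on the
substitution order, the order is a recorded parameter and a Shapley-style
average over all orders is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import ExcessMortalityModel, IncidenceSurface, PrevalenceState
from .demography import MortalitySchedule, PopulationFrame, SEXES
from .scenarios import ProjectionResult, ScenarioSpec, project

FACTORS = ("population_size", "age_structure", "relative_survival")


@dataclass
class AttributionResult:
    """Additive split of a projected case increase."""

    base_cases: float
    final_cases: float
    components: dict[str, float]  # factor -> drop in final-year cases
    residual: float
    order: tuple[str, ...]
    mode: str

    @property
    def total_increase(self) -> float:
        return self.final_cases - self.base_cases

    @property
    def pct_increase_of_base(self) -> float:
        return 100.0 * self.total_increase / self.base_cases

    def shares(self) -> dict[str, float]:
        """Each component (and the residual) as a share of the total increase."""
        tot = self.total_increase
        if tot == 0:
            return {k: 0.0 for k in (*self.components, "residual")}
        out = {k: v / tot for k, v in self.components.items()}
        out["residual"] = self.residual / tot
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, v, self.shares()[k]) for k, v in self.components.items()]
        rows.append(("residual", self.residual, self.shares()["residual"]))
        rows.append(("total_increase", self.total_increase, 1.0 if self.total_increase else 0.0))
        return pd.DataFrame(rows, columns=["component", "cases", "share_of_increase"])


def _final_cases_under(
    flags: frozenset[str],
    full: ProjectionResult,
    frozen: ProjectionResult,
    base_pop: np.ndarray,
) -> float:
    """Horizon-year case count with the flagged drivers substituted away."""
    y1 = int(full.years[-1])
    iy = full._iy(y1)
    n = (frozen if "relative_survival" in flags else full).population[iy].copy()
    p = (frozen if "relative_survival" in flags else full).prevalence[iy]
    if "population_size" in flags:
        n = n * (base_pop.sum() / n.sum())
    if "age_structure" in flags:
        n = n.sum() * (base_pop / base_pop.sum())
    return float((p * n).sum())


def decompose_increase(
    result: ProjectionResult,
    base: PrevalenceState,
    inc0: IncidenceSurface | np.ndarray,
    em: ExcessMortalityModel,
    pop: PopulationFrame,
    mort: MortalitySchedule,
    order: tuple[str, ...] = FACTORS,
    mode: str = "sequential",
) -> AttributionResult:
    """Decompose ``result``'s case increase into driver components.

    ``mode="sequential"`` applies the substitutions cumulatively in
    ``order``; ``mode="shapley"`` averages each factor's marginal
    contribution over all substitution orders.  In both modes components
    plus residual equal the total increase exactly.
    """
    if sorted(order) != sorted(FACTORS):
        raise ValueError(f"order must be a permutation of {FACTORS}")
    if mode not in ("sequential", "shapley"):
        raise ValueError(f"unknown mode {mode!r}")
    y0, y1 = int(result.years[0]), int(result.years[-1])
    base_pop = result.population[result._iy(y0)]
    base_cases = float((result.prevalence[result._iy(y0)] * base_pop).sum())
    final_cases = float(result.cases_grid(y1).sum())
    # the relative-survival counterfactual is a genuine re-run with the rr
    # trend frozen; population/composition substitutions act on the final grid
    if result.spec.mortality_trend == "constant":
        frozen = result
    else:
        frozen = project(base, inc0, em, pop, mort, replace(result.spec, mortality_trend="constant"))

    def cases_at(flags: frozenset[str]) -> float:
        return _final_cases_under(flags, result, frozen, base_pop)

    if mode == "sequential":
        components: dict[str, float] = {}
        active: frozenset[str] = frozenset()
        prev = cases_at(active)
        assert abs(prev - final_cases) < 1e-6 * max(1.0, final_cases)
        for factor in order:
            active = active | {factor}
            cur = cases_at(active)
            components[factor] = prev - cur
            prev = cur
        residual = prev - base_cases
    else:
        marg: dict[str, list[float]] = {f: [] for f in FACTORS}
        end_cases = cases_at(frozenset(FACTORS))
        for perm in itertools.permutations(FACTORS):
            active: frozenset[str] = frozenset()
            prev = final_cases
            for factor in perm:
                active = active | {factor}
                cur = cases_at(active)
                marg[factor].append(prev - cur)
                prev = cur
        components = {f: float(np.mean(marg[f])) for f in FACTORS}
        residual = end_cases - base_cases
        # distribute averaging round-off into the largest component so the
        # additive identity holds to the last digit
        slack = (final_cases - base_cases) - (sum(components.values()) + residual)
        top = max(components, key=lambda f: abs(components[f]))
        components[top] += slack
    return AttributionResult(base_cases, final_cases, components, residual, tuple(order), mode)


@dataclass
class DeclineSolution:
    """Annual incidence decline that keeps prevalence flat, with its trace."""

    delta: float
    converged: bool
    trace: pd.DataFrame  # iteration, lo, hi, mid, gap

    def __float__(self) -> float:
        return self.delta


def horizon_prevalence_gap(
    delta: float,
    base: PrevalenceState,
    inc0: IncidenceSurface | np.ndarray,
    em: ExcessMortalityModel,
    pop: PopulationFrame,
    mort: MortalitySchedule,
    spec: ScenarioSpec,
) -> float:
    """Horizon minus base total prevalence (proportion scale) at decline ``delta``."""
    run = project(base, inc0, em, pop, mort, replace(spec, incidence_trend=-delta))
    y0, y1 = int(run.years[0]), int(run.years[-1])
    return (run.total_prevalence_pct(y1) - run.total_prevalence_pct(y0)) / 100.0


def required_incidence_decline(
    base: PrevalenceState,
    inc0: IncidenceSurface | np.ndarray,
    em: ExcessMortalityModel,
    pop: PopulationFrame,
    mort: MortalitySchedule,
    spec: ScenarioSpec,
    bracket: tuple[float, float] = (0.0, 0.2),
    tol: float = 1e-6,
    max_iter: int = 200,
) -> DeclineSolution:
    """Solve for the annual incidence decline δ that flattens prevalence.

    Bisection on δ ∈ ``bracket``: the horizon-year total adult prevalence
    (both sexes) is driven to the base-year value within ``tol`` on the
    proportion scale.  Projected prevalence decreases monotonically in δ,
    which validates the bracket.  Returns δ = 0 when prevalence does not
    rise even without any decline.
    """
    gap = lambda d: horizon_prevalence_gap(d, base, inc0, em, pop, mort, spec)
    lo, hi = bracket
    rows = []
    g_lo = gap(lo)
    rows.append((0, lo, hi, lo, g_lo))
    if g_lo <= tol:
        return DeclineSolution(lo, True, pd.DataFrame(rows, columns=["iter", "lo", "hi", "mid", "gap"]))
    g_hi = gap(hi)
    rows.append((1, lo, hi, hi, g_hi))
    if g_hi > 0:
        raise ValueError(
            f"no sign change on bracket {bracket}: gap({lo})={g_lo:.3e}, gap({hi})={g_hi:.3e}; "
            "prevalence still rises at the maximum decline considered"
        )
    mid, g_mid = lo, g_lo
    for k in range(2, max_iter + 2):
        mid = 0.5 * (lo + hi)
        g_mid = gap(mid)
        rows.append((k, lo, hi, mid, g_mid))
        if abs(g_mid) <= tol:
            break
        if g_mid > 0:
            lo = mid
        else:
            hi = mid
    trace = pd.DataFrame(rows, columns=["iter", "lo", "hi", "mid", "gap"])
    return DeclineSolution(float(mid), bool(abs(g_mid) <= tol), trace)
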