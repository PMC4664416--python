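"""The discrete-time illness–death recurrence and its inversion.

For a closed birth cohort of one sex, write p_y for the diabetes prevalence
at the end of year y, m_y for the one-year death risk in the whole cohort,
m_{1,y} for the death risk among members with diabetes, and i_y for the
cumulative incidence (risk) of diabetes among the disease-free.  End-of-year
prevalence is the surviving prevalent cases plus the incident cases arising
among the year's disease-free survivors, renormalised to the surviving
cohort:

    p_y = [ (1 - m1) p_{y-1}  +  ( (1 - m) - (1 - m1) p_{y-1} ) i_y ] / (1 - m)

Because the relation is affine in i_y it inverts exactly, which is how
incidence is back-calculated from an observed prevalence series and
mortality:

    i_y = [ (1 - m) p_y - (1 - m1) p_{y-1} ] / [ (1 - m) - (1 - m1) p_{y-1} ]

Both operations are elementwise over (sex, age) grids.  The module also
closes the mortality model: published inputs give the total-population death
risk m and the relative mortality of diabetes rr, from which the pair
(m1, m0) is derived so that the cohort's mortality budget is conserved.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demography import (
    AGE_MIN,
    AGES,
    N_AGES,
    SEXES,
    AgeSexTable,
    CoverageError,
    MortalitySchedule,
)

logger = logging.getLogger("prevproj")

ArrayLike = float | np.ndarray


class ConsistencyError(ValueError):
    """Inputs violate the recurrence's internal accounting."""


class DegenerateCohortError(ZeroDivisionError):
    """The back-calculation denominator is non-positive."""


class NegativeIncidenceWarning(UserWarning):
    """Observed prevalence fell faster than mortality can explain."""


def _nan_any(cond: np.ndarray) -> bool:
    return bool(np.any(np.nan_to_num(cond.astype(float), nan=0.0)))


def forward_prevalence_step(p_prev: ArrayLike, m: ArrayLike, m1: ArrayLike, i: ArrayLike) -> ArrayLike:
    """Advance end-of-year prevalence by one year for a cohort.

    All arguments are probabilities in [0, 1]; ``m`` must be < 1 and the
    surviving prevalent mass (1−m1)·p_prev may not exceed total survival 1−m.
    NaN cells propagate (missing data stays missing).
    """
    p_prev, m, m1, i = (np.asarray(x, dtype=float) for x in (p_prev, m, m1, i))
    for name, x in (("p_prev", p_prev), ("m", m), ("m1", m1), ("i", i)):
        if _nan_any((x < 0) | (x > 1)):
            raise ValueError(f"{name} outside [0, 1]")
    if _nan_any(m >= 1):
        raise ZeroDivisionError("total death risk m = 1: cohort extinct within the year")
    surviving_prevalent = (1.0 - m1) * p_prev
    if _nan_any(surviving_prevalent > (1.0 - m) + 1e-12):
        raise ConsistencyError("surviving cases with diabetes exceed total survivors")
    p = (surviving_prevalent + ((1.0 - m) - surviving_prevalent) * i) / (1.0 - m)
    p = np.clip(p, 0.0, 1.0)  # guard float dust at the boundaries
    return p if p.ndim else float(p)


def backcalc_incidence(p_now: ArrayLike, p_prev: ArrayLike, m: ArrayLike, m1: ArrayLike) -> ArrayLike:
    """Solve the recurrence for the cumulative incidence i_y.

    A negative result means the observed prevalence fell faster than excess
    mortality explains; it is returned as-is and flagged with a
    :class:`NegativeIncidenceWarning` so data inconsistencies stay visible.
    """
    p_now, p_prev, m, m1 = (np.asarray(x, dtype=float) for x in (p_now, p_prev, m, m1))
    denom = (1.0 - m) - (1.0 - m1) * p_prev
    if _nan_any(denom <= 0):
        raise DegenerateCohortError(
            "non-positive denominator (1-m) - (1-m1)*p_prev: degenerate cohort"
        )
    i = ((1.0 - m) * p_now - (1.0 - m1) * p_prev) / denom
    if _nan_any(i < -1e-15):
        warnings.warn(
            "back-calculated incidence is negative for at least one cell",
            NegativeIncidenceWarning,
            stacklevel=2,
        )
    return i if i.ndim else float(i)


def diabetic_death_risk(
    m: ArrayLike, p: ArrayLike, rr: ArrayLike, reference: str = "vs_nondiabetic"
) -> tuple[ArrayLike, ArrayLike]:
    """Split a total-population death risk into diabetic / non-diabetic risks.

    Parameters
    ----------
    m : one-year death risk in the total population.
    p : diabetes prevalence in that population.
    rr : relative mortality risk (≥ 1) of diabetes.
    reference : ``vs_nondiabetic`` interprets rr = m1/m0 and solves the
        mixture identity p·m1 + (1−p)·m0 = m exactly; ``vs_total``
        interprets rr = m1/m and back-solves m0 from the same identity.

    Returns
    -------
    (m1, m0) : death risks among people with / without diabetes, in [0, 1].
    """
    m, p, rr = (np.asarray(x, dtype=float) for x in (m, p, rr))
    if _nan_any(rr < 1):
        raise ValueError("relative mortality rr must be >= 1")
    if reference == "vs_nondiabetic":
        # written as 1 + p(rr-1) so rr = 1 yields m0 = m1 = m exactly
        m0 = m / (1.0 + p * (rr - 1.0))
        m1 = rr * m0
    elif reference == "vs_total":
        m1 = np.minimum(rr * m, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m0 = np.where(p < 1.0, (m - p * m1) / (1.0 - p), m1)
        if _nan_any(m0 < -1e-12):
            raise ConsistencyError(
                "vs_total split implies negative non-diabetic mortality (p*rr*m > m)"
            )
    else:
        raise ValueError(f"unknown rr reference {reference!r}")
    m1 = np.clip(m1, 0.0, 1.0)
    m0 = np.clip(m0, 0.0, 1.0)
    if m1.ndim == 0:
        return float(m1), float(m0)
    return m1, m0


@dataclass
class ExcessMortalityModel:
    """Relative mortality of diabetes and its secular trend.

    ``rr0`` is the relative risk at ``base_year`` (a scalar or a (2, 81)
    sex × age grid).  Each year the excess declines by ``annual_decline``
    (default 1.6%/yr).  Under the ``excess`` convention the decline applies
    to rr−1, so rr → 1 asymptotically; under ``ratio`` it applies to rr
    itself with a floor at 1.  ``reference`` states which population rr is
    relative to and is consumed by :func:`diabetic_death_risk`.
    """

    rr0: np.ndarray | float
    base_year: int
    annual_decline: float = 0.016
    convention: str = "excess"
    reference: str = "vs_nondiabetic"

    def __post_init__(self) -> None:
        rr0 = np.asarray(self.rr0, dtype=float)
        if _nan_any(rr0 < 1):
            raise ValueError("baseline relative mortality rr0 must be >= 1")
        if not 0.0 <= self.annual_decline < 1.0:
            raise ValueError("annual_decline must be in [0, 1)")
        if self.convention not in ("excess", "ratio"):
            raise ValueError(f"unknown trend convention {self.convention!r}")
        if self.reference not in ("vs_nondiabetic", "vs_total"):
            raise ValueError(f"unknown rr reference {self.reference!r}")
        self.rr0 = rr0

    def rr_at(self, years_elapsed: int) -> np.ndarray | float:
        """Relative risk after ``years_elapsed`` years of trend (t ≥ 0)."""
        if years_elapsed < 0:
            raise ValueError("years_elapsed must be >= 0")
        decay = (1.0 - self.annual_decline) ** years_elapsed
        if self.convention == "excess":
            rr = 1.0 + (self.rr0 - 1.0) * decay
        else:
            rr = np.maximum(self.rr0 * decay, 1.0)
        return rr if np.ndim(rr) else float(rr)

    def rr_for_year(self, year: int) -> np.ndarray | float:
        """rr at a calendar year (clamped to the model's base year)."""
        return self.rr_at(max(0, int(year) - self.base_year))

    def as_grid(self, year: int) -> np.ndarray:
        rr = np.asarray(self.rr_for_year(year), dtype=float)
        return np.broadcast_to(rr, (len(SEXES), N_AGES)).copy() if rr.ndim < 2 else rr


def rr_at_year(model: ExcessMortalityModel, years_elapsed: int) -> np.ndarray | float:
    """Functional alias for :meth:`ExcessMortalityModel.rr_at`."""
    return model.rr_at(years_elapsed)


@dataclass(frozen=True)
class TreatmentShare:
    """Share of all diabetes that is not pharmacologically treated."""

    nonpharm_share: float = 0.226

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonpharm_share < 1.0:
            raise ValueError("nonpharm_share must be in [0, 1)")


def amplification_factor(share: TreatmentShare | float = TreatmentShare()) -> float:
    """Factor inflating pharmacologically treated counts to all diabetes.

    If a fraction s of all diabetes is managed without glucose-lowering
    drugs, prescription-registry counts cover 1−s of cases and the total is
    recovered by multiplying by 1/(1−s).  The default s = 0.226 gives 1.292.
    """
    s = share.nonpharm_share if isinstance(share, TreatmentShare) else float(share)
    if not 0.0 <= s < 1.0:
        raise ValueError("non-pharmacological share must be in [0, 1)")
    return 1.0 / (1.0 - s)


def apply_undiagnosed(
    prevalence: ArrayLike, undiag_share: float, convention: str = "of_total"
) -> ArrayLike:
    """Inflate diagnosed prevalence to include undiagnosed diabetes.

    ``of_total``: the share u is of *all* diabetes, so p → p / (1 − u).
    ``of_diagnosed``: u extra cases per diagnosed case, so p → p · (1 + u).
    Callers must record the convention in output metadata.
    """
    if not 0.0 <= undiag_share < 1.0:
        raise ValueError("undiagnosed share must be in [0, 1)")
    p = np.asarray(prevalence, dtype=float)
    if convention == "of_total":
        out = p / (1.0 - undiag_share)
    elif convention == "of_diagnosed":
        out = p * (1.0 + undiag_share)
    else:
        raise ValueError(f"unknown undiagnosed convention {convention!r}")
    return out if out.ndim else float(out)


@dataclass
class PrevalenceState:
    """End-of-year diabetes prevalence p(sex, age) for one calendar year."""

    year: int
    p: np.ndarray  # (2, 81)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(SEXES), N_AGES):
            raise ValueError(f"prevalence grid must be (2, {N_AGES})")
        if _nan_any((self.p < 0) | (self.p > 1)):
            raise ValueError("prevalence outside [0, 1]")


# IncidenceSurface is an AgeSexTable with role "risk", indexed by the age a
# cohort has attained at the end of the year the incidence refers to.
IncidenceSurface = AgeSexTable


@dataclass
class BaselineIncidence:
    """Back-calculated incidence surface plus its negative-cell warning mask."""

    surface: IncidenceSurface
    negative_mask: np.ndarray  # bool, same shape as surface.values
    skipped_cells: list[tuple[int, str, int]] = field(default_factory=list)

    def negative_cells(self) -> pd.DataFrame:
        recs = []
        for iy, year in enumerate(self.surface.years):
            for isex, sex in enumerate(SEXES):
                for ia in np.flatnonzero(self.negative_mask[iy, isex]):
                    recs.append(
                        (int(year), sex, int(AGE_MIN + ia), float(self.surface.values[iy, isex, ia]))
                    )
        return pd.DataFrame(recs, columns=["year", "sex", "age", "value"])


def estimate_baseline(
    prev: AgeSexTable, mort: MortalitySchedule, em: ExcessMortalityModel
) -> BaselineIncidence:
    """Back-calculate the incidence surface from an observed prevalence series.

    For each sex and each consecutive year pair (y−1, y) the cohort link
    p_{y−1}(age a) → p_y(age a+1) is inverted with the mortality of year
    y−1 and the diabetic death risk implied by the relative-mortality model
    at year y.  The result is indexed by attained age (a+1), so cells cover
    ages 21..99: age 20 has no predecessor cohort and the pooled 100+ bin
    has no invertible link (those cells are skipped and logged).
    """
    years = prev.years
    if years.size < 2:
        raise ValueError("need at least two consecutive prevalence years")
    if np.any(np.diff(years) != 1):
        gap = int(years[np.flatnonzero(np.diff(years) != 1)[0]])
        raise ValueError(f"gap in prevalence years after {gap}")
    out_years = years[1:]
    values = np.full((out_years.size, len(SEXES), N_AGES), np.nan)
    neg = np.zeros_like(values, dtype=bool)
    skipped: list[tuple[int, str, int]] = []
    for k, y in enumerate(out_years):
        p_prev = prev.at(int(y) - 1)
        p_now = prev.at(int(y))
        m = mort.at(int(y) - 1)
        rr = em.as_grid(int(y))
        for isex, sex in enumerate(SEXES):
            for ia in range(N_AGES - 1):  # starting age 20..99 -> attained 21..100
                attained = ia + 1
                if attained == N_AGES - 1:
                    # cohorts 99 and 100 pool into the absorbing bin; the
                    # individual link is not recoverable
                    skipped.append((int(y), sex, AGE_MIN + attained))
                    logger.debug("skipping pooled top-age cell (%d, %s, 100)", y, sex)
                    continue
                pp, pn, mm = p_prev[isex, ia], p_now[isex, attained], m[isex, ia]
                if np.isnan(pp) or np.isnan(pn) or np.isnan(mm):
                    continue
                m1, _ = diabetic_death_risk(mm, pp, rr[isex, ia], em.reference)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", NegativeIncidenceWarning)
                    i = backcalc_incidence(pn, pp, mm, m1)
                values[k, isex, attained] = i
                neg[k, isex, attained] = i < 0
    if neg.any():
        logger.warning("%d negative back-calculated incidence cells", int(neg.sum()))
    # negatives are preserved by design (flagged, not clamped), so the surface
    # is stored with the signed role; projections clamp at 0 downstream
    surface = AgeSexTable.from_grid(out_years, values, "signed")
    return BaselineIncidence(surface, neg, skipped)
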