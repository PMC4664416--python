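"""End-to-end pipeline: back-calculate baseline incidence, project scenarios,
decompose the increase, and solve for the flattening incidence decline.

The pipeline is configuration-driven (YAML → :class:`RunConfig`), writes
every stage as tidy CSV, and records all convention flags and warnings in a
JSON manifest so a run is auditable and byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .attribution import FACTORS, decompose_increase, required_incidence_decline
from .core import (
    ExcessMortalityModel,
    PrevalenceState,
    amplification_factor,
    apply_undiagnosed,
    estimate_baseline,
)
from .demography import (
    AgeSexTable,
    PopulationFrame,
    read_agesex_csv,
)
from .scenarios import build_scenario, project, summarize

logger = logging.getLogger("prevproj")


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    population_csv: Path
    mortality_csv: Path
    prevalence_csv: Path
    rr_csv: Optional[Path] = None
    rr_constant: Optional[float] = None

    rr_annual_decline: float = 0.016
    rr_convention: Literal["excess", "ratio"] = "excess"
    rr_reference: Literal["vs_nondiabetic", "vs_total"] = "vs_nondiabetic"

    scenarios: list[str] = Field(default_factory=lambda: ["A"])
    custom_incidence_trend: Optional[float] = None
    custom_mortality_trend: Optional[Literal["declining", "constant"]] = None
    base_year: Optional[int] = None  # default: last prevalence year
    horizon_end: int = 2050
    migrant_prevalence: Literal["cohort", "none"] = "cohort"

    amplify_treated: bool = False
    nonpharm_share: float = 0.226
    undiagnosed_share: Optional[float] = None
    undiagnosed_convention: Literal["of_total", "of_diagnosed"] = "of_total"

    decompose: bool = False
    decomposition_order: tuple[str, str, str] = FACTORS
    decomposition_mode: Literal["sequential", "shapley"] = "sequential"
    solve_decline: bool = False

    out_dir: Path = Path("results")
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_rr_source(self) -> "RunConfig":
        if self.rr_csv is None and self.rr_constant is None:
            raise ValueError("give either rr_csv or rr_constant")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate_inputs(self) -> None:
        for name in ("population_csv", "mortality_csv", "prevalence_csv", "rr_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False)
    return str(path)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return the artifact manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "conventions": {
            "rr_convention": config.rr_convention,
            "rr_reference": config.rr_reference,
            "rr_annual_decline": config.rr_annual_decline,
            "migrant_prevalence": config.migrant_prevalence,
            "undiagnosed_convention": config.undiagnosed_convention
            if config.undiagnosed_share is not None
            else None,
            "decomposition_order": list(config.decomposition_order),
            "decomposition_mode": config.decomposition_mode,
            "amplify_treated": config.amplify_treated,
        },
        "seed": config.seed,
        "stages": {},
        "warnings": {},
    }

    stage = "read_inputs"
    try:
        pop_counts = read_agesex_csv(config.population_csv, "count")
        mort = read_agesex_csv(config.mortality_csv, "risk")
        prev = read_agesex_csv(config.prevalence_csv, "proportion")
        pop = PopulationFrame.from_counts(pop_counts, mort)
        base_year = config.base_year or int(prev.years[-1])
        if config.amplify_treated:
            f = amplification_factor(config.nonpharm_share)
            values = np.clip(prev.values * f, 0.0, 1.0)
            prev = AgeSexTable.from_grid(prev.years, values, "proportion")
            manifest["conventions"]["amplification_factor"] = f
        if config.rr_csv is not None:
            rr_table = read_agesex_csv(config.rr_csv, "ratio")
            rr0 = rr_table.require_full(int(rr_table.years[0]))
        else:
            rr0 = float(config.rr_constant)
        em = ExcessMortalityModel(
            rr0=rr0,
            base_year=int(prev.years[0]),
            annual_decline=config.rr_annual_decline,
            convention=config.rr_convention,
            reference=config.rr_reference,
        )
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, e) from e

    stage = "backcalc"
    try:
        baseline = estimate_baseline(prev, mort, em)
        path = _write_csv(baseline.surface.to_frame(), out / "baseline_incidence.csv")
        manifest["stages"]["backcalc"] = path
        neg = baseline.negative_cells()
        manifest["warnings"]["negative_incidence_cells"] = int(len(neg))
        if len(neg):
            manifest["warnings"]["negative_incidence_csv"] = _write_csv(
                neg, out / "negative_incidence_cells.csv"
            )
    except Exception as e:
        raise PipelineError(stage, e) from e

    base_state = PrevalenceState(base_year, np.nan_to_num(prev.at(base_year), nan=0.0))
    inc0 = baseline.surface.at(base_year)
    results = {}
    for name in config.scenarios:
        stage = f"project_{name}"
        try:
            spec = build_scenario(
                name,
                incidence_trend=config.custom_incidence_trend,
                mortality_trend=config.custom_mortality_trend,
                horizon_end=config.horizon_end,
                base_year=base_year,
            )
            run = project(base_state, inc0, em, pop, mort, spec, config.migrant_prevalence)
            results[spec.name] = (spec, run)
            headline, annual = summarize(run)
            if config.undiagnosed_share is not None:
                headline["prevalence_pct_incl_undiagnosed"] = {
                    k: apply_undiagnosed(v / 100.0, config.undiagnosed_share, config.undiagnosed_convention) * 100.0
                    for k, v in headline["prevalence_pct"].items()
                }
            manifest["stages"][f"project_{spec.name}"] = _write_csv(
                annual, out / f"projection_{spec.name}.csv"
            )
            manifest.setdefault("headline", {})[spec.name] = headline
        except Exception as e:
            raise PipelineError(stage, e) from e

    if results:
        headrows = []
        for name, (spec, run) in results.items():
            h = manifest["headline"][name]
            headrows.append(
                {
                    "scenario": name,
                    "incidence_trend": spec.incidence_trend,
                    "mortality_trend": spec.mortality_trend,
                    **{f"prevalence_pct_{k}": v for k, v in h["prevalence_pct"].items()},
                    **{f"cases_{k}": v for k, v in h["cases"].items()},
                }
            )
        manifest["stages"]["headline_table"] = _write_csv(
            pd.DataFrame(headrows), out / "headline.csv"
        )

    first = next(iter(results.values()))[1] if results else None
    if config.decompose and first is not None:
        stage = "decompose"
        try:
            attr = decompose_increase(
                first,
                base_state,
                inc0,
                em,
                pop,
                mort,
                order=tuple(config.decomposition_order),
                mode=config.decomposition_mode,
            )
            manifest["stages"]["decompose"] = _write_csv(attr.to_frame(), out / "decomposition.csv")
            manifest["decomposition"] = {
                "total_increase_pct_of_base": attr.pct_increase_of_base,
                "shares": attr.shares(),
            }
        except Exception as e:
            raise PipelineError(stage, e) from e

    if config.solve_decline and first is not None:
        stage = "solve_decline"
        try:
            sol = required_incidence_decline(base_state, inc0, em, pop, mort, first.spec)
            manifest["stages"]["solve_decline"] = _write_csv(sol.trace, out / "decline_trace.csv")
            manifest["required_annual_incidence_decline"] = sol.delta
        except Exception as e:
            raise PipelineError(stage, e) from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["manifest_path"] = str(manifest_path)
    logger.info("pipeline complete: %d stage outputs", len(manifest["stages"]))
    return manifest
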