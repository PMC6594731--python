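"""End-to-end pipeline: forecast -> assistance -> allocation -> costs -> report.

Mirrors the five-stage cost-estimation framework: (1) progressive
forecasting of the 65+ population, (2) assistance-need estimation,
(3) comorbidity categorisation and combinatorial allocation, (4) device
bundling and life-cycle costing, (5) reporting. Each stage logs row
counts and conservation checks; any failure aborts with a stage-named
diagnostic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import datasets, io
from .catalog import BundleMap, TechnologyCatalog, TechnologyItem, deflate_price
from .comorbidity import CATEGORIES, CombinationAllocation, allocate
from .costs import CostReport, aggregate_costs, per_capita_display
from .demography import MigrationAssumption, forecast_population
from .diseases import DISEASES
from .needs import aggregate_assisted
from .rounding import display_int
from .synthetic import SyntheticConfig, synth_catalog

log = logging.getLogger("agetech")


class RunConfig(BaseModel):
    """Configuration for a full pipeline run.

    Input paths default to the bundled reference tables; the catalog and
    bundle map default to the synthetic generator (the real market price
    survey is not redistributable).
    """

    population_csv: Path | None = None
    mortality_csv: Path | None = None
    assistance_csv: Path | None = None
    disease_count_csv: Path | None = None
    single_disease_csv: Path | None = None
    comorbidity_csv: Path | None = None
    catalog_csv: Path | None = None
    bundles_csv: Path | None = None

    base_year: int = datasets.BASE_YEAR
    horizon_years: int = Field(default=datasets.HORIZON_YEARS, gt=0)
    nom_rate: float = datasets.FCW_MIGRATION.nom_rate
    nim_rate: float = datasets.FCW_MIGRATION.nim_rate
    rate_convention: Literal["destination", "origin", "mean"] = "destination"
    forecast_source: Literal["computed", "published"] = "computed"
    mode: Literal["published", "strict"] = "published"
    scenarios: tuple[str, ...] = ("low", "average")
    overall_assist_rate: float | None = None  # default: bundled table value
    top_k: int = 4
    seed: int = 0
    inflation_rate: float = 0.019  # annual, for source-year -> base-year deflation
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_paths(self):
        for name in (
            "population_csv",
            "mortality_csv",
            "assistance_csv",
            "disease_count_csv",
            "single_disease_csv",
            "comorbidity_csv",
            "catalog_csv",
            "bundles_csv",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name}: file does not exist: {p}")
        return self

    def config_hash(self) -> str:
        payload = self.model_dump_json().encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    """All intermediate tables plus the final cost report."""

    population: pd.DataFrame  # year x band counts (observed + forecast)
    totals_65plus: dict[int, float]
    assisted: dict[int, float]
    categories: pd.DataFrame  # Table-8-shaped: assisted + 0/1/2/3+ counts per year
    single_breakdown: pd.DataFrame  # Table-9-shaped per-disease one-disease strata
    allocations: dict[int, CombinationAllocation] = field(repr=False, default=None)
    report: CostReport = field(repr=False, default=None)
    report_frame: pd.DataFrame = None
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "population": io.write_table(self.population, out / "population_forecast.csv"),
            "categories": io.write_table(self.categories, out / "category_counts.csv"),
            "single": io.write_table(self.single_breakdown, out / "single_disease_breakdown.csv"),
            "report": io.write_table(self.report_frame, out / "cost_report.csv", io.REPORT_SCHEMA),
        }
        for year, alloc in self.allocations.items():
            paths[f"allocation_{year}"] = io.write_table(
                io.allocation_to_frame(alloc), out / f"allocation_{year}.csv",
                io.ALLOCATION_SCHEMA,
            )
        (out / "cost_report.json").write_text(
            json.dumps(
                {"metadata": self.metadata,
                 "report": self.report_frame.to_dict(orient="records")},
                indent=2,
            )
        )
        paths["report_json"] = out / "cost_report.json"
        return paths


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("forecast")
def _run_forecast(config: RunConfig):
    if config.population_csv is not None:
        pop = io.population_from_frame(
            io.read_table(config.population_csv, io.POPULATION_SCHEMA)
        )
    else:
        pop = datasets.load_population()
    if config.mortality_csv is not None:
        sched = io.mortality_from_frame(
            io.read_table(config.mortality_csv, io.MORTALITY_SCHEMA)
        )
    else:
        sched = datasets.load_mortality()
    migration = MigrationAssumption(nom_rate=config.nom_rate, nim_rate=config.nim_rate)

    if config.forecast_source == "published":
        forecast = datasets.load_published_forecast()
    else:
        forecast = forecast_population(
            pop,
            sched,
            migration,
            horizon_years=config.horizon_years,
            base_year=config.base_year,
            rate_convention=config.rate_convention,
        )
    years = [config.base_year] + forecast.years
    totals = {}
    for y in years:
        src = pop if y == config.base_year else forecast
        totals[y] = src.total(y, min_age=65)
    log.info(
        "forecast: %d years, 65+ totals %s",
        len(years),
        {y: display_int(v) for y, v in totals.items()},
    )
    combined = pd.concat(
        [io.population_to_frame(pop), io.population_to_frame(forecast)],
        ignore_index=True,
    )
    return combined, totals


@_stage("assistance")
def _run_assistance(config: RunConfig, totals: dict[int, float]) -> dict[int, float]:
    if config.overall_assist_rate is not None:
        rate = config.overall_assist_rate
    elif config.assistance_csv is not None:
        df = io.read_table(config.assistance_csv, io.ASSISTANCE_SCHEMA)
        row = df[df.age_band == "total"]
        if row.empty:
            raise ValueError("assistance CSV has no 'total' row for the overall rate")
        rate = float(row.iloc[0]["p_household_and_need"])
    else:
        rate = datasets.load_assistance_profile().overall_rate
    assisted = {y: aggregate_assisted(t, rate) for y, t in totals.items()}
    log.info(
        "assistance: rate %.4f, assisted %s",
        rate,
        {y: display_int(v) for y, v in assisted.items()},
    )
    return assisted


@_stage("allocation")
def _run_allocation(config: RunConfig, assisted: dict[int, float]):
    if config.disease_count_csv is not None:
        df = io.read_table(config.disease_count_csv, io.DISEASE_COUNT_SCHEMA)
        pools = {
            str(r.n_diseases): float(r.persons_thousands)
            for r in df.itertuples()
            if str(r.n_diseases) != "total"
        }
        total = next(
            (
                float(r.persons_thousands)
                for r in df.itertuples()
                if str(r.n_diseases) == "total"
            ),
            None,
        )
        from .comorbidity import DiseaseCountDistribution

        dist = DiseaseCountDistribution(pools=pools, total=total)
    else:
        dist = datasets.load_disease_distribution()
    singles = (
        {
            r.disease: float(r.persons_thousands)
            for r in io.read_table(
                config.single_disease_csv, io.SINGLE_DISEASE_SCHEMA
            ).itertuples()
        }
        if config.single_disease_csv is not None
        else datasets.load_single_counts()
    )
    if config.comorbidity_csv is not None:
        from .comorbidity import ComorbidityMatrix

        matrix = ComorbidityMatrix()
        for r in io.read_table(config.comorbidity_csv, io.COMORBIDITY_SCHEMA).itertuples():
            matrix.set_pair(r.disease_a, r.disease_b, float(r.persons_thousands))
        # residual-allocation weights fall back to pair row sums when no
        # separate marginals table accompanies the matrix
        for (a, b), v in matrix.pairs.items():
            matrix.marginals[a] = matrix.marginals.get(a, 0.0) + v
            matrix.marginals[b] = matrix.marginals.get(b, 0.0) + v
    else:
        matrix = datasets.load_comorbidity_matrix()

    allocations = {
        y: allocate(
            a, dist, singles, matrix, top_k=config.top_k, mode=config.mode
        )
        for y, a in assisted.items()
    }
    for y, alloc in allocations.items():
        conserved = alloc.total_persons()
        log.info(
            "allocation %d: %d strata, categories %s (sum %.1f vs assisted %.1f)",
            y,
            len(alloc.strata),
            {c: display_int(v) for c, v in alloc.category_totals.items()},
            conserved,
            assisted[y],
        )
    return allocations, dist, singles, matrix


@_stage("costing")
def _run_costing(config: RunConfig, allocations):
    if config.catalog_csv is not None and config.bundles_csv is not None:
        catalog = io.catalog_from_frame(io.read_table(config.catalog_csv, io.CATALOG_SCHEMA))
        bundles = io.bundles_from_frame(io.read_table(config.bundles_csv, io.BUNDLE_SCHEMA))
    else:
        catalog, bundles = synth_catalog(SyntheticConfig(seed=config.seed))

    # deflate prices quoted after the base year back to base-year AUD
    deflated = TechnologyCatalog()
    for it in catalog:
        years = max(0, (it.source_year or config.base_year) - config.base_year)
        deflated.add(
            TechnologyItem(
                id=it.id,
                name=it.name,
                function_category=it.function_category,
                price_low=deflate_price(it.price_low, config.inflation_rate, years),
                price_avg=deflate_price(it.price_avg, config.inflation_rate, years),
                lifespan=it.lifespan,
                maintenance_fraction=it.maintenance_fraction,
                installation_fraction=it.installation_fraction,
                source_year=config.base_year,
            )
        )
    report = aggregate_costs(allocations, deflated, bundles, scenarios=config.scenarios)
    for y in report.years:
        log.info(
            "costing %d: totals %s",
            y,
            {s: display_int(report.grand_total(y, s)) for s in config.scenarios},
        )
    return report, deflated, bundles


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all five stages and assemble intermediates plus the report."""
    logging.basicConfig(level=config.log_level)

    population, totals = _run_forecast(config)
    assisted = _run_assistance(config, totals)
    allocations, dist, singles, matrix = _run_allocation(config, assisted)
    report, catalog, bundles = _run_costing(config, allocations)

    years = sorted(assisted)
    categories = pd.DataFrame(
        [
            {
                "year": y,
                "total_65plus": display_int(totals[y]),
                "assisted": display_int(assisted[y]),
                **{
                    f"n_diseases_{c}": display_int(allocations[y].category_totals[c])
                    for c in CATEGORIES
                },
            }
            for y in years
        ]
    )
    single_breakdown = pd.DataFrame(
        [
            {
                "year": y,
                **{
                    d: display_int(allocations[y].strata[(d,)])
                    for d in DISEASES
                },
            }
            for y in years
        ]
    )
    report_rows = []
    for y in years:
        for c in CATEGORIES:
            for s in config.scenarios:
                total = report.total(y, c, s)
                popn = report.populations[(y, c)]
                report_rows.append(
                    {
                        "year": y,
                        "category": c,
                        "scenario": s,
                        "population": popn,
                        "total_aud": total,
                        "per_capita_aud": per_capita_display(total, popn) if popn > 0 else 0,
                    }
                )
    report_frame = pd.DataFrame(report_rows)

    metadata = {
        "config_hash": config.config_hash(),
        "mode": config.mode,
        "forecast_source": config.forecast_source,
        "seed": config.seed,
        "n_catalog_items": len(catalog),
        "catalog_source": "file" if config.catalog_csv else "synthetic",
    }
    return PipelineResult(
        population=population,
        totals_65plus=totals,
        assisted=assisted,
        categories=categories,
        single_breakdown=single_breakdown,
        allocations=allocations,
        report=report,
        report_frame=report_frame,
        metadata=metadata,
    )
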