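"""Schema-validated CSV I/O for all pipeline interchange tables.

Every table the pipeline reads or writes is a flat CSV with explicit
headers; a :class:`TableSchema` names the required columns, their dtypes
and per-column range checks, and errors cite the offending column and row
so bad inputs fail loudly at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pandas as pd


class SchemaError(ValueError):
    """A table failed schema validation (missing column / bad value)."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: str = "float"  # "float" | "int" | "str"
    check: Callable[[float], bool] | None = None
    check_desc: str = ""


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[ColumnSpec, ...] = field(default_factory=tuple)

    def validate(self, df: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
        for col in self.columns:
            if col.name not in df.columns:
                raise SchemaError(
                    f"{source}: {self.name} table is missing column {col.name!r}"
                )
            series = df[col.name]
            if col.dtype in ("float", "int"):
                coerced = pd.to_numeric(series, errors="coerce")
                bad = coerced.isna() & series.notna()
                if bad.any():
                    row = int(bad.idxmax())
                    raise SchemaError(
                        f"{source}: column {col.name!r} row {row}: "
                        f"non-numeric value {series[row]!r}"
                    )
                df = df.assign(**{col.name: coerced})
                series = df[col.name]
            if col.check is not None:
                ok = series.map(lambda v: bool(col.check(v)))
                if not ok.all():
                    row = int((~ok).idxmax())
                    raise SchemaError(
                        f"{source}: column {col.name!r} row {row}: value "
                        f"{series[row]!r} fails check ({col.check_desc})"
                    )
        return df


def _nonneg(v) -> bool:
    return v >= 0


def _fraction(v) -> bool:
    return 0.0 <= v <= 1.0


POPULATION_SCHEMA = TableSchema(
    "population",
    (
        ColumnSpec("year", "int"),
        ColumnSpec("age_band", "str"),
        ColumnSpec("persons", "float", _nonneg, "persons >= 0"),
    ),
)

MORTALITY_SCHEMA = TableSchema(
    "mortality",
    (
        ColumnSpec("year", "int"),
        ColumnSpec("age_band", "str"),
        ColumnSpec("deaths_per_1000", "float", _nonneg, "rate >= 0"),
    ),
)

ASSISTANCE_SCHEMA = TableSchema(
    "assistance",
    (
        ColumnSpec("age_band", "str"),
        ColumnSpec("p_need_assist", "float", _fraction, "fraction in [0, 1]"),
        ColumnSpec("p_household", "float", _fraction, "fraction in [0, 1]"),
    ),
)

DISEASE_COUNT_SCHEMA = TableSchema(
    "disease_count",
    (
        ColumnSpec("n_diseases", "str"),
        ColumnSpec("persons_thousands", "float", _nonneg, "persons >= 0"),
    ),
)

SINGLE_DISEASE_SCHEMA = TableSchema(
    "single_disease",
    (
        ColumnSpec("disease", "str"),
        ColumnSpec("persons_thousands", "float", _nonneg, "persons >= 0"),
    ),
)

COMORBIDITY_SCHEMA = TableSchema(
    "comorbidity",
    (
        ColumnSpec("disease_a", "str"),
        ColumnSpec("disease_b", "str"),
        ColumnSpec("persons_thousands", "float", _nonneg, "persons >= 0"),
    ),
)

CATALOG_SCHEMA = TableSchema(
    "catalog",
    (
        ColumnSpec("item_id", "str"),
        ColumnSpec("name", "str"),
        ColumnSpec("function_category", "str"),
        ColumnSpec("price_low_aud", "float", lambda v: v > 0, "price > 0"),
        ColumnSpec("price_avg_aud", "float", lambda v: v > 0, "price > 0"),
        ColumnSpec("lifespan_years", "float", lambda v: v > 0, "lifespan > 0"),
        ColumnSpec("maintenance_fraction", "float", _fraction, "fraction in [0, 1]"),
        ColumnSpec("installation_fraction", "float", _fraction, "fraction in [0, 1]"),
    ),
)

BUNDLE_SCHEMA = TableSchema(
    "bundles",
    (
        ColumnSpec("disease", "str"),
        ColumnSpec("item_id", "str"),
    ),
)

ALLOCATION_SCHEMA = TableSchema(
    "allocation",
    (
        ColumnSpec("combination", "str"),
        ColumnSpec("n_diseases", "int"),
        ColumnSpec("persons", "float", _nonneg, "persons >= 0"),
    ),
)

REPORT_SCHEMA = TableSchema(
    "report",
    (
        ColumnSpec("year", "int"),
        ColumnSpec("category", "str"),
        ColumnSpec("scenario", "str"),
        ColumnSpec("population", "float", _nonneg, "persons >= 0"),
        ColumnSpec("total_aud", "float", _nonneg, "AUD >= 0"),
        ColumnSpec("per_capita_aud", "float", _nonneg, "AUD >= 0"),
    ),
)


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against a schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path)
    return schema.validate(df, source=str(path))


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema | None = None) -> Path:
    """Validate (optionally) and write a CSV; round-trips losslessly."""
    path = Path(path)
    if schema is not None:
        df = schema.validate(df, source=f"write:{path}")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# --- conversions between dataframes and domain objects -----------------------


def population_from_frame(df: pd.DataFrame):
    from .demography import PopulationTable

    table = PopulationTable()
    for row in df.itertuples():
        table.set(int(row.year), row.age_band, float(row.persons))
    return table


def population_to_frame(table) -> pd.DataFrame:
    rows = [
        {"year": y, "age_band": lbl, "persons": v}
        for (y, lbl), v in sorted(table.counts.items())
    ]
    return pd.DataFrame(rows, columns=["year", "age_band", "persons"])


def mortality_from_frame(df: pd.DataFrame):
    from .demography import MortalitySchedule

    sched = MortalitySchedule()
    for row in df.itertuples():
        sched.set(int(row.year), row.age_band, float(row.deaths_per_1000))
    return sched


def catalog_from_frame(df: pd.DataFrame):
    from .catalog import TechnologyCatalog, TechnologyItem

    catalog = TechnologyCatalog()
    for row in df.itertuples():
        catalog.add(
            TechnologyItem(
                id=row.item_id,
                name=row.name,
                function_category=row.function_category,
                price_low=float(row.price_low_aud),
                price_avg=float(row.price_avg_aud),
                lifespan=float(row.lifespan_years),
                maintenance_fraction=float(row.maintenance_fraction),
                installation_fraction=float(row.installation_fraction),
                source_year=int(row.source_year) if "source_year" in df.columns else None,
            )
        )
    return catalog


def catalog_to_frame(catalog) -> pd.DataFrame:
    rows = [
        {
            "item_id": it.id,
            "name": it.name,
            "function_category": it.function_category,
            "price_low_aud": it.price_low,
            "price_avg_aud": it.price_avg,
            "lifespan_years": it.lifespan,
            "maintenance_fraction": it.maintenance_fraction,
            "installation_fraction": it.installation_fraction,
            "source_year": it.source_year,
        }
        for it in catalog
    ]
    return pd.DataFrame(rows)


def bundles_from_frame(df: pd.DataFrame):
    from .catalog import BundleMap

    basic = frozenset(df.loc[df.disease == "basic", "item_id"])
    disease_bundles = {
        d: frozenset(sub["item_id"])
        for d, sub in df[df.disease != "basic"].groupby("disease")
    }
    return BundleMap(basic_bundle=basic, disease_bundles=disease_bundles)


def bundles_to_frame(bundles) -> pd.DataFrame:
    rows = [{"disease": "basic", "item_id": i} for i in sorted(bundles.basic_bundle)]
    for d, items in sorted(bundles.disease_bundles.items()):
        rows.extend({"disease": d, "item_id": i} for i in sorted(items))
    return pd.DataFrame(rows, columns=["disease", "item_id"])


def allocation_to_frame(alloc) -> pd.DataFrame:
    rows = [
        {
            "combination": "+".join(combo) if combo else "none",
            "n_diseases": len(combo),
            "persons": persons,
        }
        for combo, persons in sorted(alloc.strata.items(), key=lambda kv: (len(kv[0]), kv[0]))
    ]
    return pd.DataFrame(rows, columns=["combination", "n_diseases", "persons"])
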