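"""Loaders for the bundled reference tables.

These CSVs carry the published Australian inputs the case study runs on:
ABS regional population counts and death rates for the Fitzroy & Central
West (FCW) region of Queensland, the national survey's assistance-need
and residence shares, the National Health Survey disease-count pools and
8x8 comorbidity matrix, and the published regional cost aggregates used
for per-capita ratio checks. Device prices are *not* bundled (the market
price survey is not public); use :mod:`agetech.synthetic` for a catalog.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .comorbidity import ComorbidityMatrix, DiseaseCountDistribution
from .demography import MigrationAssumption, MortalitySchedule, PopulationTable
from .needs import AssistanceProfile

#: Net overseas / interstate migration rates for FCW, fractions per year.
FCW_MIGRATION = MigrationAssumption(nom_rate=-0.00006, nim_rate=0.00058)

BASE_YEAR = 2016
HORIZON_YEARS = 10


def _read(name: str) -> pd.DataFrame:
    with resources.files("agetech.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_population() -> PopulationTable:
    """FCW census counts by five-year band, 2006/2011/2016, ages 55+."""
    table = PopulationTable()
    for row in _read("fcw_population.csv").itertuples():
        table.set(int(row.year), row.age_band, float(row.persons))
    for row in _read("regional_totals.csv").itertuples():
        if row.region == "fcw" and int(row.year) <= BASE_YEAR:
            table.totals[int(row.year)] = float(row.persons)
    return table


def load_regional_totals(region: str = "fcw") -> dict[int, float]:
    """All-ages population totals (census + published projections)."""
    df = _read("regional_totals.csv")
    df = df[df.region == region]
    if df.empty:
        raise KeyError(f"unknown region {region!r}")
    return {int(r.year): float(r.persons) for r in df.itertuples()}


def load_published_forecast() -> PopulationTable:
    """The published 2021/2026 progressive forecast, for comparison only."""
    table = PopulationTable()
    for row in _read("fcw_forecast_published.csv").itertuples():
        table.set(int(row.year), row.age_band, float(row.persons))
    for year, persons in load_regional_totals("fcw").items():
        if year > BASE_YEAR:
            table.totals[year] = persons
    return table


def load_mortality() -> MortalitySchedule:
    """Queensland age-specific death rates per 1,000, 2006-2026.

    The 2021/2026 columns are the published projections, injected directly
    so forecasts can run on the same rates the case study used.
    """
    sched = MortalitySchedule()
    for row in _read("qld_death_rates.csv").itertuples():
        sched.set(int(row.year), row.age_band, float(row.deaths_per_1000))
    return sched


def load_assistance_profile() -> AssistanceProfile:
    """Assistance-need and household-residence shares by age band."""
    df = _read("assistance_rates.csv")
    rates = {}
    overall = None
    for row in df.itertuples():
        if row.age_band == "total":
            overall = float(row.p_household_and_need)
        else:
            rates[row.age_band] = (float(row.p_need_assist), float(row.p_household))
    profile = AssistanceProfile(rates=rates)
    if overall is not None:
        profile.overall_rate = overall
    return profile


def load_disease_distribution() -> DiseaseCountDistribution:
    """National 65+ pools (thousands) by number of chronic diseases."""
    df = _read("disease_counts.csv")
    pools = {}
    total = None
    for row in df.itertuples():
        if str(row.n_diseases) == "total":
            total = float(row.persons_thousands)
        else:
            pools[str(row.n_diseases)] = float(row.persons_thousands)
    return DiseaseCountDistribution(pools=pools, total=total)


def load_single_counts() -> dict[str, float]:
    """Single-disease column of the national disease-count table."""
    df = _read("single_disease_counts.csv")
    return {r.disease: float(r.persons_thousands) for r in df.itertuples()}


def load_comorbidity_matrix() -> ComorbidityMatrix:
    """National 8x8 pairwise co-occurrence matrix plus per-disease marginals."""
    matrix = ComorbidityMatrix()
    for row in _read("comorbidity_pairs.csv").itertuples():
        matrix.set_pair(row.disease_a, row.disease_b, float(row.persons_thousands))
    for row in _read("disease_marginals.csv").itertuples():
        matrix.marginals[row.disease] = float(row.persons_thousands)
    return matrix


def load_published_cost_totals() -> pd.DataFrame:
    """Published regional cost aggregates by year, category and scenario."""
    df = _read("published_cost_totals.csv")
    df["category"] = df["category"].astype(str)
    return df
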