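"""Life-cycle cost engine: per-person and population-total annual costs.

The default accounting is amortised: purchase plus installation is spread
uniformly over the device lifespan and maintenance accrues annually, so

    annual cost = price * (1 + installation) / lifespan + maintenance * price.

All figures are constant base-year AUD with no discounting. A cash-flow
mode is also provided for budget planners who want purchases booked in
replacement years rather than smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import SCENARIOS, BundleMap, TechnologyCatalog, TechnologyItem, bundle_for
from .comorbidity import CATEGORIES, CombinationAllocation
from .rounding import round_half_up


def annual_item_cost(item: TechnologyItem, scenario: str) -> float:
    """Amortised annual cost of one device under a price scenario."""
    p = item.price(scenario)
    return p * (1.0 + item.installation_fraction) / item.lifespan + (
        item.maintenance_fraction * p
    )


def cashflow_item_cost(item: TechnologyItem, scenario: str, year_index: int) -> float:
    """Cash-flow cost in a given year since adoption (year_index 0-based).

    The full purchase plus installation is booked in year 0 and in every
    replacement year (every ``lifespan`` years); maintenance accrues in
    every year.
    """
    if year_index < 0:
        raise ValueError("year_index must be >= 0")
    p = item.price(scenario)
    cost = item.maintenance_fraction * p
    if year_index % max(int(round(item.lifespan)), 1) == 0:
        cost += p * (1.0 + item.installation_fraction)
    return cost


def person_annual_cost(
    combination,
    catalog: TechnologyCatalog,
    bundles: BundleMap,
    scenario: str,
) -> float:
    """Annual cost of the full device kit for one person's disease set."""
    return sum(
        annual_item_cost(catalog[item_id], scenario)
        for item_id in bundle_for(combination, bundles)
    )


@dataclass
class CostReport:
    """Cost totals and per-capita figures by year, category and scenario."""

    totals: dict[tuple[int, str, str], float] = field(default_factory=dict)
    populations: dict[tuple[int, str], float] = field(default_factory=dict)

    def total(self, year: int, category: str, scenario: str) -> float:
        return self.totals[(year, category, scenario)]

    def grand_total(self, year: int, scenario: str) -> float:
        return sum(self.totals[(year, c, scenario)] for c in CATEGORIES)

    def per_capita(self, year: int, category: str, scenario: str) -> float:
        return per_capita(
            self.totals[(year, category, scenario)], self.populations[(year, category)]
        )

    def grand_per_capita(self, year: int, scenario: str) -> float:
        pop = sum(self.populations[(year, c)] for c in CATEGORIES)
        return per_capita(self.grand_total(year, scenario), pop)

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _, _ in self.totals})


def aggregate_costs(
    allocations: dict[int, CombinationAllocation],
    catalog: TechnologyCatalog,
    bundles: BundleMap,
    scenarios=SCENARIOS,
) -> CostReport:
    """Population totals: sum over strata of persons x per-person annual cost.

    Stratum populations enter at full precision; per-person costs are
    computed once per distinct combination and reused across years.
    """
    bundles.validate_against(catalog)
    report = CostReport()
    cost_cache: dict[tuple[tuple[str, ...], str], float] = {}
    for year, alloc in allocations.items():
        for category in CATEGORIES:
            report.populations[(year, category)] = alloc.category_totals[category]
            for scenario in scenarios:
                total = 0.0
                for combo, persons in alloc.category_strata(category).items():
                    key = (combo, scenario)
                    if key not in cost_cache:
                        cost_cache[key] = person_annual_cost(
                            combo, catalog, bundles, scenario
                        )
                    total += persons * cost_cache[key]
                report.totals[(year, category, scenario)] = total
    return report


def per_capita(total: float, population: float) -> float:
    """Per-person annual cost; the divisor must be the unrounded population.

    Returns the full-precision quotient; display-round half-up to whole AUD.
    """
    if population <= 0:
        raise ZeroDivisionError("per-capita cost needs a positive population")
    return total / population


def per_capita_display(total: float, population: float) -> int:
    return int(round_half_up(per_capita(total, population)))
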