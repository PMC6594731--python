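"""Assistive-technology catalog: devices, prices, life-cycle parameters.

Each device carries a low and an average market price (the two scenarios
propagated through the cost model), a service lifespan after which it is
replaced, an annual maintenance fraction of price, and a one-off
installation fraction. Devices are grouped into a basic bundle everyone
receives plus per-disease bundles; a person's kit is the union over their
disease combination, so a device shared by two conditions is bought once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .diseases import check_disease

FUNCTION_CATEGORIES = (
    "mobility",
    "vision",
    "hearing",
    "home_safety",
    "fitness",
    "health_monitoring",
    "cognition",
    "communication",
)

#: Global life-cycle defaults: five-year device life, 15%/yr maintenance,
#: 5% of price for installation.
DEFAULT_LIFESPAN_YEARS = 5.0
DEFAULT_MAINTENANCE_FRACTION = 0.15
DEFAULT_INSTALLATION_FRACTION = 0.05

SCENARIOS = ("low", "average")


@dataclass(frozen=True)
class TechnologyItem:
    id: str
    name: str
    function_category: str
    price_low: float  # AUD
    price_avg: float  # AUD
    lifespan: float = DEFAULT_LIFESPAN_YEARS  # years
    maintenance_fraction: float = DEFAULT_MAINTENANCE_FRACTION  # per year
    installation_fraction: float = DEFAULT_INSTALLATION_FRACTION  # one-off
    source_year: int | None = None

    def __post_init__(self) -> None:
        if self.function_category not in FUNCTION_CATEGORIES:
            raise ValueError(
                f"item {self.id!r}: unknown function category "
                f"{self.function_category!r}"
            )
        if not 0 < self.price_low <= self.price_avg:
            raise ValueError(
                f"item {self.id!r}: require 0 < price_low <= price_avg, "
                f"got {self.price_low} / {self.price_avg}"
            )
        if self.lifespan <= 0:
            raise ValueError(f"item {self.id!r}: lifespan must be positive")
        for nm, fr in (
            ("maintenance_fraction", self.maintenance_fraction),
            ("installation_fraction", self.installation_fraction),
        ):
            if not 0.0 <= fr <= 1.0:
                raise ValueError(f"item {self.id!r}: {nm} must be in [0, 1]")

    def price(self, scenario: str) -> float:
        if scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
        return self.price_low if scenario == "low" else self.price_avg


@dataclass
class TechnologyCatalog:
    items: dict[str, TechnologyItem] = field(default_factory=dict)

    def add(self, item: TechnologyItem) -> None:
        if item.id in self.items:
            raise ValueError(f"duplicate item id {item.id!r}")
        self.items[item.id] = item

    def __getitem__(self, item_id: str) -> TechnologyItem:
        try:
            return self.items[item_id]
        except KeyError:
            raise KeyError(f"unknown technology item {item_id!r}") from None

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items.values())


@dataclass
class BundleMap:
    """Basic bundle (everyone) plus per-disease bundles of item ids."""

    basic_bundle: frozenset[str]
    disease_bundles: dict[str, frozenset[str]]

    def validate_against(self, catalog: TechnologyCatalog) -> None:
        for item_id in self.basic_bundle:
            catalog[item_id]
        for disease, bundle in self.disease_bundles.items():
            check_disease(disease)
            if not bundle:
                raise ValueError(f"empty bundle for disease {disease!r}")
            for item_id in bundle:
                catalog[item_id]


def deflate_price(price: float, annual_inflation: float, years: int) -> float:
    """Convert a price to base-year terms by removing `years` of inflation.

    Exact inverse of compounding the inflation rate forward.
    """
    if price < 0:
        raise ValueError(f"negative price {price}")
    if years < 0:
        raise ValueError(f"negative years {years}")
    if annual_inflation <= -1:
        raise ValueError(f"annual_inflation must exceed -1, got {annual_inflation}")
    return price / (1.0 + annual_inflation) ** years


def bundle_for(combination, bundles: BundleMap) -> frozenset[str]:
    """Device set for a disease combination: basic plus per-disease unions.

    Duplicates collapse: a device listed under two of the person's diseases
    is included (and later priced) once.
    """
    out = set(bundles.basic_bundle)
    for disease in combination:
        check_disease(disease)
        if disease in bundles.disease_bundles:
            out |= bundles.disease_bundles[disease]
    return frozenset(out)
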