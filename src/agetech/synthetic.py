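"""Synthetic input generation for end-to-end testing of the pipeline.

Real multimorbidity microdata are confidential, and the published device
price list is not reproducible here, so this module generates inputs with
the same statistical structure the analysis assumes:

* individual disease sets from a log-linear pairwise interaction model —
  independent per-disease prevalences tilted by pairwise odds
  multipliers. With eight diseases the 256-point outcome space is small
  enough to enumerate exactly, which gives closed-form pair probabilities
  to validate sampled frequencies against;
* a device catalog + bundle map with the schema of a market price survey
  (clearly synthetic: names are generated, prices are drawn uniformly).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .catalog import (
    DEFAULT_INSTALLATION_FRACTION,
    DEFAULT_LIFESPAN_YEARS,
    DEFAULT_MAINTENANCE_FRACTION,
    FUNCTION_CATEGORIES,
    BundleMap,
    TechnologyCatalog,
    TechnologyItem,
)
from .comorbidity import ComorbidityMatrix, DiseaseCountDistribution
from .diseases import DISEASES

#: Moderate default prevalences, ordered as DISEASES; roughly shaped like
#: national 65+ prevalence (arthritis and CVD common, cancer/COPD rarer).
DEFAULT_PREVALENCES = (0.45, 0.10, 0.25, 0.06, 0.08, 0.17, 0.50, 0.17)

DEFAULT_PRICE_RANGES = {
    "mobility": (300.0, 6000.0),
    "vision": (50.0, 800.0),
    "hearing": (150.0, 4000.0),
    "home_safety": (80.0, 1200.0),
    "fitness": (200.0, 2500.0),
    "health_monitoring": (60.0, 3000.0),
    "cognition": (100.0, 1500.0),
    "communication": (100.0, 1200.0),
}


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_individuals: int = 100_000
    disease_prevalences: tuple[float, ...] = DEFAULT_PREVALENCES
    pairwise_odds_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    price_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRICE_RANGES)
    )
    items_per_category: int = 3
    population_trend: float = 0.08  # growth fraction per 5 years
    base_death_rates: dict[str, float] = field(
        default_factory=lambda: {
            "55-59": 4.1,
            "60-64": 6.0,
            "65-69": 9.6,
            "70-74": 15.5,
            "75-79": 27.1,
            "80-84": 49.8,
            "85-89": 94.5,
            "90-94": 167.5,
        }
    )

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if len(self.disease_prevalences) != len(DISEASES):
            raise ValueError(f"need {len(DISEASES)} prevalences")
        for p in self.disease_prevalences:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {p} outside [0, 1]")
        for pair, m in self.pairwise_odds_multipliers.items():
            if m <= 0:
                raise ValueError(f"odds multiplier for {pair} must be positive")
        for cat, (lo, hi) in self.price_ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"bad price range for {cat}: ({lo}, {hi})")


def _subset_bits(idx: int) -> tuple[str, ...]:
    return tuple(d for k, d in enumerate(DISEASES) if idx >> k & 1)


def subset_distribution(config: SyntheticConfig) -> tuple[list[tuple[str, ...]], np.ndarray]:
    """Exact distribution over the 2^8 disease sets of the log-linear model.

    A set S has unnormalised weight prod_{i in S} p_i/(1-p_i) times the
    product of odds multipliers over pairs within S; prevalences of 0 or 1
    force exclusion or inclusion.
    """
    prev = dict(zip(DISEASES, config.disease_prevalences))
    mults = {
        ComorbidityMatrix.key(a, b): m
        for (a, b), m in config.pairwise_odds_multipliers.items()
    }
    subsets = [_subset_bits(i) for i in range(2 ** len(DISEASES))]
    weights = np.zeros(len(subsets))
    for i, s in enumerate(subsets):
        w = 1.0
        members = set(s)
        for d in DISEASES:
            p = prev[d]
            if d in members:
                if p == 0.0:
                    w = 0.0
                    break
                if p < 1.0:
                    w *= p / (1.0 - p)
            elif p == 1.0:
                w = 0.0
                break
        if w > 0.0:
            for a, b in combinations(s, 2):
                w *= mults.get(ComorbidityMatrix.key(a, b), 1.0)
        weights[i] = w
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate synthetic model: all subset weights zero")
    return subsets, weights / total


def pair_probabilities(config: SyntheticConfig) -> dict[tuple[str, str], float]:
    """Exact P(both diseases present) for every pair, by enumeration."""
    subsets, probs = subset_distribution(config)
    out = {pair: 0.0 for pair in combinations(DISEASES, 2)}
    for s, p in zip(subsets, probs):
        for pair in combinations(s, 2):
            out[pair] += p
    return out


def synth_individuals(config: SyntheticConfig) -> list[tuple[str, ...]]:
    """Sample individual disease sets; deterministic given config.seed."""
    subsets, probs = subset_distribution(config)
    rng = np.random.default_rng(config.seed)
    idx = rng.choice(len(subsets), size=config.n_individuals, p=probs)
    return [subsets[i] for i in idx]


def tabulate(
    individuals: list[tuple[str, ...]],
) -> tuple[DiseaseCountDistribution, dict[str, float], ComorbidityMatrix]:
    """Exact tabulation of disease sets into the three analysis inputs.

    Returns the disease-count pools (0/1/2/3+ persons), the single-disease
    column (persons whose only condition is that disease), and the pairwise
    co-occurrence matrix. As in the national tables, a pair cell counts
    everyone with both diseases regardless of how many others they have,
    and a marginal counts everyone with the disease.
    """
    if not individuals:
        raise ValueError("no individuals to tabulate")
    pools = {"0": 0.0, "1": 0.0, "2": 0.0, "3plus": 0.0}
    singles = {d: 0.0 for d in DISEASES}
    matrix = ComorbidityMatrix(
        pairs={pair: 0.0 for pair in combinations(DISEASES, 2)},
        marginals={d: 0.0 for d in DISEASES},
    )
    for s in individuals:
        n = len(s)
        pools[str(n) if n < 3 else "3plus"] += 1
        if n == 1:
            singles[s[0]] += 1
        for d in s:
            matrix.marginals[d] += 1
        for a, b in combinations(s, 2):
            matrix.pairs[ComorbidityMatrix.key(a, b)] += 1
    return DiseaseCountDistribution(pools=pools), singles, matrix


_MONITORING_CATEGORIES = ("health_monitoring", "vision", "hearing", "cognition", "communication")
_BASIC_CATEGORIES = ("home_safety", "mobility", "fitness")


def synth_catalog(config: SyntheticConfig) -> tuple[TechnologyCatalog, BundleMap]:
    """Generate a synthetic device catalog and bundle map.

    Per function category, ``items_per_category`` devices with price_low
    uniform in the category's range and price_avg = price_low x a factor
    in [1.2, 3]. Each disease receives 2-6 devices, always including at
    least one health-monitoring device; the basic bundle draws from the
    safety / mobility / fitness categories.
    """
    rng = np.random.default_rng([config.seed, 0xCA7A])
    catalog = TechnologyCatalog()
    by_category: dict[str, list[str]] = {c: [] for c in FUNCTION_CATEGORIES}
    for cat in FUNCTION_CATEGORIES:
        lo, hi = config.price_ranges.get(cat, (100.0, 1000.0))
        for j in range(config.items_per_category):
            price_low = float(rng.uniform(lo, hi))
            price_avg = price_low * float(rng.uniform(1.2, 3.0))
            item = TechnologyItem(
                id=f"{cat}_{j:02d}",
                name=f"synthetic {cat.replace('_', ' ')} device {j + 1}",
                function_category=cat,
                price_low=round(price_low, 2),
                price_avg=round(price_avg, 2),
                lifespan=DEFAULT_LIFESPAN_YEARS,
                maintenance_fraction=DEFAULT_MAINTENANCE_FRACTION,
                installation_fraction=DEFAULT_INSTALLATION_FRACTION,
                source_year=2018,
            )
            catalog.add(item)
            by_category[cat].append(item.id)

    basic_pool = [i for c in _BASIC_CATEGORIES for i in by_category[c]]
    n_basic = int(rng.integers(2, min(len(basic_pool), 4) + 1))
    basic = frozenset(rng.choice(basic_pool, size=n_basic, replace=False).tolist())

    disease_pool = [i for c in _MONITORING_CATEGORIES for i in by_category[c]]
    disease_bundles: dict[str, frozenset[str]] = {}
    for d in DISEASES:
        k = int(rng.integers(2, 7))
        k = min(k, len(disease_pool))
        chosen = set(rng.choice(disease_pool, size=k, replace=False).tolist())
        if not chosen & set(by_category["health_monitoring"]):
            chosen.pop()
            chosen.add(str(rng.choice(by_category["health_monitoring"])))
        disease_bundles[d] = frozenset(chosen)

    bundles = BundleMap(basic_bundle=basic, disease_bundles=disease_bundles)
    bundles.validate_against(catalog)
    return catalog, bundles
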