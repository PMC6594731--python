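"""Comorbidity categorisation and combinatorial allocation.

The assisted 65+ population is split into care-needs categories by number
of chronic diseases (0 / 1 / 2 / 3+) using national disease-count pools,
then each category is expanded into specific disease-combination strata:

* one disease  — per-disease shares from the single-disease column;
* two diseases — normalised ratios over the 28 pairwise co-occurrence
  cells of the 8x8 comorbidity matrix;
* three or more — the most common triples (scored by summed pairwise
  co-occurrence) take mass proportional to their scores, and the residual
  is spread over the remaining 219-minus-top subsets by the mean marginal
  prevalence of their member diseases (a weighted-average rule).

Two rounding regimes are supported. ``published`` mode reproduces the
published national tables cell-for-cell: category shares use the printed
pool total as denominator, and single-disease shares are rounded to 0.1%
before multiplying a whole-person pool. ``strict`` mode renormalises all
shares so strata sum exactly to the population they partition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

from .diseases import DISEASES, canonical_combination, check_disease

MODES = ("published", "strict")

#: Care-needs category keys, ordered by number of chronic diseases.
CATEGORIES = ("0", "1", "2", "3plus")


def _check_mode(mode: str) -> str:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return mode


@dataclass
class DiseaseCountDistribution:
    """Population pools (thousands of persons) by number of chronic diseases.

    ``total`` is the published all-categories total, which may disagree
    with the component sum by up to ~1 thousand due to source rounding;
    published mode uses it as the share denominator regardless.
    """

    pools: dict[str, float]
    total: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.pools]
        if missing:
            raise ValueError(f"distribution missing categories {missing}")
        if any(v < 0 for v in self.pools.values()):
            raise ValueError("negative pool size")
        comp = sum(self.pools[c] for c in CATEGORIES)
        if comp <= 0:
            raise ValueError("all pools are zero")
        if self.total is None:
            self.total = comp
        elif abs(comp - self.total) > 1.0:
            raise ValueError(
                f"pools sum to {comp}, printed total {self.total}: off by more than 1"
            )
        elif abs(comp - self.total) > 0.5:
            warnings.warn(
                f"pools sum to {comp} vs printed total {self.total} "
                "(source rounding preserved)",
                stacklevel=2,
            )

    def shares(self, mode: str = "published") -> dict[str, float]:
        _check_mode(mode)
        denom = self.total if mode == "published" else sum(
            self.pools[c] for c in CATEGORIES
        )
        return {c: self.pools[c] / denom for c in CATEGORIES}


@dataclass
class ComorbidityMatrix:
    """Symmetric pairwise co-occurrence counts (thousands) for the 8 diseases.

    Stored on unordered pairs, so symmetry holds by construction; the
    diagonal (self-pairs) does not exist. ``marginals`` are per-disease
    totals (all persons with the disease, any number of conditions).
    """

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)
    marginals: dict[str, float] = field(default_factory=dict)

    @staticmethod
    def key(a: str, b: str) -> tuple[str, str]:
        check_disease(a)
        check_disease(b)
        if a == b:
            raise ValueError(f"self-pair {a!r} not allowed")
        return (a, b) if DISEASES.index(a) < DISEASES.index(b) else (b, a)

    def set_pair(self, a: str, b: str, persons: float) -> None:
        if persons < 0:
            raise ValueError(f"negative pair count for ({a}, {b})")
        self.pairs[self.key(a, b)] = float(persons)

    def pair(self, a: str, b: str) -> float:
        return self.pairs.get(self.key(a, b), 0.0)

    @property
    def all_pairs(self) -> list[tuple[str, str]]:
        return list(combinations(DISEASES, 2))

    def total(self) -> float:
        return sum(self.pair(a, b) for a, b in self.all_pairs)


def categorize(
    assisted: float, dist: DiseaseCountDistribution, mode: str = "published"
) -> dict[str, float]:
    """Split the assisted population across the 0/1/2/3+ categories.

    Returns full-precision person counts; round half-up only for display.
    """
    if assisted < 0:
        raise ValueError(f"negative assisted population {assisted}")
    shares = dist.shares(mode)
    return {c: assisted * s for c, s in shares.items()}


def breakdown_single(
    pool: float,
    single_counts: dict[str, float],
    mode: str = "published",
    single_total: float | None = None,
) -> dict[str, float]:
    """Split the one-disease pool across the eight diseases.

    ``single_counts`` is the single-disease column of the national
    disease-count table (thousands) and ``single_total`` the printed pool
    total for that column, which the column over-shoots slightly in the
    source data (876.0 vs 872.6). In ``published`` mode each disease's
    share is count / printed total rounded to 0.1% before multiplying the
    whole-person pool — the spreadsheet convention behind the published
    breakdown, which can over- or under-shoot the pool. ``strict`` mode
    uses unrounded shares renormalised over the column sum, so strata
    conserve the pool exactly.
    """
    _check_mode(mode)
    if pool < 0:
        raise ValueError(f"negative pool {pool}")
    for d in single_counts:
        check_disease(d)
    if any(v < 0 for v in single_counts.values()):
        raise ValueError("negative single-disease count")
    column_sum = sum(single_counts.get(d, 0.0) for d in DISEASES)
    if column_sum <= 0:
        raise ValueError("single-disease counts are all zero")
    if mode == "published":
        denom = column_sum if single_total is None else float(single_total)
        pool_int = math.floor(pool + 0.5)
        out = {}
        for d in DISEASES:
            share = round(single_counts.get(d, 0.0) / denom * 1000.0) / 1000.0
            out[d] = pool_int * share
        return out
    return {d: pool * single_counts.get(d, 0.0) / column_sum for d in DISEASES}


def pair_shares(matrix: ComorbidityMatrix) -> dict[tuple[str, str], float]:
    """Normalised ratios over the 28 unordered disease pairs; sums to 1."""
    total = matrix.total()
    if total <= 0:
        raise ValueError("comorbidity matrix is all zero; cannot normalise")
    return {(a, b): matrix.pair(a, b) / total for a, b in matrix.all_pairs}


def enumerate_combinations(n: int, k_min: int, k_max: int) -> int:
    """Number of subsets of an n-set with size in [k_min, k_max]."""
    if not 0 <= k_min <= k_max <= n:
        raise ValueError(f"invalid range 0 <= {k_min} <= {k_max} <= {n}")
    return sum(math.comb(n, k) for k in range(k_min, k_max + 1))


def triple_scores(
    matrix: ComorbidityMatrix, score: str = "sum"
) -> dict[tuple[str, str, str], float]:
    """Score every 3-disease subset from its three pairwise cells.

    ``sum`` (default), ``min`` and ``product`` scoring are supported; the
    underlying data never state which rule generated the published ranking,
    so the rule is configurable.
    """
    if score not in ("sum", "min", "product"):
        raise ValueError(f"unknown scoring rule {score!r}")
    out = {}
    for trio in combinations(DISEASES, 3):
        cells = [matrix.pair(a, b) for a, b in combinations(trio, 2)]
        if score == "sum":
            out[trio] = sum(cells)
        elif score == "min":
            out[trio] = min(cells)
        else:
            out[trio] = cells[0] * cells[1] * cells[2]
    return out


def multi_shares(
    matrix: ComorbidityMatrix,
    top_k: int = 4,
    residual_mass: float | None = None,
    score: str = "sum",
) -> dict[tuple[str, ...], float]:
    """Shares over all 219 subsets of size >= 3; sums to 1.

    The ``top_k`` highest-scoring triples receive mass proportional to
    their scores relative to the total triple score mass; the remainder
    (by default exactly the residual score mass, overridable via
    ``residual_mass``) is spread over every other size->=3 subset weighted
    by the mean marginal prevalence of its member diseases.
    """
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    scores = triple_scores(matrix, score)
    total_score = sum(scores.values())
    if total_score <= 0:
        raise ValueError("comorbidity matrix is all zero; cannot allocate triples")

    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[: min(top_k, len(ranked))]
    shares: dict[tuple[str, ...], float] = {
        trio: sc / total_score for trio, sc in top
    }
    top_mass = sum(shares.values())
    resid = (1.0 - top_mass) if residual_mass is None else float(residual_mass)
    if residual_mass is not None:
        if not 0.0 <= residual_mass <= 1.0:
            raise ValueError("residual_mass must be in [0, 1]")
        # rescale the top shares so everything still sums to 1
        if top_mass > 0:
            scale = (1.0 - resid) / top_mass
            shares = {t: s * scale for t, s in shares.items()}

    rest = [
        subset
        for k in range(3, len(DISEASES) + 1)
        for subset in combinations(DISEASES, k)
        if subset not in shares
    ]
    if rest and resid > 0:
        weights = {
            s: sum(matrix.marginals.get(d, 0.0) for d in s) / len(s) for s in rest
        }
        wsum = sum(weights.values())
        if wsum <= 0:
            weights = {s: 1.0 for s in rest}
            wsum = float(len(rest))
        for s in rest:
            shares[s] = resid * weights[s] / wsum
    else:
        for s in rest:
            shares[s] = 0.0
    return shares


@dataclass
class CombinationAllocation:
    """Person counts per disease-combination stratum, plus category totals.

    Strata are keyed by canonical disease tuples; the empty tuple is the
    no-chronic-disease stratum. In published mode the one-disease strata
    may not sum exactly to their category total (rounded shares preserved
    from the published tables); strict mode conserves to +-1 person.
    """

    strata: dict[tuple[str, ...], float]
    category_totals: dict[str, float]
    mode: str = "published"

    def category_of(self, combination: tuple[str, ...]) -> str:
        n = len(combination)
        return str(n) if n < 3 else "3plus"

    def category_strata(self, category: str) -> dict[tuple[str, ...], float]:
        return {
            c: v for c, v in self.strata.items() if self.category_of(c) == category
        }

    def total_persons(self) -> float:
        return sum(self.category_totals.values())


def allocate(
    assisted: float,
    dist: DiseaseCountDistribution,
    single_counts: dict[str, float],
    matrix: ComorbidityMatrix,
    top_k: int = 4,
    mode: str = "published",
    score: str = "sum",
) -> CombinationAllocation:
    """Full stratification: categories, then combination strata per category."""
    _check_mode(mode)
    cats = categorize(assisted, dist, mode)
    strata: dict[tuple[str, ...], float] = {(): cats["0"]}

    for d, v in breakdown_single(
        cats["1"], single_counts, mode, single_total=dist.pools["1"]
    ).items():
        strata[(d,)] = v
    for pair, s in pair_shares(matrix).items():
        strata[pair] = cats["2"] * s
    for subset, s in multi_shares(matrix, top_k=top_k, score=score).items():
        strata[canonical_combination(subset)] = cats["3plus"] * s

    return CombinationAllocation(strata=strata, category_totals=cats, mode=mode)
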