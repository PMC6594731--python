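"""Progressive (cohort-survival) forecasting of a 65+ regional population.

The forecast advances five-year age cohorts through time: each closed band
at year ``t + 5`` receives the survivors of the next-younger band at year
``t``, the open-ended top band additionally retains its own survivors, and
net migration (overseas + interstate, expressed as annual rates of the
whole regional population) is apportioned to the 65+ bands in proportion
to cohort size. Births are irrelevant over a 10-year horizon for a 65+
population and are not modelled.

Age-specific death rates are deaths per 1,000 persons per year, applied
annually with compounding across the five-year step. Rates for forecast
years missing from the schedule are projected with per-band linear trends
fitted to the historical years.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

_BAND_RE = re.compile(r"^(\d+)\s*[-–]\s*(\d+)$")
_OPEN_RE = re.compile(r"^(\d+)\s*\+$")


@dataclass(frozen=True)
class AgeBand:
    """A five-year (or open-ended terminal) age band such as ``65-69`` or ``85+``."""

    label: str
    lower: int
    upper: int | None  # None for an open-ended band

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError(f"band {self.label!r}: lower bound must be >= 0")
        if self.upper is not None and self.lower >= self.upper:
            raise ValueError(f"band {self.label!r}: lower must be < upper")

    @property
    def is_open(self) -> bool:
        return self.upper is None

    @property
    def width(self) -> int | None:
        return None if self.upper is None else self.upper - self.lower + 1

    def contains(self, age: int) -> bool:
        return age >= self.lower and (self.upper is None or age <= self.upper)

    @classmethod
    def parse(cls, label: str) -> "AgeBand":
        """Parse labels like ``65-69``, ``85+``, ``90 and over``."""
        s = label.strip().lower().replace("and over", "+").replace(" ", "")
        m = _BAND_RE.match(s)
        if m:
            return cls(label=s, lower=int(m.group(1)), upper=int(m.group(2)))
        m = _OPEN_RE.match(s)
        if m:
            return cls(label=s, lower=int(m.group(1)), upper=None)
        raise ValueError(f"unparseable age band label {label!r}")


@dataclass
class PopulationTable:
    """Person counts by (year, age band), plus optional all-ages totals.

    Counts are stored at full precision; rounding happens only at display.
    """

    counts: dict[tuple[int, str], float] = field(default_factory=dict)
    totals: dict[int, float] = field(default_factory=dict)  # all-ages regional totals
    _bands: dict[str, AgeBand] = field(default_factory=dict)

    def set(self, year: int, band: str | AgeBand, persons: float) -> None:
        if persons < 0:
            raise ValueError(f"negative count {persons} for {band} in {year}")
        b = band if isinstance(band, AgeBand) else AgeBand.parse(band)
        self._bands[b.label] = b
        self.counts[(year, b.label)] = float(persons)

    def get(self, year: int, band: str) -> float:
        label = AgeBand.parse(band).label
        try:
            return self.counts[(year, label)]
        except KeyError:
            raise KeyError(f"no count for band {label!r} in year {year}") from None

    def has(self, year: int, band: str) -> bool:
        return (year, AgeBand.parse(band).label) in self.counts

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _ in self.counts})

    def bands(self, year: int | None = None) -> list[AgeBand]:
        if year is None:
            labels = {lbl for _, lbl in self.counts}
        else:
            labels = {lbl for y, lbl in self.counts if y == year}
        return sorted((self._bands[lbl] for lbl in labels), key=lambda b: b.lower)

    def total(self, year: int, min_age: int = 0) -> float:
        """Sum of band counts for the year, restricted to bands at or above min_age."""
        vals = [
            self.counts[(y, lbl)]
            for (y, lbl) in self.counts
            if y == year and self._bands[lbl].lower >= min_age
        ]
        if not vals:
            raise KeyError(f"no bands at age >= {min_age} for year {year}")
        return float(sum(vals))


@dataclass(frozen=True)
class TrendModel:
    """A fitted straight line value = intercept + slope * (year - reference_year)."""

    intercept: float
    slope: float
    reference_year: float

    def predict(self, year: float) -> float:
        return self.intercept + self.slope * (year - self.reference_year)


def fit_linear_trend(points: list[tuple[float, float]]) -> TrendModel:
    """Ordinary least-squares straight line through (year, value) points.

    The reference year is the mean of the observed years, so the intercept
    equals the mean observed value and residuals are orthogonal to year.
    """
    years = np.asarray([p[0] for p in points], dtype=float)
    values = np.asarray([p[1] for p in points], dtype=float)
    if len(set(years.tolist())) < 2:
        raise ValueError("linear trend needs at least 2 distinct years")
    ref = years.mean()
    x = years - ref
    slope = float(np.dot(x, values) / np.dot(x, x))
    return TrendModel(intercept=float(values.mean()), slope=slope, reference_year=float(ref))


@dataclass
class MortalitySchedule:
    """Age-specific death rates, deaths per 1,000 persons per year.

    Lookup falls back from an exact label match to the band containing the
    queried band's lower bound (so a ``85+`` population band picks up the
    ``85-89`` schedule rate). Years absent from the schedule are projected
    with a per-band linear trend over the observed years.
    """

    rates: dict[tuple[int, str], float] = field(default_factory=dict)
    _bands: dict[str, AgeBand] = field(default_factory=dict)
    strict_monotone: bool = False  # assert rates non-decreasing with age per year

    def set(self, year: int, band: str | AgeBand, rate: float) -> None:
        if rate < 0:
            raise ValueError(f"negative death rate {rate} for {band} in {year}")
        b = band if isinstance(band, AgeBand) else AgeBand.parse(band)
        self._bands[b.label] = b
        self.rates[(year, b.label)] = float(rate)

    @property
    def years(self) -> list[int]:
        return sorted({y for y, _ in self.rates})

    def _resolve_band(self, band: str) -> str:
        b = AgeBand.parse(band)
        if b.label in self._bands:
            return b.label
        for lbl, cand in self._bands.items():
            if cand.contains(b.lower):
                return lbl
        raise KeyError(f"no schedule band covering {band!r}")

    def rate(self, year: int, band: str) -> float:
        label = self._resolve_band(band)
        if (year, label) in self.rates:
            return self.rates[(year, label)]
        pts = [(y, r) for (y, lbl), r in self.rates.items() if lbl == label]
        if len({y for y, _ in pts}) < 2:
            raise KeyError(
                f"rate for {label!r} in {year} absent and not projectable "
                f"(fewer than 2 observed years)"
            )
        return max(0.0, fit_linear_trend(pts).predict(year))

    def check_monotone(self, year: int) -> None:
        """Rates should not decrease with age within a year (warn by default)."""
        rows = sorted(
            ((self._bands[lbl].lower, r) for (y, lbl), r in self.rates.items() if y == year)
        )
        for (a0, r0), (a1, r1) in zip(rows, rows[1:]):
            if r1 < r0:
                msg = f"death rate decreases with age in {year}: {r0} at {a0} -> {r1} at {a1}"
                if self.strict_monotone:
                    raise ValueError(msg)
                warnings.warn(msg, stacklevel=2)


@dataclass(frozen=True)
class MigrationAssumption:
    """Annual net overseas (NOM) and net interstate (NIM) migration rates.

    Rates are fractions of the whole regional population per year, e.g.
    NOM -0.006% is ``nom_rate=-0.00006``.
    """

    nom_rate: float = 0.0
    nim_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, r in (("nom_rate", self.nom_rate), ("nim_rate", self.nim_rate)):
            if not np.isfinite(r) or abs(r) >= 1:
                raise ValueError(f"{name} must be finite with magnitude < 1, got {r}")

    @property
    def net_rate(self) -> float:
        return self.nom_rate + self.nim_rate


def advance_cohort(
    count: float, death_rate: float, years: int, annual_net_migration: float = 0.0
) -> float:
    """Advance a cohort ``years`` years: survival then migration, each year.

    ``death_rate`` is deaths per 1,000 per year, compounded annually. The
    result is clamped at zero (out-migration cannot empty a cohort below 0).
    """
    if count < 0:
        raise ValueError(f"negative cohort count {count}")
    if death_rate < 0:
        raise ValueError(f"negative death rate {death_rate}")
    if years < 0:
        raise ValueError(f"negative duration {years}")
    survival = 1.0 - death_rate / 1000.0
    x = float(count)
    for _ in range(int(years)):
        x = max(0.0, x * survival + annual_net_migration)
    return x


RATE_CONVENTIONS = ("destination", "origin", "mean")


def forecast_population(
    base: PopulationTable,
    schedule: MortalitySchedule,
    migration: MigrationAssumption,
    horizon_years: int,
    base_year: int | None = None,
    regional_population: dict[int, float] | None = None,
    rate_convention: str = "destination",
    min_age: int = 65,
) -> PopulationTable:
    """Progressive forecast over ``horizon_years`` in five-year steps.

    ``base`` must contain every feeder band from ``min_age - 2*5`` upward at
    the base year so that two five-year advancements are closed. Regional
    all-ages population (the denominator for migration counts) is taken
    from ``regional_population`` or, failing that, from trends on the base
    table's totals; with neither available, migration counts are zero.
    """
    if rate_convention not in RATE_CONVENTIONS:
        raise ValueError(f"rate_convention must be one of {RATE_CONVENTIONS}")
    if horizon_years < 0 or horizon_years % 5:
        raise ValueError("horizon_years must be a non-negative multiple of 5")
    if base_year is None:
        base_year = max(base.years)

    bands = base.bands(base_year)
    if not bands:
        raise ValueError(f"base table has no bands for year {base_year}")
    by_lower = {b.lower: b for b in bands}

    # regional population trend for migration counts
    totals = dict(regional_population or {})
    if not totals and base.totals:
        totals = dict(base.totals)
    trend = (
        fit_linear_trend(sorted(totals.items()))
        if len({y for y in totals}) >= 2
        else None
    )

    def regional_pop(year: int) -> float:
        if year in totals:
            return totals[year]
        if trend is not None:
            return max(0.0, trend.predict(year))
        return 0.0

    def step_rate(origin: AgeBand, dest: AgeBand, year: int) -> float:
        # survivors retained inside the open terminal band age five years
        # deeper into it, so their "destination" rate is the schedule band
        # five years above the terminal band's lower bound
        if dest.is_open and origin is dest:
            dest_label = f"{dest.lower + 5}+"
        else:
            dest_label = dest.label
        r_dest = schedule.rate(year, dest_label)
        if rate_convention == "destination":
            return r_dest
        r_orig = schedule.rate(year, origin.label)
        return r_orig if rate_convention == "origin" else 0.5 * (r_orig + r_dest)

    out = PopulationTable()
    current = {b.label: base.get(base_year, b.label) for b in bands}

    for step_start in range(base_year, base_year + horizon_years, 5):
        step_end = step_start + 5
        # annual regional net migration, apportioned to 65+ destinations by
        # the size of the cohorts feeding them
        annual_migrants = migration.net_rate * regional_pop(step_start)
        feeders: dict[str, list[AgeBand]] = {}
        for b in bands:
            if b.lower < min_age:
                continue
            srcs = []
            if b.lower - 5 in by_lower:
                srcs.append(by_lower[b.lower - 5])
            if b.is_open:
                srcs.append(b)
            feeders[b.label] = srcs
        pool = sum(current.get(s.label, 0.0) for ss in feeders.values() for s in ss)

        nxt: dict[str, float] = {}
        for b in bands:
            if b.lower < min_age and b.lower - 5 not in by_lower:
                continue  # youngest feeder band ages out of view
            origin = by_lower.get(b.lower - 5)
            srcs: list[tuple[AgeBand, float]] = []
            if origin is not None:
                srcs.append((origin, current.get(origin.label, 0.0)))
            elif b.lower >= min_age:
                raise KeyError(
                    f"missing feeder band {b.lower - 5}-{b.lower - 1} "
                    f"needed to advance into {b.label}"
                )
            if b.is_open:
                srcs.append((b, current.get(b.label, 0.0)))
            val = 0.0
            for src_band, src_count in srcs:
                if b.lower >= min_age and pool > 0:
                    mig = annual_migrants * src_count / pool
                else:
                    mig = 0.0
                val += advance_cohort(
                    src_count, step_rate(src_band, b, step_end), 5, mig
                )
            nxt[b.label] = val

        for lbl, v in nxt.items():
            out.set(step_end, lbl, v)
        out.totals[step_end] = regional_pop(step_end)
        current = nxt

    return out


def growth_percent(initial: float, final: float) -> float:
    """Percentage growth 100 * (final - initial) / initial."""
    if initial <= 0:
        raise ZeroDivisionError("growth_percent needs a positive initial population")
    return 100.0 * (final - initial) / initial
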