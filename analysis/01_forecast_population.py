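"""Progressive forecast of the FCW 65+ population, 2016 -> 2026.

Advances the observed 2016 census cohorts in five-year steps under the
Queensland age-specific death-rate schedule and the regional net
migration rates (NOM -0.006%/yr, NIM 0.058%/yr), then compares the
totals with the published projection endpoints.

Writes results/population_forecast.csv and results/forecast_summary.csv.
"""

from pathlib import Path

import pandas as pd

from agetech import datasets, io
from agetech.demography import forecast_population, growth_percent
from agetech.rounding import display_int

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pop = datasets.load_population()
    sched = datasets.load_mortality()
    regional = datasets.load_regional_totals("fcw")

    fc = forecast_population(
        pop,
        sched,
        datasets.FCW_MIGRATION,
        horizon_years=datasets.HORIZON_YEARS,
        base_year=datasets.BASE_YEAR,
        regional_population=regional,
    )
    io.write_table(io.population_to_frame(fc), RESULTS / "population_forecast.csv")

    published = datasets.load_published_forecast()
    rows = []
    start = pop.total(2016, min_age=65)
    for year in (2021, 2026):
        ours = fc.total(year, min_age=65)
        ref = published.total(year, min_age=65)
        rows.append(
            {
                "year": year,
                "computed_65plus": display_int(ours),
                "published_65plus": display_int(ref),
                "relative_gap_pct": round(100 * (ours - ref) / ref, 2),
            }
        )
    summary = pd.DataFrame(rows)
    io.write_table(summary, RESULTS / "forecast_summary.csv")

    print(f"2016 observed 65+: {display_int(start)}")
    print(summary.to_string(index=False))
    print(
        "computed 10-year growth: "
        f"{growth_percent(start, fc.total(2026, min_age=65)):.1f}% "
        f"(published endpoints give {growth_percent(30314, 43824):.1f}%)"
    )
    share = 100 * published.total(2026, min_age=65) / published.totals[2026]
    print(f"published 2026 65+ share of regional population: {share:.1f}%")


if __name__ == "__main__":
    main()
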