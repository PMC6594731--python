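"""Assistance-need estimation: who needs help while living at home.

Recomputes the per-age-band joint shares (needing assistance x living in
households) from the survey marginals, then applies the overall 36.61%
rate to the 65+ totals for 2016/2021/2026.

Writes results/assistance_rates_recomputed.csv and results/assisted.csv.
"""

from pathlib import Path

import pandas as pd

from agetech import datasets, io
from agetech.needs import aggregate_assisted
from agetech.rounding import display_int, round_half_up

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    profile = datasets.load_assistance_profile()
    rows = [
        {
            "age_band": band,
            "p_need_assist": p_need,
            "p_household": p_house,
            "joint_pct": round_half_up(100 * profile.band_rate(band), 2),
        }
        for band, (p_need, p_house) in profile.rates.items()
    ]
    recomputed = pd.DataFrame(rows)
    io.write_table(recomputed, RESULTS / "assistance_rates_recomputed.csv")
    print(recomputed.to_string(index=False))
    print(f"overall at-home-and-assisted rate: {profile.overall_rate:.2%}")

    pop = datasets.load_population()
    published = datasets.load_published_forecast()
    totals = {2016: pop.total(2016, min_age=65)}
    for year in (2021, 2026):
        totals[year] = published.total(year, min_age=65)
    assisted = pd.DataFrame(
        [
            {
                "year": y,
                "total_65plus": display_int(t),
                "assisted": display_int(aggregate_assisted(t, profile.overall_rate)),
            }
            for y, t in totals.items()
        ]
    )
    io.write_table(assisted, RESULTS / "assisted.csv")
    print(assisted.to_string(index=False))


if __name__ == "__main__":
    main()
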