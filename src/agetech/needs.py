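"""Assistance-need estimation for the 65+ population.

National survey data cross-tabulate, per five-year age band, the share of
older people who need help with at least one daily activity and the share
living in private households rather than cared accommodation. Their
product — people living at home who need assistance — is the population
the assistive-technology cost model prices. The overall Australian figure
is 36.61%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Overall share of Australians 65+ living in households and needing
#: assistance with at least one activity (national survey figure). Kept as
#: the published two-decimal percentage rather than recomputed from the
#: rounded marginals (38.6% x 94.8% = 36.59%, a rounding artifact).
DEFAULT_OVERALL_RATE = 0.3661


def _check_fraction(name: str, x: float) -> float:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {x}")
    return float(x)


def household_assist_rate(p_need: float, p_household: float) -> float:
    """Share of an age band living at home *and* needing assistance.

    The two marginals are treated as independent within the band, so the
    joint share is their product.
    """
    return _check_fraction("p_need", p_need) * _check_fraction("p_household", p_household)


def aggregate_assisted(total_65plus: float, overall_rate: float = DEFAULT_OVERALL_RATE) -> float:
    """Assisted-at-home persons from a 65+ total; full precision retained."""
    if total_65plus < 0:
        raise ValueError(f"negative population {total_65plus}")
    _check_fraction("overall_rate", overall_rate)
    return total_65plus * overall_rate


@dataclass
class AssistanceProfile:
    """Per-age-band assistance and residence shares, plus the overall rate.

    ``rates`` maps an age-band label to ``(p_need_assist, p_household)``.
    """

    rates: dict[str, tuple[float, float]] = field(default_factory=dict)
    overall_rate: float = DEFAULT_OVERALL_RATE
    p_cared_accommodation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_fraction("overall_rate", self.overall_rate)
        for band, (p_need, p_house) in self.rates.items():
            _check_fraction(f"p_need_assist[{band}]", p_need)
            _check_fraction(f"p_household[{band}]", p_house)
            p_cared = self.p_cared_accommodation.get(band)
            if p_cared is not None and abs(p_house + p_cared - 1.0) > 0.01:
                raise ValueError(
                    f"band {band}: p_household + p_cared_accommodation = "
                    f"{p_house + p_cared:.4f}, expected 1 within 0.01"
                )

    def band_rate(self, band: str) -> float:
        """Joint at-home-and-needing-assistance share for one age band."""
        p_need, p_house = self.rates[band]
        return household_assist_rate(p_need, p_house)
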