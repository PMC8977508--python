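"""Per-case cost valuation: hospitalization cost, time cost, discounting,
CPI adjustment, and purchasing-power-parity conversion.

All amounts enter as nominal CNY of the service year and leave as real USD of
the base year.  The adjustment chain is

    real_usd = nominal_cny
               x (1 + discount_rate)^(base_year - service_year)   # discounting
               x cpi[base_year] / cpi[service_year]               # medical CPI
               / ppp_rate                                         # CNY per USD

Time cost uses the human-capital approach: each inpatient day is valued at
the rural annual net income per capita divided by 365, doubled to cover one
accompanying caregiver:

    time_cost = OLS x (ANI / 365) x caregiver_multiplier

where OLS is the overall length of stay in days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .claims_model import CancerCase, HospitalizationEpisode

__all__ = ["EconomicParams", "CaseCosts", "time_cost", "adjust_and_convert", "case_costs"]


def _default_cpi() -> dict[int, float]:
    # Geometric ~2%/yr medical-services CPI, normalized to 2018 = 1.
    # A stand-in series: replace with official statistics for real analyses.
    return {year: round(1.0 / 1.02 ** (2018 - year), 6) for year in range(2008, 2021)}


@dataclass(frozen=True)
class EconomicParams:
    """Economic constants for cost valuation.

    ani is the Annual Net Income per capita of rural residents (CNY/year),
    the wage proxy in the human-capital time valuation; supply either a
    scalar or a year-indexed mapping.  The default scalar reuses the
    capacity-to-pay figure (2017 per-capita disposable income of the study
    county) as a stand-in and should be replaced with provincial statistics
    for real analyses.
    """

    discount_rate: float = 0.03
    base_year: int = 2018
    cpi_medical: Mapping[int, float] = field(default_factory=_default_cpi)
    ppp_rate: float = 3.55  # CNY per USD, 2018 purchasing power parity
    ani: float | Mapping[int, float] = 10906.0
    caregiver_multiplier: float = 2.0
    che_threshold: float = 0.40
    capacity_to_pay_cny: float = 10906.0

    def __post_init__(self):
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.ppp_rate <= 0:
            raise ValueError("ppp_rate must be > 0")
        if not 0 < self.che_threshold < 1:
            raise ValueError("che_threshold must be in (0, 1)")
        if self.base_year not in self.cpi_medical:
            raise ValueError(f"cpi_medical must contain base year {self.base_year}")
        if abs(self.cpi_medical[self.base_year] - 1.0) > 1e-9:
            raise ValueError("cpi_medical must be normalized to 1 at the base year")

    def ani_for(self, year: int) -> float:
        if isinstance(self.ani, Mapping):
            if year not in self.ani:
                raise KeyError(f"no ANI configured for service year {year}")
            return float(self.ani[year])
        return float(self.ani)

    @property
    def capacity_to_pay_usd(self) -> float:
        return self.capacity_to_pay_cny / self.ppp_rate


@dataclass
class CaseCosts:
    """Cost summary for one case over the standard observation window.

    treatment_cost_usd is derived, always the exact sum of hospitalization
    and time cost (the societal-perspective definition).
    """

    participant_id: str
    hospitalization_cost_usd: float
    time_cost_usd: float
    out_of_pocket_usd: float
    ols_days: int
    n_episodes: int
    treatment_cost_usd: float = field(init=False)

    def __post_init__(self):
        for name in ("hospitalization_cost_usd", "time_cost_usd", "out_of_pocket_usd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.treatment_cost_usd = self.hospitalization_cost_usd + self.time_cost_usd


def time_cost(
    ols_days: float, params: EconomicParams, service_year: int | None = None
) -> float:
    """Human-capital time cost in nominal CNY: OLS x ANI/365 x multiplier."""
    if ols_days < 0:
        raise ValueError(f"negative overall length of stay: {ols_days}")
    year = service_year if service_year is not None else params.base_year
    return ols_days * (params.ani_for(year) / 365.0) * params.caregiver_multiplier


def adjust_and_convert(amount_cny: float, service_year: int, params: EconomicParams) -> float:
    """Discount and CPI-adjust a nominal CNY amount to base-year value, then
    convert to USD at the PPP rate.  Base-year amounts divide by the PPP rate
    only."""
    if service_year not in params.cpi_medical:
        raise KeyError(f"no medical CPI configured for service year {service_year}")
    discount = (1.0 + params.discount_rate) ** (params.base_year - service_year)
    cpi = params.cpi_medical[params.base_year] / params.cpi_medical[service_year]
    return amount_cny * discount * cpi / params.ppp_rate


def case_costs(
    case: CancerCase,
    episodes_in_window: Iterable[HospitalizationEpisode],
    params: EconomicParams,
) -> CaseCosts:
    """Aggregate one case's in-window episodes into real-USD cost components.

    Hospitalization and out-of-pocket costs sum the episodes' adjusted total
    and out-of-pocket expenses; time cost applies the human-capital formula
    to each episode's length of stay in its own service year.  A case with no
    in-window episode yields an all-zero record with a warning.
    """
    episodes = list(episodes_in_window)
    if not episodes:
        warnings.warn(
            f"case {case.participant_id}: no episode in observation window; "
            "zero-cost record",
            stacklevel=2,
        )
        return CaseCosts(case.participant_id, 0.0, 0.0, 0.0, 0, 0)

    hosp = 0.0
    oop = 0.0
    tc = 0.0
    ols = 0
    for ep in episodes:
        year = ep.service_year
        hosp += adjust_and_convert(ep.total_expense, year, params)
        oop += adjust_and_convert(ep.out_of_pocket_expense, year, params)
        tc += adjust_and_convert(time_cost(ep.length_of_stay, params, year), year, params)
        ols += ep.length_of_stay
    return CaseCosts(case.participant_id, hosp, tc, oop, ols, len(episodes))
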