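"""Facility costing: annual cost line items, currency conversion and
per-patient costs for each service-delivery strategy.

Annual operating costs of a facility are recorded as line items in local
currency (Zambian Kwacha, ZMK) and fall into three categories: capital
(building, furniture, vehicle — already annualized), recurrent (staff
salaries) and drug/laboratory (ARVs, CD4/full-blood-count and chemistry
testing).  The analysis needs, per strategy, a single per-patient annual
cost in USD:

* hospital-only strategy: hospital total / hospital patient volume;
* hospital + mobile strategy: the patient-weighted blend of the hospital
  per-patient cost and the rural-health-centre per-patient cost across
  the patients each facility type serves.

``annualize_capital`` converts a raw capital purchase price into an
equivalent annual cost with the standard annuity factor
``(1 - (1+r)^-L) / r`` (useful life ``L`` years, discount rate ``r``);
the bundled cost table already contains annualized values, so this is
for users supplying their own purchase prices.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "CostLineItem",
    "FacilityCostProfile",
    "CurrencySpec",
    "AnnualizationSpec",
    "convert_currency",
    "per_patient_annual_cost",
    "blended_per_patient_cost",
    "annualize_capital",
    "annuity_factor",
    "load_cost_table",
    "bundled_cost_table",
    "facility_profiles",
    "DEFAULT_USEFUL_LIFE_YEARS",
]

_CATEGORIES = ("capital", "recurrent", "drug_lab")

#: Assumed useful lives (years) for annualizing raw capital purchases.
#: These are conventional costing assumptions, not observed values.
DEFAULT_USEFUL_LIFE_YEARS = {"building": 30.0, "furniture": 10.0, "vehicle": 5.0}


@dataclass(frozen=True)
class CostLineItem:
    """One annual cost entry of a facility, in ZMK/year."""

    label: str
    category: str
    annual_cost: float

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("line item label must be non-empty")
        if self.category not in _CATEGORIES:
            raise ValueError(f"category must be one of {_CATEGORIES}")
        if self.annual_cost < 0:
            raise ValueError("annual_cost must be >= 0")


@dataclass(frozen=True)
class FacilityCostProfile:
    """All annual cost line items of one facility type.

    ``n_patients`` is the number of patients the facility serves per year
    (6000 for a district hospital; 300 per rural health centre).
    """

    facility_kind: str
    line_items: tuple[CostLineItem, ...]
    n_patients: int

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not self.line_items:
            raise ValueError("a facility needs at least one line item")

    @property
    def total_zmk(self) -> float:
        return sum(item.annual_cost for item in self.line_items)


@dataclass(frozen=True)
class CurrencySpec:
    """Exchange rate, local currency units per USD (5000 ZMK/USD in 2011)."""

    zmk_per_usd: float = 5000.0

    def __post_init__(self) -> None:
        if self.zmk_per_usd <= 0:
            raise ValueError("exchange rate must be positive")


@dataclass(frozen=True)
class AnnualizationSpec:
    """Discount rate and useful life for capital annualization."""

    discount_rate: float = 0.03
    useful_life: float = 1.0

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.useful_life < 1:
            raise ValueError("useful_life must be >= 1 year")


def convert_currency(amount_zmk: float, spec: CurrencySpec) -> float:
    """Convert ZMK to USD at the given rate. Unrounded; round at reporting."""
    if amount_zmk < 0:
        raise ValueError("amount must be >= 0")
    return amount_zmk / spec.zmk_per_usd


def per_patient_annual_cost(total_usd: float, n_patients: int) -> float:
    """Annual cost per patient served: facility total / patient volume."""
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    return total_usd / n_patients


def blended_per_patient_cost(components: list[tuple[float, int]]) -> float:
    """Patient-weighted mean per-patient cost across facility components.

    ``components`` holds ``(per_patient_cost_usd, n_patients)`` pairs, e.g.
    one district hospital serving 6000 patients and five rural health
    centres serving 300 each.
    """
    if not components:
        raise ValueError("need at least one cost component")
    if any(n <= 0 for _, n in components):
        raise ValueError("all component patient counts must be positive")
    total_cost = sum(cost * n for cost, n in components)
    total_n = sum(n for _, n in components)
    return total_cost / total_n


def annuity_factor(useful_life: float, discount_rate: float) -> float:
    """Present value of 1/year over ``useful_life`` years at ``discount_rate``.

    ``(1 - (1+r)^-L) / r`` for r > 0; the r -> 0 limit is L.
    """
    if useful_life < 1:
        raise ValueError("useful_life must be >= 1 year")
    if discount_rate == 0:
        return useful_life
    return (1.0 - (1.0 + discount_rate) ** (-useful_life)) / discount_rate


def annualize_capital(purchase_cost: float, spec: AnnualizationSpec) -> float:
    """Equivalent annual cost of a capital purchase over its useful life."""
    if purchase_cost < 0:
        raise ValueError("purchase_cost must be >= 0")
    return purchase_cost / annuity_factor(spec.useful_life, spec.discount_rate)


def load_cost_table(path_or_buffer) -> pd.DataFrame:
    """Read a facility cost table CSV.

    Expected columns: ``facility_kind, label, category, annual_cost_zmk,
    n_patients``.
    """
    df = pd.read_csv(path_or_buffer)
    required = {"facility_kind", "label", "category", "annual_cost_zmk", "n_patients"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cost table missing columns: {sorted(missing)}")
    return df


def bundled_cost_table() -> pd.DataFrame:
    """The packaged 2011 Zambian facility cost table (ZMK)."""
    with resources.files("artcea.data").joinpath("facility_costs.csv").open() as fh:
        return load_cost_table(fh)


def facility_profiles(table: pd.DataFrame | None = None) -> dict[str, FacilityCostProfile]:
    """Group a cost table into one `FacilityCostProfile` per facility kind."""
    if table is None:
        table = bundled_cost_table()
    profiles: dict[str, FacilityCostProfile] = {}
    for kind, sub in table.groupby("facility_kind", sort=False):
        n = sub["n_patients"].unique()
        if len(n) != 1:
            raise ValueError(f"inconsistent n_patients for {kind!r}")
        items = tuple(
            CostLineItem(row.label, row.category, float(row.annual_cost_zmk))
            for row in sub.itertuples()
        )
        profiles[str(kind)] = FacilityCostProfile(str(kind), items, int(n[0]))
    return profiles


def strategy_annual_costs(
    currency: CurrencySpec | None = None,
    n_rural_centres: int = 5,
    table: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Per-patient annual cost (USD) of each service-delivery strategy.

    Returns ``{"original": hospital-only cost, "intervention": blended
    hospital + mobile cost}`` computed from the facility cost table:
    the hospital serves 6000 patients, each of ``n_rural_centres`` rural
    health centres serves its own patient volume, and the intervention
    cost is the patient-weighted blend across all facilities.
    """
    currency = currency or CurrencySpec()
    profiles = facility_profiles(table)
    hosp = profiles["district_hospital"]
    rhc = profiles["rural_health_centre"]
    hosp_pp = per_patient_annual_cost(
        convert_currency(hosp.total_zmk, currency), hosp.n_patients
    )
    rhc_pp = per_patient_annual_cost(
        convert_currency(rhc.total_zmk, currency), rhc.n_patients
    )
    blended = blended_per_patient_cost(
        [(hosp_pp, hosp.n_patients), (rhc_pp, n_rural_centres * rhc.n_patients)]
    )
    return {"original": hosp_pp, "intervention": blended}
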