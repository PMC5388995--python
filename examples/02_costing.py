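"""Facility costing: from annual cost line items in local currency to
per-patient annual costs per strategy.

The district hospital serves 6000 patients; each of 5 rural health
centres serves 300.  The intervention cost is the patient-weighted blend.
"""

from artcea import bundled_cost_table, strategy_annual_costs
from artcea.costing import AnnualizationSpec, annualize_capital

table = bundled_cost_table()
print(table.to_string(index=False))
costs = strategy_annual_costs()
print()
print(f"hospital-only per-patient annual cost:   {costs['original']:.2f} USD")
print(f"hospital+mobile blended per-patient cost: {costs['intervention']:.2f} USD")

# annualizing a raw capital purchase (e.g. a vehicle over 5 years at 3%)
eac = annualize_capital(25_000.0, AnnualizationSpec(0.03, 5))
print(f"\n25,000 USD vehicle over 5 years at 3% -> {eac:.2f} USD/year")
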