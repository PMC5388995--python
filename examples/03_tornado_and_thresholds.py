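"""One-way sensitivity: tornado ranking and decision thresholds.

Each uncertain input moves to its range bounds with the rest at base;
the ICER swing ranks the inputs.  The threshold search then locates the
input value where the ICER crosses the willingness to pay (3x GDP per
capita = 4224 USD/QALY).
"""

from artcea import build_pair, default_config
from artcea.pipeline import base_parameter_values
from artcea.sensitivity import ParamRange, one_way_sensitivity, threshold_search, tornado_table

config = default_config()
pair = build_pair(config)
base = base_parameter_values(pair)
ranges = [
    ParamRange(name, base[name], r.low, r.high)
    for name, r in config.sensitivity.ranges.items()
]
print(tornado_table(one_way_sensitivity(pair, ranges)).to_string(index=False))

root = threshold_search(
    pair, "cost_intervention", 125.10, 500.26, criterion="icer_crosses_wtp"
)
print(
    f"\nintervention annual cost at which the ICER meets the WTP: "
    f"{root:.2f} USD (above this the intervention is no longer "
    f"cost effective at 4224 USD/QALY)"
)
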