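"""Base case: discounted lifetime cost and QALYs per patient in each arm.

Builds the two strategies from the packaged configuration (facility cost
table, retention anchors, 40 one-year cycles, 3% discount, initial
half-cycle correction) and compares them incrementally.
"""

from artcea import build_pair, run_pair
from artcea.reporting import base_case_table

result = run_pair(build_pair())
print(base_case_table(result).to_string(index=False))
print()
print(f"ICER: {result.icer:.2f} USD per QALY gained")
print(
    "Reading: each row is one strategy's discounted per-patient lifetime "
    "cost (USD) and effectiveness (QALYs); the ICER is the extra cost of "
    "the hospital+mobile strategy per additional QALY it buys."
)
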