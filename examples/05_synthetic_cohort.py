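"""Synthetic ART cohort: generate patients, then recover the retention
curve that generated them.

Patients enrol during 2010-2011, attend monthly visits, and may die or
disengage (>3 months without a visit = lost to follow-up).  The
Kaplan-Meier estimator treats death in care as a competing risk.
"""

from datetime import date

from artcea import default_config
from artcea.pipeline import build_retention_curves
from artcea.synthetic import CohortParams, estimate_retention, generate_cohort

config = default_config()
curve = build_retention_curves(config)["original"]
params = CohortParams(
    n_patients=20_000, retention=curve,
    censor_date=date(2015, 12, 31),  # long enough to observe 36 months
    seed=config.seed,
)
records = generate_cohort(params)
print(records.head().to_string(index=False))
print(f"\nevents: {records['event'].value_counts().to_dict()}")
for months in (12, 24, 36):
    est = estimate_retention(records, months, method="km")
    truth = curve.retention_at(months / 12)
    print(f"retention at {months:2d} months: estimated {est:.3f}, generating curve {truth:.3f}")
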