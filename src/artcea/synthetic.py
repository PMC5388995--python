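"""Synthetic individual-level ART cohort with the structure the
economic model assumes.

The retention anchors feeding the Markov model come from an (unpublished)
observational cohort of ~32,428 ART-naive patients enrolled between
January 2010 and December 2011, followed with monthly clinic visits and
administratively censored; a patient not seen for more than 3 months
after their last visit is lost to follow-up (LTFU).  This module
generates such a cohort from known hazards — so the retention-estimation
stage can be tested end-to-end against the generating truth — and
estimates retention from the generated records.

The generator sub-cycles monthly (annual hazards ``h`` become monthly
``1 - (1 - h)^(1/12)``) so the >3-month LTFU rule is expressible; the
economic model itself stays annual.  Within a month, death is applied
before dropout, mirroring the cohort model's default event ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .retention import RetentionCurve

__all__ = [
    "PatientRecord",
    "CohortParams",
    "generate_cohort",
    "estimate_retention",
    "write_cohort_csv",
    "read_cohort_csv",
]

IN_CARE = "in_care"
LTFU = "ltfu"
DEAD = "dead"

COLUMNS = [
    "id",
    "enrol_date",
    "age_at_start",
    "event",
    "event_time_months",
    "last_visit_month",
    "last_visit_interval",
    "potential_followup_months",
]


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient (row schema of the cohort table)."""

    id: int
    enrol_date: date
    age_at_start: float
    event: str  # in_care | ltfu | dead
    event_time_months: float
    last_visit_month: int
    last_visit_interval: int
    potential_followup_months: int


@dataclass(frozen=True)
class CohortParams:
    """Generating truth and observation scheme for a synthetic cohort."""

    n_patients: int = 32_428
    retention: RetentionCurve | None = None
    mortality_retained: float = 0.094
    mortality_not_retained: float = 0.375
    age_median: float = 33.0
    age_sd: float = 10.0
    enrol_start: date = date(2010, 1, 1)
    enrol_end: date = date(2011, 12, 31)
    censor_date: date = date(2012, 12, 31)
    visit_interval_months: int = 1
    ltfu_gap_months: int = 3
    seed: int = 20_110_412

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for h in (self.mortality_retained, self.mortality_not_retained):
            if not 0.0 <= h <= 1.0:
                raise ValueError("hazards must lie in [0, 1]")
        if self.enrol_end < self.enrol_start:
            raise ValueError("enrolment window reversed")
        if self.censor_date < self.enrol_end:
            raise ValueError("censor date before end of enrolment")


def _months_between(start: np.ndarray, end: date) -> np.ndarray:
    """Whole months elapsed from each start date to ``end``."""
    start = pd.to_datetime(pd.Series(start))
    end_ts = pd.Timestamp(end)
    months = (end_ts.year - start.dt.year) * 12 + (end_ts.month - start.dt.month)
    months -= (start.dt.day > end_ts.day).astype(int)
    return months.to_numpy()


def _monthly_prob(annual: float) -> float:
    return 1.0 - (1.0 - annual) ** (1.0 / 12.0)


def generate_cohort(
    params: CohortParams, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate patient trajectories month by month.

    Returns a DataFrame with the `PatientRecord` columns, one row per
    patient.  Deterministic for a given ``params.seed`` (or generator).

    A patient attends monthly visits while in care.  Each month they may
    die (state-specific hazard) or — while in care — drop out with the
    monthly probability implied by the retention curve,
    ``1 - R(t/12)/R((t-1)/12)``.  Dropout within ``ltfu_gap_months`` of
    the censoring date is not yet observable as LTFU and such patients
    are recorded as still in care, as they would appear in a live
    programme database.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    retention = params.retention
    if retention is None:
        raise ValueError("CohortParams.retention is required")
    n = params.n_patients

    enrol_span = (params.enrol_end - params.enrol_start).days
    enrol_offsets = rng.integers(0, enrol_span + 1, n)
    enrol_dates = (
        np.datetime64(params.enrol_start) + enrol_offsets.astype("timedelta64[D]")
    )
    ages = np.maximum(15.0, rng.normal(params.age_median, params.age_sd, n))
    potential = _months_between(enrol_dates, params.censor_date)
    max_months = int(potential.max())
    horizon_months = int(retention.horizon * 12)
    max_months = min(max_months, horizon_months)

    p_die_ret = _monthly_prob(params.mortality_retained)
    p_die_not = _monthly_prob(params.mortality_not_retained)

    state = np.zeros(n, dtype=np.int8)  # 0 in care, 1 out of care, 2 dead
    drop_month = np.full(n, -1)
    death_month = np.full(n, -1)
    for t in range(1, max_months + 1):
        active = potential >= t
        q_m = 1.0 - retention.retention_at(t / 12.0) / retention.retention_at(
            (t - 1) / 12.0
        )
        u_death = rng.random(n)
        u_drop = rng.random(n)
        in_care = (state == 0) & active
        out_care = (state == 1) & active
        # death first, then dropout among survivors (matches the model)
        dies = in_care & (u_death < p_die_ret)
        death_month[dies] = t
        state[dies] = 2
        drops = in_care & ~dies & (u_drop < q_m)
        drop_month[drops] = t
        state[drops] = 1
        dies_out = out_care & (u_death < p_die_not)
        death_month[dies_out] = t
        state[dies_out] = 2

    event = np.full(n, IN_CARE, dtype=object)
    event_time = potential.astype(float).copy()
    last_visit = potential.copy()

    dropped = drop_month >= 0
    died_in_care = (death_month >= 0) & ~dropped
    died_after_drop = (death_month >= 0) & dropped

    # deaths in care end follow-up at the death month
    event[died_in_care] = DEAD
    event_time[died_in_care] = death_month[died_in_care]
    last_visit[died_in_care] = death_month[died_in_care]

    # dropouts: last visit at the dropout month; LTFU once the gap to the
    # censor date exceeds the rule, otherwise still counted as in care
    gap = np.where(dropped, potential - drop_month, 0)
    observable = dropped & (gap > params.ltfu_gap_months)
    event[observable] = LTFU
    event_time[observable] = drop_month[observable]
    last_visit[dropped] = drop_month[dropped]
    silent = dropped & ~observable
    event_time[silent] = potential[silent]
    # a death after dropout keeps its LTFU classification: mortality out
    # of care is not observed by the programme database
    del died_after_drop
    interval = np.maximum(
        params.visit_interval_months, potential - last_visit
    )
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "enrol_date": pd.to_datetime(enrol_dates),
            "age_at_start": ages,
            "event": event,
            "event_time_months": event_time,
            "last_visit_month": last_visit,
            "last_visit_interval": interval,
            "potential_followup_months": potential,
        }
    )


def estimate_retention(
    records: pd.DataFrame, months: int, method: str = "proportion"
) -> float:
    """Fraction of patients retained in care ``months`` after enrolment.

    The retention curve treats death in care as a competing risk, not as
    non-retention (the model applies mortality separately), so deaths in
    care are censored by both estimators.

    ``proportion``
        among patients whose potential follow-up reaches ``months`` and
        who did not die in care before then, the fraction whose last
        clinic visit is at or after ``months``.  Simple and close to what
        programme reports tabulate, but slightly downward-biased because
        a death in care removes a would-be retainee while dropouts are
        kept however early they left.
    ``km``
        Kaplan-Meier estimate of dropout-only survival: the event is the
        last clinic visit of a patient who disengaged; deaths in care and
        administrative end of follow-up are censoring times.  Consistent
        for the generating curve.
    """
    if months <= 0:
        raise ValueError("months must be positive")
    died_in_care = records["event"] == DEAD
    dropped = ~died_in_care & (
        records["last_visit_month"] < records["potential_followup_months"]
    )
    if method == "proportion":
        eligible = records[
            (records["potential_followup_months"] >= months)
            & ~(died_in_care & (records["event_time_months"] < months))
        ]
        if eligible.empty:
            raise ValueError(
                f"no patient has {months} months of potential follow-up"
            )
        return float((eligible["last_visit_month"] >= months).mean())
    if method == "km":
        from lifelines import KaplanMeierFitter

        time = np.where(
            dropped,
            records["last_visit_month"],
            np.where(
                died_in_care,
                records["event_time_months"],
                records["potential_followup_months"],
            ),
        ).astype(float)
        kmf = KaplanMeierFitter()
        kmf.fit(np.maximum(time, 0.5), event_observed=dropped.to_numpy())
        return float(kmf.predict(months))
    raise ValueError("method must be 'proportion' or 'km'")


def write_cohort_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, date_format="%Y-%m-%d")


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["enrol_date"])
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return df
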