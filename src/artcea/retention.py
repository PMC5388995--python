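"""Retention-over-time curves for ART programmes.

A programme's retention curve gives the fraction of an enrolling cohort
still in care ``t`` years after ART initiation, anchored at observed or
assumed time points (e.g. 88.6% at 1 year, 81.0% at 2 years, ...).
The curve is the bridge between programme monitoring data and the annual
state-transition model: each one-year model cycle needs the *conditional*
probability of dropping out of care during that cycle, ``q_c = 1 -
R(c)/R(c-1)``, which this module derives from the anchors.

The shape between anchors is not observable from annual monitoring data;
two interpolation conventions are offered:

``linear``
    straight-line interpolation of the retention fraction (default);
``constant_hazard``
    piecewise-exponential survival, i.e. linear interpolation of
    ``log R(t)``, equivalent to a constant dropout hazard between anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RetentionCurve", "geometric_retention_curve"]

_INTERPOLATIONS = ("linear", "constant_hazard")


@dataclass(frozen=True)
class RetentionCurve:
    """Anchored retention-over-time function for one programme arm.

    Parameters
    ----------
    arm:
        Label for the strategy the curve belongs to (``"original"``,
        ``"intervention"``, or any free text for scenarios).
    anchors:
        Ordered ``(time_years, retention_fraction)`` pairs with strictly
        increasing times >= 1 and non-increasing retention in (0, 1].
        ``R(0) = 1`` is implicit: everyone enrolled is in care at time 0.
    interpolation:
        ``"linear"`` or ``"constant_hazard"`` (see module docstring).
    """

    arm: str
    anchors: tuple[tuple[float, float], ...]
    interpolation: str = "linear"

    # filled in __post_init__; kept out of repr/compare
    _times: np.ndarray = field(init=False, repr=False, compare=False)
    _values: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.interpolation not in _INTERPOLATIONS:
            raise ValueError(
                f"interpolation must be one of {_INTERPOLATIONS}, "
                f"got {self.interpolation!r}"
            )
        anchors = tuple((float(t), float(r)) for t, r in self.anchors)
        if not anchors:
            raise ValueError("retention curve needs at least one anchor")
        times = np.array([a[0] for a in anchors])
        values = np.array([a[1] for a in anchors])
        if times[0] < 1.0:
            raise ValueError("anchor times must start at >= 1 year")
        if np.any(np.diff(times) <= 0):
            raise ValueError("anchor times must be strictly increasing")
        if np.any(np.diff(values) > 0):
            raise ValueError("retention must be non-increasing over time")
        if np.any(values <= 0) or np.any(values > 1):
            raise ValueError("retention fractions must lie in (0, 1]")
        object.__setattr__(self, "anchors", anchors)
        # prepend the implicit (0, 1) anchor once, here
        object.__setattr__(self, "_times", np.concatenate([[0.0], times]))
        object.__setattr__(self, "_values", np.concatenate([[1.0], values]))

    @property
    def horizon(self) -> float:
        """Last anchored time in years; the curve is undefined beyond it."""
        return float(self._times[-1])

    def retention_at(self, t: float) -> float:
        """Fraction of the enrolling cohort retained in care at time ``t``.

        ``t`` must lie in ``[0, horizon]``; retention beyond the last anchor
        is not extrapolated.
        """
        if t < 0 or t > self.horizon:
            raise ValueError(
                f"t={t} outside the curve's domain [0, {self.horizon}]"
            )
        if self.interpolation == "linear":
            return float(np.interp(t, self._times, self._values))
        return float(np.exp(np.interp(t, self._times, np.log(self._values))))

    def conditional_dropout_prob(self, cycle: int) -> float:
        """Probability of dropping out during ``cycle``, given in care before.

        ``q_c = 1 - R(c) / R(c-1)`` for integer cycle ``c >= 1``.  Because
        retention is non-increasing and positive, ``q_c`` lies in [0, 1].
        """
        if cycle < 1:
            raise ValueError("cycle index starts at 1")
        r_prev = self.retention_at(cycle - 1)
        if r_prev == 0:
            raise ZeroDivisionError("retention already zero before this cycle")
        return 1.0 - self.retention_at(cycle) / r_prev

    def with_interpolation(self, interpolation: str) -> "RetentionCurve":
        return replace(self, interpolation=interpolation)


def geometric_retention_curve(
    arm: str, annual_reduction: float, horizon: int = 40
) -> RetentionCurve:
    """Curve with a constant proportional loss per year, R(t) = (1-r)^t.

    Used by the retention scenario analyses, which replace the anchored
    curves with "x% reduction per year" patterns (e.g. best case 10%/yr
    for the comparator and 3%/yr for the intervention).
    """
    if not 0.0 <= annual_reduction < 1.0:
        raise ValueError("annual_reduction must be in [0, 1)")
    anchors = tuple(
        (float(t), (1.0 - annual_reduction) ** t) for t in range(1, horizon + 1)
    )
    return RetentionCurve(arm=arm, anchors=anchors)
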