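"""Incremental cost-effectiveness comparison of strategies.

Given each strategy's discounted per-patient lifetime cost and QALYs,
this module computes incremental costs and effects, the incremental
cost-effectiveness ratio (ICER = ΔC/ΔE against the previous undominated
strategy on the cost-ordered frontier), dominance status, and the WHO
willingness-to-pay classification: an ICER below 1x GDP per capita is
"very cost effective", below 3x GDP per capita "cost effective",
otherwise "not cost effective" (Zambia 2011: GDP per capita 1408 USD,
hence a 4224 USD/QALY threshold).

Net monetary benefit, ``NMB = WTP x E - C``, underlies the acceptability
curve: at WTP equal to the ICER the two strategies' NMBs coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Strategy",
    "CEAResult",
    "WTPThreshold",
    "icer",
    "incremental_analysis",
    "classify_decision",
    "net_monetary_benefit",
]

UNDOMINATED = "undominated"
STRONGLY_DOMINATED = "strongly_dominated"
EXTENDEDLY_DOMINATED = "extendedly_dominated"

VERY_COST_EFFECTIVE = "very_cost_effective"
COST_EFFECTIVE = "cost_effective"
NOT_COST_EFFECTIVE = "not_cost_effective"


@dataclass(frozen=True)
class Strategy:
    """One strategy's discounted per-patient totals."""

    name: str
    cost: float
    effectiveness: float

    def __post_init__(self) -> None:
        if self.cost < 0 or self.effectiveness < 0:
            raise ValueError("cost and effectiveness must be >= 0")


@dataclass(frozen=True)
class WTPThreshold:
    """Willingness-to-pay rule: multiples of GDP per capita per QALY."""

    gdp_per_capita: float = 1408.0
    multiplier: int = 3

    def __post_init__(self) -> None:
        if self.gdp_per_capita <= 0:
            raise ValueError("gdp_per_capita must be positive")

    @property
    def value(self) -> float:
        return self.multiplier * self.gdp_per_capita


@dataclass(frozen=True)
class CEAResult:
    """Comparison outcome for one strategy on the cost-ordered frontier.

    ``icer`` is None for the cheapest strategy (no comparator), for
    dominated strategies, and when the effectiveness difference is zero
    (the undefined-ICER case).
    """

    strategy: Strategy
    incremental_cost: float | None
    incremental_effectiveness: float | None
    icer: float | None
    ce_ratio: float | None
    dominance: str
    decision: str | None


def icer(reference: Strategy, comparator: Strategy) -> float | None:
    """ΔCost/ΔEffectiveness of ``comparator`` versus ``reference``.

    Returns None when the effectiveness difference is exactly zero —
    the ratio is undefined, not an error.  Computed on unrounded inputs;
    rounding belongs to the reporting layer.
    """
    d_eff = comparator.effectiveness - reference.effectiveness
    if d_eff == 0:
        return None
    return (comparator.cost - reference.cost) / d_eff


def classify_decision(icer_value: float, wtp: WTPThreshold) -> str:
    """WHO GDP-multiple classification of a non-negative ICER."""
    if icer_value < 0:
        raise ValueError(
            "negative ICERs signal dominance and are not classified here"
        )
    if icer_value < wtp.gdp_per_capita:
        return VERY_COST_EFFECTIVE
    if icer_value < wtp.multiplier * wtp.gdp_per_capita:
        return COST_EFFECTIVE
    return NOT_COST_EFFECTIVE


def net_monetary_benefit(strategy: Strategy, wtp: float) -> float:
    """``wtp x effectiveness - cost`` (USD)."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * strategy.effectiveness - strategy.cost


def _ce_ratio(s: Strategy) -> float | None:
    return s.cost / s.effectiveness if s.effectiveness > 0 else None


def incremental_analysis(
    strategies: list[Strategy], wtp: WTPThreshold | None = None
) -> list[CEAResult]:
    """Frontier construction with strong and extended dominance.

    Strategies are sorted by ascending cost.  A strategy is strongly
    dominated if some other strategy costs no more and is strictly more
    effective; it is extendedly dominated if its ICER against the previous
    frontier member exceeds the ICER of the next more effective frontier
    member (a mix of the neighbours achieves more effect per dollar).
    ICERs are reported against the previous undominated strategy.
    """
    if not strategies:
        raise ValueError("need at least one strategy")
    wtp = wtp or WTPThreshold()
    order = sorted(strategies, key=lambda s: (s.cost, -s.effectiveness))

    dominance = {s.name: UNDOMINATED for s in order}
    for s in order:
        if any(
            (o.cost <= s.cost and o.effectiveness > s.effectiveness)
            or (o.cost < s.cost and o.effectiveness >= s.effectiveness)
            for o in order
            if o is not s
        ):
            dominance[s.name] = STRONGLY_DOMINATED

    # iterative extended-dominance pruning on the remaining frontier
    frontier = [s for s in order if dominance[s.name] == UNDOMINATED]
    changed = True
    while changed and len(frontier) >= 3:
        changed = False
        for i in range(1, len(frontier) - 1):
            prev_s, s, next_s = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_here = icer(prev_s, s)
            icer_next = icer(s, next_s)
            if icer_here is not None and icer_next is not None and icer_here > icer_next:
                dominance[s.name] = EXTENDEDLY_DOMINATED
                frontier.pop(i)
                changed = True
                break

    results: list[CEAResult] = []
    prev: Strategy | None = None
    for s in order:
        if dominance[s.name] != UNDOMINATED or prev is None:
            d_cost = d_eff = ratio = None
            if prev is not None:  # dominated: still report raw increments
                d_cost = s.cost - prev.cost
                d_eff = s.effectiveness - prev.effectiveness
        else:
            d_cost = s.cost - prev.cost
            d_eff = s.effectiveness - prev.effectiveness
            ratio = icer(prev, s)
        decision = None
        if dominance[s.name] == UNDOMINATED and ratio is not None and ratio >= 0:
            decision = classify_decision(ratio, wtp)
        results.append(
            CEAResult(
                strategy=s,
                incremental_cost=d_cost,
                incremental_effectiveness=d_eff,
                icer=ratio if dominance[s.name] == UNDOMINATED else None,
                ce_ratio=_ce_ratio(s),
                dominance=dominance[s.name],
                decision=decision,
            )
        )
        if dominance[s.name] == UNDOMINATED:
            prev = s
    return results
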