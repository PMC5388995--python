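"""Assembly of the two-strategy comparison from a configuration.

Builds the retention curves, per-patient annual costs (from the facility
cost table) and `ModelSpec` for each arm, bundles them as a `ModelPair`,
and runs the base-case comparison.  The sensitivity module perturbs
`ModelPair` objects through `apply_parameter`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .cea import CEAResult, Strategy, WTPThreshold, incremental_analysis
from .config import AnalysisConfig
from .costing import CurrencySpec, load_cost_table, strategy_annual_costs
from .markov import ArmSpec, DiscountSpec, ModelSpec, run_arm
from .retention import RetentionCurve

__all__ = [
    "ModelPair",
    "PairResult",
    "build_retention_curves",
    "build_pair",
    "run_pair",
    "apply_parameter",
    "SWEEPABLE_PARAMETERS",
]

ORIGINAL = "original"
INTERVENTION = "intervention"


@dataclass(frozen=True)
class ModelPair:
    """The two strategies' model specifications plus the WTP rule."""

    original: ModelSpec
    intervention: ModelSpec
    wtp: WTPThreshold
    cost_accrual: str = "retained_only"
    base_start_age: float = 30.0


@dataclass(frozen=True)
class PairResult:
    """Base-case outputs: per-arm totals and the incremental comparison."""

    strategies: dict[str, Strategy]
    results: list[CEAResult]

    @property
    def incremental_cost(self) -> float:
        return (
            self.strategies[INTERVENTION].cost - self.strategies[ORIGINAL].cost
        )

    @property
    def incremental_effectiveness(self) -> float:
        return (
            self.strategies[INTERVENTION].effectiveness
            - self.strategies[ORIGINAL].effectiveness
        )

    @property
    def icer(self) -> float | None:
        d_eff = self.incremental_effectiveness
        if d_eff == 0:
            return None
        return self.incremental_cost / d_eff


def build_retention_curves(
    config: AnalysisConfig,
) -> dict[str, RetentionCurve]:
    r = config.retention
    return {
        ORIGINAL: RetentionCurve(
            ORIGINAL, tuple(map(tuple, r.original_anchors)), r.interpolation
        ),
        INTERVENTION: RetentionCurve(
            INTERVENTION, tuple(map(tuple, r.intervention_anchors)), r.interpolation
        ),
    }


def _arm_costs(config: AnalysisConfig) -> dict[str, float]:
    table = (
        load_cost_table(config.costing.cost_table)
        if config.costing.cost_table
        else None
    )
    return strategy_annual_costs(
        CurrencySpec(config.costing.zmk_per_usd),
        n_rural_centres=config.costing.n_rural_centres,
        table=table,
    )


def build_pair(config: AnalysisConfig | None = None) -> ModelPair:
    """Construct both arms' model specifications from a configuration."""
    from .config import default_config

    config = config or default_config()
    curves = build_retention_curves(config)
    costs = _arm_costs(config)
    m = config.model
    discount = DiscountSpec(m.discount_rate, m.half_cycle_correction)
    specs = {}
    for name in (ORIGINAL, INTERVENTION):
        annual = costs[name]
        arm = ArmSpec(
            name=name,
            retention=curves[name],
            mortality_retained=m.mortality_retained,
            mortality_not_retained=m.mortality_not_retained,
            utility_retained=m.utility_retained,
            utility_not_retained=m.utility_not_retained,
            annual_cost_retained=annual,
            annual_cost_not_retained=(
                annual if m.cost_accrual == "all_alive" else 0.0
            ),
        )
        specs[name] = ModelSpec(
            arm=arm,
            horizon=m.horizon,
            start_age=m.start_age,
            discount=discount,
            event_ordering=m.event_ordering,
        )
    return ModelPair(
        original=specs[ORIGINAL],
        intervention=specs[INTERVENTION],
        wtp=WTPThreshold(config.cea.gdp_per_capita, config.cea.wtp_multiplier),
        cost_accrual=m.cost_accrual,
        base_start_age=m.start_age,
    )


def run_pair(pair: ModelPair) -> PairResult:
    """Run both arms and compare them incrementally."""
    strategies = {}
    for name, spec in ((ORIGINAL, pair.original), (INTERVENTION, pair.intervention)):
        _, rewards = run_arm(spec)
        strategies[name] = Strategy(name, rewards.cost, rewards.qalys)
    results = incremental_analysis(list(strategies.values()), pair.wtp)
    return PairResult(strategies=strategies, results=results)


def _extend_curve(curve: RetentionCurve, horizon: float) -> RetentionCurve:
    """Hold retention flat beyond the last anchor (long-term plateau)."""
    if curve.horizon >= horizon:
        return curve
    anchors = curve.anchors + ((float(horizon), curve.anchors[-1][1]),)
    return replace(curve, anchors=anchors)


def _with_arm_field(spec: ModelSpec, **kwargs) -> ModelSpec:
    return spec.with_arm(replace(spec.arm, **kwargs))


def _set_cost(spec: ModelSpec, value: float, cost_accrual: str) -> ModelSpec:
    return _with_arm_field(
        spec,
        annual_cost_retained=value,
        annual_cost_not_retained=value if cost_accrual == "all_alive" else 0.0,
    )


#: Parameter names accepted by `apply_parameter` (the tornado axes).
SWEEPABLE_PARAMETERS = (
    "mortality_retained",
    "mortality_not_retained",
    "utility_retained",
    "utility_not_retained",
    "discount_rate",
    "start_age",
    "cost_original",
    "cost_intervention",
)


def apply_parameter(pair: ModelPair, name: str, value: float) -> ModelPair:
    """Return a copy of the pair with one named input set to ``value``.

    Shared clinical parameters (mortalities, utilities, discount rate)
    change in both arms; per-arm costs change only their own arm.
    ``start_age`` shifts the time horizon one cycle per year of age
    (younger patients are modelled longer), holding retention flat past
    its last anchor when the horizon extends beyond it.
    """
    if name in ("mortality_retained", "mortality_not_retained",
                "utility_retained", "utility_not_retained"):
        return replace(
            pair,
            original=_with_arm_field(pair.original, **{name: value}),
            intervention=_with_arm_field(pair.intervention, **{name: value}),
        )
    if name == "discount_rate":
        def upd(spec: ModelSpec) -> ModelSpec:
            return replace(spec, discount=replace(spec.discount, rate=value))
        return replace(pair, original=upd(pair.original), intervention=upd(pair.intervention))
    if name == "start_age":
        shift = int(round(pair.base_start_age - value))
        def upd(spec: ModelSpec) -> ModelSpec:
            horizon = max(1, spec.horizon + shift)
            arm = replace(
                spec.arm, retention=_extend_curve(spec.arm.retention, horizon)
            )
            return replace(spec, arm=arm, horizon=horizon, start_age=value)
        return replace(pair, original=upd(pair.original), intervention=upd(pair.intervention))
    if name == "cost_original":
        return replace(
            pair, original=_set_cost(pair.original, value, pair.cost_accrual)
        )
    if name == "cost_intervention":
        return replace(
            pair,
            intervention=_set_cost(pair.intervention, value, pair.cost_accrual),
        )
    raise KeyError(
        f"unknown parameter {name!r}; expected one of {SWEEPABLE_PARAMETERS}"
    )


def base_parameter_values(pair: ModelPair) -> dict[str, float]:
    """Current value of every sweepable parameter in a pair."""
    arm_o, arm_i = pair.original.arm, pair.intervention.arm
    return {
        "mortality_retained": arm_o.mortality_retained,
        "mortality_not_retained": arm_o.mortality_not_retained,
        "utility_retained": arm_o.utility_retained,
        "utility_not_retained": arm_o.utility_not_retained,
        "discount_rate": pair.original.discount.rate,
        "start_age": pair.original.start_age,
        "cost_original": arm_o.annual_cost_retained,
        "cost_intervention": arm_i.annual_cost_retained,
    }
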