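"""Sensitivity analyses around the two-strategy comparison.

* **One-way (tornado)**: each uncertain input is set to its low and high
  bound with all others at base; the swing in the ICER ranks inputs.
* **Threshold search**: bisection for the input value at which the
  decision flips (ICER crosses the willingness-to-pay, or the sign of
  the incremental net monetary benefit changes).
* **Retention scenarios**: both arms' anchored retention curves are
  replaced with constant "x% reduction per year" patterns (best case:
  10%/yr comparator vs 3%/yr intervention; worst case reversed).
* **Probabilistic sensitivity analysis (PSA)**: all uncertain parameters
  are drawn jointly per iteration — beta distributions for probabilities
  and utilities, gamma for costs, hyperparameters matched by the method
  of moments treating the one-way range as a central 95% interval — and
  the model re-run; the cost-effectiveness acceptability curve (CEAC)
  reports, per willingness-to-pay value, the fraction of iterations in
  which each strategy has the higher net monetary benefit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cea import net_monetary_benefit
from .pipeline import (
    INTERVENTION,
    ORIGINAL,
    ModelPair,
    PairResult,
    apply_parameter,
    base_parameter_values,
    run_pair,
)
from .retention import geometric_retention_curve

__all__ = [
    "ParamRange",
    "TornadoEntry",
    "ParamDistribution",
    "PSADistributionSet",
    "one_way_sensitivity",
    "threshold_search",
    "scenario_retention",
    "default_psa_distributions",
    "run_psa",
    "ceac",
    "ceac_indifference_point",
]


@dataclass(frozen=True)
class ParamRange:
    """One-way sensitivity range for a named model input."""

    name: str
    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.name}: require low <= base <= high, "
                f"got {self.low}, {self.base}, {self.high}"
            )


@dataclass(frozen=True)
class TornadoEntry:
    """ICER at the low and high bound of one input; swing = |high - low|."""

    param: str
    icer_low: float | None
    icer_high: float | None

    @property
    def swing(self) -> float:
        if self.icer_low is None or self.icer_high is None:
            return math.nan
        return abs(self.icer_high - self.icer_low)


def _icer_at(pair: ModelPair, name: str, value: float) -> float | None:
    return run_pair(apply_parameter(pair, name, value)).icer


def one_way_sensitivity(
    pair: ModelPair, param_ranges: list[ParamRange]
) -> list[TornadoEntry]:
    """Re-run both arms at each range bound; sort by swing, largest first."""
    entries = [
        TornadoEntry(
            param=r.name,
            icer_low=_icer_at(pair, r.name, r.low),
            icer_high=_icer_at(pair, r.name, r.high),
        )
        for r in param_ranges
    ]
    return sorted(
        entries,
        key=lambda e: (math.isnan(e.swing), -(e.swing if not math.isnan(e.swing) else 0)),
    )


def _criterion_fn(pair: ModelPair, param: str, criterion: str, wtp: float):
    """Signed decision margin as a function of the parameter value."""

    def margin(value: float) -> float:
        result = run_pair(apply_parameter(pair, param, value))
        if criterion == "icer_crosses_wtp":
            icer = result.icer
            if icer is None:
                return math.nan
            return icer - wtp
        # decision_flip_at_wtp: incremental NMB of the intervention
        return net_monetary_benefit(
            result.strategies[INTERVENTION], wtp
        ) - net_monetary_benefit(result.strategies[ORIGINAL], wtp)

    return margin


def threshold_search(
    pair: ModelPair,
    param: str,
    low: float,
    high: float,
    criterion: str = "decision_flip_at_wtp",
    wtp: float | None = None,
    tol: float = 1e-4,
    monotonicity_grid: int = 9,
) -> float | None:
    """Parameter value at which the cost-effectiveness decision flips.

    Bisection of the signed decision margin over ``[low, high]`` to a
    tolerance of ``tol`` on the parameter scale.  Monotonicity of the
    margin is first checked on a coarse grid; a non-monotone response
    triggers a warning and a fallback grid scan for the first sign
    change.  Returns None when the margin never changes sign.
    """
    if criterion not in ("decision_flip_at_wtp", "icer_crosses_wtp"):
        raise ValueError(f"unknown criterion {criterion!r}")
    wtp = pair.wtp.value if wtp is None else wtp
    margin = _criterion_fn(pair, param, criterion, wtp)

    grid = np.linspace(low, high, monotonicity_grid)
    values = np.array([margin(v) for v in grid])
    finite = values[np.isfinite(values)]
    if len(finite) >= 2:
        diffs = np.diff(finite)
        monotone = np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9)
    else:
        monotone = True
    if not monotone:
        warnings.warn(
            f"decision margin not monotone in {param!r}; "
            "falling back to a grid scan for the first sign change",
            stacklevel=2,
        )
        grid = np.linspace(low, high, 201)
        values = np.array([margin(v) for v in grid])

    sign = np.sign(values)
    crossings = np.nonzero(
        np.isfinite(values[:-1]) & np.isfinite(values[1:]) & (sign[:-1] * sign[1:] < 0)
    )[0]
    exact = np.nonzero(np.isfinite(values) & (values == 0))[0]
    if len(exact):
        return float(grid[exact[0]])
    if not len(crossings):
        return None
    a, b = float(grid[crossings[0]]), float(grid[crossings[0] + 1])
    fa = margin(a)
    while b - a > tol:
        mid = 0.5 * (a + b)
        fm = margin(mid)
        if math.isnan(fm):
            return None
        if (fa < 0) == (fm < 0):
            a, fa = mid, fm
        else:
            b = mid
    return 0.5 * (a + b)


def scenario_retention(
    pair: ModelPair,
    original_reduction: float,
    intervention_reduction: float,
) -> PairResult:
    """Re-run the comparison under geometric annual retention losses."""
    def swap(spec, reduction: float):
        curve = geometric_retention_curve(
            spec.arm.name, reduction, horizon=spec.horizon
        )
        return spec.with_arm(replace(spec.arm, retention=curve))

    scenario_pair = replace(
        pair,
        original=swap(pair.original, original_reduction),
        intervention=swap(pair.intervention, intervention_reduction),
    )
    return run_pair(scenario_pair)


@dataclass(frozen=True)
class ParamDistribution:
    """Sampling distribution of one parameter for the PSA."""

    kind: str  # "beta" | "gamma" | "fixed"
    mean: float
    sd: float = 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "fixed" or self.sd == 0:
            return np.full(size, self.mean)
        if self.kind == "beta":
            m, v = self.mean, self.sd**2
            common = m * (1 - m) / v - 1.0
            if common <= 0:
                raise ValueError(
                    f"beta variance {v} too large for mean {m}"
                )
            return rng.beta(m * common, (1 - m) * common, size)
        if self.kind == "gamma":
            v = self.sd**2
            shape = self.mean**2 / v
            scale = v / self.mean
            return rng.gamma(shape, scale, size)
        raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass(frozen=True)
class PSADistributionSet:
    """Per-parameter distributions plus the iteration count and seed."""

    distributions: dict[str, ParamDistribution]
    n_iterations: int = 10_000
    seed: int = 20_110_412

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


#: Parameters sampled by default: the clinically uncertain probabilities
#: and utility plus both arms' costs.  Discount rate and reference age
#: are policy settings, varied deterministically, not sampled.
_PSA_PARAMS = {
    "mortality_retained": "beta",
    "mortality_not_retained": "beta",
    "utility_retained": "beta",
    "cost_original": "gamma",
    "cost_intervention": "gamma",
}


def default_psa_distributions(
    pair: ModelPair,
    ranges: dict[str, tuple[float, float]],
    n_iterations: int = 10_000,
    seed: int = 20_110_412,
) -> PSADistributionSet:
    """Method-of-moments distributions from the one-way ranges.

    Each parameter's mean is its base-case value; its standard deviation
    treats the one-way ``(low, high)`` range as a central 95% interval,
    ``sd = (high - low) / (2 x 1.96)``.
    """
    base = base_parameter_values(pair)
    dists = {}
    for name, kind in _PSA_PARAMS.items():
        if name not in ranges:
            continue
        low, high = ranges[name]
        dists[name] = ParamDistribution(
            kind=kind, mean=base[name], sd=(high - low) / (2 * 1.959963984540054)
        )
    return PSADistributionSet(dists, n_iterations, seed)


def run_psa(
    pair: ModelPair,
    dists: PSADistributionSet,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Joint Monte-Carlo re-runs of both arms.

    Returns one row per iteration with every sampled parameter value and
    each arm's discounted cost and QALYs.  Deterministic for a given
    seed (the seed lives in ``dists`` unless an explicit generator is
    passed).
    """
    rng = rng or np.random.default_rng(dists.seed)
    n = dists.n_iterations
    draws = {
        name: dist.sample(rng, n) for name, dist in dists.distributions.items()
    }
    rows = np.empty((n, 4))
    for i in range(n):
        it_pair = pair
        for name, values in draws.items():
            it_pair = apply_parameter(it_pair, name, float(values[i]))
        result = run_pair(it_pair)
        rows[i] = (
            result.strategies[ORIGINAL].cost,
            result.strategies[ORIGINAL].effectiveness,
            result.strategies[INTERVENTION].cost,
            result.strategies[INTERVENTION].effectiveness,
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "cost_original",
            "effect_original",
            "cost_intervention",
            "effect_intervention",
        ],
    )
    for name, values in draws.items():
        out[name] = values
    out.insert(0, "iteration", np.arange(n))
    return out


def ceac(psa_samples: pd.DataFrame, wtp_grid: np.ndarray) -> pd.DataFrame:
    """Acceptability curve: P(each arm has the higher NMB) per WTP value.

    Ties are split equally, so the two probabilities sum to one at every
    grid point.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if not len(psa_samples) or not len(wtp_grid):
        raise ValueError("need non-empty samples and WTP grid")
    co = psa_samples["cost_original"].to_numpy()
    eo = psa_samples["effect_original"].to_numpy()
    ci = psa_samples["cost_intervention"].to_numpy()
    ei = psa_samples["effect_intervention"].to_numpy()
    rows = []
    for wtp in wtp_grid:
        nmb_o = wtp * eo - co
        nmb_i = wtp * ei - ci
        p_int = np.mean(nmb_i > nmb_o) + 0.5 * np.mean(nmb_i == nmb_o)
        rows.append((wtp, 1.0 - p_int, p_int))
    return pd.DataFrame(
        rows, columns=["wtp", "prob_original_optimal", "prob_intervention_optimal"]
    )


def ceac_indifference_point(ceac_table: pd.DataFrame) -> float | None:
    """WTP at which the acceptability curves cross 0.5 (interpolated)."""
    wtp = ceac_table["wtp"].to_numpy()
    p = ceac_table["prob_intervention_optimal"].to_numpy()
    above = p >= 0.5
    if above.all() or not above.any():
        return None
    idx = int(np.argmax(above))
    if idx == 0:
        return float(wtp[0])
    w0, w1, p0, p1 = wtp[idx - 1], wtp[idx], p[idx - 1], p[idx]
    if p1 == p0:
        return float(w1)
    return float(w0 + (0.5 - p0) * (w1 - w0) / (p1 - p0))


def tornado_table(entries: list[TornadoEntry]) -> pd.DataFrame:
    """Tornado entries as a DataFrame (sorted as given)."""
    return pd.DataFrame(
        [(e.param, e.icer_low, e.icer_high, e.swing) for e in entries],
        columns=["param", "icer_low", "icer_high", "swing"],
    )
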