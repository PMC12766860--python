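"""Sensitivity analyses over the staging cost model's parameters.

Three standard decision-analytic exercises:

* one-way deterministic sweeps of a single parameter over a grid,
* break-even (threshold) analysis for a pair of strategies,
* probabilistic sensitivity analysis (PSA) propagating parameter
  uncertainty by Monte Carlo.

The model is re-parameterised by rates — ``prevalence``, ``sensitivity``,
``specificity`` — plus the three unit costs, so a perturbed parameter set
always defines a coherent joint distribution over the decision tree's
branches.  Probability parameters default to Beta(successes + 1,
failures + 1) posteriors from the observed 2x2 counts; costs default to
Gamma distributions parameterised by mean and coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import bisect

from .cost_model import STRATEGY_IDS, strategy_expected_costs
from .domain_types import CohortCounts, CostInputs

__all__ = [
    "PROBABILITY_PARAMS",
    "COST_PARAMS",
    "ModelParams",
    "ParamDistribution",
    "default_distributions",
    "NoBreakEvenError",
    "one_way_sweep",
    "break_even",
    "PSAResult",
    "psa",
]

PROBABILITY_PARAMS = ("prevalence", "sensitivity", "specificity")
COST_PARAMS = ("c_pet", "c_lap", "c_gast")


@dataclass(frozen=True)
class ModelParams:
    """Rate-parameterised inputs of the cost model."""

    prevalence: float
    sensitivity: float
    specificity: float
    c_pet: float
    c_lap: float
    c_gast: float

    def __post_init__(self) -> None:
        for name in PROBABILITY_PARAMS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in COST_PARAMS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_observed(cls, counts: CohortCounts, costs: CostInputs) -> "ModelParams":
        """Base case: observed cohort frequencies plus given unit costs."""
        return cls(
            prevalence=counts.ref_pos / counts.n,
            sensitivity=counts.tp / counts.ref_pos,
            specificity=counts.tn / counts.ref_neg,
            c_pet=costs.c_pet,
            c_lap=costs.c_lap,
            c_gast=costs.c_gast,
        )

    def costs(self) -> Dict[str, float]:
        """Deterministic expected cost per strategy at these parameters."""
        return strategy_expected_costs(
            self.prevalence,
            self.sensitivity,
            self.specificity,
            self.c_pet,
            self.c_lap,
            self.c_gast,
        )


def _check_domain(param: str, values: Iterable[float]) -> None:
    if param in PROBABILITY_PARAMS:
        bad = [v for v in values if not 0.0 <= v <= 1.0]
        if bad:
            raise ValueError(f"{param} values outside [0, 1]: {bad[:3]}")
    elif param in COST_PARAMS:
        bad = [v for v in values if v < 0]
        if bad:
            raise ValueError(f"{param} values must be >= 0: {bad[:3]}")
    else:
        raise ValueError(f"unknown parameter {param!r}")


def one_way_sweep(
    params: ModelParams, param: str, grid: Sequence[float]
) -> pd.DataFrame:
    """Deterministic one-way sweep of *param* over *grid*.

    The model is rebuilt from scratch at each grid value (all other
    parameters held at *params*).  Returns a DataFrame with one row per grid
    value: the swept value, the four strategy costs, and all six pairwise
    differences (``S1_minus_S2`` etc.).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty sweep grid")
    _check_domain(param, grid)
    rows = []
    for v in grid:
        c = replace(params, **{param: float(v)}).costs()
        row = {param: float(v)}
        row.update({s: c[s] for s in STRATEGY_IDS})
        for i, a in enumerate(STRATEGY_IDS):
            for b in STRATEGY_IDS[i + 1 :]:
                row[f"{a}_minus_{b}"] = c[a] - c[b]
        rows.append(row)
    return pd.DataFrame(rows)


class NoBreakEvenError(ValueError):
    """The strategy-pair cost difference does not change sign on the domain."""


def break_even(
    params: ModelParams,
    param: str,
    strategy_pair: Tuple[str, str],
    domain: Tuple[float, float] = None,
    tol: float = 1e-6,
) -> float:
    """Parameter value at which two strategies cost the same.

    Finds a root of ``cost(a) - cost(b)`` in *param* by bisection on a
    bracketing interval.  The default domain is (0, 1) for probability
    parameters and (0, 10 x the base value) for costs.  The returned value
    satisfies ``|cost(a) - cost(b)| < 0.01`` when re-evaluated.

    Raises
    ------
    NoBreakEvenError
        If the difference has the same sign at both domain endpoints
        ("no break-even in domain").
    """
    a, b = strategy_pair
    for s in (a, b):
        if s not in STRATEGY_IDS:
            raise ValueError(f"unknown strategy {s!r}")
    if domain is None:
        if param in PROBABILITY_PARAMS:
            domain = (1e-9, 1.0 - 1e-9)
        else:
            base = getattr(params, param)
            domain = (0.0, 10.0 * base if base > 0 else 1e5)
    _check_domain(param, domain)

    def diff(v: float) -> float:
        c = replace(params, **{param: float(v)}).costs()
        return c[a] - c[b]

    lo, hi = domain
    d_lo, d_hi = diff(lo), diff(hi)
    if d_lo == 0.0 and d_hi == 0.0:
        # identically equal strategies: no crossing to report
        raise NoBreakEvenError(
            f"no break-even in domain [{lo}, {hi}]: {a} and {b} cost the same everywhere"
        )
    if d_lo == 0.0:
        return float(lo)
    if d_hi == 0.0:
        return float(hi)
    if np.sign(d_lo) == np.sign(d_hi):
        raise NoBreakEvenError(
            f"no break-even in domain [{lo}, {hi}] for {a} vs {b} over {param}"
        )
    root = bisect(diff, lo, hi, xtol=tol)
    if abs(diff(root)) >= 0.01:
        raise NoBreakEvenError(
            f"bisection converged to {root} but |cost difference| >= $0.01"
        )
    return float(root)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamDistribution:
    """Uncertainty distribution of one model parameter.

    family
        ``"beta"`` (probability parameters only; parameters ``alpha``,
        ``beta``), ``"gamma"`` (cost parameters only; parameters ``mean``,
        ``cv``), or ``"point"`` (any parameter; parameter ``value``).
    """

    name: str
    family: str
    parameters: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.name not in PROBABILITY_PARAMS + COST_PARAMS:
            raise ValueError(f"unknown parameter {self.name!r}")
        if self.family == "beta":
            if self.name not in PROBABILITY_PARAMS:
                raise ValueError(f"beta distribution restricted to probabilities, not {self.name!r}")
            a, b = self.parameters["alpha"], self.parameters["beta"]
            if a <= 0 or b <= 0:
                raise ValueError(f"beta shapes must be positive, got ({a}, {b})")
        elif self.family == "gamma":
            if self.name not in COST_PARAMS:
                raise ValueError(f"gamma distribution restricted to costs, not {self.name!r}")
            m, cv = self.parameters["mean"], self.parameters["cv"]
            if m <= 0 or cv <= 0:
                raise ValueError(f"gamma mean and cv must be positive, got ({m}, {cv})")
        elif self.family == "point":
            if "value" not in self.parameters:
                raise ValueError("point distribution needs a 'value' parameter")
        else:
            raise ValueError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "point":
            return np.full(size, float(self.parameters["value"]))
        if self.family == "beta":
            return rng.beta(self.parameters["alpha"], self.parameters["beta"], size)
        # gamma by mean/cv: shape = 1/cv^2, scale = mean * cv^2
        m, cv = self.parameters["mean"], self.parameters["cv"]
        return rng.gamma(1.0 / cv**2, m * cv**2, size)


def default_distributions(
    counts: CohortCounts, costs: CostInputs, cost_cv: float = 0.10
) -> Dict[str, ParamDistribution]:
    """Conventional defaults: Beta(k+1, n-k+1) posteriors for the observed
    probabilities, Gamma(mean = unit cost, cv = *cost_cv*) for costs."""
    beta = lambda name, k, n: ParamDistribution(
        name, "beta", {"alpha": k + 1.0, "beta": n - k + 1.0}
    )
    gamma = lambda name, mean: ParamDistribution(name, "gamma", {"mean": mean, "cv": cost_cv})
    return {
        "prevalence": beta("prevalence", counts.ref_pos, counts.n),
        "sensitivity": beta("sensitivity", counts.tp, counts.ref_pos),
        "specificity": beta("specificity", counts.tn, counts.ref_neg),
        "c_pet": gamma("c_pet", costs.c_pet),
        "c_lap": gamma("c_lap", costs.c_lap),
        "c_gast": gamma("c_gast", costs.c_gast),
    }


@dataclass(frozen=True)
class PSAResult:
    """Monte-Carlo summary of the probabilistic sensitivity analysis.

    ``cost_draws`` (strategy id -> per-draw expected-cost array) is kept only
    when the analysis is run with ``keep_draws=True``; it is excluded from
    :meth:`to_dict`.
    """

    n_draws: int
    seed: int
    mean_cost: Dict[str, float]
    diff_quantiles: Dict[str, Dict[str, float]]
    prob_cheapest: Dict[str, float]
    cost_draws: Union[Dict[str, np.ndarray], None] = None

    def to_dict(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "mean_cost": self.mean_cost,
            "diff_quantiles": self.diff_quantiles,
            "prob_cheapest": self.prob_cheapest,
        }


def psa(
    params: ModelParams,
    distributions: Mapping[str, ParamDistribution],
    n_draws: int,
    seed: int,
    keep_draws: bool = False,
) -> PSAResult:
    """Probabilistic sensitivity analysis of the four-strategy cost model.

    Each draw samples every parameter independently from its distribution
    (parameters without a distribution stay at their *params* value) and
    evaluates the closed-form strategy costs.  Reproducible bit-for-bit for
    a given (seed, n_draws, distribution set).

    Returns mean cost per strategy, 2.5/50/97.5% quantiles of each pairwise
    cost difference, and the probability that each strategy is the cheapest
    (ties broken in favour of the earlier strategy id, S1 < S2 < S3 < S4).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws: Dict[str, np.ndarray] = {}
    # fixed iteration order so the draw stream is reproducible
    for name in PROBABILITY_PARAMS + COST_PARAMS:
        if name in distributions:
            dist = distributions[name]
            if dist.name != name:
                raise ValueError(f"distribution for {dist.name!r} keyed as {name!r}")
            draws[name] = dist.sample(rng, n_draws)
        else:
            draws[name] = np.full(n_draws, getattr(params, name))

    cost = strategy_expected_costs(
        draws["prevalence"],
        draws["sensitivity"],
        draws["specificity"],
        draws["c_pet"],
        draws["c_lap"],
        draws["c_gast"],
    )
    matrix = np.vstack([cost[s] for s in STRATEGY_IDS])
    cheapest = matrix.argmin(axis=0)  # argmin takes the first minimum: ties -> lower id
    mean_cost = {s: float(matrix[i].mean()) for i, s in enumerate(STRATEGY_IDS)}
    prob_cheapest = {
        s: float((cheapest == i).mean()) for i, s in enumerate(STRATEGY_IDS)
    }
    qs = (0.025, 0.5, 0.975)
    diff_quantiles: Dict[str, Dict[str, float]] = {}
    for i, a in enumerate(STRATEGY_IDS):
        for b in STRATEGY_IDS[i + 1 :]:
            d = matrix[i] - matrix[STRATEGY_IDS.index(b)]
            diff_quantiles[f"{a}_minus_{b}"] = {
                f"q{int(q * 1000) / 10}": float(np.quantile(d, q)) for q in qs
            }
    return PSAResult(
        n_draws=n_draws,
        seed=seed,
        mean_cost=mean_cost,
        diff_quantiles=diff_quantiles,
        prob_cheapest=prob_cheapest,
        cost_draws={s: matrix[i] for i, s in enumerate(STRATEGY_IDS)} if keep_draws else None,
    )
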