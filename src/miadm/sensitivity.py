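"""Probabilistic, one-way (tornado + threshold) and two-way sensitivity analyses.

All analyses ride on the vectorised Markov engine: a probabilistic
sensitivity analysis (PSA) draws every distributed parameter jointly per
iteration and evaluates all six strategies on the same draw; one-way sweeps
and two-way grids move one or two parameters over their published ranges
with everything else held at the point estimates; threshold search bisects
a one-way sweep for the value at which the identity of the optimal strategy
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .life_table import MortalityTable
from .markov_engine import evaluate_batch
from .parameters import ParameterSet
from .strategies import STRATEGY_ORDER

__all__ = [
    "PSAResult",
    "TornadoEntry",
    "ThresholdResult",
    "TwoWayMap",
    "run_psa",
    "optimal_frequencies",
    "pairwise_preference",
    "psa_stability",
    "one_way_sweep",
    "tornado",
    "threshold_search",
    "two_way_grid",
]


def _argmax_fixed_order(ev: np.ndarray, axis: int = 0) -> np.ndarray:
    """Argmax over strategies; np.argmax's first-hit tie-break matches the
    fixed strategy order because rows are laid out in that order."""
    return np.argmax(ev, axis=axis)


@dataclass(frozen=True)
class PSAResult:
    """Joint parameter draws and the six strategies' QALYs per iteration."""

    seed: int
    strategies: tuple[str, ...]
    evs: np.ndarray  # (n_strategies, n_iterations)
    samples: pd.DataFrame  # one column per sampled parameter
    n_renormalized: int  # draws whose branch risks summed above 1

    @property
    def n_iterations(self) -> int:
        return self.evs.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.evs.T, columns=[f"ev_{s}" for s in self.strategies])
        df.insert(0, "iteration", np.arange(self.n_iterations))
        df["optimal"] = [self.strategies[i] for i in _argmax_fixed_order(self.evs)]
        return df


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    ev_at_low: float
    ev_at_high: float
    spread: float
    optimal_switches: bool


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    threshold: float | None
    strategy_below: str
    strategy_above: str
    tolerance: float
    multiple_switches: bool = False


@dataclass(frozen=True)
class TwoWayMap:
    parameter_x: str
    parameter_y: str
    x_values: np.ndarray
    y_values: np.ndarray
    optimal: np.ndarray  # (len(x), len(y)) of strategy ids
    strategies: tuple[str, ...] = field(default=STRATEGY_ORDER)

    def to_frame(self) -> pd.DataFrame:
        xs, ys = np.meshgrid(self.x_values, self.y_values, indexing="ij")
        return pd.DataFrame(
            {
                self.parameter_x: xs.ravel(),
                self.parameter_y: ys.ravel(),
                "optimal_strategy": self.optimal.ravel(),
            }
        )


def run_psa(
    params: ParameterSet,
    table: MortalityTable,
    n_iterations: int = 10_000,
    seed: int = 0,
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Every distributed parameter is drawn once per iteration from its
    uncertainty distribution and all strategies are evaluated on the same
    joint draw.  Draws making a treatment branch's risks sum above 1 are
    renormalised inside the engine; their count is reported.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    values = params.sample_values(rng, size=n_iterations)
    n_renorm = 0
    for suffix in ("one", "two", "sah"):
        total = (
            np.clip(values[f"mortality_after_{suffix}"], 0, 1)
            + np.clip(values[f"modsev_after_{suffix}"], 0, 1)
            + np.clip(values[f"mild_after_{suffix}"], 0, 1)
        )
        n_renorm += int(np.count_nonzero(total > 1.0))
    evs = np.stack(
        [evaluate_batch(s, values, table, params.settings) for s in STRATEGY_ORDER]
    )
    samples = pd.DataFrame({k: np.broadcast_to(v, (n_iterations,)) for k, v in values.items()})
    return PSAResult(
        seed=seed,
        strategies=STRATEGY_ORDER,
        evs=evs,
        samples=samples,
        n_renormalized=n_renorm,
    )


def optimal_frequencies(psa: PSAResult) -> dict[str, float]:
    """Percentage of iterations in which each strategy attains the top EV."""
    best = _argmax_fixed_order(psa.evs)
    counts = np.bincount(best, minlength=len(psa.strategies))
    return {
        s: 100.0 * c / psa.n_iterations for s, c in zip(psa.strategies, counts)
    }


def pairwise_preference(psa: PSAResult, a: str = "treat_two", b: str = "treat_one") -> float:
    """Percentage of iterations in which strategy ``a`` out-performs ``b``."""
    ia, ib = psa.strategies.index(a), psa.strategies.index(b)
    return 100.0 * float(np.mean(psa.evs[ia] > psa.evs[ib]))


def psa_stability(
    params: ParameterSet,
    table: MortalityTable,
    n_iterations: int = 10_000,
    n_repeats: int = 10,
    seeds: list[int] | None = None,
) -> pd.DataFrame:
    """Repeat the PSA under different seeds to check Monte Carlo stability.

    Returns one row per repeat with the optimal-strategy frequencies and the
    pairwise treat-two vs treat-one preference; repeats should scatter
    within binomial error around a common value.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    rows = []
    for seed in seeds:
        psa = run_psa(params, table, n_iterations=n_iterations, seed=seed)
        row = {"seed": seed, **optimal_frequencies(psa)}
        row["treat_two_vs_treat_one"] = pairwise_preference(psa)
        rows.append(row)
    return pd.DataFrame(rows)


def one_way_sweep(
    parameter: str,
    params: ParameterSet,
    table: MortalityTable,
    n_points: int = 101,
) -> pd.DataFrame:
    """Per-strategy EV over one parameter's published range, others at means."""
    spec = params.spec(parameter)
    if spec.low == spec.high:
        raise ValueError(f"{parameter} has a degenerate range; nothing to sweep")
    xs = np.linspace(spec.low, spec.high, n_points)
    values = dict(params.base_values())
    values[parameter] = xs
    evs = np.stack(
        [evaluate_batch(s, values, table, params.settings) for s in STRATEGY_ORDER]
    )
    df = pd.DataFrame(evs.T, columns=list(STRATEGY_ORDER))
    df.insert(0, parameter, xs)
    df["optimal_strategy"] = [STRATEGY_ORDER[i] for i in _argmax_fixed_order(evs)]
    return df


def tornado(
    params: ParameterSet,
    table: MortalityTable,
    parameters: list[str] | None = None,
    n_points: int = 41,
) -> list[TornadoEntry]:
    """One-way effect of every parameter on the best-strategy EV.

    For each parameter the maximal EV across strategies is recorded at the
    range endpoints; ``optimal_switches`` flags parameters whose variation
    changes the identity of the optimal strategy anywhere along the sweep.
    Entries come back sorted by spread, largest first.
    """
    if parameters is None:
        parameters = [
            n for n, s in params.all_specs.items() if s.high > s.low
        ]
    entries = []
    for name in parameters:
        df = one_way_sweep(name, params, table, n_points=n_points)
        evs = df[list(STRATEGY_ORDER)].to_numpy()
        best = evs.max(axis=1)
        switches = df["optimal_strategy"].nunique() > 1
        entries.append(
            TornadoEntry(
                parameter=name,
                ev_at_low=float(best[0]),
                ev_at_high=float(best[-1]),
                spread=float(abs(best[-1] - best[0])),
                optimal_switches=bool(switches),
            )
        )
    return sorted(entries, key=lambda e: -e.spread)


def _optimal_at(x: float, parameter: str, params, table) -> int:
    values = dict(params.base_values())
    values[parameter] = x
    ev = np.array(
        [float(evaluate_batch(s, values, table, params.settings)[0]) for s in STRATEGY_ORDER]
    )
    return int(np.argmax(ev))


def bisect_switch(
    optimal_fn,
    lo: float,
    hi: float,
    tolerance: float = 1e-4,
    n_scan: int = 64,
):
    """Locate where ``optimal_fn(x)`` (an integer label) first changes on [lo, hi].

    A coarse scan brackets every label change; the first bracket from the
    low end is refined by bisection until narrower than ``tolerance``.
    Returns ``(threshold, label_below, label_above, n_switches)``; the
    threshold is None when the label is constant over the interval.
    """
    xs = np.linspace(lo, hi, n_scan)
    labels = [optimal_fn(float(x)) for x in xs]
    brackets = [i for i in range(n_scan - 1) if labels[i] != labels[i + 1]]
    if not brackets:
        return None, labels[0], labels[0], 0
    i = brackets[0]
    a, b = float(xs[i]), float(xs[i + 1])
    lab_a, lab_b = labels[i], labels[i + 1]
    while b - a > tolerance:
        mid = 0.5 * (a + b)
        lab = optimal_fn(mid)
        if lab == lab_a:
            a = mid
        else:
            b, lab_b = mid, lab
    return 0.5 * (a + b), lab_a, lab_b, len(brackets)


def threshold_search(
    parameter: str,
    params: ParameterSet,
    table: MortalityTable,
    tolerance: float = 1e-4,
    n_scan: int = 64,
) -> ThresholdResult:
    """Bisect for the parameter value at which the optimal strategy switches.

    All other parameters are held at their means.  If the optimal strategy
    never changes across the published range, ``threshold`` is None; if it
    changes more than once, the first switch from the low end is returned
    and flagged.
    """
    spec = params.spec(parameter)
    lo, hi = spec.low, spec.high
    if hi <= lo:
        raise ValueError(f"{parameter} has a degenerate range")
    threshold, lab_a, lab_b, n_switches = bisect_switch(
        lambda x: _optimal_at(x, parameter, params, table),
        lo,
        hi,
        tolerance=tolerance,
        n_scan=n_scan,
    )
    if threshold is None:
        sid = STRATEGY_ORDER[lab_a]
        return ThresholdResult(parameter, None, sid, sid, tolerance)
    return ThresholdResult(
        parameter=parameter,
        threshold=float(threshold),
        strategy_below=STRATEGY_ORDER[lab_a],
        strategy_above=STRATEGY_ORDER[lab_b],
        tolerance=tolerance,
        multiple_switches=n_switches > 1,
    )


def two_way_grid(
    parameter_x: str,
    parameter_y: str,
    params: ParameterSet,
    table: MortalityTable,
    grid_size: int = 41,
) -> TwoWayMap:
    """Optimal strategy over the Cartesian product of two parameter ranges."""
    if parameter_x == parameter_y:
        raise ValueError("two-way analysis needs two distinct parameters")
    sx, sy = params.spec(parameter_x), params.spec(parameter_y)
    if grid_size == 1:  # degenerate grid: the base-case point itself
        xs, ys = np.array([sx.mean]), np.array([sy.mean])
    else:
        xs = np.linspace(sx.low, sx.high, grid_size)
        ys = np.linspace(sy.low, sy.high, grid_size)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    values = dict(params.base_values())
    values[parameter_x] = gx.ravel()
    values[parameter_y] = gy.ravel()
    evs = np.stack(
        [evaluate_batch(s, values, table, params.settings) for s in STRATEGY_ORDER]
    )
    best = _argmax_fixed_order(evs).reshape(grid_size, grid_size)
    optimal = np.array(STRATEGY_ORDER, dtype=object)[best]
    return TwoWayMap(
        parameter_x=parameter_x,
        parameter_y=parameter_y,
        x_values=xs,
        y_values=ys,
        optimal=optimal,
    )
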