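"""Nine-state annual-cycle Markov cohort engine.

The cohort starts at age 57 with two small unruptured intracranial
aneurysms and is followed in one-year cycles until age 99.  States:

* WELL_MIA             — both aneurysms present, neither growing
* WELL_GROWING_MIA     — an untreated aneurysm has grown (rupture-prone)
* WELL_SINGLE_GROWING  — one aneurysm treated, the untreated one growing
* WELL_ONE_TREATED     — one treated, the other present and non-growing
* WELL_BOTH_TREATED    — both aneurysms secured
* SAH                  — subarachnoid hemorrhage, a one-cycle transient
                         state: the bleed is coiled and resolves to death,
                         permanent disability or full recovery within the
                         cycle's transition
* MILD_DISABILITY      — permanent, mRS 2
* MOD_SEVERE_DISABILITY— permanent, mRS 3-5
* DEATH                — absorbing

Within a cycle, competing events are composed sequentially in a fixed
order: background death, then rupture, then growth (or its detection at a
screening visit), then de novo aneurysm formation.  Risk ratios multiply
annual probabilities (capped at 1) unless the hazard-transform toggle is
set.  Effectiveness is the discounted sum of state utilities, with a
temporary fractional disutility in any cycle entered through a coiling
procedure.

The internal engine is vectorised: every clinical value may be a scalar or
an equal-length 1-D array, in which case a whole batch of parameter sets
(PSA iterations, sweep grids) is propagated through the cohort at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .life_table import MortalityTable, cause_deleted_adjustment
from .parameters import ModelSettings, ParameterSet
from .strategies import STRATEGY_ORDER, StrategySpec, get_strategy, screening_due

__all__ = [
    "HealthState",
    "TransitionRow",
    "CohortTrace",
    "StrategyEV",
    "transition_row",
    "treatment_outcome_branch",
    "run_cohort",
    "discounted_qalys",
    "evaluate_strategies",
    "evaluate_batch",
    "rank_strategies",
]


class HealthState(IntEnum):
    WELL_MIA = 0
    WELL_GROWING_MIA = 1
    WELL_SINGLE_GROWING = 2
    WELL_ONE_TREATED = 3
    WELL_BOTH_TREATED = 4
    SAH = 5
    MILD_DISABILITY = 6
    MOD_SEVERE_DISABILITY = 7
    DEATH = 8


N_STATES = len(HealthState)

_ROW_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TransitionRow:
    """One origin state's single-cycle transition distribution."""

    origin: HealthState
    probabilities: dict[HealthState, float]
    coil_flags: dict[HealthState, float]  # share of each arc carrying a coiling procedure

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"transition row from {self.origin.name} sums to {total}")


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy for one strategy.

    ``occupancy[t, s]`` is the cohort share in state ``s`` at cycle ``t``
    (age = start_age + t); ``coil_arrivals[t, s]`` is the share of that
    occupancy that entered via a coiling procedure during the preceding
    transition (and therefore incurs the temporary procedure disutility).
    """

    strategy: str
    occupancy: np.ndarray
    coil_arrivals: np.ndarray
    start_age: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in HealthState])
        df.insert(0, "age", self.start_age + np.arange(len(df)))
        df.insert(0, "cycle", np.arange(len(df)))
        return df


@dataclass(frozen=True)
class StrategyEV:
    """Discounted quality-adjusted life-years for one strategy."""

    strategy: str
    qalys: float


def _apply_rr(p, rr, hazard_transform: bool):
    """Scale an annual probability by a risk ratio."""
    p = np.asarray(p, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if hazard_transform:
        return 1.0 - (1.0 - np.clip(p, 0.0, 1.0)) ** rr
    return np.clip(p * rr, 0.0, 1.0)


def _clamp01(x):
    return np.clip(np.asarray(x, dtype=float), 0.0, 1.0)


def _branch(values: dict, suffix: str):
    """Outcome split (death, modsev, mild, full_recovery) of a coiling branch.

    Component probabilities are clamped to [0, 1]; if the three risks sum
    above 1 (possible for extreme sampled draws) they are renormalised and
    full recovery is 0.
    """
    d = _clamp01(values[f"mortality_after_{suffix}"])
    ms = _clamp01(values[f"modsev_after_{suffix}"])
    mi = _clamp01(values[f"mild_after_{suffix}"])
    total = d + ms + mi
    scale = np.where(total > 1.0, 1.0 / np.where(total > 0, total, 1.0), 1.0)
    d, ms, mi = d * scale, ms * scale, mi * scale
    fr = 1.0 - (d + ms + mi)
    return d, ms, mi, np.clip(fr, 0.0, 1.0)


def treatment_outcome_branch(kind: str, params) -> dict[str, float]:
    """Outcome distribution of a coiling procedure.

    ``kind`` is ``treat_one``, ``treat_two`` or ``sah_coiling``; ``params``
    may be a :class:`ParameterSet` or a plain value mapping.
    """
    suffix = {"treat_one": "one", "treat_two": "two", "sah_coiling": "sah"}.get(kind)
    if suffix is None:
        raise ValueError(f"unknown branch kind {kind!r}")
    values = params.base_values() if isinstance(params, ParameterSet) else params
    raw = sum(
        float(values[f"{k}_after_{suffix}"])
        for k in ("mortality", "modsev", "mild")
    )
    if raw > 1.0 + 1e-12:
        raise ValueError(f"branch {kind}: component probabilities sum above 1")
    d, ms, mi, fr = _branch(values, suffix)
    return {
        "death": float(d) if np.ndim(d) == 0 else d,
        "moderate_severe": float(ms) if np.ndim(ms) == 0 else ms,
        "mild": float(mi) if np.ndim(mi) == 0 else mi,
        "full_recovery": float(fr) if np.ndim(fr) == 0 else fr,
    }


def _batch_size(values: dict) -> int:
    n = 1
    for v in values.values():
        v = np.asarray(v)
        if v.ndim == 1:
            if n != 1 and v.shape[0] != n:
                raise ValueError("inconsistent batch sizes in parameter values")
            n = max(n, v.shape[0])
    return n


def _transition_matrix(
    spec: StrategySpec,
    next_cycle: int,
    q,
    values: dict,
    settings: ModelSettings,
    n: int,
):
    """Build (n, 9, 9) transition probabilities P and coil-arc flags F.

    ``q`` is the cause-deleted background death probability at the current
    age; ``next_cycle`` is the index of the cycle being entered (screening
    visits are checked against it).
    """
    S = HealthState
    P = np.zeros((n, N_STATES, N_STATES))
    F = np.zeros((n, N_STATES, N_STATES))
    ht = settings.hazard_transform

    q = np.broadcast_to(np.asarray(q, dtype=float), (n,))
    live = 1.0 - q

    p_rupt_mia = _apply_rr(values["rupture_rate_nongrowing"], values["rr_rupture_mia"], ht)
    p_grow_mia = _apply_rr(values["growth_rate_small"], values["rr_growth_mia"], ht)
    p_rupt_grow = _clamp01(values["rupture_rate_growing"])
    if settings.rr_on_growing:
        p_rupt_grow = _apply_rr(p_rupt_grow, values["rr_rupture_mia"], ht)
    p_rupt_single = _clamp01(values["rupture_rate_nongrowing"])
    p_grow_single = _clamp01(values["growth_rate_small"])
    p_denovo = _apply_rr(values["de_novo_rate"], values["rr_de_novo_mia"], ht)

    d1, ms1, mi1, fr1 = _branch(values, "one")
    ds, mss, mis, frs = _branch(values, "sah")

    # WELL_MIA: death -> rupture -> growth
    P[:, S.WELL_MIA, S.DEATH] = q
    P[:, S.WELL_MIA, S.SAH] = live * p_rupt_mia
    rem = live * (1.0 - p_rupt_mia)
    P[:, S.WELL_MIA, S.WELL_GROWING_MIA] = rem * p_grow_mia
    P[:, S.WELL_MIA, S.WELL_MIA] = rem * (1.0 - p_grow_mia)

    # WELL_GROWING_MIA: death -> rupture -> (detection at a screening visit)
    detect = spec.screening_interval is not None and screening_due(
        next_cycle, spec.screening_interval
    )
    P[:, S.WELL_GROWING_MIA, S.DEATH] = q
    P[:, S.WELL_GROWING_MIA, S.SAH] = live * p_rupt_grow
    rem = live * (1.0 - p_rupt_grow)
    if detect:
        # the grown aneurysm is coiled; survivors keep one untreated aneurysm
        P[:, S.WELL_GROWING_MIA, S.DEATH] += rem * d1
        P[:, S.WELL_GROWING_MIA, S.MOD_SEVERE_DISABILITY] = rem * ms1
        P[:, S.WELL_GROWING_MIA, S.MILD_DISABILITY] = rem * mi1
        P[:, S.WELL_GROWING_MIA, S.WELL_ONE_TREATED] = rem * fr1
        for dest in (S.MOD_SEVERE_DISABILITY, S.MILD_DISABILITY, S.WELL_ONE_TREATED):
            F[:, S.WELL_GROWING_MIA, dest] = 1.0
    else:
        P[:, S.WELL_GROWING_MIA, S.WELL_GROWING_MIA] = rem

    # WELL_SINGLE_GROWING: fully recovered treated patients are under annual
    # surveillance, so growth of the remaining aneurysm is detected (and
    # coiled) at the next cycle regardless of the strategy's own interval.
    P[:, S.WELL_SINGLE_GROWING, S.DEATH] = q
    P[:, S.WELL_SINGLE_GROWING, S.SAH] = live * p_rupt_grow
    rem = live * (1.0 - p_rupt_grow)
    P[:, S.WELL_SINGLE_GROWING, S.DEATH] += rem * d1
    P[:, S.WELL_SINGLE_GROWING, S.MOD_SEVERE_DISABILITY] = rem * ms1
    P[:, S.WELL_SINGLE_GROWING, S.MILD_DISABILITY] = rem * mi1
    P[:, S.WELL_SINGLE_GROWING, S.WELL_BOTH_TREATED] = rem * fr1
    for dest in (S.MOD_SEVERE_DISABILITY, S.MILD_DISABILITY, S.WELL_BOTH_TREATED):
        F[:, S.WELL_SINGLE_GROWING, dest] = 1.0

    # WELL_ONE_TREATED: the untreated aneurysm behaves as a single aneurysm
    # (no multiplicity risk ratio); de novo formation needs a second coiling
    # and, on full recovery, leaves the patient back in this state.
    P[:, S.WELL_ONE_TREATED, S.DEATH] = q
    P[:, S.WELL_ONE_TREATED, S.SAH] = live * p_rupt_single
    rem = live * (1.0 - p_rupt_single)
    P[:, S.WELL_ONE_TREATED, S.WELL_SINGLE_GROWING] = rem * p_grow_single
    rem = rem * (1.0 - p_grow_single)
    P[:, S.WELL_ONE_TREATED, S.DEATH] += rem * p_denovo * d1
    P[:, S.WELL_ONE_TREATED, S.MOD_SEVERE_DISABILITY] = rem * p_denovo * ms1
    P[:, S.WELL_ONE_TREATED, S.MILD_DISABILITY] = rem * p_denovo * mi1
    P[:, S.WELL_ONE_TREATED, S.WELL_ONE_TREATED] = rem * (1.0 - p_denovo) + rem * p_denovo * fr1
    with np.errstate(invalid="ignore", divide="ignore"):
        stay = rem * (1.0 - p_denovo) + rem * p_denovo * fr1
        frac = np.where(stay > 0, rem * p_denovo * fr1 / np.where(stay > 0, stay, 1.0), 0.0)
    F[:, S.WELL_ONE_TREATED, S.WELL_ONE_TREATED] = frac
    for dest in (S.MOD_SEVERE_DISABILITY, S.MILD_DISABILITY):
        F[:, S.WELL_ONE_TREATED, dest] = 1.0

    # WELL_BOTH_TREATED: only background death and de novo formation remain.
    P[:, S.WELL_BOTH_TREATED, S.DEATH] = q
    rem = live
    P[:, S.WELL_BOTH_TREATED, S.DEATH] += rem * p_denovo * d1
    P[:, S.WELL_BOTH_TREATED, S.MOD_SEVERE_DISABILITY] = rem * p_denovo * ms1
    P[:, S.WELL_BOTH_TREATED, S.MILD_DISABILITY] = rem * p_denovo * mi1
    stay = rem * (1.0 - p_denovo) + rem * p_denovo * fr1
    P[:, S.WELL_BOTH_TREATED, S.WELL_BOTH_TREATED] = stay
    frac = np.where(stay > 0, rem * p_denovo * fr1 / np.where(stay > 0, stay, 1.0), 0.0)
    F[:, S.WELL_BOTH_TREATED, S.WELL_BOTH_TREATED] = frac
    for dest in (S.MOD_SEVERE_DISABILITY, S.MILD_DISABILITY):
        F[:, S.WELL_BOTH_TREATED, dest] = 1.0

    # SAH tunnel: the bleed is coiled and resolves within this transition.
    # The branch's 35% mortality dominates background death, which is not
    # additionally applied during the SAH cycle.
    P[:, S.SAH, S.DEATH] = ds
    P[:, S.SAH, S.MOD_SEVERE_DISABILITY] = mss
    P[:, S.SAH, S.MILD_DISABILITY] = mis
    P[:, S.SAH, S.WELL_BOTH_TREATED] = frs
    for dest in (S.MOD_SEVERE_DISABILITY, S.MILD_DISABILITY, S.WELL_BOTH_TREATED):
        F[:, S.SAH, dest] = 1.0

    # Permanent disability: elevated background mortality, no further
    # aneurysm events (disabled patients are not re-screened or re-treated).
    q_mild = np.minimum(1.0, np.asarray(values["rr_death_mild"], dtype=float) * q)
    q_ms = np.minimum(1.0, np.asarray(values["rr_death_modsev"], dtype=float) * q)
    P[:, S.MILD_DISABILITY, S.DEATH] = q_mild
    P[:, S.MILD_DISABILITY, S.MILD_DISABILITY] = 1.0 - q_mild
    P[:, S.MOD_SEVERE_DISABILITY, S.DEATH] = q_ms
    P[:, S.MOD_SEVERE_DISABILITY, S.MOD_SEVERE_DISABILITY] = 1.0 - q_ms

    P[:, S.DEATH, S.DEATH] = 1.0

    row_sums = P.sum(axis=2)
    if not np.allclose(row_sums, 1.0, rtol=0.0, atol=1e-9):
        worst = float(np.abs(row_sums - 1.0).max())
        raise RuntimeError(f"transition rows do not conserve probability (max err {worst:g})")
    return P, F


def _entry_occupancy(spec: StrategySpec, values: dict, n: int):
    """Cycle-0 occupancy (after the strategy's entry procedure, if any)."""
    S = HealthState
    occ = np.zeros((n, N_STATES))
    coil = np.zeros((n, N_STATES))
    if spec.entry_procedure is None:
        occ[:, S.WELL_MIA] = 1.0
        return occ, coil
    suffix = "one" if spec.entry_procedure == "treat_one" else "two"
    well = S.WELL_ONE_TREATED if suffix == "one" else S.WELL_BOTH_TREATED
    d, ms, mi, fr = _branch(values, suffix)
    occ[:, S.DEATH] = d
    occ[:, S.MOD_SEVERE_DISABILITY] = ms
    occ[:, S.MILD_DISABILITY] = mi
    occ[:, well] = fr
    coil[:, [S.MOD_SEVERE_DISABILITY, S.MILD_DISABILITY, well]] = occ[
        :, [S.MOD_SEVERE_DISABILITY, S.MILD_DISABILITY, well]
    ]
    return occ, coil


def _utility_matrix(values: dict, n: int) -> np.ndarray:
    """(n, 9) utility weights per state."""
    S = HealthState
    u = np.zeros((n, N_STATES))
    full = np.broadcast_to(np.asarray(values["utility_full_recovery"], dtype=float), (n,))
    for s in (
        S.WELL_MIA,
        S.WELL_GROWING_MIA,
        S.WELL_SINGLE_GROWING,
        S.WELL_ONE_TREATED,
        S.WELL_BOTH_TREATED,
    ):
        u[:, s] = full
    u[:, S.SAH] = np.broadcast_to(np.asarray(values["utility_sah"], dtype=float), (n,))
    u[:, S.MILD_DISABILITY] = np.broadcast_to(
        np.asarray(values["utility_mild"], dtype=float), (n,)
    )
    u[:, S.MOD_SEVERE_DISABILITY] = np.broadcast_to(
        np.asarray(values["utility_modsev"], dtype=float), (n,)
    )
    return u


def _run_batch(
    spec: StrategySpec,
    values: dict,
    table: MortalityTable,
    settings: ModelSettings,
    keep_trace: bool = False,
):
    """Propagate the cohort; returns (qalys[n], occupancy, coil_arrivals)."""
    n = _batch_size(values)
    n_cycles = settings.n_cycles
    if table.min_age > settings.start_age or table.max_age < settings.max_age:
        raise ValueError(
            f"life table [{table.min_age}, {table.max_age}] does not cover "
            f"the model horizon [{settings.start_age}, {settings.max_age}]"
        )
    qc = cause_deleted_adjustment(table, settings.sah_fraction)

    occ, coil = _entry_occupancy(spec, values, n)
    u = _utility_matrix(values, n)
    disc = (1.0 + settings.discount_rate) ** -np.arange(n_cycles)
    dis = settings.procedure_disutility

    if keep_trace:
        occ_hist = np.empty((n, n_cycles, N_STATES))
        coil_hist = np.empty((n, n_cycles, N_STATES))
        occ_hist[:, 0] = occ
        coil_hist[:, 0] = coil

    ev = disc[0] * ((occ * u).sum(axis=1) - dis * (coil * u).sum(axis=1))
    for t in range(n_cycles - 1):
        age = settings.start_age + t
        P, F = _transition_matrix(spec, t + 1, qc.q_at(age), values, settings, n)
        coil = np.einsum("ns,nsj->nj", occ, P * F)
        occ = np.einsum("ns,nsj->nj", occ, P)
        ev += disc[t + 1] * ((occ * u).sum(axis=1) - dis * (coil * u).sum(axis=1))
        if keep_trace:
            occ_hist[:, t + 1] = occ
            coil_hist[:, t + 1] = coil

    if keep_trace:
        return ev, occ_hist, coil_hist
    return ev, None, None


def evaluate_batch(
    strategy, values: dict, table: MortalityTable, settings: ModelSettings
) -> np.ndarray:
    """Discounted QALYs for a batch of parameter-value vectors.

    ``values`` maps parameter names to scalars or equal-length 1-D arrays;
    returns an array of QALYs of the batch length.
    """
    spec = strategy if isinstance(strategy, StrategySpec) else get_strategy(strategy)
    ev, _, _ = _run_batch(spec, values, table, settings)
    return ev


def transition_row(
    strategy, state: HealthState, age: int, params: ParameterSet, table: MortalityTable,
    cycle: int | None = None,
) -> TransitionRow:
    """Single-cycle transition distribution from one state at one age.

    ``cycle`` defaults to ``age - start_age + 1`` (the cycle being entered),
    which determines whether a screening visit falls in this transition.
    """
    spec = strategy if isinstance(strategy, StrategySpec) else get_strategy(strategy)
    settings = params.settings
    if cycle is None:
        cycle = age - settings.start_age + 1
    qc = cause_deleted_adjustment(table, settings.sah_fraction)
    P, F = _transition_matrix(spec, cycle, qc.q_at(age), params.base_values(), settings, 1)
    probs = {HealthState(j): float(P[0, state, j]) for j in range(N_STATES)}
    flags = {HealthState(j): float(F[0, state, j]) for j in range(N_STATES)}
    return TransitionRow(origin=HealthState(state), probabilities=probs, coil_flags=flags)


def run_cohort(strategy, params: ParameterSet, table: MortalityTable) -> CohortTrace:
    """Run the cohort simulation at base-case (mean) parameter values."""
    spec = strategy if isinstance(strategy, StrategySpec) else get_strategy(strategy)
    _, occ_hist, coil_hist = _run_batch(
        spec, params.base_values(), table, params.settings, keep_trace=True
    )
    return CohortTrace(
        strategy=spec.id,
        occupancy=occ_hist[0],
        coil_arrivals=coil_hist[0],
        start_age=params.settings.start_age,
    )


def discounted_qalys(trace: CohortTrace, params: ParameterSet) -> StrategyEV:
    """Discounted QALY total of a cohort trace.

    EV = sum_t (1+r)^-t * sum_s [occ(t,s) - disutility * coil_arrivals(t,s)] * u(s)
    """
    settings = params.settings
    values = params.base_values()
    u = _utility_matrix(values, 1)[0]
    n_cycles = trace.occupancy.shape[0]
    disc = (1.0 + settings.discount_rate) ** -np.arange(n_cycles)
    per_cycle = trace.occupancy @ u - settings.procedure_disutility * (
        trace.coil_arrivals @ u
    )
    return StrategyEV(strategy=trace.strategy, qalys=float(disc @ per_cycle))


def evaluate_strategies(
    params: ParameterSet,
    table: MortalityTable,
    strategy_ids: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Base-case discounted QALYs for each strategy (deterministic)."""
    ids = strategy_ids or STRATEGY_ORDER
    values = params.base_values()
    return {
        sid: float(evaluate_batch(sid, values, table, params.settings)[0]) for sid in ids
    }


def rank_strategies(evs: dict[str, float]) -> list[tuple[str, float]]:
    """Strategies sorted by QALYs descending, ties broken by fixed order."""
    order = {sid: i for i, sid in enumerate(STRATEGY_ORDER)}
    return sorted(evs.items(), key=lambda kv: (-kv[1], order.get(kv[0], 99)))
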