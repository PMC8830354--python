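"""The six compared management strategies and the screening schedule.

A strategy is either immediate prophylactic coiling (of one or of both
aneurysms), imaging surveillance at a fixed interval (growth detected at
screening visits triggers coiling of the grown aneurysm), or no
intervention at all (natural history).  ``STRATEGY_ORDER`` is the fixed
tie-break order used whenever an argmax over strategies is taken.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["StrategySpec", "list_strategies", "get_strategy", "screening_due", "STRATEGY_ORDER"]


@dataclass(frozen=True)
class StrategySpec:
    id: str
    label: str
    screening_interval: int | None  # years between MRA screens, None if none
    entry_procedure: str | None  # None | "treat_one" | "treat_two"


# Fixed order: also the tie-break order for "optimal strategy" argmaxes.
STRATEGY_ORDER = (
    "treat_two",
    "treat_one",
    "follow_up_1y",
    "follow_up_2y",
    "follow_up_5y",
    "natural_history",
)

_STRATEGIES = {
    "treat_two": StrategySpec("treat_two", "Treat both aneurysms", None, "treat_two"),
    "treat_one": StrategySpec("treat_one", "Treat one aneurysm", None, "treat_one"),
    "follow_up_1y": StrategySpec("follow_up_1y", "Annual follow-up", 1, None),
    "follow_up_2y": StrategySpec("follow_up_2y", "Biennial follow-up", 2, None),
    "follow_up_5y": StrategySpec("follow_up_5y", "Follow-up every 5 years", 5, None),
    "natural_history": StrategySpec("natural_history", "Natural history", None, None),
}


def list_strategies() -> list[StrategySpec]:
    """All six strategies, in the fixed comparison order."""
    return [_STRATEGIES[s] for s in STRATEGY_ORDER]


def get_strategy(strategy_id: str) -> StrategySpec:
    try:
        return _STRATEGIES[strategy_id]
    except KeyError:
        raise KeyError(
            f"unknown strategy {strategy_id!r}; choose from {list(STRATEGY_ORDER)}"
        ) from None


def screening_due(cycle_index: int, interval: int) -> bool:
    """Whether an MRA screen happens at this cycle.

    Screens start one interval after model entry: no screen fires at
    cycle 0 (the decision point itself).
    """
    if interval < 1:
        raise ValueError(f"screening interval must be >= 1 year, got {interval}")
    if cycle_index < 0:
        raise ValueError("cycle index must be non-negative")
    return cycle_index > 0 and cycle_index % interval == 0
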