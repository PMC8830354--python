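"""Age-specific background mortality and its adjustments.

The model needs an annual probability of death from any cause at each age of
the simulated horizon.  National census life tables are not bundled; the
default fixture is a Gompertz schedule q(age) = min(1, a*exp(b*age)) with
(a, b) anchored so that q(57) = 0.005 and q(85) = 0.08, a plausible shape
for a recent East Asian adult life table.  Any user table can be supplied
as a CSV with columns ``age,q``.

Two adjustments are provided: cause deletion, which removes the small share
of background deaths attributable to aneurysmal subarachnoid hemorrhage so
the model does not count rupture deaths twice, and disability adjustment,
which scales mortality multiplicatively for disabled patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MortalityTable",
    "gompertz_from_anchors",
    "build_fixture_table",
    "cause_deleted_adjustment",
    "disability_adjusted_mortality",
    "DISABILITY_LEVELS",
]

DISABILITY_LEVELS = ("none", "mild", "moderate_severe")

# Anchor points defining the default Gompertz fixture.
_ANCHOR_LOW = (57, 0.005)
_ANCHOR_HIGH = (85, 0.08)


@dataclass(frozen=True)
class MortalityTable:
    """Annual death probabilities q indexed by integer age."""

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)
        if ages.shape != q.shape or ages.ndim != 1:
            raise ValueError("ages and q must be 1-D arrays of equal length")
        if len(ages) == 0:
            raise ValueError("empty mortality table")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be consecutive integers without gaps")
        if np.any((q < 0.0) | (q > 1.0)):
            raise ValueError("death probabilities must lie in [0, 1]")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q_at(self, age) -> np.ndarray | float:
        """Annual death probability at ``age`` (scalar or array)."""
        age = np.asarray(age)
        if np.any(age < self.min_age) or np.any(age > self.max_age):
            raise ValueError(
                f"age {age} outside table span [{self.min_age}, {self.max_age}]"
            )
        out = self.q[age - self.min_age]
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "q": self.q})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MortalityTable":
        df = pd.read_csv(path)
        if not {"age", "q"}.issubset(df.columns):
            raise ValueError("life-table CSV must have columns age,q")
        df = df.sort_values("age")
        return cls(ages=df["age"].to_numpy(), q=df["q"].to_numpy())


def gompertz_from_anchors(
    anchor_low: tuple[int, float] = _ANCHOR_LOW,
    anchor_high: tuple[int, float] = _ANCHOR_HIGH,
) -> tuple[float, float]:
    """Gompertz (a, b) passing exactly through two (age, q) anchor points."""
    (x1, q1), (x2, q2) = anchor_low, anchor_high
    if q1 <= 0 or q2 <= 0 or x2 == x1:
        raise ValueError("anchors must have positive q and distinct ages")
    b = math.log(q2 / q1) / (x2 - x1)
    a = q1 * math.exp(-b * x1)
    return a, b


def build_fixture_table(
    a: float | None = None,
    b: float | None = None,
    age_span: tuple[int, int] = (57, 99),
) -> MortalityTable:
    """Gompertz mortality fixture q(age) = min(1, a*exp(b*age)).

    With ``a``/``b`` omitted, the default anchors give q(57) = 0.005 and
    q(85) = 0.08.
    """
    if a is None and b is None:
        a, b = gompertz_from_anchors()
    if a is None or b is None:
        raise ValueError("provide both a and b, or neither")
    if a <= 0 or b <= 0:
        raise ValueError(f"Gompertz parameters must be positive, got a={a}, b={b}")
    lo, hi = age_span
    if hi < lo:
        raise ValueError("age span must be non-decreasing")
    ages = np.arange(lo, hi + 1)
    q = np.minimum(1.0, a * np.exp(b * ages))
    return MortalityTable(ages=ages, q=q)


def cause_deleted_adjustment(table: MortalityTable, sah_fraction: float) -> MortalityTable:
    """Remove the SAH-attributable share from background mortality.

    q'(age) = q(age) * (1 - sah_fraction).  Rupture deaths are generated
    inside the model, so they must not also appear in the all-cause rates.
    """
    if not 0.0 <= sah_fraction < 1.0:
        raise ValueError(f"sah_fraction must lie in [0, 1), got {sah_fraction}")
    return MortalityTable(ages=table.ages, q=table.q * (1.0 - sah_fraction))


def disability_adjusted_mortality(age, level: str, table: MortalityTable, params) -> float:
    """Annual death probability adjusted for permanent disability.

    ``none`` returns q(age); ``mild`` and ``moderate_severe`` multiply by the
    respective mortality risk ratios from ``params`` (capped at 1).
    """
    if level not in DISABILITY_LEVELS:
        raise ValueError(f"unknown disability level {level!r}")
    q = table.q_at(age)
    if level == "none":
        return q
    name = "rr_death_mild" if level == "mild" else "rr_death_modsev"
    rr = params.clinical[name].mean if hasattr(params, "clinical") else float(params[name])
    return float(np.minimum(1.0, rr * q))
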