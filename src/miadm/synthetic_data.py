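"""Synthetic inputs with the statistical structure the analysis assumes.

The treatment-outcome probabilities in the default parameter table were
estimated from a hospital registry of patients with two small unruptured
aneurysms (129 with one aneurysm coiled, 95 with both coiled).  That
registry is not distributable, so this module generates patient-level
records with the same category frequencies, and the estimator that turns
such records back into parameter-table rows.  It also re-exports the
Gompertz life-table fixture for pipeline convenience.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_table import MortalityTable, build_fixture_table

__all__ = [
    "OUTCOME_CATEGORIES",
    "PatientRecord",
    "generate_treatment_cohort",
    "estimate_outcome_proportions",
    "generate_life_table",
]

OUTCOME_CATEGORIES = ("full_recovery", "mild", "moderate_severe", "death")

# Registry demographics emulated by the generator: mean age 56 (SD 10),
# about two-thirds female, follow-up around 31 months (SD 23).
_AGE_MEAN, _AGE_SD = 56.0, 10.0
_FEMALE_FRACTION = 0.655
_FOLLOWUP_MEAN, _FOLLOWUP_SD = 31.0, 23.0


@dataclass(frozen=True)
class PatientRecord:
    age: float
    sex: str
    treated_count: int
    outcome: str
    follow_up_months: float


def _branch_probs(outcome_probs: dict, branch: int) -> np.ndarray:
    """Category probabilities (full_recovery, mild, moderate_severe, death)."""
    key = "one" if branch == 1 else "two"
    mi = float(outcome_probs[f"mild_after_{key}"])
    ms = float(outcome_probs[f"modsev_after_{key}"])
    d = float(outcome_probs[f"mortality_after_{key}"])
    if min(mi, ms, d) < 0 or mi + ms + d > 1.0:
        raise ValueError(
            f"branch '{key}': outcome probabilities must be non-negative and sum to <= 1"
        )
    return np.array([1.0 - mi - ms - d, mi, ms, d])


def generate_treatment_cohort(
    n_one: int,
    n_two: int,
    outcome_probs: dict,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate patient-level endovascular-treatment records.

    ``outcome_probs`` maps ``{mild,modsev,mortality}_after_{one,two}`` to
    probabilities (a ``ParameterSet.base_values()`` dict works).  Outcomes
    are drawn independently per patient from the branch distribution; the
    complement of the three risks is full recovery.
    """
    if n_one < 0 or n_two < 0:
        raise ValueError("cohort sizes must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for treated, n in ((1, n_one), (2, n_two)):
        probs = _branch_probs(outcome_probs, treated)
        outcomes = rng.choice(OUTCOME_CATEGORIES, size=n, p=probs)
        ages = rng.normal(_AGE_MEAN, _AGE_SD, size=n)
        sexes = np.where(rng.random(n) < _FEMALE_FRACTION, "female", "male")
        fu = np.maximum(0.0, rng.normal(_FOLLOWUP_MEAN, _FOLLOWUP_SD, size=n))
        for i in range(n):
            rows.append(
                {
                    "age": float(ages[i]),
                    "sex": str(sexes[i]),
                    "treated_count": treated,
                    "outcome": str(outcomes[i]),
                    "follow_up_months": float(fu[i]),
                }
            )
    return pd.DataFrame(rows, columns=["age", "sex", "treated_count", "outcome", "follow_up_months"])


def estimate_outcome_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Per-branch outcome proportions with binomial standard deviations.

    Rows are directly consumable as parameter-table entries: for each
    treated-count branch and each adverse category, proportion = count / n
    and SD = sqrt(p(1-p)/n).
    """
    rows = []
    for treated, key in ((1, "one"), (2, "two")):
        sub = records[records["treated_count"] == treated]
        n = len(sub)
        if n == 0:
            raise ValueError(f"no records with treated_count={treated}")
        for cat, name in (
            ("mild", f"mild_after_{key}"),
            ("moderate_severe", f"modsev_after_{key}"),
            ("death", f"mortality_after_{key}"),
        ):
            k = int((sub["outcome"] == cat).sum())
            p = k / n
            rows.append(
                {
                    "name": name,
                    "branch_n": n,
                    "events": k,
                    "proportion": p,
                    "sd": float(np.sqrt(p * (1.0 - p) / n)),
                }
            )
    return pd.DataFrame(rows)


def generate_life_table(
    a: float | None = None,
    b: float | None = None,
    age_span: tuple[int, int] = (57, 99),
) -> MortalityTable:
    """Gompertz background-mortality fixture (see ``life_table``)."""
    return build_fixture_table(a=a, b=b, age_span=age_span)
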