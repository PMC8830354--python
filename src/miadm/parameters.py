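"""Clinical parameters, utilities and their uncertainty distributions.

Each model input is a :class:`ParameterSpec` carrying a point estimate
(used for the base case and as the centre of one-way sweeps), a plausible
range (the interval swept in one-way/two-way analyses) and an uncertainty
distribution (sampled in probabilistic sensitivity analysis).  Probabilities
are given beta distributions, risk ratios lognormal distributions and
utilities triangular distributions; beta and lognormal shapes are recovered
from the published mean and standard deviation by moment matching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ParameterSpec",
    "ModelSettings",
    "ParameterSet",
    "load_base_parameters",
    "beta_from_moments",
    "lognormal_from_moments",
    "sample_parameter",
    "CLINICAL_NAMES",
    "UTILITY_NAMES",
]

DIST_FAMILIES = ("beta", "lognormal", "triangular", "fixed")

#: The 18 clinical inputs, in canonical order.
CLINICAL_NAMES = (
    "growth_rate_small",
    "rupture_rate_nongrowing",
    "rupture_rate_growing",
    "rr_growth_mia",
    "rr_rupture_mia",
    "de_novo_rate",
    "rr_de_novo_mia",
    "mild_after_one",
    "modsev_after_one",
    "mortality_after_one",
    "mild_after_two",
    "modsev_after_two",
    "mortality_after_two",
    "mild_after_sah",
    "modsev_after_sah",
    "mortality_after_sah",
    "rr_death_mild",
    "rr_death_modsev",
)

UTILITY_NAMES = (
    "utility_mild",
    "utility_modsev",
    "utility_sah",
    "utility_full_recovery",
)

# A beta distribution with mean exactly 0 is undefined; probabilities
# reported as 0 are sampled around this small surrogate mean instead.
# The base case still uses exactly 0.
ZERO_MEAN_BETA_EPS = 5e-4


class ParameterValidationError(ValueError):
    """A parameter row violates its invariants; the message names the row."""


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta shapes for a given mean and SD.

    nu = mean*(1-mean)/sd**2 - 1; alpha = mean*nu; beta = (1-mean)*nu.

    Raises
    ------
    ValueError
        If ``mean`` is outside (0, 1) or ``sd**2 >= mean*(1-mean)``
        (no beta distribution has such moments).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must lie in (0, 1), got {mean}")
    if sd <= 0.0:
        raise ValueError(f"beta sd must be positive, got {sd}")
    if sd * sd >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible beta moments: sd^2={sd*sd:g} >= mean(1-mean)={mean*(1-mean):g}"
        )
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return mean * nu, (1.0 - mean) * nu


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with the given arithmetic moments.

    sigma^2 = ln(1 + sd^2/mean^2); mu = ln(mean) - sigma^2/2.  The SD is
    interpreted on the ratio (natural) scale, not the log scale.
    """
    if mean <= 0.0 or sd <= 0.0:
        raise ValueError(f"lognormal moments must be positive, got mean={mean}, sd={sd}")
    sigma2 = math.log(1.0 + (sd * sd) / (mean * mean))
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


@dataclass(frozen=True)
class ParameterSpec:
    """One model input: point estimate, range and uncertainty distribution."""

    name: str
    mean: float
    low: float
    high: float
    dist_family: str
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.dist_family not in DIST_FAMILIES:
            raise ParameterValidationError(
                f"{self.name}: unknown distribution family {self.dist_family!r}"
            )
        if not self.low <= self.mean <= self.high:
            raise ParameterValidationError(
                f"{self.name}: mean {self.mean} outside range [{self.low}, {self.high}]"
            )
        if self.dist_family == "beta":
            if self.sd is None or self.sd <= 0:
                raise ParameterValidationError(f"{self.name}: beta spec requires sd > 0")
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ParameterValidationError(
                    f"{self.name}: beta spec range must lie within [0, 1]"
                )
            m = self.sampling_mean
            if self.sd * self.sd >= m * (1.0 - m):
                raise ParameterValidationError(
                    f"{self.name}: sd^2 must be below mean(1-mean)"
                )
        elif self.dist_family == "lognormal":
            if self.mean <= 0:
                raise ParameterValidationError(f"{self.name}: lognormal mean must be > 0")
            if self.sd is None or self.sd <= 0:
                raise ParameterValidationError(f"{self.name}: lognormal spec requires sd > 0")

    @property
    def sampling_mean(self) -> float:
        """Mean used for sampling; zero-mean probabilities get a small surrogate."""
        if self.dist_family == "beta" and self.mean == 0.0:
            return ZERO_MEAN_BETA_EPS
        return self.mean

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the spec's uncertainty distribution (see module docs)."""
        return sample_parameter(self, rng, size)


def sample_parameter(spec: ParameterSpec, rng: np.random.Generator, size: int | None = None):
    """Draw from a parameter's distribution.

    Beta and lognormal draws are *not* truncated to ``[low, high]``: the
    printed range drives only deterministic sweeps.  Triangular draws use
    (low, mean, high) as (min, mode, max).  ``fixed`` returns the mean.
    """
    if spec.dist_family == "fixed":
        if size is None:
            return spec.mean
        return np.full(size, spec.mean)
    if spec.dist_family == "beta":
        a, b = beta_from_moments(spec.sampling_mean, float(spec.sd))
        return rng.beta(a, b, size=size)
    if spec.dist_family == "lognormal":
        mu, sigma = lognormal_from_moments(spec.mean, float(spec.sd))
        return rng.lognormal(mu, sigma, size=size)
    if spec.dist_family == "triangular":
        return rng.triangular(spec.low, spec.mean, spec.high, size=size)
    raise ParameterValidationError(f"{spec.name}: unknown family {spec.dist_family!r}")


@dataclass(frozen=True)
class ModelSettings:
    """Fixed model settings and structural toggles.

    start_age/max_age bound the annual-cycle horizon (57..99 -> 43 cycles);
    discount_rate discounts utilities annually; procedure_disutility is the
    temporary fractional utility loss in the cycle a coiling procedure
    occurs; sah_fraction is the share of background deaths attributed to
    aneurysmal subarachnoid hemorrhage and removed from the life table so
    rupture deaths are not double counted.
    """

    start_age: int = 57
    max_age: int = 99
    cycle_length: float = 1.0
    discount_rate: float = 0.03
    procedure_disutility: float = 0.05
    sah_fraction: float = 0.003
    # Risk ratios are applied multiplicatively to annual probabilities with a
    # cap at 1 by default; True switches to the hazard transform 1-(1-p)^RR.
    hazard_transform: bool = False
    # Whether the rupture risk ratio also scales the growing-aneurysm rate
    # (off by default: that rate already describes a growing aneurysm).
    rr_on_growing: bool = False

    @property
    def n_cycles(self) -> int:
        return self.max_age - self.start_age + 1


@dataclass(frozen=True)
class ParameterSet:
    """The full validated input set: clinical rates, utilities, settings."""

    clinical: dict[str, ParameterSpec]
    utilities: dict[str, ParameterSpec]
    settings: ModelSettings = field(default_factory=ModelSettings)

    def __post_init__(self) -> None:
        missing = [n for n in CLINICAL_NAMES if n not in self.clinical]
        if missing:
            raise ParameterValidationError(f"missing clinical parameters: {missing}")
        extra = [n for n in self.clinical if n not in CLINICAL_NAMES]
        if extra:
            raise ParameterValidationError(f"unknown clinical parameters: {extra}")
        for n in UTILITY_NAMES:
            if n not in self.utilities:
                raise ParameterValidationError(f"missing utility: {n}")
            u = self.utilities[n]
            if not (0.0 <= u.low and u.high <= 1.0):
                raise ParameterValidationError(f"{n}: utility must lie in [0, 1]")
        if self.utilities["utility_full_recovery"].mean != 1.0:
            raise ParameterValidationError("full-recovery utility must be fixed at 1")
        for branch in ("one", "two", "sah"):
            total = sum(
                self.clinical[f"{k}_after_{branch}" if k != "mortality" else f"mortality_after_{branch}"].mean
                for k in ("mild", "modsev", "mortality")
            )
            if total >= 1.0:
                raise ParameterValidationError(
                    f"treatment branch '{branch}': outcome means sum to {total} >= 1"
                )

    def spec(self, name: str) -> ParameterSpec:
        if name in self.clinical:
            return self.clinical[name]
        if name in self.utilities:
            return self.utilities[name]
        raise KeyError(f"unknown parameter {name!r}")

    @property
    def all_specs(self) -> dict[str, ParameterSpec]:
        return {**self.clinical, **self.utilities}

    def base_values(self) -> dict[str, float]:
        """Point-estimate values for deterministic (base-case) evaluation."""
        return {name: spec.mean for name, spec in self.all_specs.items()}

    def sample_values(self, rng: np.random.Generator, size: int | None = None) -> dict:
        """One joint draw (or a vector of draws) of every distributed input."""
        return {
            name: sample_parameter(spec, rng, size)
            for name, spec in self.all_specs.items()
        }

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """A copy with one parameter's mean replaced (for sweeps)."""
        spec = self.spec(name)
        new = replace(
            spec,
            mean=value,
            low=min(spec.low, value),
            high=max(spec.high, value),
        )
        clinical = dict(self.clinical)
        utilities = dict(self.utilities)
        if name in clinical:
            clinical[name] = new
        else:
            utilities[name] = new
        return ParameterSet(clinical=clinical, utilities=utilities, settings=self.settings)

    def with_settings(self, **kwargs) -> "ParameterSet":
        return ParameterSet(
            clinical=self.clinical,
            utilities=self.utilities,
            settings=replace(self.settings, **kwargs),
        )


def _specs_from_frame(df: pd.DataFrame) -> Iterable[ParameterSpec]:
    required = {"name", "mean", "low", "high", "family"}
    if not required.issubset(df.columns):
        raise ParameterValidationError(
            f"parameter table must have columns {sorted(required)}, got {list(df.columns)}"
        )
    for _, row in df.iterrows():
        sd = row.get("sd")
        sd = None if sd is None or (isinstance(sd, float) and math.isnan(sd)) else float(sd)
        yield ParameterSpec(
            name=str(row["name"]),
            mean=float(row["mean"]),
            low=float(row["low"]),
            high=float(row["high"]),
            dist_family=str(row["family"]),
            sd=sd,
        )


def load_base_parameters(
    source: str | None = None, settings: ModelSettings | None = None
) -> ParameterSet:
    """Load a parameter table (CSV: name,mean,low,high,family,sd).

    ``source=None`` loads the bundled default table of published point
    estimates, ranges and distributions.
    """
    if source is None:
        with resources.files("miadm.data").joinpath("default_parameters.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(source)
    clinical: dict[str, ParameterSpec] = {}
    utilities: dict[str, ParameterSpec] = {}
    for spec in _specs_from_frame(df):
        (utilities if spec.name.startswith("utility_") else clinical)[spec.name] = spec
    return ParameterSet(
        clinical=clinical,
        utilities=utilities,
        settings=settings or ModelSettings(),
    )
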