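"""Monthly discrete-time simulation of a female cohort's reproductive histories.

Each woman marries at a lognormal age (in months), and from the first whole
month after marriage to age 50 runs one Bernoulli conception trial per month
while susceptible. A conception at month ``c`` produces a birth at
``c + gestation`` (recorded only if it falls within the window) and blocks
further trials through ``c + gestation + ceil(delta)`` months.

Because all women in a cohort share a birth month, the age-dependent hazard
is a single scalar per simulated month and the cohort advances as a
vectorised month-major sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from natfert.fecundability import (
    FecundabilityCurve,
    FrailtyModel,
    conception_probability,
    sample_frailty,
)

#: month index of the start / end of the reproductive window
WINDOW_START_MONTH = 120
WINDOW_END_MONTH = 600

DEFAULT_AGE_GRID = tuple(range(15, 50))

__all__ = [
    "ParameterVector",
    "SimulationConfig",
    "ReproductiveHistory",
    "ASFRSchedule",
    "sample_marriage_ages",
    "simulate_cohort",
    "simulate_asfr",
    "compute_asfr",
    "completed_fertility",
    "DEFAULT_AGE_GRID",
]


@dataclass(frozen=True)
class ParameterVector:
    """The five estimands of the model.

    mu_m, sigma_m : mean / SD of the age-at-marriage distribution, years.
    phi1, phi2    : fecundability curve coefficients (monthly scale).
    delta         : duration of post-partum amenorrhea, months.
    """

    mu_m: float
    sigma_m: float
    phi1: float
    phi2: float
    delta: float

    def __post_init__(self) -> None:
        vals = (self.mu_m, self.sigma_m, self.phi1, self.phi2, self.delta)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all parameters must be finite")
        if not (10.0 < self.mu_m < 50.0):
            raise ValueError(f"mu_m must lie in (10, 50) years, got {self.mu_m}")
        if self.sigma_m <= 0:
            raise ValueError(f"sigma_m must be > 0, got {self.sigma_m}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")

    @property
    def curve(self) -> FecundabilityCurve:
        return FecundabilityCurve(self.phi1, self.phi2)

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.mu_m, self.sigma_m, self.phi1, self.phi2, self.delta]
        )

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "ParameterVector":
        return cls(*(float(v) for v in a))


PARAM_NAMES = ("mu_m", "sigma_m", "phi1", "phi2", "delta")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings."""

    n_women: int = 5000
    gestation: int = 9
    seed: Optional[int] = None
    age_grid: tuple[int, ...] = DEFAULT_AGE_GRID
    heterogeneity: Optional[FrailtyModel] = None

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        if self.gestation < 1:
            raise ValueError("gestation must be >= 1 month")
        grid = tuple(int(a) for a in self.age_grid)
        if list(grid) != list(range(grid[0], grid[-1] + 1)):
            raise ValueError("age_grid must be consecutive integer ages")
        object.__setattr__(self, "age_grid", grid)

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class ReproductiveHistory:
    """One woman's dated reproductive events, ages in months since birth."""

    marriage_age: float
    conception_ages: list[int] = field(default_factory=list)
    birth_ages: list[int] = field(default_factory=list)
    frailty: float = 1.0

    @property
    def n_births(self) -> int:
        return len(self.birth_ages)


@dataclass(frozen=True)
class ASFRSchedule:
    """Single-age fertility rates on a grid of completed ages.

    The denominator at every age is the full cohort, so the rates sum to
    the mean number of births per woman when the grid spans the window.
    """

    ages: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        if ages.shape != rates.shape:
            raise ValueError("ages and rates must align")
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)

    def __len__(self) -> int:
        return len(self.ages)

    def same_grid(self, other: "ASFRSchedule") -> bool:
        return np.array_equal(self.ages, other.ages)


def sample_marriage_ages(
    mu_m: float, sigma_m: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal ages at marriage in months, moment-parametrised.

    The distribution mean is ``mu_m * 12`` months and SD ``sigma_m * 12``
    months: location ``ln(m^2 / sqrt(m^2 + v))`` and scale
    ``sqrt(ln(1 + v / m^2))`` with ``m``, ``v`` the target mean and
    variance. Draws below 120 months (age 10) are resampled.
    """
    if mu_m <= 0 or sigma_m <= 0:
        raise ValueError("mu_m and sigma_m must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    m = mu_m * 12.0
    v = (sigma_m * 12.0) ** 2
    loc = math.log(m * m / math.sqrt(m * m + v))
    scale = math.sqrt(math.log1p(v / (m * m)))
    out = rng.lognormal(mean=loc, sigma=scale, size=n)
    bad = out < WINDOW_START_MONTH
    while np.any(bad):
        out[bad] = rng.lognormal(mean=loc, sigma=scale, size=int(bad.sum()))
        bad = out < WINDOW_START_MONTH
    return out


def _monthly_hazard(curve: FecundabilityCurve, gestation: int) -> np.ndarray:
    """Hazard for trial months 121 .. WINDOW_END, indexed from 121."""
    months = np.arange(WINDOW_START_MONTH + 1, WINDOW_END_MONTH + 1)
    return conception_probability(months / 12.0, curve)


def _simulate_events(
    theta: ParameterVector,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Core sweep. Returns (marriage_ages, frailty, conc_woman, conc_month).

    ``conc_woman`` / ``conc_month`` list every conception event in
    chronological order (month-major).
    """
    n = config.n_women
    marriage = sample_marriage_ages(theta.mu_m, theta.sigma_m, n, rng)
    if config.heterogeneity is not None:
        z = sample_frailty(config.heterogeneity, n, rng)
    else:
        z = np.ones(n)

    hazard = _monthly_hazard(theta.curve, config.gestation)
    block = config.gestation + math.ceil(theta.delta) + 1  # months to next trial
    # first trial in the first whole month strictly after marriage
    next_free = np.floor(marriage).astype(np.int64) + 1

    u = rng.random((WINDOW_END_MONTH - WINDOW_START_MONTH, n))
    conc_w: list[np.ndarray] = []
    conc_t: list[int] = []
    for k, t in enumerate(range(WINDOW_START_MONTH + 1, WINDOW_END_MONTH + 1)):
        p = hazard[k]
        if p <= 0.0:
            continue
        if config.heterogeneity is not None:
            hit = np.flatnonzero((next_free <= t) & (u[k] < np.minimum(z * p, 1.0)))
        else:
            hit = np.flatnonzero((next_free <= t) & (u[k] < p))
        if hit.size:
            conc_w.append(hit)
            conc_t.extend([t] * hit.size)
            next_free[hit] = t + block
    if conc_w:
        woman = np.concatenate(conc_w)
        month = np.asarray(conc_t, dtype=np.int64)
    else:
        woman = np.empty(0, dtype=np.int64)
        month = np.empty(0, dtype=np.int64)
    return marriage, z, woman, month


def simulate_cohort(
    theta: ParameterVector,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[ReproductiveHistory]:
    """Simulate full reproductive histories for a cohort.

    Pregnancies still in progress at month 600 (age 50) are censored:
    the conception is recorded, the birth is not.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    marriage, z, woman, month = _simulate_events(theta, config, rng)
    histories = [
        ReproductiveHistory(marriage_age=float(m), frailty=float(zi))
        for m, zi in zip(marriage, z)
    ]
    for w, t in zip(woman, month):
        h = histories[w]
        h.conception_ages.append(int(t))
        b = int(t) + config.gestation
        if b <= WINDOW_END_MONTH:
            h.birth_ages.append(b)
    return histories


def simulate_asfr(
    theta: ParameterVector,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> ASFRSchedule:
    """Simulate a cohort and reduce it directly to its ASFR schedule.

    Equivalent to ``compute_asfr(simulate_cohort(...), config.age_grid)``
    but skips building per-woman history objects; used in the inner loop
    of reference-table construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    _, _, _, month = _simulate_events(theta, config, rng)
    births = month + config.gestation
    births = births[births <= WINDOW_END_MONTH]
    return _asfr_from_birth_months(births, config.n_women, config.age_grid)


def _asfr_from_birth_months(
    birth_months: np.ndarray, n_women: int, age_grid: Sequence[int]
) -> ASFRSchedule:
    ages = np.asarray(age_grid, dtype=int)
    counts = np.bincount(
        birth_months // 12, minlength=int(ages[-1]) + 1
    )
    rates = counts[ages] / float(n_women)
    return ASFRSchedule(ages=ages, rates=rates)


def compute_asfr(
    histories: Sequence[ReproductiveHistory],
    age_grid: Sequence[int] = DEFAULT_AGE_GRID,
) -> ASFRSchedule:
    """ASFR at completed age ``a`` = births at age ``a`` / cohort size.

    Completed age at birth is ``floor(birth_age_months / 12)``; the
    denominator is the full cohort at every age (one woman-year per
    woman per age), so rates over the whole window sum to the mean
    number of births per woman.
    """
    if len(histories) == 0:
        raise ValueError("empty cohort")
    births = np.array(
        [b for h in histories for b in h.birth_ages], dtype=np.int64
    )
    return _asfr_from_birth_months(births, len(histories), age_grid)


def completed_fertility(histories: Sequence[ReproductiveHistory]) -> float:
    """Mean number of recorded births per woman."""
    if len(histories) == 0:
        raise ValueError("empty cohort")
    return float(np.mean([h.n_births for h in histories]))
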