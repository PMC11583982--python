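"""Likelihood-free estimation of the simulator parameters.

Rejection ABC on the Euclidean distance between simulated and observed
ASFR vectors, followed by a per-parameter random-forest regression
adjustment evaluated at the observed summary (out-of-bag predictions at
the accepted rows). Priors are independent uniforms; the (phi1, phi2)
rectangle is truncated so the implied peak fecundability stays inside a
plausible band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from natfert.fecundability import (
    FecundabilityCurve,
    FrailtyModel,
    peak_fecundability,
    peak_values,
)
from natfert.simulate import (
    PARAM_NAMES,
    ASFRSchedule,
    ParameterVector,
    SimulationConfig,
    simulate_asfr,
)

__all__ = [
    "PriorBox",
    "RFSettings",
    "ReferenceTable",
    "PosteriorSample",
    "HeterogeneityScenario",
    "sample_prior",
    "euclidean_distance",
    "build_reference_table",
    "simulate_reference_table",
    "reject",
    "rf_adjust",
    "estimate",
    "summarize_posterior",
    "posterior_predictive",
    "estimate_with_heterogeneity",
]


@dataclass(frozen=True)
class PriorBox:
    """Uniform prior bounds for the five parameters.

    ``phi1`` and ``phi2`` are drawn uniformly on a rectangle and
    truncated to the draws whose implied peak monthly fecundability lies
    in ``peak_range``, so the stated peak band holds exactly.
    """

    mu_m: tuple[float, float] = (19.0, 27.0)
    sigma_m: tuple[float, float] = (2.0, 7.0)
    delta: tuple[float, float] = (6.0, 18.0)
    phi1: tuple[float, float] = (0.0, 0.8)
    phi2: tuple[float, float] = (0.0, 0.8)
    peak_range: tuple[float, float] = (0.12, 0.35)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"prior bounds for {name} must satisfy lo < hi")
        if not 0 <= self.peak_range[0] < self.peak_range[1] <= 1:
            raise ValueError("peak_range must be an interval inside [0, 1]")

    @property
    def bounds(self) -> np.ndarray:
        """(5, 2) array of [lower, upper] in canonical parameter order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    def contains(self, params: np.ndarray) -> np.ndarray:
        b = self.bounds
        p = np.atleast_2d(params)
        return np.all((p >= b[:, 0]) & (p <= b[:, 1]), axis=1)


@dataclass(frozen=True)
class RFSettings:
    """Random-forest settings for the regression adjustment."""

    n_trees: int = 500
    min_accepted: int = 50
    # p/3 split features, the customary regression-forest default
    max_features: float | str | int = 1 / 3


@dataclass
class ReferenceTable:
    """Aligned prior draws, simulated ASFR vectors and (optionally) distances."""

    params: np.ndarray  # (N, 5)
    summaries: np.ndarray  # (N, n_ages)
    ages: np.ndarray  # (n_ages,)
    config: SimulationConfig
    distances: Optional[np.ndarray] = None  # (N,) vs. a fixed observed vector
    param_names: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self) -> None:
        if self.params.shape[0] != self.summaries.shape[0]:
            raise ValueError("params and summaries must have the same rows")
        if self.distances is not None:
            if len(self.distances) != len(self.params):
                raise ValueError("distances misaligned with params")
            if np.any(self.distances < 0):
                raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return self.params.shape[0]

    def subset(self, idx: np.ndarray) -> "ReferenceTable":
        return ReferenceTable(
            params=self.params[idx],
            summaries=self.summaries[idx],
            ages=self.ages,
            config=self.config,
            distances=None if self.distances is None else self.distances[idx],
            param_names=self.param_names,
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {n: self.params[:, j] for j, n in enumerate(self.param_names)}
        for j, a in enumerate(self.ages):
            cols[f"asfr_{int(a)}"] = self.summaries[:, j]
        if self.distances is not None:
            cols["distance"] = self.distances
        return pd.DataFrame(cols)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path, config: Optional[SimulationConfig] = None) -> "ReferenceTable":
        df = pd.read_csv(path)
        names = [n for n in PARAM_NAMES if n in df.columns]
        age_cols = [c for c in df.columns if c.startswith("asfr_")]
        ages = np.array([int(c.split("_")[1]) for c in age_cols])
        dist = df["distance"].to_numpy() if "distance" in df.columns else None
        return cls(
            params=df[names].to_numpy(),
            summaries=df[age_cols].to_numpy(),
            ages=ages,
            config=config or SimulationConfig(age_grid=tuple(ages)),
            distances=dist,
            param_names=tuple(names),
        )


@dataclass
class PosteriorSample:
    """Accepted raw draws plus their regression-adjusted versions."""

    raw: np.ndarray  # (n_accepted, 5)
    adjusted: np.ndarray  # (n_accepted, 5)
    summaries: np.ndarray  # (n_accepted, n_ages) simulated summaries
    ages: np.ndarray
    param_names: tuple[str, ...] = PARAM_NAMES

    def summary(self) -> pd.DataFrame:
        return summarize_posterior(self.adjusted, self.param_names)


def sample_prior(
    box: PriorBox, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` parameter vectors (rows, canonical order) from the prior."""
    if n == 0:
        return np.empty((0, 5))
    b = box.bounds
    out = rng.uniform(b[:, 0], b[:, 1], size=(n, 5))
    # truncate (phi1, phi2) to the admissible peak-fecundability band
    lo, hi = box.peak_range
    peaks = peak_values(out[:, 2], out[:, 3])
    bad = np.flatnonzero((peaks < lo) | (peaks > hi))
    while bad.size:
        redraw = rng.uniform(
            b[2:4, 0], b[2:4, 1], size=(bad.size, 2)
        )
        out[bad, 2:4] = redraw
        peaks = peak_values(out[bad, 2], out[bad, 3])
        bad = bad[(peaks < lo) | (peaks > hi)]
    return out


def euclidean_distance(sim: ASFRSchedule, obs: ASFRSchedule) -> float:
    """Plain (unweighted) Euclidean distance between two rate vectors."""
    if not sim.same_grid(obs):
        raise ValueError("ASFR schedules are on different age grids")
    return float(np.linalg.norm(sim.rates - obs.rates))


def simulate_reference_table(
    box: PriorBox,
    n: int,
    config: SimulationConfig,
    seed: Optional[int | np.random.SeedSequence] = None,
    params: Optional[np.ndarray] = None,
) -> ReferenceTable:
    """Prior draws paired with their simulated ASFR vectors (no distances).

    Row ``i`` is simulated with an independent child stream spawned from
    the root seed, so the result is identical whether rows are run
    sequentially or in parallel.
    """
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    prior_seed, *_ = root.spawn(1)
    if params is None:
        params = sample_prior(box, n, np.random.default_rng(prior_seed))
    else:
        params = np.asarray(params, dtype=float)
        if params.shape != (n, 5):
            raise ValueError("params must have shape (n, 5)")
    row_seeds = root.spawn(n + 1)[1:]
    summaries = np.empty((n, len(config.age_grid)))
    for i in range(n):
        theta = ParameterVector.from_array(params[i])
        sched = simulate_asfr(theta, config, np.random.default_rng(row_seeds[i]))
        summaries[i] = sched.rates
    return ReferenceTable(
        params=params,
        summaries=summaries,
        ages=np.asarray(config.age_grid, dtype=int),
        config=config,
    )


def build_reference_table(
    obs: ASFRSchedule,
    box: PriorBox,
    n: int,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> ReferenceTable:
    """Reference table with Euclidean distances to the observed schedule."""
    grid = np.asarray(config.age_grid, dtype=int)
    if not np.array_equal(grid, obs.ages):
        raise ValueError(
            "simulation age_grid must match the observed schedule grid"
        )
    table = simulate_reference_table(box, n, config, seed=seed)
    diff = table.summaries - obs.rates
    table.distances = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    return table


def reject(table: ReferenceTable, accept_fraction: float) -> ReferenceTable:
    """Keep the rows whose distance falls in the lowest ``accept_fraction``.

    Ties at the cutoff are broken by keeping the earliest row index
    (stable sort), so the selection is deterministic. The returned
    subset preserves the original row order.
    """
    if table.distances is None:
        raise ValueError("table has no distances; build it against an observation")
    if len(table) == 0:
        raise ValueError("empty reference table")
    if not 0.0 < accept_fraction <= 1.0:
        raise ValueError("accept_fraction must lie in (0, 1]")
    k = max(1, int(np.ceil(accept_fraction * len(table))))
    order = np.argsort(table.distances, kind="stable")[:k]
    return table.subset(np.sort(order))


def _oob_predictions(rf: RandomForestRegressor, X: np.ndarray) -> np.ndarray:
    oob = rf.oob_prediction_
    missing = ~np.isfinite(oob)
    if np.any(missing):  # rows in every bootstrap sample: fall back to predict
        oob = oob.copy()
        oob[missing] = rf.predict(X[missing])
    return oob


def rf_adjust(
    accepted: ReferenceTable,
    obs: ASFRSchedule,
    box: PriorBox,
    settings: RFSettings = RFSettings(),
    seed: Optional[int] = None,
) -> PosteriorSample:
    """Random-forest regression adjustment of the accepted draws.

    For each parameter ``j`` independently, a forest regresses the
    accepted ``theta_j`` on the simulated summary vectors; the adjusted
    draw is ``theta_j,i - m_oob(s_i) + m(s_obs)``, clipped to the prior
    box. A single accepted row is returned unadjusted (nothing to
    regress on).
    """
    n_acc = len(accepted)
    if n_acc == 0:
        raise ValueError("no accepted draws")
    if n_acc == 1:
        # nothing to regress on: return the single draw unadjusted
        return PosteriorSample(
            raw=accepted.params.copy(),
            adjusted=accepted.params.copy(),
            summaries=accepted.summaries.copy(),
            ages=accepted.ages,
            param_names=accepted.param_names,
        )
    if n_acc < settings.min_accepted:
        raise ValueError(
            f"only {n_acc} accepted draws (< {settings.min_accepted}); "
            "increase N or accept_fraction"
        )
    if not np.array_equal(accepted.ages, obs.ages):
        raise ValueError("observed schedule grid does not match the table")
    X = accepted.summaries
    s_obs = obs.rates.reshape(1, -1)
    adjusted = np.empty_like(accepted.params)
    ss = np.random.SeedSequence(seed).generate_state(accepted.params.shape[1])
    for j in range(accepted.params.shape[1]):
        y = accepted.params[:, j]
        rf = RandomForestRegressor(
            n_estimators=settings.n_trees,
            oob_score=True,
            bootstrap=True,
            max_features=settings.max_features,
            random_state=int(ss[j]) % (2**32 - 1),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse-OOB warning on tiny sets
            rf.fit(X, y)
        m_i = _oob_predictions(rf, X)
        m_obs = rf.predict(s_obs)[0]
        adjusted[:, j] = y - m_i + m_obs
    b = box.bounds
    adjusted = np.clip(adjusted, b[:, 0], b[:, 1])
    return PosteriorSample(
        raw=accepted.params.copy(),
        adjusted=adjusted,
        summaries=X.copy(),
        ages=accepted.ages,
        param_names=accepted.param_names,
    )


def summarize_posterior(
    draws: np.ndarray, param_names: Sequence[str] = PARAM_NAMES
) -> pd.DataFrame:
    """Mean, median and central 95% interval per parameter (rows)."""
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    if draws.shape[0] == 0:
        raise ValueError("no posterior draws")
    q = np.quantile(draws, [0.025, 0.5, 0.975], axis=0)
    return pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "median": q[1],
            "q2.5": q[0],
            "q97.5": q[2],
        },
        index=list(param_names),
    )


@dataclass(frozen=True)
class Envelope:
    """Pointwise posterior-predictive percentile curves."""

    ages: np.ndarray
    lower: np.ndarray  # 2.5th percentile
    median: np.ndarray
    upper: np.ndarray  # 97.5th percentile


def posterior_predictive(
    posterior: PosteriorSample | np.ndarray,
    config: SimulationConfig,
    n_rep: int,
    rng: np.random.Generator,
) -> Envelope:
    """Simulate ``n_rep`` schedules at parameters resampled from the posterior."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    draws = posterior.adjusted if isinstance(posterior, PosteriorSample) else posterior
    draws = np.atleast_2d(draws)
    idx = rng.integers(0, draws.shape[0], size=n_rep)
    sims = np.empty((n_rep, len(config.age_grid)))
    for r, i in enumerate(idx):
        theta = ParameterVector.from_array(draws[i])
        sims[r] = simulate_asfr(theta, config, rng).rates
    lo, med, hi = np.percentile(sims, [2.5, 50.0, 97.5], axis=0)
    return Envelope(
        ages=np.asarray(config.age_grid, dtype=int),
        lower=lo,
        median=med,
        upper=hi,
    )


def estimate(
    obs: ASFRSchedule,
    box: PriorBox,
    config: SimulationConfig,
    n_draws: int = 10_000,
    accept_fraction: float = 0.05,
    rf: RFSettings = RFSettings(),
    seed: Optional[int] = None,
) -> PosteriorSample:
    """Full pipeline: prior -> reference table -> rejection -> RF adjustment."""
    table = build_reference_table(obs, box, n_draws, config, seed=seed)
    accepted = reject(table, accept_fraction)
    return rf_adjust(accepted, obs, box, settings=rf, seed=seed)


@dataclass
class HeterogeneityScenario:
    """Posterior summary of one assumed frailty-variance scenario."""

    sigma2: float
    posterior: PosteriorSample
    median_phi1: float
    median_phi2: float
    peak_age: float
    peak_phi: float  # peak of the posterior-median curve
    mean_peak_phi: float  # mean over draws of each draw's peak
    variance_at_peak: float  # sigma2 * peak_phi**2


def estimate_with_heterogeneity(
    obs: ASFRSchedule,
    sigma2_list: Sequence[float],
    box: PriorBox,
    config: SimulationConfig,
    n_draws: int = 10_000,
    accept_fraction: float = 0.05,
    rf: RFSettings = RFSettings(),
    seed: Optional[int] = None,
) -> list[HeterogeneityScenario]:
    """Re-estimate under each assumed frailty variance (0 = homogeneous).

    All scenarios share the same root seed (common random numbers), so
    between-scenario differences reflect the frailty assumption rather
    than Monte-Carlo noise.
    """
    out: list[HeterogeneityScenario] = []
    for sigma2 in sigma2_list:
        if sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        het = None if sigma2 == 0 else FrailtyModel.from_sigma2(sigma2)
        cfg = config.with_(heterogeneity=het)
        post = estimate(
            obs, box, cfg, n_draws=n_draws,
            accept_fraction=accept_fraction, rf=rf, seed=seed,
        )
        med = np.median(post.adjusted, axis=0)
        age, peak = peak_fecundability(FecundabilityCurve(med[2], med[3]))
        mean_peak = float(
            np.mean(peak_values(post.adjusted[:, 2], post.adjusted[:, 3]))
        )
        out.append(
            HeterogeneityScenario(
                sigma2=float(sigma2),
                posterior=post,
                median_phi1=float(med[2]),
                median_phi2=float(med[3]),
                peak_age=float(age),
                peak_phi=float(peak),
                mean_peak_phi=mean_peak,
                variance_at_peak=float(sigma2) * float(peak) ** 2,
            )
        )
    return out
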