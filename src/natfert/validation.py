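"""Cross-validation of the estimator and the scaled prediction-error statistic.

A reference-table row is promoted to pseudo-observed data, the remaining
rows are used for rejection + regression adjustment, and the posterior
mean is compared with the row's (known) generating parameters. Over many
validation rows this yields, per parameter j,

    ERR_j = sum_i (theta_hat_ij - theta_ij)^2 / Var(theta_ij),

with Var the sample variance (n-1 denominator) of the true values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from natfert.abc import (
    ASFRSchedule,
    PosteriorSample,
    PriorBox,
    ReferenceTable,
    RFSettings,
    reject,
    rf_adjust,
    sample_prior,
    simulate_reference_table,
)
from natfert.simulate import PARAM_NAMES, SimulationConfig

__all__ = [
    "ValidationReport",
    "leave_one_out_estimate",
    "prediction_error",
    "recovery_experiment",
]


@dataclass
class ValidationReport:
    """Truth/estimate pairs and ERR per parameter for one sample-size tier."""

    tier: int
    truths: np.ndarray  # (replicates, 5)
    estimates: np.ndarray  # (replicates, 5) posterior means
    err: np.ndarray  # (5,)
    ci_widths: np.ndarray  # (replicates, 5) central-95% widths
    param_names: tuple[str, ...] = PARAM_NAMES

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for j, n in enumerate(self.param_names):
            cols[f"true_{n}"] = self.truths[:, j]
            cols[f"est_{n}"] = self.estimates[:, j]
            cols[f"ci_width_{n}"] = self.ci_widths[:, j]
        return pd.DataFrame(cols)

    def err_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": self.param_names, "err": self.err, "tier": self.tier}
        )


def _loo_posterior(
    table: ReferenceTable,
    i: int,
    box: PriorBox,
    accept_fraction: float,
    rf: RFSettings,
    seed: Optional[int],
) -> PosteriorSample:
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 reference-table rows")
    if not 0 <= i < n:
        raise IndexError(f"row index {i} out of range for table of {n}")
    obs = ASFRSchedule(ages=table.ages, rates=table.summaries[i])
    rest = table.subset(np.delete(np.arange(n), i))
    diff = rest.summaries - obs.rates
    rest.distances = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    accepted = reject(rest, accept_fraction)
    settings = rf
    if len(accepted) < rf.min_accepted:
        settings = RFSettings(
            n_trees=rf.n_trees,
            min_accepted=min(rf.min_accepted, len(accepted)),
            max_features=rf.max_features,
        )
    return rf_adjust(accepted, obs, box, settings=settings, seed=seed)


def leave_one_out_estimate(
    table: ReferenceTable,
    i: int,
    box: PriorBox = PriorBox(),
    accept_fraction: float = 0.05,
    rf: RFSettings = RFSettings(),
    seed: Optional[int] = None,
) -> np.ndarray:
    """Posterior-mean estimate of row ``i``'s parameters from all other rows."""
    post = _loo_posterior(table, i, box, accept_fraction, rf, seed)
    return post.adjusted.mean(axis=0)


def prediction_error(truths, estimates) -> np.ndarray:
    """ERR per parameter: squared errors scaled by the truths' sample variance."""
    t = np.atleast_2d(np.asarray(truths, dtype=float))
    e = np.atleast_2d(np.asarray(estimates, dtype=float))
    if t.shape != e.shape:
        raise ValueError("truths and estimates must align")
    if t.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    var = t.var(axis=0, ddof=1)
    if np.any(var == 0):
        raise ValueError("zero variance in the true parameter values")
    return ((e - t) ** 2).sum(axis=0) / var


def recovery_experiment(
    tiers: Sequence[int] = (161, 3235, 5000),
    replicates: int = 100,
    n_draws: int = 10_000,
    box: PriorBox = PriorBox(),
    base_config: SimulationConfig = SimulationConfig(),
    accept_fraction: float = 0.05,
    rf: RFSettings = RFSettings(),
    seed: Optional[int] = None,
    share_draws: bool = True,
) -> dict[int, ValidationReport]:
    """Full cross-validation at each cohort-size tier.

    Per tier: one reference table of ``n_draws`` rows at that cohort
    size; ``replicates`` validation rows drawn without replacement; each
    validation row estimated from the remaining rows. Deterministic
    given the root seed.

    With ``share_draws`` (default) the prior draws, validation rows and
    adjustment seeds are common across tiers, so between-tier ERR
    comparisons are paired: only the cohort size (and hence the
    summary-statistic noise) differs.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tiers = [int(t) for t in tiers]
    root = np.random.SeedSequence(seed)
    prior_ss, pick_ss, rf_ss, *tier_ss = root.spawn(3 + len(tiers))
    shared_params = (
        sample_prior(box, n_draws, np.random.default_rng(prior_ss))
        if share_draws
        else None
    )
    n_val = min(replicates, n_draws)
    rows = np.random.default_rng(pick_ss).choice(n_draws, n_val, replace=False)
    rf_seeds = np.random.default_rng(rf_ss).integers(0, 2**31, size=n_val)
    out: dict[int, ValidationReport] = {}
    for tier, tss in zip(tiers, tier_ss):
        cfg = base_config.with_(n_women=int(tier))
        table = simulate_reference_table(
            box, n_draws, cfg, seed=tss, params=shared_params
        )
        truths = np.empty((len(rows), 5))
        estimates = np.empty((len(rows), 5))
        widths = np.empty((len(rows), 5))
        for r, i in enumerate(rows):
            post = _loo_posterior(
                table, int(i), box, accept_fraction, rf, int(rf_seeds[r])
            )
            truths[r] = table.params[i]
            estimates[r] = post.adjusted.mean(axis=0)
            q = np.quantile(post.adjusted, [0.025, 0.975], axis=0)
            widths[r] = q[1] - q[0]
        err = (
            prediction_error(truths, estimates)
            if len(rows) >= 2
            else np.full(5, np.nan)
        )
        out[int(tier)] = ValidationReport(
            tier=int(tier),
            truths=truths,
            estimates=estimates,
            err=err,
            ci_widths=widths,
        )
    return out
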