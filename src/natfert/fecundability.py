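"""Age profile of the monthly conception probability and its frailty extension.

The conception hazard is a cubic on the reproductive window [10, 50] years,
expressed in the Bernstein basis with the two endpoint coefficients pinned
at zero so the hazard vanishes exactly at both ends of the window:

    phi(x) = phi1 * B1(xs) + phi2 * B2(xs),    xs = (x - 10) / 40

Couple-level heterogeneity multiplies the common curve by a Gamma frailty
``z ~ Gamma(shape=s, rate=s)`` with mean 1 and variance ``1/s``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

AGE_LO = 10.0  #: lower end of the reproductive window, years
AGE_HI = 50.0  #: upper end of the reproductive window, years
_SPAN = AGE_HI - AGE_LO

__all__ = [
    "AGE_LO",
    "AGE_HI",
    "FecundabilityCurve",
    "FrailtyModel",
    "scale_age",
    "bernstein_basis",
    "conception_probability",
    "peak_fecundability",
    "sample_frailty",
    "couple_fecundability",
]


@dataclass(frozen=True)
class FecundabilityCurve:
    """Two free coefficients of the degree-3 Bernstein conception hazard.

    Parameters
    ----------
    phi1
        Coefficient on B1 (monthly probability scale). Controls mainly
        the level of the hazard around its peak.
    phi2
        Coefficient on B2. Controls mainly the pace of decline towards
        the end of the window.
    """

    phi1: float
    phi2: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.phi1) and np.isfinite(self.phi2)):
            raise ValueError("curve coefficients must be finite")
        if self.phi1 < 0 or self.phi2 < 0:
            raise ValueError(
                f"curve coefficients must be non-negative, got "
                f"phi1={self.phi1}, phi2={self.phi2}"
            )
        # max of phi over [0,1] is bounded by (4/9)*max(phi1, phi2) for a
        # single-coefficient curve and by 0.75*max for equal coefficients;
        # an exact check keeps phi a valid probability everywhere.
        _, peak = _peak_of(self.phi1, self.phi2)
        if peak > 1.0:
            raise ValueError(
                f"curve implies conception probability {peak:.3f} > 1"
            )


@dataclass(frozen=True)
class FrailtyModel:
    """Gamma frailty with equal shape and rate so the mean multiplier is 1."""

    shape: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and self.shape > 0):
            raise ValueError(f"frailty shape must be > 0, got {self.shape}")

    @property
    def sigma2(self) -> float:
        """Variance of the frailty multiplier, ``1/shape``."""
        return 1.0 / self.shape

    @classmethod
    def from_sigma2(cls, sigma2: float) -> "FrailtyModel":
        if not (np.isfinite(sigma2) and sigma2 > 0):
            raise ValueError(f"frailty variance must be > 0, got {sigma2}")
        return cls(shape=1.0 / sigma2)


def scale_age(x):
    """Map an age in years on [10, 50] to the unit interval.

    Accepts scalars or arrays; raises ``ValueError`` outside the window.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < AGE_LO) or np.any(x > AGE_HI):
        raise ValueError(f"age outside [{AGE_LO:g}, {AGE_HI:g}] years")
    out = (x - AGE_LO) / _SPAN
    return out if out.ndim else float(out)


def bernstein_basis(xs):
    """Evaluate the four cubic Bernstein polynomials at scaled age ``xs``.

    Returns ``(B1, B2, B3, B4)`` with
    ``B1 = 3 xs (1-xs)^2``, ``B2 = 3 xs^2 (1-xs)``,
    ``B3 = (1-xs)^3``, ``B4 = xs^3``; they sum to 1.
    """
    xs = np.asarray(xs, dtype=float)
    if np.any(xs < 0.0) or np.any(xs > 1.0):
        raise ValueError("scaled age outside [0, 1]")
    om = 1.0 - xs
    b1 = 3.0 * xs * om * om
    b2 = 3.0 * xs * xs * om
    b3 = om**3
    b4 = xs**3
    if xs.ndim:
        return b1, b2, b3, b4
    return float(b1), float(b2), float(b3), float(b4)


def conception_probability(x, curve: FecundabilityCurve):
    """Monthly conception probability at age ``x`` (years) for a curve.

    Exactly zero at the window endpoints for every admissible curve.
    Vectorised over ``x``.
    """
    xs = scale_age(x)
    b1, b2, _, _ = bernstein_basis(xs)
    return curve.phi1 * b1 + curve.phi2 * b2


def _peak_of(phi1: float, phi2: float) -> tuple[float, float]:
    """Interior maximiser (scaled age) and value of phi1*B1 + phi2*B2 on [0,1].

    The stationarity condition is the quadratic
    ``3(phi1 - phi2) xs^2 + (2 phi2 - 4 phi1) xs + phi1 = 0``.
    """
    if phi1 == 0.0 and phi2 == 0.0:
        return 0.5, 0.0
    a = 3.0 * (phi1 - phi2)
    b = 2.0 * phi2 - 4.0 * phi1
    c = phi1
    if a == 0.0:
        roots = [-c / b] if b != 0.0 else []
    else:
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            roots = []
        else:
            # numerically stable form: avoids cancellation when a -> 0
            q = -0.5 * (b + math.copysign(math.sqrt(disc), b if b != 0 else 1.0))
            roots = [q / a]
            if q != 0.0:
                roots.append(c / q)
    best_xs, best_val = 0.5, -np.inf
    for r in roots:
        if 0.0 < r < 1.0:
            om = 1.0 - r
            val = 3.0 * r * om * (phi1 * om + phi2 * r)
            if val > best_val:
                best_xs, best_val = r, val
    if not np.isfinite(best_val):
        # degenerate cubic; should not happen for non-negative coefficients
        grid = np.linspace(0.0, 1.0, 4001)
        vals = 3.0 * grid * (1 - grid) * (phi1 * (1 - grid) + phi2 * grid)
        k = int(np.argmax(vals))
        best_xs, best_val = float(grid[k]), float(vals[k])
    return float(best_xs), float(best_val)


def peak_fecundability(curve: FecundabilityCurve) -> tuple[float, float]:
    """Age (years) and value of the maximum of the conception hazard.

    The maximiser solves the quadratic stationarity condition of the
    cubic in closed form. For the degenerate all-zero curve a warning is
    emitted and peak 0 is reported at the window midpoint.
    """
    if curve.phi1 == 0.0 and curve.phi2 == 0.0:
        warnings.warn("degenerate curve: phi1 = phi2 = 0", stacklevel=2)
        return AGE_LO + 0.5 * _SPAN, 0.0
    xs, val = _peak_of(curve.phi1, curve.phi2)
    return AGE_LO + xs * _SPAN, val


def peak_values(phi1, phi2) -> np.ndarray:
    """Vectorised peak of ``phi1*B1 + phi2*B2`` over [0, 1].

    Used to truncate the (phi1, phi2) prior rectangle to a band of
    admissible peak fecundability values. Candidate maximisers are the
    two roots of the quadratic stationarity condition plus the midpoint
    (exact when phi1 == phi2); invalid candidates score -inf.
    """
    p1 = np.asarray(phi1, dtype=float)
    p2 = np.asarray(phi2, dtype=float)
    a = 3.0 * (p1 - p2)
    b = 2.0 * p2 - 4.0 * p1
    c = p1
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = b * b - 4.0 * a * c
        sq = np.sqrt(np.maximum(disc, 0.0))
        # stable quadratic roots (no cancellation as a -> 0)
        q = -0.5 * (b + np.where(b != 0, np.sign(b), 1.0) * sq)
        r1 = np.where(a != 0.0, q / a, np.nan)
        r2 = np.where((a != 0.0) & (q != 0.0), c / np.where(q != 0, q, 1.0), np.nan)

    def _val(r):
        ok = np.isfinite(r) & (r > 0.0) & (r < 1.0)
        r = np.where(ok, r, 0.0)
        v = 3.0 * r * (1.0 - r) * (p1 * (1.0 - r) + p2 * r)
        return np.where(ok, v, -np.inf)

    best = np.maximum(_val(r1), _val(r2))
    best = np.maximum(best, _val(np.full_like(p1, 0.5)))
    return np.maximum(best, 0.0)


def sample_frailty(
    model: FrailtyModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` positive frailty multipliers with mean 1, variance 1/shape."""
    if n < 1:
        raise ValueError("n must be >= 1")
    s = model.shape
    return rng.gamma(shape=s, scale=1.0 / s, size=n)


def couple_fecundability(z, x, curve: FecundabilityCurve):
    """Couple-level monthly conception probability ``min(z * phi(x), 1)``.

    Clamping keeps the Bernoulli-trial semantics when an extreme frailty
    draw pushes the product above 1; for admissible priors (peak hazard
    <= 0.35) clamping only engages for z beyond ~3 and is negligible.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("frailty multiplier must be > 0")
    p = np.minimum(z * conception_probability(x, curve), 1.0)
    return p if p.ndim else float(p)
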