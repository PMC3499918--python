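"""Non-Monte-Carlo moments of the reciprocal of a normal score.

If X ~ Normal(mu, sigma), the unconditional mean of 1/X does not exist:
the density puts mass arbitrarily close to the pole at zero.  The
simulation modules sidestep the pole by resampling normative draws below
a conditioning floor (positivity bound or a z-based bound a few SDs below
the mean, whichever is higher), so the quantity they estimate is the
moment of 1/X *conditional on X above that floor*.  This module computes
exactly that —

    E[1/X | floor < X < upper]   and   SD[1/X | floor < X < upper]

— by adaptive quadrature of the renormalized normal density, plus an
asymptotic delta-method series in v = (sigma/mu)^2 as an independent
cross-check:

    E[1/X]  ~ (1/mu)  (1 +  v +  3 v^2 +  15 v^3 + 105 v^4)
    E[1/X^2]~ (1/mu^2)(1 + 3 v + 15 v^2 + 105 v^3 + 945 v^4)

The series is asymptotic, not convergent: its accuracy degrades below
mean/SD ratios of about 5 and adding terms eventually hurts.  The
quadrature is the authoritative oracle; the upper integration bound
mu + 10 sigma contributes less than the requested tolerance for all
studied ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import integrate
from scipy.stats import norm

from .normative_simulation import ReciprocalStats, StatsSource

# coefficients of v^k in the expansions of mu*E[1/X] and mu^2*E[1/X^2]:
# (2k-1)!! and (2k+1)!!/1 respectively
_MEAN_COEFFS = (1.0, 1.0, 3.0, 15.0, 105.0)
_MSQ_COEFFS = (1.0, 3.0, 15.0, 105.0, 945.0)


@dataclass(frozen=True)
class QuadratureSpec:
    """Integration window and tolerance for the conditional moments.

    The lower bound mirrors the simulator's normative conditioning floor:
    the larger of ``epsilon_frac`` times the mean (hard positivity) and
    ``floor_sigmas`` SDs below the mean, so that "oracle equals Monte
    Carlo" targets one and the same estimand.  ``upper_sigmas`` sets the
    upper bound mean + k*sd; mass beyond it is below the tolerance for
    all studied ratios.
    """

    epsilon_frac: float = 1e-3
    floor_sigmas: float = 3.89
    upper_sigmas: float = 10.0
    rel_tol: float = 1e-10

    def __post_init__(self) -> None:
        if not (0 < self.epsilon_frac < 1):
            raise ValueError(f"epsilon_frac must be in (0, 1), got {self.epsilon_frac}")
        if not (self.floor_sigmas > 0):
            raise ValueError(f"floor_sigmas must be positive, got {self.floor_sigmas}")
        if self.upper_sigmas <= 0:
            raise ValueError(f"upper_sigmas must be positive, got {self.upper_sigmas}")

    def lower_bound(self, mean: float, sd: float) -> float:
        return max(self.epsilon_frac * mean, mean - self.floor_sigmas * sd)


def conditional_reciprocal_moments(
    mean: float, sd: float, spec: QuadratureSpec = QuadratureSpec()
) -> ReciprocalStats:
    """Quadrature mean/SD of 1/X conditional on eps < X < mean + k*sd.

    Deterministic to the requested relative tolerance; raises if the
    integrator's error estimate exceeds it.  Scale-covariant: scaling
    (mean, sd) by c scales both outputs by 1/c.
    """
    if not (mean > 0 and sd > 0):
        raise ValueError(f"mean and sd must be positive, got ({mean!r}, {sd!r})")
    lo = spec.lower_bound(mean, sd)
    hi = mean + spec.upper_sigmas * sd
    if hi <= lo:
        raise ValueError("upper integration bound must exceed the positivity floor")
    mass = norm.cdf(hi, mean, sd) - norm.cdf(lo, mean, sd)

    def moment(power: int) -> float:
        val, err = integrate.quad(
            lambda x: x ** (-power) * norm.pdf(x, mean, sd),
            lo,
            hi,
            epsabs=0.0,
            epsrel=spec.rel_tol,
            limit=200,
        )
        if err > 10 * spec.rel_tol * abs(val):
            raise RuntimeError(
                f"quadrature for E[X^-{power}] did not reach rel_tol="
                f"{spec.rel_tol:g}: achieved {err / abs(val):.2g}"
            )
        return val / mass

    m1 = moment(1)
    m2 = moment(2)
    return ReciprocalStats(
        mean=m1,
        sd=math.sqrt(m2 - m1 * m1),
        source=StatsSource.QUADRATURE,
    )


def series_reciprocal_moments(
    mean: float, sd: float, order: int = 4
) -> ReciprocalStats:
    """Delta-method series for the reciprocal moments, truncated at v^order.

    Valid only as an asymptotic approximation; intended for mean/SD ratios
    of roughly 5 and above.
    """
    if not (1 <= order <= 4):
        raise ValueError(f"order must be in 1..4, got {order}")
    if not (mean > 0 and sd > 0):
        raise ValueError(f"mean and sd must be positive, got ({mean!r}, {sd!r})")
    v = (sd / mean) ** 2
    e1 = sum(c * v**k for k, c in enumerate(_MEAN_COEFFS[: order + 1])) / mean
    e2 = sum(c * v**k for k, c in enumerate(_MSQ_COEFFS[: order + 1])) / mean**2
    var = e2 - e1 * e1
    if var <= 0:
        raise ValueError(
            f"series variance non-positive at mean/SD ratio {mean / sd:.3g}: "
            "the asymptotic expansion has broken down"
        )
    return ReciprocalStats(mean=e1, sd=math.sqrt(var), source=StatsSource.SERIES)


def map_z_analytic(
    z_x: float, ratio: float, spec: QuadratureSpec = QuadratureSpec()
) -> float:
    """Deterministic z-mapping using the quadrature moments.

    Same formula as the Monte Carlo mapping — the score z_x SDs from the
    mean is inverted and standardized against the reciprocal-scale mean
    and SD — but smooth and reproducible to quadrature tolerance.
    """
    placement = 1.0 + z_x / ratio
    if placement <= spec.epsilon_frac:
        raise ValueError(
            f"z = {z_x} at ratio {ratio} lies at or beyond the reciprocal "
            "pole (score <= positivity floor)"
        )
    rstats = conditional_reciprocal_moments(1.0, 1.0 / ratio, spec)
    return (1.0 / placement - rstats.mean) / rstats.sd


def moments_report(mean: float, sd: float, spec: QuadratureSpec = QuadratureSpec()) -> dict:
    """JSON-ready report of quadrature and series moments with the spec echo."""
    quad = conditional_reciprocal_moments(mean, sd, spec)
    series = series_reciprocal_moments(mean, sd)
    return {
        "input": {"mean": mean, "sd": sd, "ratio": mean / sd},
        "spec": {
            "epsilon_frac": spec.epsilon_frac,
            "upper_sigmas": spec.upper_sigmas,
            "rel_tol": spec.rel_tol,
        },
        "quadrature": {"mean": quad.mean, "sd": quad.sd},
        "series_order4": {"mean": series.mean, "sd": series.sd},
    }
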