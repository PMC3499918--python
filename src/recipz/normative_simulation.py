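"""Monte Carlo study of the z-mapping between reciprocal score scales.

If the normative sec/syll distribution is Normal(mean, sd), the syll/sec
scores of the same children are the reciprocals of the same draws — a
heavy-tailed, right-skewed "reciprocal normal" whose shape depends only on
the mean/SD ratio r = mean/sd.  A child at z_x SDs above the sec/syll mean
therefore lands at

    z_y = (1 / (mean + z_x * sd) - mean_recip) / sd_recip

on the syll/sec scale, where mean_recip and sd_recip are the mean and SD of
the reciprocal-transformed normative sample.  This module estimates those
reciprocal statistics by simulation (N draws, several replicate seeds),
maps z-scores between the scales, builds the full ratio-by-z mapping table,
and locates the diagnostic discrepancy region: the band of sec/syll
z-scores classified pathological on sec/syll (z >= +2) but normal on
syll/sec (z > -2).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .score_core import Cutoff, NormativeStats, Scale
from .synthetic_cohorts import SimulationConfig, sample_normative

#: Default grids for the mapping table: mean/SD ratios spanning the studied
#: 3-50 range and z columns up to gross impairment.
DEFAULT_RATIOS = (3.0, 4.0, 5.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0, 50.0)
DEFAULT_Z_VALUES = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


class StatsSource(enum.Enum):
    MONTE_CARLO = "monte_carlo"
    QUADRATURE = "quadrature"
    SERIES = "series"


@dataclass(frozen=True)
class ReciprocalStats:
    """Mean/SD of the reciprocal-transformed normative distribution.

    For Monte Carlo estimates with more than one replicate, ``rep_means``
    and ``rep_sds`` keep the per-replicate values so downstream quantities
    (mapped z, crossing point) can be solved per replicate and averaged,
    and ``se_mean``/``se_sd`` carry the replicate standard errors.
    """

    mean: float
    sd: float
    source: StatsSource
    n_effective: int | None = None
    se_mean: float | None = None
    se_sd: float | None = None
    rep_means: tuple[float, ...] | None = None
    rep_sds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (self.mean > 0 and self.sd > 0):
            raise ValueError(
                f"reciprocal mean and sd must be positive, got "
                f"({self.mean!r}, {self.sd!r})"
            )

    @property
    def replicates(self) -> int:
        return 1 if self.rep_means is None else len(self.rep_means)


@dataclass(frozen=True)
class Estimate:
    """A Monte Carlo estimate with its replicate standard error."""

    value: float
    se: float


def _ratio_key(ratio: float) -> int:
    # stable integer stream key for a (possibly fractional) ratio
    return int(round(ratio * 1_000_000))


def reciprocal_stats_mc(
    mean: float, sd: float, config: SimulationConfig
) -> ReciprocalStats:
    """Empirical mean/SD of 1/X for X ~ Normal(mean, sd), truncated positive.

    Draws ``config.n`` scores per replicate through
    :func:`~recipz.synthetic_cohorts.sample_normative` (so the positivity
    policy applies), transforms each draw by the reciprocal, and averages
    the per-replicate mean and SD over ``config.replicates`` independent
    seed streams.  The stream key depends on the mean/SD ratio only, so
    (mean, sd) and (c*mean, c*sd) reuse identical standard-normal draws and
    their results are exact 1/c multiples of each other.
    """
    ratio = mean / sd
    rep_means = np.empty(config.replicates)
    rep_sds = np.empty(config.replicates)
    for rep in range(config.replicates):
        rng = config.rng(_ratio_key(ratio), rep)
        sample = sample_normative(mean, sd, config, rng=rng)
        recip = 1.0 / sample.values
        rep_means[rep] = recip.mean()
        rep_sds[rep] = recip.std(ddof=1)
    r = config.replicates
    se_mean = float(rep_means.std(ddof=1) / math.sqrt(r)) if r > 1 else None
    se_sd = float(rep_sds.std(ddof=1) / math.sqrt(r)) if r > 1 else None
    return ReciprocalStats(
        mean=float(rep_means.mean()),
        sd=float(rep_sds.mean()),
        source=StatsSource.MONTE_CARLO,
        n_effective=config.n * r,
        se_mean=se_mean,
        se_sd=se_sd,
        rep_means=tuple(rep_means),
        rep_sds=tuple(rep_sds),
    )


def _check_pole(z_x: float, ratio: float, config: SimulationConfig) -> None:
    placement = 1.0 + z_x / ratio  # in units of the normative mean
    if placement <= config.epsilon_frac:
        raise ValueError(
            f"z = {z_x} at mean/SD ratio {ratio} places the score at "
            f"{placement:.4g} normative means, at or below the positivity "
            f"floor: the reciprocal scale has a pole there"
        )


def map_z(
    z_x: float,
    ratio: float,
    config: SimulationConfig,
    recip_stats: ReciprocalStats | None = None,
) -> Estimate:
    """Map a z-score from the normal scale to the reciprocal scale.

    The score at ``z_x`` SDs from the normative mean is inverted and
    standardized against the reciprocal-sample statistics.  With replicated
    Monte Carlo stats the mapping is evaluated per replicate and the mean
    and standard error over replicates are returned.  The result depends on
    the mean/SD ratio only, never on the measurement unit.

    Pass ``recip_stats`` to reuse frozen statistics (e.g. across the cells
    of one table row); otherwise they are simulated here.
    """
    _check_pole(z_x, ratio, config)
    if recip_stats is None:
        recip_stats = reciprocal_stats_mc(1.0, 1.0 / ratio, config)
    y = 1.0 / (1.0 + z_x / ratio)  # reciprocal score in units of 1/mean
    if recip_stats.rep_means is not None and recip_stats.replicates > 1:
        zs = np.array(
            [
                (y - m) / s
                for m, s in zip(recip_stats.rep_means, recip_stats.rep_sds)
            ]
        )
        return Estimate(
            value=float(zs.mean()),
            se=float(zs.std(ddof=1) / math.sqrt(len(zs))),
        )
    return Estimate(value=(y - recip_stats.mean) / recip_stats.sd, se=0.0)


@dataclass
class MappingTable:
    """Grid of syll/sec z estimates by (mean/SD ratio, sec/syll z)."""

    ratios: tuple[float, ...]
    z_values: tuple[float, ...]
    cells: np.ndarray  # shape (len(ratios), len(z_values)) of estimates
    ses: np.ndarray
    config: SimulationConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells,
            index=pd.Index(self.ratios, name="mean_sd_ratio"),
            columns=pd.Index(self.z_values, name="z_sec_syll"),
        )

    def to_csv(self, path: str | Path) -> None:
        """CSV with 'estimate±se' cells, ratios as rows."""
        df = pd.DataFrame(
            [
                [
                    f"{self.cells[i, j]:.4f}±{self.ses[i, j]:.4f}"
                    for j in range(len(self.z_values))
                ]
                for i in range(len(self.ratios))
            ],
            index=pd.Index(self.ratios, name="mean_sd_ratio"),
            columns=pd.Index(self.z_values, name="z_sec_syll"),
        )
        df.to_csv(path)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ratios": list(self.ratios),
            "z_values": list(self.z_values),
            "estimates": self.cells.tolist(),
            "standard_errors": self.ses.tolist(),
            "config": {
                "n": self.config.n,
                "seed": self.config.seed,
                "replicates": self.config.replicates,
                "positivity_policy": self.config.positivity_policy.value,
                "epsilon_frac": self.config.epsilon_frac,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def build_mapping_table(
    ratios: Sequence[float] = DEFAULT_RATIOS,
    z_values: Sequence[float] = DEFAULT_Z_VALUES,
    config: SimulationConfig = SimulationConfig(),
) -> MappingTable:
    """Build the full ratio-by-z mapping table.

    One set of reciprocal statistics is simulated per ratio (its own seed
    stream) and reused across that row's z columns, which preserves the
    within-row monotone decrease of the mapped z.
    """
    cells = np.empty((len(ratios), len(z_values)))
    ses = np.empty_like(cells)
    for i, r in enumerate(ratios):
        if not (3.0 <= r <= 50.0):
            import warnings

            warnings.warn(
                f"mean/SD ratio {r} lies outside the studied range [3, 50]",
                stacklevel=2,
            )
        rstats = reciprocal_stats_mc(1.0, 1.0 / r, config)
        for j, z in enumerate(z_values):
            est = map_z(z, r, config, recip_stats=rstats)
            cells[i, j] = est.value
            ses[i, j] = est.se
    return MappingTable(
        ratios=tuple(ratios),
        z_values=tuple(z_values),
        cells=cells,
        ses=ses,
        config=config,
    )


def crossing_point(
    ratio: float,
    cutoff: Cutoff = Cutoff(),
    config: SimulationConfig = SimulationConfig(),
    recip_stats: ReciprocalStats | None = None,
) -> Estimate:
    """The sec/syll z at which the mapped syll/sec z reaches the cut-off.

    With reciprocal statistics (m, s) frozen, the mapped z

        g(z) = (1 / (1 + z/ratio) - m) / s

    is strictly decreasing in z, so g(z) = -cutoff has at most one root;
    it is bracketed and solved by Brent's method to 1e-6 in z.  With
    replicated Monte Carlo statistics the root is solved once per
    replicate's frozen (m, s) pair — never against statistics re-simulated
    inside the solver — and the replicate mean and standard error are
    returned.
    """
    if recip_stats is None:
        recip_stats = reciprocal_stats_mc(1.0, 1.0 / ratio, config)
    pairs = (
        list(zip(recip_stats.rep_means, recip_stats.rep_sds))
        if recip_stats.rep_means is not None
        else [(recip_stats.mean, recip_stats.sd)]
    )
    target = -cutoff.magnitude
    roots = []
    lo = 0.0
    hi = 1e6 * ratio  # mapped z has plateaued at -m/s long before this
    for m, s in pairs:
        def g(z: float, m: float = m, s: float = s) -> float:
            return (1.0 / (1.0 + z / ratio) - m) / s - target

        if g(lo) <= 0 or g(hi) >= 0:
            raise ValueError(
                f"mapped z never crosses {target} on [{lo}, {hi}] at ratio "
                f"{ratio}: plateau z = {-m / s:.3f} vs cut-off {target}"
            )
        roots.append(optimize.brentq(g, lo, hi, xtol=1e-6))
    roots = np.asarray(roots)
    se = float(roots.std(ddof=1) / math.sqrt(len(roots))) if len(roots) > 1 else 0.0
    return Estimate(value=float(roots.mean()), se=se)


def discrepancy_region(
    ratio: float,
    cutoff: Cutoff = Cutoff(),
    config: SimulationConfig = SimulationConfig(),
    recip_stats: ReciprocalStats | None = None,
) -> tuple[float, float]:
    """The band of sec/syll z classified pathological on sec/syll only.

    Returns [cutoff, crossing point): inside it the child is at least
    ``cutoff`` SDs beyond the sec/syll mean yet still above the
    -``cutoff`` syll/sec cut-off.
    """
    upper = crossing_point(ratio, cutoff, config, recip_stats=recip_stats)
    return (cutoff.magnitude, upper.value)


def distribution_normality(sample: np.ndarray) -> dict[str, float]:
    """Moment-based normality summary of a sample and of its reciprocal.

    Reports skewness and excess kurtosis on both scales so the caller can
    judge which is closer to normal; no hypothesis test is attached.
    Requires at least 20 positive observations and non-degenerate spread.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 20:
        raise ValueError(f"need at least 20 observations, got {sample.size}")
    if np.any(sample <= 0):
        raise ValueError("sample must be strictly positive")
    if sample.std(ddof=1) == 0:
        raise ValueError("degenerate sample: zero standard deviation")
    recip = 1.0 / sample
    return {
        "skewness": float(sps.skew(sample)),
        "excess_kurtosis": float(sps.kurtosis(sample)),
        "skewness_reciprocal": float(sps.skew(recip)),
        "excess_kurtosis_reciprocal": float(sps.kurtosis(recip)),
    }
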