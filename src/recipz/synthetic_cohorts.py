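"""Synthetic normative samples, placed patients, and pre/post designs.

The generator emulates the study conditions of the underlying Monte Carlo
analysis: normative sec/syll (or syll/sec) samples drawn from a normal
distribution with a given mean/SD ratio, N = 20,000 by default; individual
patients placed deterministically at chosen z positions; and balanced
two-group pre/post treatment designs with group-level z-shifts plus
subject-level noise.

A normal model for a positive score can produce non-positive draws when
the mean/SD ratio is small (ratio 3 gives about 0.135% of draws below
zero).  The default policy resamples such draws above a floor and records
how many were replaced; a strict ``reject_run`` mode fails instead.

The normative floor is the larger of a hard positivity bound
(``epsilon_frac`` times the mean, default mean/1000) and a z-based bound
``floor_sigmas`` SDs below the mean (default 3.89, the magnitude of the
standard-normal quantile at 1/20,000: the z below which a normative
sample of the default size expects less than one observation).  Without
the z-bound the reciprocal-transformed second moment is dominated by a
sliver of near-zero scores that a finite sample essentially never
contains, which would make the Monte Carlo reciprocal SD unstable at
small mean/SD ratios and inconsistent with any fixed analytic estimand.
The z-bound applies to normative cohorts only; explicitly placed patients
and pre/post subjects are constrained by positivity alone.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .score_core import NormativeStats, Scale, reciprocal

DEFAULT_N = 20_000
DEFAULT_REPLICATES = 10


class PositivityPolicy(enum.Enum):
    RESAMPLE = "resample"
    REJECT_RUN = "reject_run"


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo configuration shared across the simulation modules.

    ``epsilon_frac`` sets the positivity floor as a fraction of the target
    mean (floor = mean * epsilon_frac), so that configurations with the
    same mean/SD ratio but different units behave identically.
    """

    n: int = DEFAULT_N
    seed: int = 0
    replicates: int = DEFAULT_REPLICATES
    positivity_policy: PositivityPolicy = PositivityPolicy.RESAMPLE
    epsilon_frac: float = 1e-3
    floor_sigmas: float = 3.89

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if not (0 < self.epsilon_frac < 1):
            raise ValueError(
                f"epsilon_frac must be in (0, 1), got {self.epsilon_frac}"
            )
        if not (self.floor_sigmas > 0):
            raise ValueError(f"floor_sigmas must be positive, got {self.floor_sigmas}")

    def epsilon(self, mean: float) -> float:
        """Hard positivity floor in score units."""
        return mean * self.epsilon_frac

    def normative_floor(self, mean: float, sd: float) -> float:
        """Conditioning floor for normative cohorts (see module docstring)."""
        return max(self.epsilon(mean), mean - self.floor_sigmas * sd)

    def rng(self, *stream: int) -> np.random.Generator:
        """Child generator for a named stream, derived from the root seed.

        Each (ratio, replicate) cell of a mapping table gets its own
        deterministic stream so cells are independently reproducible.
        """
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=tuple(stream))
        )


@dataclass
class CohortSample:
    """One simulated normative cohort with its positivity bookkeeping."""

    values: np.ndarray
    mean_target: float
    sd_target: float
    resampled: int = 0


def sample_normative(
    mean: float,
    sd: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> CohortSample:
    """Draw ``config.n`` normative scores from Normal(mean, sd).

    Draws at or below the normative floor (positivity bound or z-based
    bound, whichever is higher) are handled per the configured policy:
    resampled (redrawn until above the floor, count recorded) or fatal.
    Internally the draws are mean + sd * Z with Z standard normal, so two
    calls sharing an RNG state and a mean/SD ratio produce samples that
    are exact scalar multiples of each other.
    """
    if not (sd > 0):
        raise ValueError(f"sd must be positive, got {sd!r}")
    if not (mean > 0):
        raise ValueError(f"mean must be positive, got {mean!r}")
    eps = config.normative_floor(mean, sd)
    if rng is None:
        rng = config.rng(0)

    z = rng.standard_normal(config.n)
    values = mean + sd * z
    bad = values <= eps
    n_bad = int(bad.sum())
    if n_bad and config.positivity_policy is PositivityPolicy.REJECT_RUN:
        raise RuntimeError(
            f"{n_bad} of {config.n} draws fell at or below the positivity "
            f"floor {eps:.6g} (mean/sd ratio {mean / sd:.3g}); rerun with the "
            "resample policy or a larger ratio"
        )
    total_resampled = 0
    while n_bad:
        total_resampled += n_bad
        values[bad] = mean + sd * rng.standard_normal(n_bad)
        bad = values <= eps
        n_bad = int(bad.sum())
    return CohortSample(
        values=values, mean_target=mean, sd_target=sd, resampled=total_resampled
    )


def patient_score(z: float, stats: NormativeStats) -> float:
    """Deterministic placement of a patient at a chosen z: mean + z*sd.

    Rejected if the placement is non-positive — on the raw score scale the
    reciprocal transform has a pole at zero, so such a z position does not
    correspond to any realizable performance.
    """
    value = stats.mean + z * stats.sd
    if not (value > 0):
        raise ValueError(
            f"z = {z} places the patient at {value:.6g} <= 0 on a positive "
            f"score scale (mean {stats.mean}, sd {stats.sd}); the reciprocal "
            "transform is undefined there"
        )
    return value


@dataclass(frozen=True)
class PrePostSpec:
    """Specification of a balanced two-group pre/post treatment design.

    Baselines and improvements are expressed in z-units of the generating
    scale's normative distribution.  Subject-level noise (also in z-units)
    is added independently to the pre and post measurements.
    """

    stats: NormativeStats
    group_sizes: tuple[int, int] = (12, 12)
    baselines_z: tuple[float, float] = (-4.0, -1.0)
    improvements_z: tuple[float, float] = (1.0, 1.0)
    noise_sd_z: float = 0.5
    group_labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValueError(f"group sizes must be >= 2, got {self.group_sizes}")
        if self.noise_sd_z < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.noise_sd_z}")


@dataclass
class PrePostDesign:
    """Realized two-group pre/post dataset on a declared scale."""

    scale: Scale
    groups: np.ndarray  # str labels, one per subject
    pre: np.ndarray
    post: np.ndarray
    spec: PrePostSpec

    def __post_init__(self) -> None:
        if not (len(self.groups) == len(self.pre) == len(self.post)):
            raise ValueError("groups, pre and post must have equal length")
        if np.any(self.pre <= 0) or np.any(self.post <= 0):
            raise ValueError("all scores must be positive")

    def scores_on(self, scale: Scale) -> tuple[np.ndarray, np.ndarray]:
        """(pre, post) expressed on the requested scale."""
        if scale is self.scale:
            return self.pre, self.post
        return 1.0 / self.pre, 1.0 / self.post

    def gains_on(self, scale: Scale) -> np.ndarray:
        """Per-subject improvement on the requested scale.

        Signed so that positive = clinical improvement on that scale
        (post - pre on units-per-time, pre - post on time-per-unit).
        """
        pre, post = self.scores_on(scale)
        return (post - pre) * (-scale.pathology_sign)


def sample_pre_post(
    spec: PrePostSpec,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PrePostDesign:
    """Simulate a pre/post design per its specification.

    Subject i in group g has pre z-position baseline_g + e1 and post
    z-position baseline_g + improvement_g*direction + e2, with e1, e2 iid
    Normal(0, noise_sd_z); z-positions are mapped to raw scores through
    the generating normative stats.  Subjects whose pre or post score
    would fall at or below the positivity floor are redrawn (resample
    policy) or fatal (reject_run).
    """
    if rng is None:
        rng = config.rng(1)
    stats = spec.stats
    eps = config.epsilon(stats.mean)
    # improvement raises z on units_per_time, lowers it on time_per_unit
    gain_sign = -stats.scale.pathology_sign

    groups, pres, posts = [], [], []
    for label, size, base, improv in zip(
        spec.group_labels, spec.group_sizes, spec.baselines_z, spec.improvements_z
    ):
        for _ in range(size):
            for attempt in range(1000):
                e1, e2 = rng.standard_normal(2) * spec.noise_sd_z
                pre = stats.mean + (base + e1) * stats.sd
                post = stats.mean + (base + gain_sign * improv + e2) * stats.sd
                if pre > eps and post > eps:
                    break
                if config.positivity_policy is PositivityPolicy.REJECT_RUN:
                    raise RuntimeError(
                        f"non-positive score for group {label} at baseline "
                        f"z={base}; use the resample policy"
                    )
            else:
                raise RuntimeError(
                    f"could not draw a positive score pair for group {label} "
                    f"(baseline z={base}, mean/sd ratio {stats.ratio:.3g})"
                )
            groups.append(label)
            pres.append(pre)
            posts.append(post)
    return PrePostDesign(
        scale=stats.scale,
        groups=np.array(groups),
        pre=np.array(pres),
        post=np.array(posts),
        spec=spec,
    )


def write_design_csv(design: PrePostDesign, path: str | Path) -> None:
    """Long-format CSV: id, group, time, score, scale."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "group", "time", "score", "scale"])
        for i, (g, pre, post) in enumerate(
            zip(design.groups, design.pre, design.post)
        ):
            writer.writerow([i, g, "pre", repr(float(pre)), design.scale.value])
            writer.writerow([i, g, "post", repr(float(post)), design.scale.value])


def write_cohort_csv(
    sample: CohortSample, scale: Scale, path: str | Path, group: str = "norm"
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "group", "time", "score", "scale"])
        for i, v in enumerate(sample.values):
            writer.writerow([i, group, "single", repr(float(v)), scale.value])
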