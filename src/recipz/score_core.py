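"""Deterministic score algebra for reciprocal reading-speed scales.

Reading speed can be expressed as time per unit read (sec/syll, here the
``TIME_PER_UNIT`` scale) or units read per unit time (syll/sec,
``UNITS_PER_TIME``).  For one and the same performance the two scores are
exact reciprocals of each other, hence related by a hyperbola rather than a
line.  Everything in this module is exact arithmetic: reciprocal and log
transforms, z-scores against normative statistics, z-differences, and
cut-off classification.  All scores carry an explicit scale tag; mixing
scales silently is exactly the mistake this package exists to expose, so
mismatched tags are rejected.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class Scale(enum.Enum):
    """Measurement scale of a reading-speed score.

    ``TIME_PER_UNIT``  – e.g. seconds per syllable; higher = worse reading.
    ``UNITS_PER_TIME`` – e.g. syllables per second; lower = worse reading.
    """

    TIME_PER_UNIT = "time_per_unit"
    UNITS_PER_TIME = "units_per_time"

    @property
    def pathology_sign(self) -> int:
        """+1 if pathology lies at high z on this scale, -1 if at low z."""
        return +1 if self is Scale.TIME_PER_UNIT else -1

    @property
    def opposite(self) -> "Scale":
        return (
            Scale.UNITS_PER_TIME
            if self is Scale.TIME_PER_UNIT
            else Scale.TIME_PER_UNIT
        )


class Category(enum.Enum):
    NORMAL = "normal"
    PATHOLOGICAL = "pathological"


@dataclass(frozen=True)
class ReadingPerformance:
    """A raw reading observation: how many syllables in how many seconds."""

    syllables: int
    seconds: float
    id: str | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.syllables, (int,)) and self.syllables >= 1):
            raise ValueError(
                f"syllables must be a positive integer, got {self.syllables!r}"
            )
        if not (self.seconds > 0 and math.isfinite(self.seconds)):
            raise ValueError(f"seconds must be positive and finite, got {self.seconds!r}")

    @property
    def sec_per_syll(self) -> float:
        return self.seconds / self.syllables

    @property
    def syll_per_sec(self) -> float:
        return self.syllables / self.seconds

    def score(self, scale: Scale) -> float:
        return self.sec_per_syll if scale is Scale.TIME_PER_UNIT else self.syll_per_sec


@dataclass(frozen=True)
class NormativeStats:
    """Mean/SD (and optionally n) of a normative sample on one scale.

    The mean/SD ratio ``r`` is the sole parameter governing the z-mapping
    between the two reciprocal scales; it is always derived from mean and
    sd, never stored separately.
    """

    scale: Scale
    mean: float
    sd: float
    n: int | None = None

    def __post_init__(self) -> None:
        if not (self.mean > 0 and math.isfinite(self.mean)):
            raise ValueError(f"mean must be positive, got {self.mean!r}")
        if not (self.sd > 0 and math.isfinite(self.sd)):
            raise ValueError(f"sd must be positive, got {self.sd!r}")
        if self.n is not None and self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n!r}")

    @property
    def ratio(self) -> float:
        """Mean/SD ratio of the normative distribution."""
        return self.mean / self.sd


@dataclass(frozen=True)
class Cutoff:
    """Diagnostic cut-off magnitude in z-units (default |z| = 2).

    The pathology direction follows from the scale: high z on a
    time-per-unit scale, low z on a units-per-time scale.  A score exactly
    at the cut-off counts as pathological ("at least" two SDs is read
    inclusively).
    """

    magnitude: float = 2.0

    def __post_init__(self) -> None:
        if not (self.magnitude > 0):
            raise ValueError(f"cutoff magnitude must be positive, got {self.magnitude!r}")

    def threshold(self, scale: Scale) -> float:
        """Signed z threshold on the given scale."""
        return scale.pathology_sign * self.magnitude


@dataclass(frozen=True)
class Classification:
    z: float
    category: Category
    scale: Scale

    def to_dict(self) -> dict:
        return {"z": self.z, "category": self.category.value, "scale": self.scale.value}


def compute_rates(perf: ReadingPerformance) -> tuple[float, float]:
    """Both scores of one performance: (sec_per_syll, syll_per_sec).

    The two returned values are exact reciprocals; their product is 1 to
    machine precision.
    """
    return perf.sec_per_syll, perf.syll_per_sec


def reciprocal(score: float) -> float:
    """1/score.  Strictly decreasing involution on the positive reals."""
    if not (score > 0):
        raise ValueError(f"score must be positive, got {score!r}")
    return 1.0 / score


def log_score(score: float) -> float:
    """Natural log of a positive score.

    log of the reciprocal is the negated log, so the two reciprocal scales
    become linearly related (and hence fully equivalent) after this
    transform.
    """
    if not (score > 0):
        raise ValueError(f"score must be positive, got {score!r}")
    return math.log(score)


def z_score(value: float, stats: NormativeStats) -> float:
    """(value - mean) / sd against the normative sample."""
    return (value - stats.mean) / stats.sd


def delta_z(before: float, after: float, stats: NormativeStats) -> float:
    """Change in z-units between two scores of the same individual.

    Sign convention: positive means clinical improvement.  On a
    time-per-unit scale improvement is a *drop* in the raw score, so the
    value is z(before) - z(after); on a units-per-time scale it is
    z(after) - z(before).
    """
    dz = z_score(before, stats) - z_score(after, stats)
    return dz * stats.scale.pathology_sign


def classify(z: float, scale: Scale, cutoff: Cutoff = Cutoff()) -> Classification:
    """Classify a z-score as normal or pathological on its scale.

    Pathological iff z >= +magnitude on a time-per-unit scale, or
    z <= -magnitude on a units-per-time scale (boundary inclusive).
    """
    beyond = z * scale.pathology_sign >= cutoff.magnitude
    return Classification(
        z=z,
        category=Category.PATHOLOGICAL if beyond else Category.NORMAL,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# External interfaces: CSV performance tables in, JSON classifications out.

def read_performances(path: str | Path) -> list[ReadingPerformance]:
    """Read a CSV of performances (columns: syllables, seconds, optional id)."""
    out: list[ReadingPerformance] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"syllables", "seconds"} <= set(
            reader.fieldnames
        ):
            raise ValueError(
                f"{path}: expected columns 'syllables' and 'seconds', "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            out.append(
                ReadingPerformance(
                    syllables=int(row["syllables"]),
                    seconds=float(row["seconds"]),
                    id=row.get("id") or None,
                )
            )
    return out


def write_classifications(
    records: Iterable[Classification], path: str | Path
) -> None:
    """Write classification records as a JSON array."""
    payload = [c.to_dict() for c in records]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
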