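"""Transforms (baseline / normalise / scale, in that fixed order) and
replicate aggregation.

The transform chain always runs baseline subtraction first, then
normalisation, then scaling.  Reference means are computed per group over
unmasked, non-missing replicates of the designated test value, so after the
full chain the baseline test has mean 0 and the normalisation test has mean
equal to the scale factor.

Aggregation reduces each replicate set to a mean plus a variation half-width:
sample SD (n-1 denominator), SEM = SD/sqrt(n), or a 95% confidence interval
half-width t(0.975, n-1)*SEM.  A t-based interval is used rather than
1.96*SEM because plate replicate counts are small.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .plate_model import DataGroup, PlateLayout, ReplicateSet

__all__ = [
    "VariationKind",
    "AggregatedPoint",
    "AggregatedSeries",
    "subtract_baseline",
    "normalise",
    "scale",
    "aggregate",
    "reference_mean",
]


class TransformError(ValueError):
    """Raised when a transform's reference replicates are unusable."""


class VariationKind(enum.Enum):
    SD = "sd"
    SEM = "sem"
    CI95 = "ci95"


@dataclass(frozen=True)
class AggregatedPoint:
    x: float
    mean: float | None
    variation: float | None  # half-width, same units as mean; None if n<2
    n_used: int
    fully_masked: bool


@dataclass(frozen=True)
class AggregatedSeries:
    group_name: str
    points: tuple[AggregatedPoint, ...]
    variation_kind: VariationKind

    def usable_points(self) -> tuple[AggregatedPoint, ...]:
        return tuple(p for p in self.points if not p.fully_masked)

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, mean) arrays over non-fully-masked points."""
        pts = self.usable_points()
        return (
            np.array([p.x for p in pts], dtype=float),
            np.array([p.mean for p in pts], dtype=float),
        )


def reference_mean(group: DataGroup, layout: PlateLayout, test_value: float) -> float:
    """Mean of the unmasked, non-missing replicates of one test value."""
    wells = layout.wells_for(test_value)
    vals = [
        group.values[w.row, w.col]
        for w in wells
        if not group.outlier_mask[w.row, w.col]
        and np.isfinite(group.values[w.row, w.col])
    ]
    if not vals:
        raise TransformError(
            f"baseline unavailable: no usable replicate at test {test_value!r} "
            f"in group {group.name!r} (all masked or missing)"
        )
    return float(np.mean(vals))


def subtract_baseline(
    group: DataGroup, layout: PlateLayout, baseline_test: float
) -> DataGroup:
    """Subtract the baseline replicate mean from every non-blank value."""
    b = reference_mean(group, layout, baseline_test)
    return replace(group, values=group.values - b)


def normalise(group: DataGroup, layout: PlateLayout, norm_test: float) -> DataGroup:
    """Divide every non-blank value by the normalisation replicate mean."""
    m = reference_mean(group, layout, norm_test)
    if m == 0:
        raise TransformError(
            f"degenerate normalisation reference: replicate mean at test "
            f"{norm_test!r} is zero in group {group.name!r}"
        )
    return replace(group, values=group.values / m)


def scale(group: DataGroup, factor: float) -> DataGroup:
    """Multiply every non-blank value by a constant factor."""
    if not np.isfinite(factor) or factor == 0:
        raise TransformError(f"scale factor must be finite and non-zero, got {factor!r}")
    return replace(group, values=group.values * factor)


def _variation(vals: np.ndarray, kind: VariationKind) -> float:
    n = len(vals)
    sd = float(np.std(vals, ddof=1))
    if kind is VariationKind.SD:
        return sd
    sem = float(sd / np.sqrt(n))
    if kind is VariationKind.SEM:
        return sem
    return float(stats.t.ppf(0.975, n - 1) * sem)  # CI95 half-width


def aggregate(sets: list[ReplicateSet], kind: VariationKind) -> AggregatedSeries:
    """Reduce replicate sets to one point each: mean, variation, count.

    Masked and missing replicates are excluded; sets with nothing usable
    become fully_masked points that downstream fitting ignores.
    """
    if not sets:
        raise ValueError("aggregate needs at least one replicate set")
    points = []
    for rs in sorted(sets, key=lambda s: s.test_value):
        vals = rs.unmasked_values()
        n = len(vals)
        points.append(
            AggregatedPoint(
                x=rs.test_value,
                mean=float(np.mean(vals)) if n >= 1 else None,
                variation=_variation(vals, kind) if n >= 2 else None,
                n_used=n,
                fully_masked=(n == 0),
            )
        )
    return AggregatedSeries(
        group_name=sets[0].group_name, points=tuple(points), variation_kind=kind
    )
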