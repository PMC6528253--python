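"""Grubbs' test for outliers within replicate sets.

The test statistic is G = max_i |x_i - mean| / s with s the sample standard
deviation; the value farthest from the mean is the single candidate.  The
two-sided critical value at significance level alpha is

    G_crit = (n-1)/sqrt(n) * sqrt( t^2 / (n - 2 + t^2) )

with t the upper alpha/(2n) quantile of Student's t on n-2 degrees of
freedom.  Screening is non-iterative: at most one value is flagged per
replicate set per run, which suits the small replicate counts (2-4) typical
of plate assays.  Sets with fewer than 3 usable values, or with zero
variance, are skipped and noted in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .plate_model import DataGroup, PlateLayout, ReplicateSet, Well, mask_wells, replicate_sets

__all__ = [
    "OutlierReport",
    "FlaggedWell",
    "grubbs_statistic",
    "grubbs_critical",
    "screen_outliers",
]

DEFAULT_ALPHA = 0.05  # two-sided; ISO-recommended default


@dataclass(frozen=True)
class FlaggedWell:
    well: Well
    test_value: float
    observed: float
    g_statistic: float
    g_critical: float


@dataclass(frozen=True)
class OutlierReport:
    group_name: str
    alpha: float
    flagged: tuple[FlaggedWell, ...] = ()
    skipped: tuple[tuple[float, str], ...] = ()  # (test_value, reason)


def grubbs_statistic(values) -> tuple[float, int]:
    """Return (G, index of the farthermost value).

    G = max|x_i - mean|/s with the sample SD.  Zero-variance samples return
    G = 0 (no outlier possible); ties go to the lowest index so the earliest
    well in row-major order is the deterministic candidate.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError(f"Grubbs test not applicable: n = {len(x)} < 3")
    s = float(np.std(x, ddof=1))
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))  # argmax takes the first maximum on ties
    if s == 0:
        return 0.0, idx
    return float(dev[idx] / s), idx


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size n at level alpha."""
    if n < 3:
        raise ValueError(f"Grubbs test needs n >= 3, got {n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def screen_outliers(
    layout: PlateLayout, group: DataGroup, alpha: float = DEFAULT_ALPHA
) -> tuple[DataGroup, OutlierReport]:
    """Screen every replicate set of one group; mask at most one value per set.

    Operates on raw (pre-transform) values, respecting any manual masks
    already present: masked and missing members never enter the mean or SD.
    Returns the updated group and a report listing flagged wells and
    skipped (inapplicable) sets.
    """
    flagged: list[FlaggedWell] = []
    skipped: list[tuple[float, str]] = []
    to_mask: list[Well] = []
    for rs in replicate_sets(layout, group):
        usable = [
            (w, v) for w, v, m in rs.members if not m and np.isfinite(v)
        ]
        if len(usable) < 3:
            skipped.append((rs.test_value, f"n too small ({len(usable)} < 3)"))
            continue
        vals = [v for _, v in usable]
        g, idx = grubbs_statistic(vals)
        g_crit = grubbs_critical(len(vals), alpha)
        if g > g_crit:
            well, value = usable[idx]
            to_mask.append(well)
            flagged.append(
                FlaggedWell(
                    well=well,
                    test_value=rs.test_value,
                    observed=value,
                    g_statistic=g,
                    g_critical=g_crit,
                )
            )
    new_group = mask_wells(group, to_mask) if to_mask else group
    report = OutlierReport(
        group_name=group.name,
        alpha=alpha,
        flagged=tuple(flagged),
        skipped=tuple(skipped),
    )
    return new_group, report
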