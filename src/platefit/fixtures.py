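"""Synthetic plate-assay generator with known ground truth.

Builds a plate layout (each dose repeated ``n_replicates`` times, filled
row-major) and one or more data groups whose responses follow a known 4PL
or linear model plus i.i.d. Gaussian replicate noise — the distribution
Grubbs' test assumes.  A seeded fraction of wells is displaced by a gross
additive error of random sign, expressed in multiples of the response
range, to exercise two-sided outlier screening.  The truth record keeps
the generating parameters and the injected wells so a completed run can be
scored against them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .fitting import FitModel, FitResult, LinearParams, Logistic4Params, linear_eval, logistic4_eval
from .outliers import OutlierReport
from .plate_model import DataGroup, PlateLayout, Well, bind_group, parse_layout

__all__ = ["SimSpec", "TruthRecord", "RunScore", "simulate_plate", "score_run"]


@dataclass(frozen=True)
class SimSpec:
    model: FitModel
    truth: Logistic4Params | LinearParams
    doses: tuple[float, ...]            # strictly increasing; may include 0
    n_replicates: int = 4
    noise_sd: float = 0.0               # response units
    outlier_frac: float = 0.0           # fraction of labelled wells displaced
    outlier_magnitude: float = 6.0      # in multiples of the response range
    n_groups: int = 1
    seed: int = 0
    n_cols: int = 12                    # plate width for the row-major fill

    def __post_init__(self):
        d = tuple(float(v) for v in self.doses)
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("doses must be strictly increasing")
        if not 0 <= self.outlier_frac < 1:
            raise ValueError("outlier_frac must be in [0, 1)")
        if self.n_replicates < 1 or self.n_groups < 1:
            raise ValueError("n_replicates and n_groups must be >= 1")
        object.__setattr__(self, "doses", d)

    @property
    def response_range(self) -> float:
        if self.model is FitModel.LOGISTIC4:
            return abs(self.truth.top - self.truth.bottom)
        return abs(self.truth.slope) * (max(self.doses) - min(self.doses))

    def digest(self) -> str:
        """Stable hash tying truth records to the spec that produced them."""
        key = repr((self.model.value, self.truth, self.doses, self.n_replicates,
                    self.noise_sd, self.outlier_frac, self.outlier_magnitude,
                    self.n_groups, self.seed, self.n_cols))
        return hashlib.sha256(key.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class TruthRecord:
    spec_hash: str
    model: FitModel
    params: Logistic4Params | LinearParams
    outlier_wells: dict[str, tuple[Well, ...]] = field(default_factory=dict)


@dataclass(frozen=True)
class RunScore:
    sensitivity: float | None   # None when no outliers were injected
    false_positives: int
    param_rel_err: dict[str, float]


def simulate_plate(spec: SimSpec) -> tuple[PlateLayout, list[DataGroup], TruthRecord]:
    """Generate (layout, groups, truth). All randomness comes from spec.seed."""
    n_wells = len(spec.doses) * spec.n_replicates
    n_rows = -(-n_wells // spec.n_cols)  # ceil
    if n_rows < 1:
        raise ValueError("plate too small for doses x replicates")
    cells: list[list[float | None]] = [
        [None] * spec.n_cols for _ in range(n_rows)
    ]
    flat = [d for d in spec.doses for _ in range(spec.n_replicates)]
    for k, d in enumerate(flat):
        cells[k // spec.n_cols][k % spec.n_cols] = d
    layout = parse_layout(cells)

    rng = np.random.default_rng(spec.seed)
    labelled = [
        Well(i, j)
        for i in range(n_rows)
        for j in range(spec.n_cols)
        if cells[i][j] is not None
    ]
    n_out = int(np.floor(spec.outlier_frac * len(labelled)))
    groups: list[DataGroup] = []
    outlier_wells: dict[str, tuple[Well, ...]] = {}
    for g in range(spec.n_groups):
        vals = np.full((n_rows, spec.n_cols), np.nan)
        for w in labelled:
            x = layout.cells[w.row, w.col]
            mu = (
                logistic4_eval(float(x), spec.truth)
                if spec.model is FitModel.LOGISTIC4
                else linear_eval(float(x), spec.truth)
            )
            vals[w.row, w.col] = mu + rng.normal(0.0, spec.noise_sd)
        picked = (
            [labelled[i] for i in sorted(rng.choice(len(labelled), size=n_out, replace=False))]
            if n_out
            else []
        )
        for w in picked:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            vals[w.row, w.col] += sign * spec.outlier_magnitude * spec.response_range
        name = f"group{g + 1}"
        groups.append(bind_group(layout, name, vals, source=f"simulated seed={spec.seed}"))
        outlier_wells[name] = tuple(picked)
    truth = TruthRecord(
        spec_hash=spec.digest(),
        model=spec.model,
        params=spec.truth,
        outlier_wells=outlier_wells,
    )
    return layout, groups, truth


def score_run(
    truth: TruthRecord,
    report: OutlierReport | None,
    fit: FitResult,
    expected_hash: str | None = None,
) -> RunScore:
    """Score one group's run against the generating truth.

    Sensitivity = flagged-and-injected / injected (None if nothing was
    injected); false positives = flagged wells that were not injected.
    Parameter errors are relative where the true value is non-zero,
    absolute otherwise.
    """
    if expected_hash is not None and expected_hash != truth.spec_hash:
        raise ValueError(
            f"spec hash mismatch: truth {truth.spec_hash} vs expected {expected_hash}"
        )
    injected = set(truth.outlier_wells.get(report.group_name, ())) if report else set()
    flagged = {f.well for f in report.flagged} if report else set()
    sensitivity = len(flagged & injected) / len(injected) if injected else None
    fp = len(flagged - injected)
    rel_err = {}
    for k, true_v in truth.params.as_dict().items():
        fit_v = fit.params.as_dict()[k]
        rel_err[k] = abs(fit_v - true_v) / abs(true_v) if true_v != 0 else abs(fit_v)
    return RunScore(sensitivity=sensitivity, false_positives=fp, param_rel_err=rel_err)
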