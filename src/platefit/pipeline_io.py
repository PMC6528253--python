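"""Pipeline orchestration and file I/O.

Runs the fixed analysis pipeline per group — outlier screen, baseline
subtraction, normalisation, scaling, aggregation, model fit — and handles
spreadsheet/CSV import, results export (workbook + tab-separated mirrors),
per-stage ASCII logs, and plot rendering.

Workbook conventions: sheet "PlateSetup" holds the layout matrix from cell
A1; sheet "Data" holds the group blocks stacked vertically, each preceded
by a single cell with the group name and separated by at least one blank
row.  CSV inputs use one file for the layout and one file per group (the
group is named after the file stem).
"""

from __future__ import annotations

import contextlib
import csv
import datetime
import enum
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import openpyxl

from . import preprocess
from .fitting import (
    FitModel,
    FitResult,
    LinearParams,
    Logistic4Params,
    linear_eval,
    lm_fit,
    logistic4_eval,
)
from .outliers import DEFAULT_ALPHA, OutlierReport, screen_outliers
from .plate_model import (
    DataGroup,
    PlateError,
    PlateLayout,
    bind_group,
    parse_layout,
    well_label,
)
from .preprocess import AggregatedSeries, VariationKind, aggregate
from .plate_model import replicate_sets

__all__ = [
    "AnalysisConfig",
    "ResultsRow",
    "ImageFormat",
    "read_inputs",
    "write_inputs",
    "run_analysis",
    "write_results",
    "write_log",
    "render_plot",
]


class ImageFormat(enum.Enum):
    PNG = "png"
    SVG = "svg"


@dataclass(frozen=True)
class AnalysisConfig:
    layout_source: str | Path
    data_source: str | Path | tuple[str | Path, ...]
    fit_model: FitModel = FitModel.LOGISTIC4
    baseline_test: float | None = None
    norm_test: float | None = None
    scale_factor: float | None = None
    variation: VariationKind = VariationKind.SEM
    outlier_check: bool = False
    alpha: float = DEFAULT_ALPHA
    x_title: str = "test value"
    y_title: str = "response"
    plot_title: str = ""
    out_dir: str | Path = "."
    image_format: ImageFormat = ImageFormat.PNG
    seed: int | None = None  # fixtures only; the pipeline itself is deterministic

    def __post_init__(self):
        if self.scale_factor is not None and (
            not np.isfinite(self.scale_factor) or self.scale_factor == 0
        ):
            raise ValueError("scale_factor must be finite and non-zero")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if (
            self.baseline_test is not None
            and self.norm_test is not None
            and self.baseline_test == self.norm_test
        ):
            raise ValueError(
                "baseline_test == norm_test is unsupported: after baseline "
                "subtraction the normalisation reference mean is zero"
            )


@dataclass(frozen=True)
class ResultsRow:
    group_name: str
    model: FitModel
    params: dict[str, float] | None
    param_se: dict[str, float] | None
    ssr: float | None
    r2: float | None
    rmse: float | None
    converged: bool | None
    n_outliers_flagged: int
    n_points_used: int
    error: str | None = None


# ------------------------------------------------------------------- reading

def _cell_to_opt(v):
    if v is None:
        return None
    if isinstance(v, str):
        return v.strip() or None
    return v


def _sheet_matrix(ws) -> list[list]:
    return [[_cell_to_opt(c.value) for c in row] for row in ws.iter_rows()]


def _trim_trailing_blanks(mat: list[list]) -> list[list]:
    """Drop all-blank trailing rows/cols (spreadsheet bounding-box noise)."""
    while mat and all(v is None for v in mat[-1]):
        mat.pop()
    if mat:
        ncol = max(
            (max((j for j, v in enumerate(row) if v is not None), default=-1) for row in mat),
            default=-1,
        ) + 1
        mat = [row[:ncol] + [None] * (ncol - len(row)) for row in mat]
    return mat


def _read_csv_matrix(path: Path) -> list[list]:
    with open(path, newline="", encoding="utf-8") as fh:
        mat = [[_cell_to_opt(v) for v in row] for row in csv.reader(fh)]
    return _trim_trailing_blanks(mat)


def _parse_data_blocks(mat: list[list], layout: PlateLayout):
    """Split the stacked "Data" sheet into (name, block, start_row) tuples."""
    blocks = []
    i = 0
    while i < len(mat):
        row = mat[i]
        if all(v is None for v in row):
            i += 1
            continue
        name = row[0]
        if name is None or not isinstance(name, str):
            raise PlateError(
                f"malformed block starting at sheet row {i + 1}: expected a "
                f"group-name cell, found {row[0]!r}"
            )
        block = mat[i + 1 : i + 1 + layout.n_rows]
        if len(block) < layout.n_rows or any(all(v is None for v in r) for r in block):
            raise PlateError(
                f"malformed block {name!r} starting at sheet row {i + 1}: "
                f"expected {layout.n_rows} data rows"
            )
        block = [list(r[: layout.n_cols]) + [None] * (layout.n_cols - len(r)) for r in block]
        blocks.append((name, block, i + 1))
        i += 1 + layout.n_rows
    return blocks


def read_inputs(layout_source, data_source) -> tuple[PlateLayout, list[DataGroup]]:
    """Load a layout plus its data groups from .xlsx or .csv sources."""
    layout_path = Path(layout_source)
    if layout_path.suffix.lower() == ".xlsx":
        wb = openpyxl.load_workbook(layout_path, data_only=True)
        if "PlateSetup" not in wb.sheetnames:
            raise PlateError(f"{layout_path}: no 'PlateSetup' sheet")
        layout = parse_layout(_trim_trailing_blanks(_sheet_matrix(wb["PlateSetup"])))
    else:
        layout = parse_layout(_read_csv_matrix(layout_path))

    groups: list[DataGroup] = []
    seen: set[str] = set()

    def _add(name, block, source):
        if name in seen:
            raise PlateError(f"duplicate group name {name!r}")
        seen.add(name)
        groups.append(bind_group(layout, name, block, source=source))

    if isinstance(data_source, (list, tuple)):
        paths = [Path(p) for p in data_source]
    else:
        paths = [Path(data_source)]
    for p in paths:
        if p.suffix.lower() == ".xlsx":
            wb = openpyxl.load_workbook(p, data_only=True)
            if "Data" not in wb.sheetnames:
                raise PlateError(f"{p}: no 'Data' sheet")
            for name, block, start in _parse_data_blocks(
                _trim_trailing_blanks(_sheet_matrix(wb["Data"])), layout
            ):
                _add(name, block, f"{p}#Data@row{start}")
        elif p.is_dir():
            for f in sorted(p.glob("*.csv")):
                _add(f.stem, _read_csv_matrix(f), str(f))
        else:
            _add(p.stem, _read_csv_matrix(p), str(p))
    if not groups:
        raise PlateError("no data groups found")
    return layout, groups


# ------------------------------------------------------------------- writing

def _fmt(v) -> str:
    """Full-precision, round-trippable cell text."""
    if v is None:
        return ""
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):  # incl. numpy scalars
        return repr(float(v))
    return str(v)


@contextlib.contextmanager
def _full_precision_numbers():
    """openpyxl serialises floats with %.16g, which drops the last ulp.
    Within this context, numeric cells are written with repr() (shortest
    exact decimal) so saved workbooks round-trip bit-exactly."""
    import openpyxl.cell._writer as cw

    original = cw.safe_string

    def exact(value):
        if isinstance(value, float) and np.isfinite(value):
            return repr(float(value))
        return original(value)

    cw.safe_string = exact
    try:
        yield
    finally:
        cw.safe_string = original


def write_inputs(layout: PlateLayout, groups: list[DataGroup], dest) -> list[Path]:
    """Write layout + groups: one .xlsx workbook, or a directory of CSVs.

    The output re-reads bit-exactly via :func:`read_inputs`.
    """
    dest = Path(dest)

    def cellval(v):
        return float(v) if np.isfinite(v) else None

    if dest.suffix.lower() == ".xlsx":
        wb = openpyxl.Workbook()
        ws = wb.active
        ws.title = "PlateSetup"
        for i in range(layout.n_rows):
            for j in range(layout.n_cols):
                ws.cell(row=i + 1, column=j + 1, value=cellval(layout.cells[i, j]))
        wd = wb.create_sheet("Data")
        r = 1
        for g in groups:
            wd.cell(row=r, column=1, value=g.name)
            for i in range(layout.n_rows):
                for j in range(layout.n_cols):
                    wd.cell(row=r + 1 + i, column=j + 1, value=cellval(g.values[i, j]))
            r += layout.n_rows + 2  # one blank separator row
        dest.parent.mkdir(parents=True, exist_ok=True)
        with _full_precision_numbers():
            wb.save(dest)
        return [dest]
    dest.mkdir(parents=True, exist_ok=True)
    paths = []
    lp = dest / "layout.csv"
    with open(lp, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        for i in range(layout.n_rows):
            w.writerow([_fmt(cellval(layout.cells[i, j])) for j in range(layout.n_cols)])
    paths.append(lp)
    for g in groups:
        gp = dest / f"{g.name}.csv"
        with open(gp, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            for i in range(layout.n_rows):
                w.writerow([_fmt(cellval(g.values[i, j])) for j in range(layout.n_cols)])
        paths.append(gp)
    return paths


def _results_table(rows: list[ResultsRow]) -> tuple[list[str], list[list]]:
    pnames = (
        ["bottom", "top", "ec50", "hill"]
        if rows and rows[0].model is FitModel.LOGISTIC4
        else ["intercept", "slope"]
    )
    header = (
        ["group", "model"]
        + pnames
        + [f"se_{p}" for p in pnames]
        + ["ssr", "r2", "rmse", "converged", "n_outliers_flagged", "n_points_used", "error"]
    )
    table = []
    for r in rows:
        p = r.params or {}
        se = r.param_se or {}
        table.append(
            [r.group_name, r.model.value]
            + [p.get(n) for n in pnames]
            + [se.get(n) for n in pnames]
            + [r.ssr, r.r2, r.rmse, r.converged, r.n_outliers_flagged, r.n_points_used, r.error]
        )
    return header, table


def _aggregated_table(series_by_group: dict[str, AggregatedSeries]):
    header = ["group", "x", "mean", "variation", "variation_kind", "n_used", "fully_masked"]
    table = []
    for name, s in series_by_group.items():
        for p in s.points:
            table.append([name, p.x, p.mean, p.variation, s.variation_kind.value,
                          p.n_used, p.fully_masked])
    return header, table


def _outliers_table(reports: list[OutlierReport]):
    header = ["group", "well", "test_value", "observed", "G", "G_critical", "alpha", "note"]
    table = []
    for rep in reports:
        for f in rep.flagged:
            table.append([rep.group_name, f.well.label, f.test_value, f.observed,
                          f.g_statistic, f.g_critical, rep.alpha, ""])
        for test_value, reason in rep.skipped:
            table.append([rep.group_name, "", test_value, None, None, None, rep.alpha,
                          f"skipped: {reason}"])
    return header, table


def _config_table(config: AnalysisConfig):
    header = ["key", "value"]
    table = []
    for f in dc_fields(config):
        v = getattr(config, f.name)
        if isinstance(v, enum.Enum):
            v = v.value
        table.append([f.name, str(v)])
    return header, table


def write_results(
    rows: list[ResultsRow],
    reports: list[OutlierReport],
    series_by_group: dict[str, AggregatedSeries],
    config: AnalysisConfig,
    out_dir,
) -> dict[str, Path]:
    """Results workbook (sheets results/aggregated/outliers/config) plus
    tab-separated plain-text mirrors of each sheet."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise OSError(f"output directory {out} is not writable")
    sheets = {
        "results": _results_table(rows),
        "aggregated": _aggregated_table(series_by_group),
        "outliers": _outliers_table(reports),
        "config": _config_table(config),
    }
    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    artifacts: dict[str, Path] = {}
    for name, (header, table) in sheets.items():
        ws = wb.create_sheet(name)
        ws.append(header)
        for row in table:
            ws.append([v if not isinstance(v, bool) else str(v) for v in row])
        mirror = out / f"{name}.tsv"
        with open(mirror, "w", encoding="utf-8") as fh:
            fh.write("\t".join(header) + "\n")
            for row in table:
                fh.write("\t".join(_fmt(v) for v in row) + "\n")
        artifacts[f"{name}.tsv"] = mirror
    wb_path = out / "results.xlsx"
    with _full_precision_numbers():
        wb.save(wb_path)
    artifacts["results.xlsx"] = wb_path
    return artifacts


def write_log(stage_events: list[dict], out_dir) -> Path:
    """Plain-text log: one timestamped block per stage per group."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "analysis.log"
    try:
        with open(path, "w", encoding="utf-8") as fh:
            for ev in stage_events:
                fh.write(f"[{ev['time']}] group={ev['group']} stage={ev['stage']} "
                         f"status={ev['status']}\n")
                for k, v in ev.get("detail", {}).items():
                    fh.write(f"    {k}: {v}\n")
                fh.write("\n")
    except OSError as exc:  # logging failure must not kill the run
        import sys

        print(f"warning: could not write log: {exc}", file=sys.stderr)
    return path


def render_plot(
    series: AggregatedSeries, fit: FitResult | None, config: AnalysisConfig
) -> Path:
    """Scatter of means with error bars plus the fitted curve; masked
    points are omitted.  Saves PNG or SVG per the config."""
    pts = series.usable_points()
    x = np.array([p.x for p in pts])
    y = np.array([p.mean for p in pts])
    yerr = np.array([p.variation if p.variation is not None else 0.0 for p in pts])
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.errorbar(x, y, yerr=yerr, fmt="o", capsize=3, label="mean ± "
                + series.variation_kind.value.upper())
    if fit is not None:
        if fit.model is FitModel.LOGISTIC4:
            pos = x[x > 0]
            grid = np.geomspace(pos.min(), pos.max(), 200)
            ax.plot(grid, logistic4_eval(grid, fit.params), "-", label="4PL fit")
            ax.set_xscale("log")
        else:
            grid = np.linspace(x.min(), x.max(), 200)
            ax.plot(grid, linear_eval(grid, fit.params), "-", label="linear fit")
    ax.set_xlabel(config.x_title)
    ax.set_ylabel(config.y_title)
    if config.plot_title:
        ax.set_title(f"{config.plot_title} — {series.group_name}")
    else:
        ax.set_title(series.group_name)
    ax.legend()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"{series.group_name}.{config.image_format.value}"
    fig.savefig(path)
    plt.close(fig)
    return path


# ------------------------------------------------------------------ pipeline

def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


def run_analysis(
    config: AnalysisConfig,
) -> tuple[list[ResultsRow], list[dict], dict[str, Path]]:
    """Run the full pipeline for every group in the inputs.

    Stage order per group: outlier screen (if enabled), baseline
    subtraction, normalisation, scaling, aggregation, model fit.  A stage
    error stops that group only; remaining groups still run and the failed
    group gets an error row.
    """
    layout, groups = read_inputs(config.layout_source, config.data_source)
    rows: list[ResultsRow] = []
    reports: list[OutlierReport] = []
    events: list[dict] = []
    series_by_group: dict[str, AggregatedSeries] = {}
    fits: dict[str, FitResult] = {}

    def log(group, stage, status, **detail):
        events.append({"time": _now(), "group": group, "stage": stage,
                       "status": status, "detail": detail})

    for g in groups:
        name = g.name
        n_flagged = 0
        try:
            # 1. outlier screen — always the very first step when enabled
            if config.outlier_check:
                g, rep = screen_outliers(layout, g, config.alpha)
                reports.append(rep)
                n_flagged = len(rep.flagged)
                log(name, "outlier", "ok",
                    alpha=config.alpha,
                    flagged=", ".join(
                        f"{f.well.label} (test={f.test_value}, value={f.observed}, "
                        f"G={f.g_statistic:.4f} > {f.g_critical:.4f})"
                        for f in rep.flagged) or "none",
                    skipped="; ".join(f"test {t}: {r}" for t, r in rep.skipped) or "none")
            else:
                log(name, "outlier", "skipped")
            # 2. baseline subtraction
            if config.baseline_test is not None:
                b = preprocess.reference_mean(g, layout, config.baseline_test)
                g = preprocess.subtract_baseline(g, layout, config.baseline_test)
                log(name, "baseline", "ok", baseline_test=config.baseline_test,
                    baseline_mean=b)
            else:
                log(name, "baseline", "skipped")
            # 3. normalisation
            if config.norm_test is not None:
                m = preprocess.reference_mean(g, layout, config.norm_test)
                g = preprocess.normalise(g, layout, config.norm_test)
                log(name, "normalise", "ok", norm_test=config.norm_test, norm_mean=m)
            else:
                log(name, "normalise", "skipped")
            # 4. scaling
            if config.scale_factor is not None:
                g = preprocess.scale(g, config.scale_factor)
                log(name, "scale", "ok", factor=config.scale_factor)
            else:
                log(name, "scale", "skipped")
            # 5. aggregation
            series = aggregate(replicate_sets(layout, g), config.variation)
            series_by_group[name] = series
            log(name, "aggregate", "ok",
                n_points=len(series.points),
                fully_masked=sum(p.fully_masked for p in series.points),
                variation=config.variation.value)
            # 6. fit (4PL drops x = 0 points that served as transform references)
            fit_series = series
            if config.fit_model is FitModel.LOGISTIC4:
                refs = {config.baseline_test, config.norm_test}
                keep = tuple(
                    p for p in series.points if not (p.x == 0 and p.x in refs)
                )
                if len(keep) < len(series.points):
                    fit_series = AggregatedSeries(
                        group_name=name, points=keep,
                        variation_kind=series.variation_kind)
            fit = lm_fit(fit_series, config.fit_model)
            fits[name] = fit
            log(name, "fit", "ok",
                model=config.fit_model.value,
                start_params=fit.start_params.as_dict(),
                params=fit.params.as_dict(),
                converged=fit.converged, n_iter=fit.n_iter,
                ssr=fit.ssr, r2=fit.r2, rmse=fit.rmse)
            rows.append(ResultsRow(
                group_name=name, model=config.fit_model,
                params=fit.params.as_dict(), param_se=fit.param_se,
                ssr=fit.ssr, r2=fit.r2, rmse=fit.rmse,
                converged=fit.converged, n_outliers_flagged=n_flagged,
                n_points_used=len(fit_series.usable_points())))
        except Exception as exc:
            log(name, "error", "failed", message=str(exc))
            rows.append(ResultsRow(
                group_name=name, model=config.fit_model, params=None,
                param_se=None, ssr=None, r2=None, rmse=None, converged=None,
                n_outliers_flagged=n_flagged,
                n_points_used=0, error=str(exc)))

    artifacts = write_results(rows, reports, series_by_group, config, config.out_dir)
    artifacts["analysis.log"] = write_log(events, config.out_dir)
    for name, series in series_by_group.items():
        try:
            artifacts[f"plot:{name}"] = render_plot(series, fits.get(name), config)
        except Exception as exc:  # plot failure never kills the run
            log(name, "plot", "failed", message=str(exc))
    return rows, events, artifacts
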