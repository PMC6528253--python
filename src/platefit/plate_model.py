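"""Plate-layout model: wells, layouts, data groups and replicate binding.

A plate layout is a rectangular matrix whose non-blank cells carry numeric
"test" values (e.g. compound concentrations).  All wells sharing a test
value are replicates of that condition.  Observed data for one dataset
("group") occupy a matrix of identical shape; a per-well boolean mask
excludes values flagged as outliers from all downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Well",
    "PlateLayout",
    "DataGroup",
    "ReplicateSet",
    "parse_layout",
    "bind_group",
    "replicate_sets",
    "mask_test",
    "well_label",
    "label_to_rc",
]


class PlateError(ValueError):
    """Raised for malformed layouts, shape mismatches and unknown tests."""


def well_label(row: int, col: int) -> str:
    """0-based (row, col) -> A1-style label. Rows beyond Z use AA, AB, ..."""
    if row < 0 or col < 0:
        raise PlateError(f"negative well index ({row}, {col})")
    letters = ""
    r = row
    while True:
        letters = chr(ord("A") + r % 26) + letters
        r = r // 26 - 1
        if r < 0:
            break
    return f"{letters}{col + 1}"


def label_to_rc(label: str) -> tuple[int, int]:
    """A1-style label -> 0-based (row, col); inverse of :func:`well_label`."""
    i = 0
    while i < len(label) and label[i].isalpha():
        i += 1
    if i == 0 or i == len(label) or not label[i:].isdigit():
        raise PlateError(f"malformed well label {label!r}")
    row = 0
    for ch in label[:i].upper():
        row = row * 26 + (ord(ch) - ord("A") + 1)
    return row - 1, int(label[i:]) - 1


@dataclass(frozen=True, order=True)
class Well:
    row: int
    col: int

    @property
    def label(self) -> str:
        return well_label(self.row, self.col)

    def __repr__(self) -> str:  # compact, label-first for log readability
        return f"Well({self.label})"


@dataclass(frozen=True)
class PlateLayout:
    """Matrix of test values; NaN marks a blank (unused) well."""

    cells: np.ndarray  # float matrix, NaN = blank
    test_index: dict[float, tuple[Well, ...]] = field(compare=False)

    @property
    def n_rows(self) -> int:
        return self.cells.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cells.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def test_values(self) -> tuple[float, ...]:
        return tuple(self.test_index)

    def wells_for(self, test_value: float) -> tuple[Well, ...]:
        try:
            return self.test_index[float(test_value)]
        except KeyError:
            avail = ", ".join(repr(t) for t in self.test_index)
            raise PlateError(
                f"unknown test value {test_value!r}; available: {avail}"
            ) from None


@dataclass(frozen=True)
class DataGroup:
    """One dataset's observations aligned to a layout.

    ``values`` uses NaN both for wells blank in the layout and for missing
    observations at labelled wells; the two cases are distinguished by the
    layout.  ``outlier_mask`` is True where a value is excluded.
    """

    name: str
    values: np.ndarray
    outlier_mask: np.ndarray
    source: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ReplicateSet:
    group_name: str
    test_value: float
    members: tuple[tuple[Well, float, bool], ...]  # (well, value, masked)

    def unmasked_values(self) -> np.ndarray:
        """Values that enter statistics: unmasked and non-missing."""
        return np.array(
            [v for _, v, m in self.members if not m and np.isfinite(v)],
            dtype=float,
        )


def _as_cell_matrix(cells) -> np.ndarray:
    """Coerce a nested sequence / array of optional numbers to a float
    matrix with NaN blanks.  Raises naming the offending well on a
    non-numeric cell."""
    rows = list(cells)
    if not rows:
        raise PlateError("empty layout: no rows")
    ncol = len(rows[0])
    out = np.full((len(rows), ncol), np.nan)
    for i, row in enumerate(rows):
        if len(row) != ncol:
            raise PlateError(f"ragged matrix: row {i + 1} has {len(row)} cells, expected {ncol}")
        for j, cell in enumerate(row):
            if cell is None or (isinstance(cell, str) and cell.strip() == ""):
                continue
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise PlateError(
                    f"non-numeric cell {cell!r} at well {well_label(i, j)}"
                ) from None
            if np.isnan(v):  # NaN is the internal blank marker
                continue
            if not np.isfinite(v):
                raise PlateError(f"non-finite cell at well {well_label(i, j)}")
            out[i, j] = v
    return out


def parse_layout(cells) -> PlateLayout:
    """Build a :class:`PlateLayout` from a matrix of optional reals.

    Wells are grouped by exact numeric equality of their test labels;
    distinct test values iterate in ascending order, wells within a test
    in row-major order.
    """
    mat = _as_cell_matrix(cells)
    if not np.isfinite(mat).any():
        raise PlateError("empty layout: every cell is blank")
    index: dict[float, list[Well]] = {}
    for t in sorted({float(v) for v in mat[np.isfinite(mat)]}):
        index[t] = []
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            if np.isfinite(mat[i, j]):
                index[float(mat[i, j])].append(Well(i, j))
    return PlateLayout(cells=mat, test_index={t: tuple(w) for t, w in index.items()})


def bind_group(layout: PlateLayout, name: str, values, source: str = "") -> DataGroup:
    """Bind an observation matrix to a layout as a named group.

    Blank data cells at labelled wells are allowed (missing observations,
    excluded downstream); shape must match the layout exactly.
    """
    mat = _as_cell_matrix(values)
    if mat.shape != layout.shape:
        raise PlateError(
            f"layout mismatch for group {name!r}: data is "
            f"{mat.shape[0]}x{mat.shape[1]}, layout is "
            f"{layout.shape[0]}x{layout.shape[1]}"
        )
    # wells blank in the layout must be blank in the data
    stray = np.isfinite(mat) & ~np.isfinite(layout.cells)
    if stray.any():
        i, j = np.argwhere(stray)[0]
        raise PlateError(
            f"group {name!r} has a value at blank layout well {well_label(i, j)}"
        )
    return DataGroup(
        name=name,
        values=mat,
        outlier_mask=np.zeros(mat.shape, dtype=bool),
        source=source,
    )


def missing_wells(layout: PlateLayout, group: DataGroup) -> list[Well]:
    """Labelled wells with no observation in the group."""
    holes = np.isfinite(layout.cells) & ~np.isfinite(group.values)
    return [Well(int(i), int(j)) for i, j in np.argwhere(holes)]


def replicate_sets(layout: PlateLayout, group: DataGroup) -> list[ReplicateSet]:
    """One ReplicateSet per distinct test value, ascending by test value."""
    if group.shape != layout.shape:
        raise PlateError("group not bound to this layout (shape mismatch)")
    sets = []
    for t, wells in layout.test_index.items():
        members = tuple(
            (w, float(group.values[w.row, w.col]), bool(group.outlier_mask[w.row, w.col]))
            for w in wells
        )
        sets.append(ReplicateSet(group_name=group.name, test_value=t, members=members))
    return sets


def mask_test(group: DataGroup, layout: PlateLayout, test_value: float) -> DataGroup:
    """Mask every well of one test value. Idempotent; values untouched."""
    wells = layout.wells_for(test_value)
    mask = group.outlier_mask.copy()
    for w in wells:
        if np.isfinite(group.values[w.row, w.col]):  # missing cells stay unmasked
            mask[w.row, w.col] = True
    return replace(group, outlier_mask=mask)


def mask_wells(group: DataGroup, wells) -> DataGroup:
    """Mask individual wells (manual outlier marking)."""
    mask = group.outlier_mask.copy()
    for w in wells:
        if np.isfinite(group.values[w.row, w.col]):
            mask[w.row, w.col] = True
    return replace(group, outlier_mask=mask)
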