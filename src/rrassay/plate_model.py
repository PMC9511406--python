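"""96-well plates, layouts, and the round-robin study hierarchy.

The assay runs in standard 8x12 microtiter plates seeded without the outer
wells, so only rows B-G and columns 2-11 (60 wells) can ever carry a role.
The round-robin convention places the curcumin reference series in the three
upper usable rows (B-D, one concentration per column, triplicate down the
rows) and either the chemical controls (reference plate) or one test
material (experimental plate) in the lower rows (E-G).

Canonical on-disk form is a long CSV with one row per well
(``plate_id,lab_id,experiment,assay,row,col,value``); an 8x12 grid export
can be read but not written. Layouts travel in a separate CSV
(``row,col,role,substance,concentration,unit``).
"""

from __future__ import annotations

import csv
import io
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np

ROWS = "ABCDEFGH"
COLUMNS = tuple(range(1, 13))
USABLE_ROWS = "BCDEFG"
USABLE_COLUMNS = tuple(range(2, 12))
REFERENCE_ROWS = "BCD"  # curcumin reference series
TEST_ROWS = "EFG"       # test item or chemical controls

MOLAR = "M"
UG_PER_ML = "ug/ml"
UNITS = (MOLAR, UG_PER_ML)


class WellRole(str, Enum):
    SOLVENT_CONTROL = "solvent_control"
    REFERENCE_COMPOUND = "reference_compound"
    POSITIVE_CONTROL = "positive_control"
    NEGATIVE_CONTROL = "negative_control"
    TEST_ITEM = "test_item"
    UNTREATED_CONTROL = "untreated_control"
    EXCLUDED = "excluded"


#: roles whose wells carry no exposure, hence concentration is exactly 0
ZERO_CONC_ROLES = frozenset(
    {WellRole.SOLVENT_CONTROL, WellRole.UNTREATED_CONTROL, WellRole.EXCLUDED}
)


@dataclass(frozen=True, order=True)
class WellCoord:
    """One well position, row letter A-H and column 1-12."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise ValueError(f"row must be one of {ROWS!r}, got {self.row!r}")
        if self.column not in COLUMNS:
            raise ValueError(f"column must be in 1..12, got {self.column}")

    @property
    def usable(self) -> bool:
        """False for the outer frame (rows A/H, columns 1/12)."""
        return self.row in USABLE_ROWS and self.column in USABLE_COLUMNS

    @classmethod
    def parse(cls, label: str) -> "WellCoord":
        """Parse labels like ``'B2'`` or ``'H12'``."""
        label = label.strip().upper()
        if len(label) < 2:
            raise ValueError(f"cannot parse well label {label!r}")
        return cls(label[0], int(label[1:]))

    def __str__(self) -> str:
        return f"{self.row}{self.column}"


def usable_coords() -> list[WellCoord]:
    """All 60 inner-well coordinates, row-major."""
    return [WellCoord(r, c) for r in USABLE_ROWS for c in USABLE_COLUMNS]


@dataclass(frozen=True)
class WellAssignment:
    """Role, substance, and exposure concentration of one layout well."""

    role: WellRole
    substance: str | None = None
    concentration: float = 0.0
    unit: str = ""

    def __post_init__(self) -> None:
        if self.concentration < 0 or not math.isfinite(self.concentration):
            raise ValueError("concentration must be finite and >= 0")
        if self.role in ZERO_CONC_ROLES:
            if self.concentration != 0:
                raise ValueError(f"{self.role.value} wells must have concentration 0")
        else:
            if self.concentration <= 0:
                raise ValueError(f"{self.role.value} wells must have concentration > 0")
            if self.unit not in UNITS:
                raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
            if not self.substance:
                raise ValueError(f"{self.role.value} wells must name a substance")


@dataclass(frozen=True)
class DilutionSeries:
    """A strictly decreasing concentration series for one substance."""

    substance: str
    concentrations: tuple[float, ...]
    unit: str

    def __post_init__(self) -> None:
        if len(self.concentrations) < 2:
            raise ValueError("a dilution series needs at least 2 points")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")
        if any(a <= b for a, b in zip(self.concentrations, self.concentrations[1:])):
            raise ValueError("concentrations must be strictly decreasing")
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")

    def __len__(self) -> int:
        return len(self.concentrations)


def make_log_dilution_series(
    top: float, bottom: float, n_points: int, substance: str = "", unit: str = MOLAR
) -> DilutionSeries:
    """Geometric (log-spaced) series of ``n_points`` from ``top`` down to ``bottom``.

    ``make_log_dilution_series(1e-4, 1e-8, 5)`` gives exact decade steps;
    9 points over the same range gives a constant half-decade ratio.
    """
    if bottom <= 0 or top <= 0:
        raise ValueError("series bounds must be positive")
    if top <= bottom:
        raise ValueError("top must exceed bottom")
    if n_points < 2:
        raise ValueError("need at least 2 points")
    concs = np.logspace(math.log10(top), math.log10(bottom), n_points)
    return DilutionSeries(substance, tuple(float(c) for c in concs), unit)


PLATE_CLASSES = ("reference", "experimental")


@dataclass
class PlateLayout:
    """Maps usable wells to (role, substance, concentration).

    Invariants enforced: no role on outer wells; reference-compound wells
    only in rows B-D; test/positive/negative wells only in rows E-G; at
    least 2 solvent-control wells; zero concentration exactly on
    solvent/untreated/excluded wells.
    """

    wells: dict[WellCoord, WellAssignment]
    plate_class: str = "experimental"

    def __post_init__(self) -> None:
        if self.plate_class not in PLATE_CLASSES:
            raise ValueError(f"plate_class must be one of {PLATE_CLASSES}")
        for coord, a in self.wells.items():
            if not coord.usable:
                raise ValueError(f"outer well {coord} cannot hold a role")
            if a.role is WellRole.REFERENCE_COMPOUND and coord.row not in REFERENCE_ROWS:
                raise ValueError(f"reference compound outside rows B-D at {coord}")
            if (
                a.role in (WellRole.TEST_ITEM, WellRole.POSITIVE_CONTROL, WellRole.NEGATIVE_CONTROL)
                and coord.row not in TEST_ROWS
            ):
                raise ValueError(f"{a.role.value} outside rows E-G at {coord}")
        if len(self.coords_with_role(WellRole.SOLVENT_CONTROL)) < 2:
            raise ValueError("layout needs at least 2 solvent-control wells")

    def coords_with_role(self, role: WellRole) -> list[WellCoord]:
        return sorted(c for c, a in self.wells.items() if a.role is role)

    def conditions(self, role: WellRole) -> dict[tuple[str, float, str], list[WellCoord]]:
        """Group wells of ``role`` by (substance, concentration, unit)."""
        out: dict[tuple[str, float, str], list[WellCoord]] = {}
        for c, a in sorted(self.wells.items()):
            if a.role is role:
                out.setdefault((a.substance or "", a.concentration, a.unit), []).append(c)
        return out

    @property
    def usable_wells(self) -> list[WellCoord]:
        return sorted(self.wells)


ASSAYS = ("luciferase", "viability")


@dataclass
class PlateRead:
    """One plate's raw signal plus its provenance and layout."""

    lab_id: str
    experiment_index: int
    plate_id: str
    assay: str
    layout: PlateLayout
    signal: dict[WellCoord, float]

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}")
        if self.experiment_index < 1:
            raise ValueError("experiment_index must be >= 1")
        unknown = set(self.signal) - set(self.layout.wells)
        if unknown:
            raise ValueError(f"signal for wells missing from layout: {sorted(unknown)[:4]}")
        for coord, v in self.signal.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"signal at {coord} must be finite and >= 0, got {v}")


@dataclass
class StudyDataset:
    """All plates of a round-robin study.

    Each (lab, experiment) group of luciferase plates must contain exactly
    one reference plate and at least one experimental plate; each lab must
    contribute at least two experiments.
    """

    plates: list[PlateRead]
    materials: list[str] = field(default_factory=list)
    labs: list[str] = field(default_factory=list)
    validate: bool = True

    def __post_init__(self) -> None:
        if not self.labs:
            self.labs = sorted({p.lab_id for p in self.plates if p.assay == "luciferase"})
        if not self.materials:
            self.materials = sorted(
                {
                    a.substance
                    for p in self.plates
                    for a in p.layout.wells.values()
                    if a.role is WellRole.TEST_ITEM and a.substance
                }
            )
        if self.validate:
            self.check_structure()

    def check_structure(self) -> None:
        groups: dict[tuple[str, int], list[PlateRead]] = {}
        for p in self.plates:
            if p.assay == "luciferase":
                groups.setdefault((p.lab_id, p.experiment_index), []).append(p)
        exps_per_lab: dict[str, set[int]] = {}
        for (lab, exp), plates in groups.items():
            n_ref = sum(1 for p in plates if p.layout.plate_class == "reference")
            n_exp = sum(1 for p in plates if p.layout.plate_class == "experimental")
            if n_ref != 1:
                raise ValueError(f"(lab={lab}, experiment={exp}) has {n_ref} reference plates, expected 1")
            if n_exp < 1:
                raise ValueError(f"(lab={lab}, experiment={exp}) has no experimental plates")
            exps_per_lab.setdefault(lab, set()).add(exp)
        for lab in self.labs:
            if len(exps_per_lab.get(lab, ())) < 2:
                raise ValueError(f"lab {lab} has fewer than 2 experiments")

    def luciferase_plates(self) -> list[PlateRead]:
        return [p for p in self.plates if p.assay == "luciferase"]

    def viability_plates(self) -> list[PlateRead]:
        return [p for p in self.plates if p.assay == "viability"]


# ---------------------------------------------------------------------------
# standard round-robin layouts

#: defaults mirror the harmonized protocol: 9-point half-decade curcumin
#: series 1e-4..1e-8 M; 4-point dichlorvos 1e-5..7e-7 M; 4-point mannitol
#: 1e-3..1e-5 M
def default_curcumin_series() -> DilutionSeries:
    return make_log_dilution_series(1e-4, 1e-8, 9, "curcumin", MOLAR)


def default_dichlorvos_series() -> DilutionSeries:
    return make_log_dilution_series(1e-5, 7e-7, 4, "dichlorvos", MOLAR)


def default_mannitol_series() -> DilutionSeries:
    return make_log_dilution_series(1e-3, 1e-5, 4, "mannitol", MOLAR)


def _place_series(
    wells: dict[WellCoord, WellAssignment],
    rows: str,
    series: DilutionSeries,
    role: WellRole,
    start_col: int,
) -> int:
    """Place a series one concentration per column, triplicate down ``rows``.

    Returns the first free column after the block.
    """
    for i, conc in enumerate(series.concentrations):
        col = start_col + i
        if col not in USABLE_COLUMNS:
            raise ValueError(
                f"series for {series.substance!r} does not fit: column {col} is outside the usable area"
            )
        for row in rows:
            wells[WellCoord(row, col)] = WellAssignment(role, series.substance, conc, series.unit)
    return start_col + len(series.concentrations)


def _fill_solvent(wells: dict[WellCoord, WellAssignment], rows: str, start_col: int) -> None:
    for col in range(start_col, USABLE_COLUMNS[-1] + 1):
        for row in rows:
            wells[WellCoord(row, col)] = WellAssignment(WellRole.SOLVENT_CONTROL)


def standard_biorima_layout(
    plate_class: str,
    test_substance: str | None = None,
    test_series: DilutionSeries | None = None,
    curcumin_series: DilutionSeries | None = None,
    dichlorvos_series: DilutionSeries | None = None,
    mannitol_series: DilutionSeries | None = None,
) -> PlateLayout:
    """The harmonized round-robin plate layout.

    Rows B-D carry the curcumin reference series (one concentration per
    column, triplicate); leftover upper columns hold solvent controls.
    Rows E-G carry the positive + negative chemical-control series on a
    reference plate, or the test-item series on an experimental plate;
    leftover lower columns hold solvent controls. Every plate therefore
    carries its own solvent wells for induction-factor normalization.
    """
    if plate_class not in PLATE_CLASSES:
        raise ValueError(f"plate_class must be one of {PLATE_CLASSES}")
    curcumin_series = curcumin_series or default_curcumin_series()
    if len(curcumin_series) > len(USABLE_COLUMNS) - 1:
        raise ValueError("curcumin series leaves no solvent-control column in rows B-D")

    wells: dict[WellCoord, WellAssignment] = {}
    nxt = _place_series(wells, REFERENCE_ROWS, curcumin_series, WellRole.REFERENCE_COMPOUND, USABLE_COLUMNS[0])
    _fill_solvent(wells, REFERENCE_ROWS, nxt)

    if plate_class == "reference":
        dichlorvos_series = dichlorvos_series or default_dichlorvos_series()
        mannitol_series = mannitol_series or default_mannitol_series()
        if len(dichlorvos_series) + len(mannitol_series) > len(USABLE_COLUMNS) - 1:
            raise ValueError("control series leave no solvent-control column in rows E-G")
        nxt = _place_series(wells, TEST_ROWS, dichlorvos_series, WellRole.POSITIVE_CONTROL, USABLE_COLUMNS[0])
        nxt = _place_series(wells, TEST_ROWS, mannitol_series, WellRole.NEGATIVE_CONTROL, nxt)
        _fill_solvent(wells, TEST_ROWS, nxt)
    else:
        if test_series is None or test_substance is None:
            raise ValueError("experimental plate needs test_substance and test_series")
        if len(test_series) > len(USABLE_COLUMNS) - 1:
            raise ValueError(
                f"test series of {len(test_series)} points does not fit the "
                f"{len(USABLE_COLUMNS)} usable columns with a solvent control"
            )
        if test_series.substance != test_substance:
            test_series = DilutionSeries(test_substance, test_series.concentrations, test_series.unit)
        nxt = _place_series(wells, TEST_ROWS, test_series, WellRole.TEST_ITEM, USABLE_COLUMNS[0])
        _fill_solvent(wells, TEST_ROWS, nxt)

    return PlateLayout(wells, plate_class)


def viability_layout(test_substance: str, test_series: DilutionSeries) -> PlateLayout:
    """Layout for a viability (resazurin) plate: untreated controls in rows
    B-D, the test series in triplicate in rows E-G, solvent controls in any
    leftover lower columns."""
    if len(test_series) > len(USABLE_COLUMNS):
        raise ValueError("test series does not fit the usable columns")
    wells: dict[WellCoord, WellAssignment] = {}
    for col in USABLE_COLUMNS:
        for row in REFERENCE_ROWS:
            wells[WellCoord(row, col)] = WellAssignment(WellRole.UNTREATED_CONTROL)
    if test_series.substance != test_substance:
        test_series = DilutionSeries(test_substance, test_series.concentrations, test_series.unit)
    nxt = _place_series(wells, TEST_ROWS, test_series, WellRole.TEST_ITEM, USABLE_COLUMNS[0])
    _fill_solvent(wells, TEST_ROWS, nxt)
    return PlateLayout(wells, "experimental")


# ---------------------------------------------------------------------------
# tabular IO

PLATE_COLUMNS = ["plate_id", "lab_id", "experiment", "assay", "row", "col", "value"]
LAYOUT_COLUMNS = ["row", "col", "role", "substance", "concentration", "unit"]


def _open(path_or_stream, mode: str = "r"):
    if isinstance(path_or_stream, (str, Path)):
        return open(path_or_stream, mode, newline=""), True
    return path_or_stream, False


def read_plate_table(
    path_or_stream,
    layout: PlateLayout,
    *,
    plate_id: str = "plate",
    lab_id: str = "lab",
    experiment_index: int = 1,
    assay: str = "luciferase",
) -> PlateRead:
    """Read one plate from a long-form or 8x12 grid CSV.

    Long form needs at least ``row,col,value`` columns; ``plate_id``,
    ``lab_id``, ``experiment`` and ``assay`` columns override the keyword
    defaults when present. Grid form is 8 rows labelled A-H by the first
    column under a numeric column header. Values in wells the layout does
    not use are dropped with a warning; a usable layout well missing from
    the file is a hard error.
    """
    stream, should_close = _open(path_or_stream)
    try:
        text = stream.read()
    finally:
        if should_close:
            stream.close()
    rows = list(csv.reader(io.StringIO(text)))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise ValueError("empty plate table")

    header = [c.strip().lower() for c in rows[0]]
    records: list[tuple[str, int, str]] = []  # (row, col, raw value)
    meta: dict[str, set[str]] = {k: set() for k in ("plate_id", "lab_id", "experiment", "assay")}
    if "row" in header and ("col" in header or "column" in header) and "value" in header:
        idx = {name: header.index(name) for name in header}
        ccol = idx.get("col", idx.get("column"))
        for r in rows[1:]:
            records.append((r[idx["row"]].strip(), int(r[ccol]), r[idx["value"]].strip()))
            for key in meta:
                if key in idx:
                    meta[key].add(r[idx[key]].strip())
    else:
        # grid form: optional header of column numbers, then A-H rows
        body = rows
        if body[0][0].strip() == "" or body[0][0].strip().lower() in ("row", "well"):
            body = rows[1:]
        for r in body:
            row_label = r[0].strip().upper()
            if row_label not in ROWS:
                raise ValueError(f"grid row label {r[0]!r} is not A-H")
            for j, cell in enumerate(r[1:13], start=1):
                if cell.strip() != "":
                    records.append((row_label, j, cell.strip()))

    for key, vals in meta.items():
        if len(vals) > 1:
            raise ValueError(f"plate table mixes several {key} values: {sorted(vals)}")
    if meta["plate_id"]:
        plate_id = meta["plate_id"].pop()
    if meta["lab_id"]:
        lab_id = meta["lab_id"].pop()
    if meta["experiment"]:
        experiment_index = int(meta["experiment"].pop())
    if meta["assay"]:
        assay = meta["assay"].pop()

    signal: dict[WellCoord, float] = {}
    for row_label, col, raw in records:
        coord = WellCoord(row_label, col)
        try:
            value = float(raw)
        except ValueError:
            raise ValueError(f"non-numeric signal {raw!r} at {coord}") from None
        if value < 0 or not math.isfinite(value):
            raise ValueError(f"negative or non-finite signal {value} at {coord}")
        if coord not in layout.wells:
            warnings.warn(f"dropping value in well {coord} not present in layout", stacklevel=2)
            continue
        signal[coord] = value

    missing = sorted(set(layout.wells) - set(signal))
    if missing:
        raise ValueError(f"plate table missing usable well(s): {', '.join(map(str, missing))}")
    return PlateRead(lab_id, experiment_index, plate_id, assay, layout, signal)


def write_plate_table(plates: PlateRead | Iterable[PlateRead], path_or_stream) -> None:
    """Write one or more plates as the canonical long-form CSV."""
    if isinstance(plates, PlateRead):
        plates = [plates]
    stream, should_close = _open(path_or_stream, "w")
    try:
        w = csv.writer(stream)
        w.writerow(PLATE_COLUMNS)
        for p in plates:
            for coord in sorted(p.signal):
                w.writerow(
                    [p.plate_id, p.lab_id, p.experiment_index, p.assay, coord.row, coord.column,
                     repr(p.signal[coord])]
                )
    finally:
        if should_close:
            stream.close()


def write_layout_table(layout: PlateLayout, path_or_stream, *, plate_id: str | None = None) -> None:
    """Write a layout CSV (optionally tagged with a plate_id column)."""
    stream, should_close = _open(path_or_stream, "w")
    try:
        w = csv.writer(stream)
        cols = (["plate_id"] if plate_id is not None else []) + LAYOUT_COLUMNS + ["plate_class"]
        w.writerow(cols)
        for coord in sorted(layout.wells):
            a = layout.wells[coord]
            row = [coord.row, coord.column, a.role.value, a.substance or "",
                   repr(a.concentration), a.unit, layout.plate_class]
            if plate_id is not None:
                row = [plate_id] + row
            w.writerow(row)
    finally:
        if should_close:
            stream.close()


def read_layout_table(path_or_stream) -> PlateLayout:
    """Read a single-plate layout CSV written by :func:`write_layout_table`."""
    layouts = read_layout_tables(path_or_stream)
    if len(layouts) != 1:
        raise ValueError(f"expected one layout, found plate_ids {sorted(layouts)}")
    return next(iter(layouts.values()))


def read_layout_tables(path_or_stream) -> dict[str, PlateLayout]:
    """Read a layout CSV, keyed by plate_id ('' when the column is absent)."""
    stream, should_close = _open(path_or_stream)
    try:
        reader = csv.DictReader(stream)
        raw: dict[str, tuple[dict[WellCoord, WellAssignment], str]] = {}
        for rec in reader:
            pid = (rec.get("plate_id") or "").strip()
            wells, plate_class = raw.setdefault(pid, ({}, "experimental"))
            role = WellRole(rec["role"].strip())
            conc = float(rec["concentration"] or 0.0)
            assignment = WellAssignment(role, rec.get("substance") or None, conc, (rec.get("unit") or "").strip())
            wells[WellCoord(rec["row"].strip().upper(), int(rec["col"]))] = assignment
            if rec.get("plate_class"):
                raw[pid] = (wells, rec["plate_class"].strip())
    finally:
        if should_close:
            stream.close()
    return {pid: PlateLayout(wells, plate_class) for pid, (wells, plate_class) in raw.items()}


def write_study(dataset: StudyDataset, plates_path, layouts_path) -> None:
    """Write a whole study: one long plates CSV plus a layouts CSV keyed by plate_id."""
    write_plate_table(dataset.plates, plates_path)
    stream, should_close = _open(layouts_path, "w")
    try:
        w = csv.writer(stream)
        w.writerow(["plate_id"] + LAYOUT_COLUMNS + ["plate_class"])
        for p in dataset.plates:
            for coord in sorted(p.layout.wells):
                a = p.layout.wells[coord]
                w.writerow([p.plate_id, coord.row, coord.column, a.role.value,
                            a.substance or "", repr(a.concentration), a.unit, p.layout.plate_class])
    finally:
        if should_close:
            stream.close()


def read_study(plates_path, layouts_path, *, validate: bool = True) -> StudyDataset:
    """Read a study written by :func:`write_study`."""
    layouts = read_layout_tables(layouts_path)
    stream, should_close = _open(plates_path)
    try:
        reader = csv.DictReader(stream)
        groups: dict[tuple[str, str, int, str], dict[WellCoord, float]] = {}
        for rec in reader:
            key = (rec["plate_id"], rec["lab_id"], int(rec["experiment"]), rec["assay"])
            groups.setdefault(key, {})[WellCoord(rec["row"].strip().upper(), int(rec["col"]))] = float(rec["value"])
    finally:
        if should_close:
            stream.close()
    plates = []
    for (pid, lab, exp, assay), signal in groups.items():
        if pid not in layouts:
            raise ValueError(f"no layout for plate_id {pid!r}")
        plates.append(PlateRead(lab, exp, pid, assay, layouts[pid], signal))
    plates.sort(key=lambda p: (p.lab_id, p.experiment_index, p.plate_id))
    return StudyDataset(plates, validate=validate)
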