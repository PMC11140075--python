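"""Workbook (XLSX) and tidy CSV input/output for scoring experiments.

The workbook dialect mirrors a microscopy scoring spreadsheet: sheets
"Conditions", "Blinds", "Test", "A".."Z", "AM Results" and
"Information + Warnings".  Each lettered sheet holds up to 15 counting
tables laid out side by side in 8-column blocks:

    row 1:  Table | <index> | Condition | <code> | Blind | <label> | Override | <1|empty>
    row 2:  Points | <n_points>
    row 3:  Point | EH | H | IH | A | V | S
    row 4+: <point number> | mark cells

A mark cell holds the literal ``1`` when the structure was observed and
is empty otherwise; any other value is rejected on read with the
offending cell named.  "AM Results" and "Information + Warnings" are
derived sheets, recomputed on every write.

The tidy CSV export is long-format: one row per (replicate, structure)
plus a Total row, carrying counts, denominators and RLC percentages.
Importing it reconstructs counts (and the Total union size) but not the
positions of individual marks, the design's variable names, the blind
map, test tables or metadata — the CSV direction is documented as lossy.
"""

from __future__ import annotations

import csv
import datetime
import io
import os
import zipfile
from typing import Optional, Sequence

import numpy as np
import openpyxl
from openpyxl.workbook import Workbook
from openpyxl.worksheet.worksheet import Worksheet

from . import scoring
from .model import (
    DEFAULT_N_POINTS,
    INTRARADICAL_CODES,
    MAX_CONDITIONS,
    MAX_REPLICATES,
    MAX_TEST_TABLES,
    MAX_VARIABLES,
    SHEET_LETTERS,
    TABLES_PER_SHEET,
    TEST_SHEET,
    TOTAL,
    CapacityError,
    CountingTable,
    Experiment,
    ExperimentDesign,
    Structure,
)

__all__ = [
    "write_workbook",
    "read_workbook",
    "export_tidy",
    "import_tidy",
    "WorkbookFormatError",
    "MarkValueError",
]

_ADMIN_SHEETS = ("Conditions", "Blinds", "AM Results", "Information + Warnings")
_MANDATORY_SHEETS = ("Conditions", "Blinds", TEST_SHEET) + tuple(SHEET_LETTERS)
_BLOCK_WIDTH = 8
_STRUCT_HEADERS = tuple(s.code for s in Structure)
_RESULT_COLUMNS = _STRUCT_HEADERS + (TOTAL,)

#: Fixed document timestamp so identical experiments serialize byte-identically.
_EPOCH = datetime.datetime(2000, 1, 1, 0, 0, 0)


class WorkbookFormatError(ValueError):
    """The file is not a valid colonization-scoring workbook."""


class MarkValueError(WorkbookFormatError):
    """A mark cell holds something other than empty or the literal 1."""


# ---------------------------------------------------------------------------
# deterministic XLSX saving


def save_workbook_deterministic(wb: Workbook, destination: str | os.PathLike) -> None:
    """Save a workbook with fixed document and zip timestamps.

    openpyxl stamps both the document properties and every zip member
    with the wall clock; rewriting them against a fixed epoch makes
    repeated exports of identical content byte-identical.
    """
    wb.properties.created = _EPOCH
    wb.properties.modified = _EPOCH
    buf = io.BytesIO()
    wb.save(buf)
    buf.seek(0)
    with zipfile.ZipFile(buf) as src, zipfile.ZipFile(
        destination, "w", zipfile.ZIP_DEFLATED
    ) as dst:
        for name in sorted(src.namelist()):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            dst.writestr(info, src.read(name))


# ---------------------------------------------------------------------------
# writing


def _write_table_block(ws: Worksheet, table: CountingTable) -> None:
    c0 = (table.table_index - 1) * _BLOCK_WIDTH + 1
    ws.cell(row=1, column=c0, value="Table")
    ws.cell(row=1, column=c0 + 1, value=table.table_index)
    ws.cell(row=1, column=c0 + 2, value="Condition")
    if table.condition_code is not None:
        ws.cell(row=1, column=c0 + 3, value=table.condition_code)
    ws.cell(row=1, column=c0 + 4, value="Blind")
    if table.blind_label is not None:
        ws.cell(row=1, column=c0 + 5, value=table.blind_label)
    ws.cell(row=1, column=c0 + 6, value="Override")
    if table.no_fungus_override:
        ws.cell(row=1, column=c0 + 7, value=1)
    ws.cell(row=2, column=c0, value="Points")
    ws.cell(row=2, column=c0 + 1, value=table.n_points)
    ws.cell(row=3, column=c0, value="Point")
    for j, code in enumerate(_STRUCT_HEADERS):
        ws.cell(row=3, column=c0 + 1 + j, value=code)
    for i in range(table.n_points):
        ws.cell(row=4 + i, column=c0, value=i + 1)
        for j in range(len(Structure)):
            if table.marks[i, j]:
                ws.cell(row=4 + i, column=c0 + 1 + j, value=1)


def write_workbook(experiment: Experiment, destination: str | os.PathLike) -> None:
    """Write an experiment as an XLSX workbook in the canonical layout.

    All 26 lettered sheets plus Conditions/Blinds/Test/AM Results/
    Information + Warnings are always present; capacity violations are
    rejected before anything is written.
    """
    experiment.validate()
    wb = Workbook()
    wb.remove(wb.active)

    ws = wb.create_sheet("Conditions")
    ws.append(["Code"] + list(experiment.design.variable_names))
    for code, values in experiment.design.condition_table.items():
        ws.append([code] + list(values))

    ws = wb.create_sheet("Blinds")
    ws.append(["Label", "Condition"])
    for label, code in experiment.design.blind_map.items():
        ws.append([label, code])

    ws = wb.create_sheet(TEST_SHEET)
    for idx in sorted(experiment.test_tables):
        _write_table_block(ws, experiment.test_tables[idx])

    by_sheet: dict[str, list[CountingTable]] = {}
    for table in experiment.tables.values():
        by_sheet.setdefault(table.sheet_letter, []).append(table)
    for letter in SHEET_LETTERS:
        ws = wb.create_sheet(letter)
        for table in sorted(by_sheet.get(letter, []), key=lambda t: t.table_index):
            _write_table_block(ws, table)

    ws = wb.create_sheet("AM Results")
    ws.append(
        ["Sheet", "Table", "Condition", "Blind", "N_scored"]
        + list(_RESULT_COLUMNS)
    )
    for res in scoring.experiment_results(experiment):
        sheet, idx = res.replicate_id
        ws.append(
            [sheet, idx, res.condition_code, res.blind_label, res.n_scored]
            + [res.rlc[c] for c in _RESULT_COLUMNS]
        )

    ws = wb.create_sheet("Information + Warnings")
    ws.append(["Metadata key", "Value"])
    for key in sorted(experiment.metadata):
        ws.append([key, experiment.metadata[key]])
    ws.append([])
    ws.append(["Sheet", "Table", "Warning", "Detail"])
    for rec in scoring.validate_experiment(experiment):
        ws.append([rec.replicate_id[0], rec.replicate_id[1], rec.kind.value, rec.detail])

    save_workbook_deterministic(wb, destination)


# ---------------------------------------------------------------------------
# reading


def _cell_name(sheet: str, row: int, col: int) -> str:
    return f"{sheet}!{openpyxl.utils.get_column_letter(col)}{row}"


def _parse_mark(value, sheet: str, row: int, col: int) -> bool:
    if value is None or value == "":
        return False
    if value == 1 or value == "1":
        return True
    raise MarkValueError(
        f"invalid mark value {value!r} at {_cell_name(sheet, row, col)}; "
        "mark cells must be empty or hold the literal 1"
    )


def _read_table_block(
    ws, sheet_name: str, table_index: int
) -> Optional[CountingTable]:
    c0 = (table_index - 1) * _BLOCK_WIDTH + 1
    if ws.cell(row=1, column=c0).value != "Table":
        return None
    condition = ws.cell(row=1, column=c0 + 3).value
    blind = ws.cell(row=1, column=c0 + 5).value
    override = _parse_mark(
        ws.cell(row=1, column=c0 + 7).value, sheet_name, 1, c0 + 7
    )
    n_points = ws.cell(row=2, column=c0 + 1).value
    if not isinstance(n_points, int) or n_points < 1:
        raise WorkbookFormatError(
            f"bad point count {n_points!r} at {_cell_name(sheet_name, 2, c0 + 1)}"
        )
    marks = np.zeros((n_points, len(Structure)), dtype=bool)
    for i in range(n_points):
        for j in range(len(Structure)):
            marks[i, j] = _parse_mark(
                ws.cell(row=4 + i, column=c0 + 1 + j).value,
                sheet_name,
                4 + i,
                c0 + 1 + j,
            )
    return CountingTable(
        sheet_letter=sheet_name,
        table_index=table_index,
        marks=marks,
        no_fungus_override=override,
        blind_label=str(blind) if blind is not None else None,
        condition_code=str(condition) if condition is not None else None,
    )


def read_workbook(source: str | os.PathLike) -> Experiment:
    """Read a workbook written by :func:`write_workbook` back into an Experiment."""
    try:
        wb = openpyxl.load_workbook(source, data_only=True)
    except Exception as exc:
        raise WorkbookFormatError(f"cannot open {source}: {exc}") from exc
    try:
        missing = [s for s in _MANDATORY_SHEETS if s not in wb.sheetnames]
        if missing:
            raise WorkbookFormatError(
                "not a colonization-scoring workbook: missing sheet(s) "
                + ", ".join(missing)
            )

        ws = wb["Conditions"]
        rows = list(ws.iter_rows(values_only=True))
        if not rows or rows[0][0] != "Code":
            raise WorkbookFormatError("Conditions sheet lacks a 'Code' header")
        header = [c for c in rows[0][1:] if c is not None]
        variable_names = [str(v) for v in header]
        nvar = len(variable_names)
        condition_table: dict[str, tuple[str, ...]] = {}
        for row in rows[1:]:
            if row[0] is None:
                continue
            values = tuple(
                "" if v is None else str(v) for v in row[1 : 1 + nvar]
            )
            condition_table[str(row[0])] = values

        blind_map: dict[str, str] = {}
        for row in wb["Blinds"].iter_rows(min_row=2, values_only=True):
            if row and row[0] is not None:
                blind_map[str(row[0])] = str(row[1])

        design = ExperimentDesign(variable_names, condition_table, blind_map)
        experiment = Experiment(design=design)

        for sheet_name in list(SHEET_LETTERS) + [TEST_SHEET]:
            ws = wb[sheet_name]
            for idx in range(1, TABLES_PER_SHEET + 1):
                table = _read_table_block(ws, sheet_name, idx)
                if table is not None:
                    experiment.add_table(table)

        if "Information + Warnings" in wb.sheetnames:
            rows = list(wb["Information + Warnings"].iter_rows(values_only=True))
            for row in rows[1:]:
                if not row or row[0] is None:
                    break
                if row[0] == "Sheet":
                    break
                experiment.metadata[str(row[0])] = (
                    "" if len(row) < 2 or row[1] is None else str(row[1])
                )
    finally:
        wb.close()

    experiment.validate()
    return experiment


# ---------------------------------------------------------------------------
# tidy CSV


_TIDY_COLUMNS = (
    ["sheet", "table", "condition_code", "blind_label"]
    + [f"variable_{i}" for i in range(1, MAX_VARIABLES + 1)]
    + ["structure", "count", "n_scored", "rlc_percent"]
)


def export_tidy(experiment: Experiment, destination: str | os.PathLike) -> None:
    """Write the long-format CSV: one row per replicate x structure, plus Total.

    Rows are ordered by sheet, table, then structure (EH, H, IH, A, V,
    S, Total).  RLC is printed with one decimal place; test tables are
    not exported.
    """
    experiment.validate()
    design = experiment.design
    with open(destination, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TIDY_COLUMNS)
        for table in experiment.sorted_tables():
            res = scoring.compute_rlc(table)
            counts = table.counts()
            counts[TOTAL] = table.total_count()
            varvals = [""] * MAX_VARIABLES
            if table.condition_code is not None:
                for i, v in enumerate(design.variable_values(table.condition_code)):
                    varvals[i] = v
            for code in _RESULT_COLUMNS:
                writer.writerow(
                    [
                        table.sheet_letter,
                        table.table_index,
                        table.condition_code or "",
                        table.blind_label or "",
                        *varvals,
                        code,
                        counts[code],
                        table.n_points,
                        f"{res.rlc[code]:.1f}",
                    ]
                )


def _marks_from_counts(
    counts: dict[str, int], total: int, n_points: int
) -> np.ndarray:
    """Build a mark grid reproducing per-structure counts and the Total union.

    Intraradical structures are laid down left to right, each overlapping
    the points already covered as much as possible while still growing
    the union to exactly ``total``.  EH and H fill from point 0.
    """
    marks = np.zeros((n_points, len(Structure)), dtype=bool)
    struct_index = {s.code: i for i, s in enumerate(Structure)}
    intr = [c for c in INTRARADICAL_CODES]
    if total > n_points or any(counts[c] > total for c in intr):
        raise ValueError(
            f"inconsistent counts {counts} for union {total} over {n_points} points"
        )
    if total > sum(counts[c] for c in intr):
        raise ValueError(
            f"union {total} exceeds the sum of intraradical counts"
        )
    covered = 0
    for code in intr:
        c = counts[code]
        extend = min(c, total - covered)
        overlap = c - extend
        if overlap > covered:
            raise ValueError(
                f"cannot place {c} marks of {code} with union {total}"
            )
        j = struct_index[code]
        marks[covered - overlap : covered + extend, j] = True
        covered += extend
    for code in ("EH", "H"):
        marks[: counts[code], struct_index[code]] = True
    return marks


def import_tidy(source: str | os.PathLike) -> Experiment:
    """Rebuild an experiment from a tidy CSV export.

    Counts and Total union sizes are reproduced exactly; individual mark
    positions are synthesized (leftmost placement), variable names come
    back as variable_1..variable_4, and the blind map holds only labels
    seen in the file.
    """
    with open(source, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != _TIDY_COLUMNS:
            raise WorkbookFormatError(
                f"unexpected tidy CSV header: {reader.fieldnames}"
            )
        rows = list(reader)

    grouped: dict[tuple[str, int], list[dict]] = {}
    for row in rows:
        key = (row["sheet"], int(row["table"]))
        grouped.setdefault(key, []).append(row)

    condition_table: dict[str, tuple[str, ...]] = {}
    blind_map: dict[str, str] = {}
    nvar = 0
    for key, group in grouped.items():
        row = group[0]
        if row["condition_code"]:
            values = tuple(
                row[f"variable_{i}"] for i in range(1, MAX_VARIABLES + 1)
            )
            used = len(values)
            while used > 1 and values[used - 1] == "":
                used -= 1
            nvar = max(nvar, used)
            condition_table[row["condition_code"]] = values
            if row["blind_label"]:
                blind_map[row["blind_label"]] = row["condition_code"]

    nvar = max(nvar, 1)
    condition_table = {
        code: values[:nvar] for code, values in condition_table.items()
    }
    design = ExperimentDesign(
        [f"variable_{i}" for i in range(1, nvar + 1)], condition_table, blind_map
    )
    experiment = Experiment(design=design)

    for (sheet, idx), group in sorted(grouped.items()):
        counts = {row["structure"]: int(row["count"]) for row in group}
        n_points = int(group[0]["n_scored"])
        total = counts.pop(TOTAL, 0)
        marks = _marks_from_counts(counts, total, n_points)
        override = not marks.any()
        experiment.add_table(
            CountingTable(
                sheet_letter=sheet,
                table_index=idx,
                marks=marks,
                no_fungus_override=override,
                blind_label=group[0]["blind_label"] or None,
                condition_code=group[0]["condition_code"] or None,
            )
        )
    experiment.validate()
    return experiment
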