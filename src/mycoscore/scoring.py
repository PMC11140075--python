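"""Scoring sessions, table validation and percent-colonization arithmetic.

Root length colonization (RLC) for a structure is the percentage of
scored points at which that structure was observed.  The Total is the
percentage of points at which at least one intraradical structure
(intraradical hyphae, arbuscules, vesicles or spores) was observed —
i.e. the union of marked point sets, not the sum of the per-structure
percentages.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    INTRARADICAL_COLUMNS,
    TOTAL,
    CountingTable,
    Experiment,
    ReplicateResult,
    Structure,
)

__all__ = [
    "WarningKind",
    "WarningRecord",
    "ScoringSession",
    "OverrideConflictError",
    "UnresolvedBlindError",
    "apply_entry",
    "validate_table",
    "validate_experiment",
    "compute_rlc",
    "experiment_results",
    "resolve_blinds",
    "average_slides",
    "TOO_FEW_COUNTS_THRESHOLD",
]

#: Default "too few counts?" threshold: tables with 1..T total marks and no
#: override are flagged as possible accidental entries.
TOO_FEW_COUNTS_THRESHOLD = 2


class WarningKind(enum.Enum):
    EMPTY_NO_OVERRIDE = "EMPTY_NO_OVERRIDE"
    TOO_FEW_COUNTS = "TOO_FEW_COUNTS"
    OVERRIDE_CONFLICT = "OVERRIDE_CONFLICT"
    UNASSIGNED_CONDITION = "UNASSIGNED_CONDITION"


@dataclass(frozen=True)
class WarningRecord:
    replicate_id: tuple[str, int]
    kind: WarningKind
    detail: str


class OverrideConflictError(ValueError):
    """No-fungus override requested on a table that already has marks."""


class UnresolvedBlindError(ValueError):
    """A table carries a blind label absent from the design's blind map."""


@dataclass
class ScoringSession:
    """Cursor-driven entry into a counting table.

    Mimics a two-key scoring workflow: mark the current cell, advance to
    the next cell (wrapping from the last structure of a point to the
    first structure of the next point), or retreat.  The session is
    complete once the cursor has advanced past the final cell.
    """

    table: CountingTable
    point: int = 0
    structure: int = 0
    log: list[tuple[int, int, int, str]] = field(default_factory=list)
    _seq: int = 0

    @property
    def cursor(self) -> tuple[int, int]:
        return (self.point, self.structure)

    @property
    def complete(self) -> bool:
        return self.point >= self.table.n_points

    def _record(self, action: str) -> None:
        self.log.append((self._seq, self.point, self.structure, action))
        self._seq += 1


def apply_entry(session: ScoringSession, action: str) -> ScoringSession:
    """Apply one entry action: mark, unmark, advance, retreat or override."""
    table = session.table
    n_struct = len(Structure)
    if action in ("mark", "unmark"):
        if session.complete:
            raise ValueError("table complete: cursor is past the final cell")
        if table.no_fungus_override and action == "mark":
            raise OverrideConflictError(
                "cannot mark a table with the no-fungus override set"
            )
        table.marks[session.point, session.structure] = action == "mark"
    elif action == "advance":
        if not session.complete:
            session.structure += 1
            if session.structure >= n_struct:
                session.structure = 0
                session.point += 1
    elif action == "retreat":
        if session.cursor != (0, 0):
            session.structure -= 1
            if session.structure < 0:
                session.structure = n_struct - 1
                session.point -= 1
    elif action == "override":
        if not table.no_fungus_override and table.marks.any():
            raise OverrideConflictError(
                f"table {table.replicate_id} has "
                f"{int(table.marks.sum())} marks; clear them before overriding"
            )
        table.no_fungus_override = not table.no_fungus_override
    else:
        raise ValueError(f"unknown entry action {action!r}")
    session._record(action)
    return session


def validate_table(
    table: CountingTable, too_few_threshold: int = TOO_FEW_COUNTS_THRESHOLD
) -> list[WarningRecord]:
    """Proofreading checks on one table; returns warnings, never raises."""
    warnings: list[WarningRecord] = []
    rid = table.replicate_id
    total_marks = int(table.marks.sum())
    if table.no_fungus_override and total_marks > 0:
        warnings.append(
            WarningRecord(
                rid,
                WarningKind.OVERRIDE_CONFLICT,
                f"no-fungus override set but {total_marks} marks present",
            )
        )
    elif not table.no_fungus_override:
        if total_marks == 0:
            warnings.append(
                WarningRecord(
                    rid,
                    WarningKind.EMPTY_NO_OVERRIDE,
                    "no marks entered and no-fungus override not set",
                )
            )
        elif total_marks <= too_few_threshold:
            warnings.append(
                WarningRecord(
                    rid,
                    WarningKind.TOO_FEW_COUNTS,
                    f"only {total_marks} mark(s) entered — accidental entry?",
                )
            )
    if (
        (total_marks > 0 or table.no_fungus_override)
        and table.condition_code is None
        and table.blind_label is None
    ):
        warnings.append(
            WarningRecord(
                rid,
                WarningKind.UNASSIGNED_CONDITION,
                "table holds data but no condition or blind label",
            )
        )
    return warnings


def validate_experiment(
    experiment: Experiment, too_few_threshold: int = TOO_FEW_COUNTS_THRESHOLD
) -> list[WarningRecord]:
    """Warnings for every non-test table, in sheet/table order."""
    out: list[WarningRecord] = []
    for table in experiment.sorted_tables():
        out.extend(validate_table(table, too_few_threshold))
    return out


def compute_rlc(table: CountingTable) -> ReplicateResult:
    """Percent root length colonization of each structure for one replicate.

    rlc[s] = 100 * (points where s marked) / n_points;
    rlc[Total] = 100 * (points where any intraradical structure marked) / n_points.
    A no-fungus override yields an all-zero, complete result.
    """
    n = table.n_points
    if n == 0:
        raise ValueError(f"table {table.replicate_id} has zero scored points")
    counts = table.counts()
    rlc = {s.code: 100.0 * counts[s.code] / n for s in Structure}
    rlc[TOTAL] = 100.0 * table.total_count() / n
    complete = table.no_fungus_override or table.marks.any()
    return ReplicateResult(
        replicate_id=table.replicate_id,
        condition_code=table.condition_code,
        n_scored=n,
        rlc=rlc,
        blind_label=table.blind_label,
        complete=bool(complete),
    )


def experiment_results(experiment: Experiment) -> list[ReplicateResult]:
    """Per-replicate results for all non-test tables, in sheet/table order."""
    return [compute_rlc(t) for t in experiment.sorted_tables()]


def resolve_blinds(experiment: Experiment) -> Experiment:
    """Assign condition codes from the blind map; idempotent.

    Blind labels are retained on the tables for provenance.
    """
    unknown: list[tuple[str, int]] = []
    all_tables = list(experiment.tables.values()) + list(
        experiment.test_tables.values()
    )
    for table in all_tables:
        if table.blind_label is not None:
            if table.blind_label not in experiment.design.blind_map:
                unknown.append(table.replicate_id)
    if unknown:
        raise UnresolvedBlindError(
            "blind labels absent from the blind map on tables: "
            + ", ".join(f"{s}:{i}" for s, i in sorted(unknown))
        )
    for table in all_tables:
        if table.blind_label is not None:
            table.condition_code = experiment.design.blind_map[table.blind_label]
    return experiment


def average_slides(
    results: list[ReplicateResult], grouping: dict[object, object]
) -> list[ReplicateResult]:
    """Average multi-slide replicates into one result per plant.

    ``grouping`` maps replicate ids to plant ids.  RLC values are the
    unweighted arithmetic mean over a plant's slides (not pooled
    counts); denominators are summed.  All slides of one plant must
    share a condition code.
    """
    by_plant: dict[object, list[ReplicateResult]] = {}
    order: list[object] = []
    for res in results:
        plant = grouping.get(res.replicate_id, res.replicate_id)
        if plant not in by_plant:
            by_plant[plant] = []
            order.append(plant)
        by_plant[plant].append(res)
    out: list[ReplicateResult] = []
    for plant in order:
        group = by_plant[plant]
        conditions = {r.condition_code for r in group}
        if len(conditions) > 1:
            raise ValueError(
                f"plant {plant!r}: slides carry mixed condition codes {conditions}"
            )
        keys = group[0].rlc.keys()
        mean_rlc = {k: float(np.mean([r.rlc[k] for r in group])) for k in keys}
        out.append(
            ReplicateResult(
                replicate_id=plant,
                condition_code=group[0].condition_code,
                n_scored=sum(r.n_scored for r in group),
                rlc=mean_rlc,
                blind_label=group[0].blind_label,
                complete=all(r.complete for r in group),
            )
        )
    return out
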