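"""Domain model for mycorrhizal colonization scoring experiments.

An experiment is a workbook-shaped container: up to 26 lettered scoring
sheets of 15 counting tables each (one table per biological replicate,
usually one plant), a 15-table "Test" sheet for throwaway counts, a
condition table describing up to 4 experimental variables, and a blind
map for blind-coded scoring.  Each counting table records the presence
or absence of six fungal structures at each of ``n_points`` scored
intersections or fields of view (100 by default).
"""

from __future__ import annotations

import enum
import string
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "Structure",
    "TOTAL",
    "STRUCTURE_CODES",
    "INTRARADICAL_CODES",
    "SHEET_LETTERS",
    "TEST_SHEET",
    "MAX_SHEETS",
    "TABLES_PER_SHEET",
    "MAX_REPLICATES",
    "MAX_TEST_TABLES",
    "MAX_CONDITIONS",
    "MAX_VARIABLES",
    "DEFAULT_N_POINTS",
    "condition_codes",
    "CapacityError",
    "CountingTable",
    "ExperimentDesign",
    "Experiment",
    "ReplicateResult",
]


class Structure(enum.Enum):
    """The six microscopically scoreable fungal structures.

    ``is_intraradical`` marks the structures that live inside the root
    (intraradical hyphae, arbuscules, vesicles, spores); these define
    total root length colonization.  Extraradical hyphae and hyphopodia
    are surface/medium structures and are reported but excluded from
    the Total.
    """

    EH = ("EH", "Extraradical hyphae", False)
    H = ("H", "Hyphopodia", False)
    IH = ("IH", "Intraradical hyphae", True)
    A = ("A", "Arbuscules", True)
    V = ("V", "Vesicles", True)
    S = ("S", "Spores", True)

    def __init__(self, code: str, display_name: str, is_intraradical: bool):
        self.code = code
        self.display_name = display_name
        self.is_intraradical = is_intraradical

    @classmethod
    def from_code(cls, code: str) -> "Structure":
        for s in cls:
            if s.code == code:
                return s
        raise KeyError(f"unknown structure code {code!r}")


#: Derived summary code: percentage of points with >=1 intraradical structure.
TOTAL = "Total"

STRUCTURE_CODES: tuple[str, ...] = tuple(s.code for s in Structure)
INTRARADICAL_CODES: tuple[str, ...] = tuple(
    s.code for s in Structure if s.is_intraradical
)
#: Column indices (into the mark grid) of the intraradical structures.
INTRARADICAL_COLUMNS: tuple[int, ...] = tuple(
    i for i, s in enumerate(Structure) if s.is_intraradical
)

SHEET_LETTERS: str = string.ascii_uppercase
TEST_SHEET = "Test"

MAX_SHEETS = 26
TABLES_PER_SHEET = 15
MAX_REPLICATES = MAX_SHEETS * TABLES_PER_SHEET  # 390
MAX_TEST_TABLES = 15
MAX_CONDITIONS = 78
MAX_VARIABLES = 4
DEFAULT_N_POINTS = 100


def condition_codes(n: Optional[int] = None) -> Iterator[str]:
    """Yield condition codes in canonical order: A..Z, AA..AZ, BA..BZ.

    Exactly 78 codes exist (26 single letters + 52 two-letter codes).
    """
    count = 0
    for letter in SHEET_LETTERS:
        if n is not None and count >= n:
            return
        yield letter
        count += 1
    for first in "AB":
        for second in SHEET_LETTERS:
            if n is not None and count >= n:
                return
            yield first + second
            count += 1


class CapacityError(ValueError):
    """A container limit (sheets, tables, conditions, variables) was exceeded."""


@dataclass
class CountingTable:
    """One biological replicate's presence/absence grid.

    ``marks`` is an ``n_points x 6`` boolean array; column order follows
    :class:`Structure` (EH, H, IH, A, V, S).  ``no_fungus_override``
    records an explicitly scored all-absent sample, distinguishing a
    true zero from a table that was never scored.
    """

    sheet_letter: str
    table_index: int
    marks: np.ndarray
    no_fungus_override: bool = False
    blind_label: Optional[str] = None
    condition_code: Optional[str] = None

    @classmethod
    def empty(
        cls,
        sheet_letter: str,
        table_index: int,
        n_points: int = DEFAULT_N_POINTS,
        **kwargs,
    ) -> "CountingTable":
        return cls(
            sheet_letter,
            table_index,
            np.zeros((n_points, len(Structure)), dtype=bool),
            **kwargs,
        )

    def __post_init__(self) -> None:
        self.marks = np.asarray(self.marks, dtype=bool)
        if self.marks.ndim != 2 or self.marks.shape[1] != len(Structure):
            raise ValueError(
                f"marks must have shape (n_points, {len(Structure)}); "
                f"got {self.marks.shape}"
            )

    @property
    def n_points(self) -> int:
        return self.marks.shape[0]

    @property
    def replicate_id(self) -> tuple[str, int]:
        return (self.sheet_letter, self.table_index)

    def counts(self) -> dict[str, int]:
        """Per-structure mark counts (column sums)."""
        sums = self.marks.sum(axis=0)
        return {s.code: int(sums[i]) for i, s in enumerate(Structure)}

    def total_count(self) -> int:
        """Points at which at least one intraradical structure was marked."""
        return int(self.marks[:, list(INTRARADICAL_COLUMNS)].any(axis=1).sum())

    def validate(self) -> None:
        if not (
            self.sheet_letter == TEST_SHEET
            or (len(self.sheet_letter) == 1 and self.sheet_letter in SHEET_LETTERS)
        ):
            raise ValueError(f"invalid sheet letter {self.sheet_letter!r}")
        if not 1 <= self.table_index <= TABLES_PER_SHEET:
            raise ValueError(
                f"table_index must be in [1, {TABLES_PER_SHEET}]; "
                f"got {self.table_index}"
            )
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if self.no_fungus_override and self.marks.any():
            raise ValueError(
                f"table {self.replicate_id}: no-fungus override set but marks present"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountingTable):
            return NotImplemented
        return (
            self.sheet_letter == other.sheet_letter
            and self.table_index == other.table_index
            and self.no_fungus_override == other.no_fungus_override
            and self.blind_label == other.blind_label
            and self.condition_code == other.condition_code
            and self.marks.shape == other.marks.shape
            and bool(np.array_equal(self.marks, other.marks))
        )


@dataclass
class ExperimentDesign:
    """Experimental variables, condition codes and the blind map.

    ``condition_table`` maps each short condition code (see
    :func:`condition_codes`) to a tuple of variable values, one per
    entry of ``variable_names``.  ``blind_map`` maps opaque scoring
    labels to condition codes; it is resolved after scoring so the
    scorer never sees the conditions.
    """

    variable_names: list[str]
    condition_table: dict[str, tuple[str, ...]]
    blind_map: dict[str, str] = field(default_factory=dict)

    @classmethod
    def create(
        cls,
        variable_names: list[str],
        combinations: list[tuple[str, ...]],
        blind_map: Optional[dict[str, str]] = None,
    ) -> "ExperimentDesign":
        """Build a design assigning canonical codes to the combinations in order."""
        codes = list(condition_codes(len(combinations)))
        if len(codes) < len(combinations):
            raise CapacityError(
                f"at most {MAX_CONDITIONS} condition combinations are supported; "
                f"got {len(combinations)}"
            )
        table = {c: tuple(combo) for c, combo in zip(codes, combinations)}
        return cls(list(variable_names), table, dict(blind_map or {}))

    def variable_values(self, code: str) -> tuple[str, ...]:
        return self.condition_table[code]

    def validate(self) -> None:
        if not 1 <= len(self.variable_names) <= MAX_VARIABLES:
            raise CapacityError(
                f"a design carries 1 to {MAX_VARIABLES} variables; "
                f"got {len(self.variable_names)}"
            )
        if len(set(self.variable_names)) != len(self.variable_names):
            raise ValueError("variable names must be unique")
        if len(self.condition_table) > MAX_CONDITIONS:
            raise CapacityError(
                f"at most {MAX_CONDITIONS} condition codes are supported; "
                f"got {len(self.condition_table)}"
            )
        nvar = len(self.variable_names)
        for code, values in self.condition_table.items():
            if len(values) != nvar:
                raise ValueError(
                    f"condition {code!r} has {len(values)} values for "
                    f"{nvar} variables"
                )
        for label, code in self.blind_map.items():
            if code not in self.condition_table:
                raise ValueError(
                    f"blind label {label!r} maps to unknown condition {code!r}"
                )


@dataclass
class Experiment:
    """A full scoring experiment: design, replicate tables, test tables."""

    design: ExperimentDesign
    tables: dict[tuple[str, int], CountingTable] = field(default_factory=dict)
    test_tables: dict[int, CountingTable] = field(default_factory=dict)
    metadata: dict[str, str] = field(default_factory=dict)

    def add_table(self, table: CountingTable) -> None:
        if table.sheet_letter == TEST_SHEET:
            if len(self.test_tables) >= MAX_TEST_TABLES and (
                table.table_index not in self.test_tables
            ):
                raise CapacityError(
                    f"the Test sheet holds at most {MAX_TEST_TABLES} tables"
                )
            self.test_tables[table.table_index] = table
        else:
            key = table.replicate_id
            if key not in self.tables and len(self.tables) >= MAX_REPLICATES:
                raise CapacityError(
                    f"an experiment holds at most {MAX_REPLICATES} replicate tables"
                )
            self.tables[key] = table

    def sorted_tables(self) -> list[CountingTable]:
        return [self.tables[k] for k in sorted(self.tables)]

    def next_free_slot(self) -> tuple[str, int]:
        """First unused (sheet, table) slot in scoring order A1..A15, B1..."""
        for letter in SHEET_LETTERS:
            for idx in range(1, TABLES_PER_SHEET + 1):
                if (letter, idx) not in self.tables:
                    return (letter, idx)
        raise CapacityError(f"all {MAX_REPLICATES} replicate slots are in use")

    def validate(self) -> None:
        self.design.validate()
        if len(self.tables) > MAX_REPLICATES:
            raise CapacityError(
                f"an experiment holds at most {MAX_REPLICATES} replicate tables; "
                f"got {len(self.tables)}"
            )
        if len(self.test_tables) > MAX_TEST_TABLES:
            raise CapacityError(
                f"the Test sheet holds at most {MAX_TEST_TABLES} tables; "
                f"got {len(self.test_tables)}"
            )
        per_sheet: dict[str, int] = {}
        for (letter, idx), table in self.tables.items():
            per_sheet[letter] = per_sheet.get(letter, 0) + 1
            if table.replicate_id != (letter, idx):
                raise ValueError(
                    f"table keyed {(letter, idx)} reports id {table.replicate_id}"
                )
            table.validate()
            if (
                table.condition_code is not None
                and table.condition_code not in self.design.condition_table
            ):
                raise ValueError(
                    f"table {table.replicate_id} references unknown condition "
                    f"{table.condition_code!r}"
                )
            if table.blind_label is not None and table.condition_code is not None:
                # a table may carry both only as the result of blind
                # resolution, in which case they must agree with the map
                mapped = self.design.blind_map.get(table.blind_label)
                if mapped != table.condition_code:
                    raise ValueError(
                        f"table {table.replicate_id}: blind label "
                        f"{table.blind_label!r} and condition "
                        f"{table.condition_code!r} disagree with the blind map"
                    )
        for letter, n in per_sheet.items():
            if n > TABLES_PER_SHEET:
                raise CapacityError(
                    f"sheet {letter} holds {n} tables; the limit is "
                    f"{TABLES_PER_SHEET} per sheet"
                )
        for idx, table in self.test_tables.items():
            table.validate()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Experiment):
            return NotImplemented
        return (
            self.design == other.design
            and self.tables == other.tables
            and self.test_tables == other.test_tables
            and self.metadata == other.metadata
        )


@dataclass
class ReplicateResult:
    """Per-replicate percent root length colonization, one value per structure.

    ``rlc`` maps each structure code plus ``Total`` to a percentage in
    [0, 100]; each percentage is 100 * count / n_scored, so
    rlc * n_scored / 100 recovers the integer count.  ``complete`` is
    False for tables that were neither scored nor overridden.
    """

    replicate_id: object
    condition_code: Optional[str]
    n_scored: int
    rlc: dict[str, float]
    blind_label: Optional[str] = None
    complete: bool = True

    def validate(self) -> None:
        for code, value in self.rlc.items():
            if not 0.0 <= value <= 100.0:
                raise ValueError(
                    f"replicate {self.replicate_id}: rlc[{code}] = {value} "
                    "outside [0, 100]"
                )
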