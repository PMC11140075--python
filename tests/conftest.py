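import numpy as np
import pytest

from mycoscore import (
    CountingTable,
    Experiment,
    ExperimentDesign,
    Structure,
)

STRUCT_COL = {s.code: i for i, s in enumerate(Structure)}


def make_table(
    sheet="A",
    index=1,
    n_points=100,
    marks_at=None,
    override=False,
    condition=None,
    blind=None,
):
    """Build a table with marks at {structure_code: [point indices]}."""
    marks = np.zeros((n_points, len(Structure)), dtype=bool)
    for code, points in (marks_at or {}).items():
        marks[list(points), STRUCT_COL[code]] = True
    return CountingTable(
        sheet_letter=sheet,
        table_index=index,
        marks=marks,
        no_fungus_override=override,
        condition_code=condition,
        blind_label=blind,
    )


def random_table(rng, sheet="A", index=1, n_points=None, condition=None):
    n = n_points or int(rng.integers(1, 30))
    marks = rng.random((n, len(Structure))) < 0.3
    return CountingTable(
        sheet_letter=sheet,
        table_index=index,
        marks=marks,
        condition_code=condition,
    )


@pytest.fixture
def design():
    return ExperimentDesign.create(
        ["Genotype", "Treatment"],
        [("WT", "Mock"), ("WT", "AMF"), ("mutant", "AMF")],
    )


@pytest.fixture
def small_experiment(design):
    exp = Experiment(design=design, metadata={"title": "demo", "scorer": "EJ"})
    exp.add_table(
        make_table("A", 1, 10, {"IH": range(4), "A": range(2)}, condition="A")
    )
    exp.add_table(
        make_table("A", 2, 10, {"IH": range(6), "V": [4, 5, 6]}, condition="B")
    )
    exp.add_table(make_table("B", 1, 10, override=True, condition="C"))
    exp.add_table(make_table("Test", 3, 5, {"EH": [0]}))
    return exp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
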