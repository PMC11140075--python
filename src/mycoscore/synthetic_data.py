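"""Synthetic colonization experiments with known ground truth.

The generative model treats each scored point as an independent
Bernoulli trial per structure, with biologically motivated nesting:
intraradical hyphae (IH) are the entry event, and arbuscules, vesicles
and spores occur only at points that carry IH (so A, V, S marked points
are always subsets of IH marked points, and the Total union equals the
IH percentage in expectation).  Extraradical hyphae and hyphopodia are
independent surface events.  Between-plant heterogeneity enters as a
plant-level random effect on the logit of the IH probability with
standard deviation ``sigma``; ``sigma = 0`` gives pure binomial
sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model import (
    DEFAULT_N_POINTS,
    MAX_REPLICATES,
    SHEET_LETTERS,
    TABLES_PER_SHEET,
    TOTAL,
    CapacityError,
    CountingTable,
    Experiment,
    ExperimentDesign,
    Structure,
)
from . import scoring

__all__ = [
    "ConditionModel",
    "SimulationSpec",
    "simulate_experiment",
    "slide_grouping",
    "recover_parameters",
    "default_spec",
]

_COL = {s.code: i for i, s in enumerate(Structure)}


@dataclass
class ConditionModel:
    """Per-point structure probabilities for one condition.

    ``p_ih`` is the base intraradical colonization probability; the
    ``p_*_given_ih`` values are conditional on IH at the same point.
    ``p_eh`` and ``p_h`` are independent marginal probabilities.
    """

    p_ih: float
    p_a_given_ih: float = 0.0
    p_v_given_ih: float = 0.0
    p_s_given_ih: float = 0.0
    p_eh: float = 0.0
    p_h: float = 0.0

    def validate(self) -> None:
        for name in (
            "p_ih", "p_a_given_ih", "p_v_given_ih", "p_s_given_ih", "p_eh", "p_h",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")

    def expected_rlc(self) -> dict[str, float]:
        """Expected RLC percentages under sigma = 0."""
        return {
            "EH": 100.0 * self.p_eh,
            "H": 100.0 * self.p_h,
            "IH": 100.0 * self.p_ih,
            "A": 100.0 * self.p_ih * self.p_a_given_ih,
            "V": 100.0 * self.p_ih * self.p_v_given_ih,
            "S": 100.0 * self.p_ih * self.p_s_given_ih,
            TOTAL: 100.0 * self.p_ih,
        }


@dataclass
class SimulationSpec:
    """A complete synthetic-experiment recipe."""

    design: ExperimentDesign
    models: dict[str, ConditionModel]
    sigma: float = 0.0
    replicates_per_condition: int = 6
    slides_per_plant: int = 1
    n_points: int = DEFAULT_N_POINTS
    seed: int = 0
    assign_blinds: bool = False
    metadata: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        self.design.validate()
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.replicates_per_condition < 1 or self.slides_per_plant < 1:
            raise ValueError("replicate and slide counts must be >= 1")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        for code in self.models:
            if code not in self.design.condition_table:
                raise ValueError(f"model given for unknown condition {code!r}")
            self.models[code].validate()
        for code in self.design.condition_table:
            if code not in self.models:
                raise ValueError(f"no structure model for condition {code!r}")
        total = (
            len(self.models)
            * self.replicates_per_condition
            * self.slides_per_plant
        )
        if total > MAX_REPLICATES:
            raise CapacityError(
                f"spec requires {total} tables; the container holds at most "
                f"{MAX_REPLICATES}"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationSpec":
        variables = list(data["variables"])
        combos = [tuple(map(str, c)) for c in data["conditions"]]
        design = ExperimentDesign.create(variables, combos)
        models = {}
        model_list = data["models"]
        for code, m in zip(design.condition_table, model_list):
            models[code] = ConditionModel(**m)
        return cls(
            design=design,
            models=models,
            sigma=float(data.get("sigma", 0.0)),
            replicates_per_condition=int(data.get("replicates_per_condition", 6)),
            slides_per_plant=int(data.get("slides_per_plant", 1)),
            n_points=int(data.get("n_points", DEFAULT_N_POINTS)),
            seed=int(data.get("seed", 0)),
            assign_blinds=bool(data.get("assign_blinds", False)),
            metadata={str(k): str(v) for k, v in data.get("metadata", {}).items()},
        )

    @classmethod
    def from_file(cls, path: str) -> "SimulationSpec":
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


def default_spec(seed: int = 0) -> SimulationSpec:
    """A realistic three-condition default: mock inoculation, a wild type
    and an impaired mutant, six plants each, 100 points per plant."""
    design = ExperimentDesign.create(
        ["Genotype", "Treatment"],
        [("WT", "Mock"), ("WT", "AMF"), ("mutant", "AMF")],
    )
    models = {
        "A": ConditionModel(p_ih=0.0),
        "B": ConditionModel(
            p_ih=0.55, p_a_given_ih=0.6, p_v_given_ih=0.25,
            p_s_given_ih=0.05, p_eh=0.35, p_h=0.08,
        ),
        "C": ConditionModel(
            p_ih=0.2, p_a_given_ih=0.3, p_v_given_ih=0.15,
            p_s_given_ih=0.02, p_eh=0.25, p_h=0.05,
        ),
    }
    return SimulationSpec(
        design=design, models=models, sigma=0.4,
        replicates_per_condition=6, seed=seed,
        metadata={"title": "synthetic demonstration experiment"},
    )


def _adjusted_p(p: float, effect: float) -> float:
    if p <= 0.0 or p >= 1.0 or effect == 0.0:
        return p
    return float(expit(logit(p) + effect))


def _slot(k: int) -> tuple[str, int]:
    return (SHEET_LETTERS[k // TABLES_PER_SHEET], k % TABLES_PER_SHEET + 1)


def simulate_experiment(spec: SimulationSpec) -> Experiment:
    """Draw a full experiment from the spec's generative model.

    Tables fill sheets in scoring order (A1..A15, B1, ...), grouped by
    condition then plant then slide.  Tables with no marks at all get
    the no-fungus override (they were "scored" and found empty).  With
    ``assign_blinds`` the tables carry shuffled blind labels instead of
    condition codes, and the design's blind map holds the key.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    design = ExperimentDesign(
        list(spec.design.variable_names),
        dict(spec.design.condition_table),
        dict(spec.design.blind_map),
    )
    experiment = Experiment(design=design, metadata=dict(spec.metadata))

    n_tables = (
        len(spec.models) * spec.replicates_per_condition * spec.slides_per_plant
    )
    blind_labels: Optional[list[str]] = None
    if spec.assign_blinds:
        labels = [f"X{i + 1:03d}" for i in range(n_tables)]
        blind_labels = list(rng.permutation(labels))

    k = 0
    for code, model in spec.models.items():
        for _plant in range(spec.replicates_per_condition):
            effect = rng.normal(0.0, spec.sigma) if spec.sigma > 0 else 0.0
            p_ih = _adjusted_p(model.p_ih, effect)
            for _slide in range(spec.slides_per_plant):
                marks = np.zeros((spec.n_points, len(Structure)), dtype=bool)
                ih = rng.random(spec.n_points) < p_ih
                marks[:, _COL["IH"]] = ih
                for struct, p_cond in (
                    ("A", model.p_a_given_ih),
                    ("V", model.p_v_given_ih),
                    ("S", model.p_s_given_ih),
                ):
                    marks[:, _COL[struct]] = ih & (
                        rng.random(spec.n_points) < p_cond
                    )
                marks[:, _COL["EH"]] = rng.random(spec.n_points) < model.p_eh
                marks[:, _COL["H"]] = rng.random(spec.n_points) < model.p_h
                sheet, idx = _slot(k)
                table = CountingTable(
                    sheet_letter=sheet,
                    table_index=idx,
                    marks=marks,
                    no_fungus_override=not marks.any(),
                )
                if blind_labels is not None:
                    table.blind_label = blind_labels[k]
                    design.blind_map[table.blind_label] = code
                else:
                    table.condition_code = code
                experiment.add_table(table)
                k += 1
    experiment.validate()
    return experiment


def slide_grouping(spec: SimulationSpec) -> dict[tuple[str, int], str]:
    """Map each simulated table's (sheet, index) to its plant id.

    Plant ids are ``<condition>-p<k>``; useful with
    :func:`mycoscore.scoring.average_slides` when ``slides_per_plant > 1``.
    """
    grouping: dict[tuple[str, int], str] = {}
    k = 0
    for code in spec.models:
        for plant in range(spec.replicates_per_condition):
            for _slide in range(spec.slides_per_plant):
                grouping[_slot(k)] = f"{code}-p{plant + 1}"
                k += 1
    return grouping


def recover_parameters(experiment: Experiment, spec: SimulationSpec) -> pd.DataFrame:
    """Compare observed mean RLC per condition/structure with expectations.

    Expectations are exact for ``sigma = 0`` (e.g. E[RLC_A] =
    100 * p_ih * p_a_given_ih); for ``sigma > 0`` they are the
    zero-effect values and the bias column then reflects the random
    effect's nonlinearity.  ``mc_se`` is the Monte-Carlo standard error
    of the observed mean; ``within_3se`` flags |bias| <= 3 * mc_se.
    """
    if spec.assign_blinds:
        experiment = scoring.resolve_blinds(experiment)
    results = scoring.experiment_results(experiment)
    rows = []
    for code, model in spec.models.items():
        expected = model.expected_rlc()
        cond_results = [r for r in results if r.condition_code == code]
        for struct, exp_value in expected.items():
            values = np.array([r.rlc[struct] for r in cond_results])
            observed = float(values.mean())
            mc_se = (
                float(values.std(ddof=1) / np.sqrt(len(values)))
                if len(values) > 1
                else float("nan")
            )
            bias = observed - exp_value
            rows.append(
                {
                    "condition": code,
                    "structure": struct,
                    "expected": exp_value,
                    "observed": observed,
                    "bias": bias,
                    "mc_se": mc_se,
                    "n": len(values),
                    "within_3se": bool(
                        mc_se > 0 and abs(bias) <= 3 * mc_se
                    ) or bias == 0.0,
                }
            )
    return pd.DataFrame(rows)
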