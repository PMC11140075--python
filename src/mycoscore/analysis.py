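"""Filtering, pairwise statistics and group annotation for colonization data.

Replicate-level RLC percentages are filtered down to the conditions and
structures of interest, organized by up to three faceting variables, and
compared with pairwise tests:

* ``TukeyHSD`` — studentized-range pairwise comparisons after a one-way
  ANOVA; family-wise error is controlled by the studentized range
  itself, so no further p-value adjustment applies.
* ``Wilcoxon`` — pairwise two-sample rank-sum (Mann-Whitney) tests,
  followed by a p-value adjustment across the pair family.
* ``Dunn`` — the Kruskal-Wallis post-hoc z comparisons on mean ranks
  (with tie correction), followed by a p-value adjustment.

Group annotations are either a compact letter display (two groups share
a letter exactly when their adjusted p >= alpha) or asterisks relative
to a reference condition.  Tests run independently within each
structure x facet cell — no pooling across facets.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .model import (
    STRUCTURE_CODES,
    TOTAL,
    ExperimentDesign,
    ReplicateResult,
)

__all__ = [
    "AnalysisSelection",
    "Comparison",
    "PairwiseStatsReport",
    "FILTERABLE_STRUCTURES",
    "ADJUST_METHODS",
    "EmptySelectionError",
    "filter_results",
    "adjust_pvalues",
    "dunn_test",
    "run_pairwise_test",
    "run_pairwise_tests",
    "compact_letter_display",
    "asterisk_annotation",
    "export_stats",
    "TEST_REGISTRY",
]

#: Structure filter codes exposed to analysis (hyphopodia carry no code
#: and are reachable only through the tidy export / AM Results sheet).
FILTERABLE_STRUCTURES = (TOTAL, "EH", "IH", "A", "V", "S")

_ADJUST_MAP = {
    "holm": "holm",
    "bonferroni": "bonferroni",
    "BH": "fdr_bh",
    "BY": "fdr_by",
    "hochberg": "simes-hochberg",
}
ADJUST_METHODS = tuple(_ADJUST_MAP) + ("none",)

_SIDEDNESS = ("two-sided", "less", "greater")


class EmptySelectionError(ValueError):
    """The selection filtered away every row."""


@dataclass
class AnalysisSelection:
    """Which conditions, structures and facet variables to analyse.

    Include and exclude lists are mutually exclusive per axis; an
    include list wins when given, otherwise everything minus the
    excluded codes is kept.
    """

    condition_include: Optional[Sequence[str]] = None
    condition_exclude: Optional[Sequence[str]] = None
    structure_include: Optional[Sequence[str]] = None
    structure_exclude: Optional[Sequence[str]] = None
    facet_1: Optional[str] = None
    facet_2: Optional[str] = None
    facet_3: Optional[str] = None

    @property
    def facets(self) -> list[str]:
        return [f for f in (self.facet_1, self.facet_2, self.facet_3) if f]

    def validate(self, design: ExperimentDesign) -> None:
        if self.condition_include is not None and self.condition_exclude is not None:
            raise ValueError(
                "condition_include and condition_exclude are mutually exclusive"
            )
        if self.structure_include is not None and self.structure_exclude is not None:
            raise ValueError(
                "structure_include and structure_exclude are mutually exclusive"
            )
        for codes in (self.condition_include, self.condition_exclude):
            for code in codes or []:
                if code not in design.condition_table:
                    raise ValueError(f"unknown condition code {code!r}")
        for codes in (self.structure_include, self.structure_exclude):
            for code in codes or []:
                if code not in FILTERABLE_STRUCTURES:
                    raise ValueError(
                        f"unknown structure code {code!r}; valid codes: "
                        + ", ".join(FILTERABLE_STRUCTURES)
                    )
        facets = self.facets
        if len(set(facets)) != len(facets):
            raise ValueError("facet variables must be distinct")
        for name in facets:
            if name not in design.variable_names:
                raise ValueError(
                    f"facet variable {name!r} is not one of the design's "
                    f"variables {design.variable_names}"
                )


def filter_results(
    results: Sequence[ReplicateResult],
    selection: AnalysisSelection,
    design: ExperimentDesign,
) -> pd.DataFrame:
    """Long table of (condition, structure, value) rows for the selection.

    Facet variable values are resolved from each row's condition code.
    Replicates without a condition assignment are dropped (resolve
    blinds first).
    """
    selection.validate(design)
    if selection.condition_include is not None:
        conditions = set(selection.condition_include)
    else:
        conditions = set(design.condition_table) - set(
            selection.condition_exclude or []
        )
    if selection.structure_include is not None:
        structures = [
            s for s in FILTERABLE_STRUCTURES if s in set(selection.structure_include)
        ]
    else:
        structures = [
            s
            for s in FILTERABLE_STRUCTURES
            if s not in set(selection.structure_exclude or [])
        ]

    rows = []
    for res in results:
        if res.condition_code is None or res.condition_code not in conditions:
            continue
        values = design.variable_values(res.condition_code)
        facet_values = {
            name: values[design.variable_names.index(name)]
            for name in selection.facets
        }
        for code in structures:
            rows.append(
                {
                    "replicate": res.replicate_id,
                    "condition": res.condition_code,
                    "structure": code,
                    "value": res.rlc[code],
                    **facet_values,
                }
            )
    if not rows:
        raise EmptySelectionError(
            "no replicates match the selection (conditions "
            f"{sorted(conditions)}, structures {structures})"
        )
    columns = ["replicate", "condition", "structure", "value"] + selection.facets
    return pd.DataFrame(rows, columns=columns)


def adjust_pvalues(p: Sequence[float], method: str = "holm") -> np.ndarray:
    """Adjust a family of p-values; ``none`` is the identity."""
    arr = np.asarray(p, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return arr.copy()
    if method not in _ADJUST_MAP:
        raise ValueError(
            f"unknown adjustment {method!r}; choose from {ADJUST_METHODS}"
        )
    if arr.size == 0:
        return arr.copy()
    return multipletests(arr, method=_ADJUST_MAP[method])[1]


# ---------------------------------------------------------------------------
# tests


@dataclass(frozen=True)
class Comparison:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adj: float


@dataclass
class PairwiseStatsReport:
    """All pairwise comparisons within one structure x facet cell."""

    test_name: str
    sidedness: str
    adjust_method: str
    alpha: float
    groups: list[str]
    comparisons: list[Comparison]
    annotation: Optional[dict[str, str]] = None
    annotation_style: Optional[str] = None
    notes: list[str] = field(default_factory=list)

    def pair_p(self, a: str, b: str) -> float:
        for c in self.comparisons:
            if {c.group_a, c.group_b} == {a, b}:
                return c.p_adj
        raise KeyError(f"no comparison for pair ({a}, {b})")


def _group_arrays(
    table: pd.DataFrame, order: Optional[Sequence[str]] = None
) -> dict[str, np.ndarray]:
    groups = {}
    seen = list(dict.fromkeys(table["condition"]))
    for g in order or seen:
        vals = table.loc[table["condition"] == g, "value"].to_numpy(dtype=float)
        if len(vals):
            groups[g] = vals
    return groups


def dunn_test(
    groups: dict[str, np.ndarray], sidedness: str = "two-sided"
) -> list[tuple[str, str, float, float]]:
    """Kruskal-Wallis post-hoc z comparisons on mean ranks, tie-corrected.

    For groups i, j over the pooled mid-ranks of all N observations:

        z = (rbar_i - rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    with tie correction T = sum(t^3 - t) / (12 (N - 1)) over tie-group
    sizes t.  Returns (group_a, group_b, z, raw p) per pair.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        n = len(groups[g])
        mean_ranks[g] = ranks[start : start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    out = []
    for a, b in itertools.combinations(names, 2):
        denom = np.sqrt(base_var * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
        if denom == 0:
            z = 0.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / denom
        if sidedness == "two-sided":
            p = 2.0 * stats.norm.sf(abs(z))
        elif sidedness == "greater":
            p = float(stats.norm.sf(z))
        elif sidedness == "less":
            p = float(stats.norm.cdf(z))
        else:
            raise ValueError(f"unknown sidedness {sidedness!r}")
        out.append((a, b, float(z), min(1.0, float(p))))
    return out


def _wilcoxon_pairs(
    groups: dict[str, np.ndarray], sidedness: str
) -> tuple[list[tuple[str, str, float, float]], list[str]]:
    out, notes = [], []
    for a, b in itertools.combinations(groups, 2):
        x, y = groups[a], groups[b]
        if np.ptp(np.concatenate([x, y])) == 0:
            out.append((a, b, len(x) * len(y) / 2.0, 1.0))
            notes.append(f"{a} vs {b}: all values tied; p set to 1")
            continue
        res = stats.mannwhitneyu(x, y, alternative=sidedness)
        out.append((a, b, float(res.statistic), float(res.pvalue)))
        if len(np.unique(np.concatenate([x, y]))) < len(x) + len(y):
            notes.append(f"{a} vs {b}: ties present; normal approximation used")
    return out, notes


def _tukey_pairs(
    groups: dict[str, np.ndarray], alpha: float
) -> list[tuple[str, str, float, float]]:
    names = list(groups)
    values = np.concatenate([groups[g] for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    if np.ptp(values) == 0:
        # zero contrast, zero variance: every pair is indistinguishable
        return [(a, b, 0.0, 1.0) for a, b in itertools.combinations(names, 2)]
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    out = []
    pairs = list(itertools.combinations(sorted(names), 2))
    for (a, b), diff, p in zip(pairs, res.meandiffs, res.pvalues):
        if np.isnan(p):
            # degenerate within-group variance: decide by the mean contrast
            p = 1.0 if diff == 0 else 0.0
        out.append((a, b, float(diff), float(p)))
    return out


TEST_REGISTRY: dict[str, Callable] = {}


def run_pairwise_test(
    table: pd.DataFrame,
    test: str,
    *,
    sidedness: str = "two-sided",
    adjust_method: Optional[str] = None,
    alpha: float = 0.05,
    group_order: Optional[Sequence[str]] = None,
) -> PairwiseStatsReport:
    """Pairwise comparisons of conditions within one structure x facet cell.

    ``table`` must hold one structure (and one facet level combination);
    use :func:`run_pairwise_tests` to sweep a filtered table cell by
    cell.  Defaults: Holm adjustment for the rank tests, none for
    TukeyHSD (which controls the family-wise rate itself).
    """
    if test not in ("TukeyHSD", "Wilcoxon", "Dunn"):
        raise ValueError(f"unknown test {test!r}; choose TukeyHSD, Wilcoxon or Dunn")
    if sidedness not in _SIDEDNESS:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if test == "TukeyHSD":
        if sidedness != "two-sided":
            raise ValueError("one-sided TukeyHSD is not supported")
        if adjust_method not in (None, "none"):
            raise ValueError(
                "TukeyHSD applies its own studentized-range family-wise "
                "control; adjust_method must be omitted or 'none'"
            )
        adjust_method = "none"
    elif adjust_method is None:
        adjust_method = "holm"

    groups = _group_arrays(table, group_order)
    if len(groups) < 2:
        raise ValueError(f"need at least 2 groups; got {sorted(groups)}")
    if test == "TukeyHSD":
        for g, vals in groups.items():
            if len(vals) < 2:
                raise ValueError(f"TukeyHSD needs >=2 observations per group ({g})")

    notes: list[str] = []
    if test == "TukeyHSD":
        raw = _tukey_pairs(groups, alpha)
        adjusted = [p for *_, p in raw]
    elif test == "Wilcoxon":
        raw, notes = _wilcoxon_pairs(groups, sidedness)
        adjusted = adjust_pvalues([p for *_, p in raw], adjust_method)
    else:
        raw = dunn_test(groups, sidedness)
        adjusted = adjust_pvalues([p for *_, p in raw], adjust_method)

    comparisons = [
        Comparison(a, b, stat, p, float(padj))
        for (a, b, stat, p), padj in zip(raw, adjusted)
    ]
    return PairwiseStatsReport(
        test_name=test,
        sidedness=sidedness,
        adjust_method=adjust_method,
        alpha=alpha,
        groups=list(groups),
        comparisons=comparisons,
        notes=notes,
    )


def run_pairwise_tests(
    table: pd.DataFrame,
    test: str,
    *,
    sidedness: str = "two-sided",
    adjust_method: Optional[str] = None,
    alpha: float = 0.05,
    group_order: Optional[Sequence[str]] = None,
    stat_display: str = "none",
    reference: Optional[str] = None,
) -> dict[tuple, PairwiseStatsReport]:
    """Run the pairwise test independently in every structure x facet cell.

    Returns a mapping from (structure, facet values...) to the cell's
    report; annotations are attached per ``stat_display`` ("letters",
    "asterisks" or "none").
    """
    facet_cols = [
        c for c in table.columns
        if c not in ("replicate", "condition", "structure", "value")
    ]
    reports: dict[tuple, PairwiseStatsReport] = {}
    keys = table[["structure"] + facet_cols].drop_duplicates()
    for _, keyrow in keys.iterrows():
        mask = table["structure"] == keyrow["structure"]
        for c in facet_cols:
            mask &= table[c] == keyrow[c]
        cell = table[mask]
        if cell["condition"].nunique() < 2:
            # a facet level containing a single condition has no pairs
            continue
        report = run_pairwise_test(
            cell,
            test,
            sidedness=sidedness,
            adjust_method=adjust_method,
            alpha=alpha,
            group_order=group_order,
        )
        if stat_display == "letters":
            report.annotation = compact_letter_display(report.comparisons, alpha)
            report.annotation_style = "letters"
        elif stat_display == "asterisks":
            report.annotation = asterisk_annotation(report.comparisons, reference)
            report.annotation_style = "asterisks"
        reports[tuple(keyrow)] = report
    return reports


# ---------------------------------------------------------------------------
# annotation


def compact_letter_display(
    comparisons: Sequence[Comparison],
    alpha: float = 0.05,
    order: Optional[Sequence[str]] = None,
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share at least one letter exactly when their adjusted p
    is >= alpha.  Letters are assigned a, b, ... in first-use order
    following the groups' display order.
    """
    seen: dict[tuple[str, str], float] = {}
    groups: list[str] = list(order) if order else []
    for c in comparisons:
        for g in (c.group_a, c.group_b):
            if g not in groups:
                groups.append(g)
        key = tuple(sorted((c.group_a, c.group_b)))
        if key in seen and seen[key] != c.p_adj:
            raise ValueError(
                f"pair {key} listed twice with conflicting adjusted p "
                f"({seen[key]} vs {c.p_adj})"
            )
        seen[key] = c.p_adj
    for a, b in itertools.combinations(groups, 2):
        if tuple(sorted((a, b))) not in seen:
            raise ValueError(f"comparisons do not cover the pair ({a}, {b})")

    # insert-and-absorb over sets of mutually non-significant groups
    classes: list[set[str]] = [set(groups)]
    for (a, b), p in seen.items():
        if p >= alpha:
            continue
        new_classes: list[set[str]] = []
        for cls in classes:
            if a in cls and b in cls:
                new_classes.append(cls - {a})
                new_classes.append(cls - {b})
            else:
                new_classes.append(cls)
        # absorb: keep only the maximal, distinct classes
        classes = []
        for cls in new_classes:
            if not cls or any(cls < other for other in new_classes):
                continue
            if cls not in classes:
                classes.append(cls)

    # order classes by the display position of their first group
    def class_key(cls: set[str]) -> tuple:
        return tuple(sorted(groups.index(g) for g in cls))

    classes.sort(key=class_key)
    letters = "abcdefghijklmnopqrstuvwxyz"
    if len(classes) > len(letters):
        raise ValueError("more letter classes than available letters")
    out = {g: "" for g in groups}
    for letter, cls in zip(letters, classes):
        for g in groups:
            if g in cls:
                out[g] += letter
    return out


def asterisk_annotation(
    comparisons: Sequence[Comparison],
    reference: str,
    alpha_levels: tuple[float, float, float] = (0.05, 0.01, 0.001),
) -> dict[str, str]:
    """Annotate each group vs the reference: ns / * / ** / *** (strict <).

    The reference group itself is annotated with an empty string.
    """
    groups: list[str] = []
    for c in comparisons:
        for g in (c.group_a, c.group_b):
            if g not in groups:
                groups.append(g)
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not among {groups}")
    weak, mid, strong = sorted(alpha_levels, reverse=True)
    out = {reference: ""}
    for c in comparisons:
        if reference not in (c.group_a, c.group_b):
            continue
        other = c.group_b if c.group_a == reference else c.group_a
        p = c.p_adj
        if p < strong:
            out[other] = "***"
        elif p < mid:
            out[other] = "**"
        elif p < weak:
            out[other] = "*"
        else:
            out[other] = "ns"
    return out


# ---------------------------------------------------------------------------
# export


def _sheet_name(key: tuple) -> str:
    name = "_".join(str(k) for k in key if str(k) != "")
    return name[:31] or "results"


def export_stats(
    reports: dict[tuple, PairwiseStatsReport], destination: str | os.PathLike
) -> None:
    """Save the statistics reports: one sheet (or CSV block) per cell.

    Destination ``.xlsx`` gives one worksheet per structure x facet
    cell; ``.csv`` mirrors the same content in a single stacked file.
    Output is deterministic: re-exporting identical reports yields a
    byte-identical file.
    """
    if not reports:
        raise ValueError("no reports to export")
    dest = str(destination)
    if dest.endswith(".csv"):
        frames = []
        for key, rep in reports.items():
            df = _report_frame(rep)
            df.insert(0, "cell", _sheet_name(key))
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(dest, index=False)
        return

    from openpyxl import Workbook

    from .format_io import save_workbook_deterministic

    wb = Workbook()
    wb.remove(wb.active)
    for key, rep in reports.items():
        ws = wb.create_sheet(_sheet_name(key))
        ws.append(["Test", rep.test_name])
        ws.append(["Sidedness", rep.sidedness])
        ws.append(["Adjustment", rep.adjust_method])
        ws.append(["Alpha", rep.alpha])
        ws.append([])
        ws.append(["Group A", "Group B", "Statistic", "p (raw)", "p (adjusted)"])
        for c in rep.comparisons:
            ws.append([c.group_a, c.group_b, c.statistic, c.p_raw, c.p_adj])
        if rep.annotation:
            ws.append([])
            ws.append(["Group", "Annotation"])
            for g in rep.groups:
                ws.append([g, rep.annotation.get(g, "")])
        if rep.notes:
            ws.append([])
            for note in rep.notes:
                ws.append(["Note", note])
    save_workbook_deterministic(wb, dest)


def _report_frame(rep: PairwiseStatsReport) -> pd.DataFrame:
    rows = [
        {
            "test": rep.test_name,
            "sidedness": rep.sidedness,
            "adjustment": rep.adjust_method,
            "group_a": c.group_a,
            "group_b": c.group_b,
            "statistic": c.statistic,
            "p_raw": c.p_raw,
            "p_adjusted": c.p_adj,
            "annotation_a": (rep.annotation or {}).get(c.group_a, ""),
            "annotation_b": (rep.annotation or {}).get(c.group_b, ""),
        }
        for c in rep.comparisons
    ]
    return pd.DataFrame(rows)
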