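import itertools
import math

import numpy as np
import openpyxl
import pandas as pd
import pytest

from mycoscore import (
    AnalysisSelection,
    Comparison,
    EmptySelectionError,
    adjust_pvalues,
    asterisk_annotation,
    compact_letter_display,
    compute_rlc,
    dunn_test,
    export_stats,
    filter_results,
    run_pairwise_test,
    run_pairwise_tests,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# independent Dunn oracle: manual mid-ranks (sort-based, no scipy), textbook
# z formula from rank sums


def _manual_midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def dunn_oracle(groups):
    labels = []
    pooled = []
    for name, vals in groups.items():
        for v in vals:
            labels.append(name)
            pooled.append(float(v))
    ranks = _manual_midranks(pooled)
    n = len(pooled)
    mean_rank = {}
    for name in groups:
        rs = [r for r, lab in zip(ranks, labels) if lab == name]
        mean_rank[name] = sum(rs) / len(rs)
    tie_sizes = {}
    for v in pooled:
        tie_sizes[v] = tie_sizes.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in tie_sizes.values()) / (12.0 * (n - 1))
    out = {}
    for a, b in itertools.combinations(groups, 2):
        var = (n * (n + 1) / 12.0 - tie_term) * (
            1.0 / len(groups[a]) + 1.0 / len(groups[b])
        )
        z = (mean_rank[a] - mean_rank[b]) / math.sqrt(var)
        p = math.erfc(abs(z) / math.sqrt(2.0))  # two-sided normal tail
        out[(a, b)] = (z, min(1.0, p))
    return out


def make_results(value_map, n=100):
    """ReplicateResults with given Total/IH percentages per condition."""
    results = []
    k = 0
    for condition, values in value_map.items():
        for v in values:
            t = make_table(
                "ABCDEF"[k // 15], k % 15 + 1, n,
                {"IH": range(int(round(v * n / 100)))}, condition=condition,
            )
            results.append(compute_rlc(t))
            k += 1
    return results


class TestFilterResults:
    def test_include_restricts(self, design):
        results = make_results({"A": [10, 20], "B": [30], "C": [40]})
        sel = AnalysisSelection(
            condition_include=["A", "B"], structure_include=["Total", "A"]
        )
        table = filter_results(results, sel, design)
        assert set(table["condition"]) == {"A", "B"}
        assert set(table["structure"]) == {"Total", "A"}
        assert len(table) == 3 * 2

    def test_exclude_equals_complement_include(self, design):
        results = make_results({"A": [10], "B": [30], "C": [40]})
        ex = filter_results(
            results, AnalysisSelection(condition_exclude=["C"]), design
        )
        inc = filter_results(
            results, AnalysisSelection(condition_include=["A", "B"]), design
        )
        pd.testing.assert_frame_equal(
            ex.reset_index(drop=True), inc.reset_index(drop=True)
        )

    def test_include_and_exclude_mutually_exclusive(self, design):
        sel = AnalysisSelection(condition_include=["A"], condition_exclude=["B"])
        with pytest.raises(ValueError, match="mutually exclusive"):
            sel.validate(design)

    def test_unknown_codes_named(self, design):
        with pytest.raises(ValueError, match="QQ"):
            AnalysisSelection(condition_include=["QQ"]).validate(design)
        with pytest.raises(ValueError, match="'H'"):
            AnalysisSelection(structure_include=["H"]).validate(design)

    def test_facets_resolved_from_condition(self, design):
        results = make_results({"A": [10], "B": [30]})
        sel = AnalysisSelection(
            structure_include=["Total"], facet_1="Genotype", facet_2="Treatment"
        )
        table = filter_results(results, sel, design)
        row = table[table["condition"] == "B"].iloc[0]
        assert row["Genotype"] == "WT" and row["Treatment"] == "AMF"

    def test_empty_selection_error(self, design):
        results = make_results({"A": [10]})
        with pytest.raises(EmptySelectionError):
            filter_results(
                results, AnalysisSelection(condition_include=["B"]), design
            )


class TestAdjustPvalues:
    def test_worked_triples(self):
        p = [0.01, 0.02, 0.03]
        assert np.allclose(adjust_pvalues(p, "bonferroni"), [0.03, 0.06, 0.09])
        assert np.allclose(adjust_pvalues(p, "holm"), [0.03, 0.04, 0.04])
        assert np.allclose(adjust_pvalues(p, "BH"), [0.03, 0.03, 0.03])

    def test_none_is_identity(self, rng):
        p = rng.random(10)
        assert np.array_equal(adjust_pvalues(p, "none"), p)

    @pytest.mark.parametrize("method", ["holm", "bonferroni", "BH", "BY", "hochberg"])
    def test_bounded_and_dominates_raw(self, method, rng):
        for _ in range(20):
            p = rng.random(8)
            adj = adjust_pvalues(p, method)
            assert np.all(adj >= p - 1e-12)
            assert np.all(adj <= 1.0) and np.all(adj >= 0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "holm")


class TestDunn:
    def test_matches_independent_oracle(self, rng):
        """Dunn z and raw p agree with a hand-coded rank-sum oracle to 1e-10."""
        for _ in range(50):
            k = int(rng.integers(2, 5))
            groups = {
                f"g{i}": rng.normal(rng.uniform(-1, 1), 1, int(rng.integers(3, 9)))
                for i in range(k)
            }
            if rng.random() < 0.5:  # force ties sometimes
                groups = {g: np.round(v, 0) for g, v in groups.items()}
            expected = dunn_oracle({g: list(v) for g, v in groups.items()})
            got = dunn_test(groups)
            for a, b, z, p in got:
                ez, ep = expected[(a, b)]
                assert abs(z - ez) < 1e-10
                assert abs(p - ep) < 1e-10


class TestRunPairwiseTest:
    def _table(self, value_map):
        rows = []
        for cond, vals in value_map.items():
            for i, v in enumerate(vals):
                rows.append(
                    {"replicate": (cond, i), "condition": cond,
                     "structure": "Total", "value": float(v)}
                )
        return pd.DataFrame(rows)

    def test_identical_groups_wilcoxon_p_one(self):
        table = self._table({"A": [1, 2, 3], "B": [1, 2, 3]})
        report = run_pairwise_test(table, "Wilcoxon")
        assert report.comparisons[0].p_adj == 1.0

    def test_tukey_zero_contrast(self):
        table = self._table({"A": [0, 0, 0, 0], "B": [0, 0, 0, 0]})
        report = run_pairwise_test(table, "TukeyHSD")
        c = report.comparisons[0]
        assert c.statistic == 0.0 and c.p_adj == 1.0

    def test_group_order_invariance(self, rng):
        vals = {g: list(rng.normal(i, 1, 6)) for i, g in enumerate("ABC")}
        t1 = self._table(vals)
        t2 = self._table({g: vals[g] for g in reversed("ABC")})
        for test in ("Wilcoxon", "Dunn", "TukeyHSD"):
            r1 = run_pairwise_test(t1, test)
            r2 = run_pairwise_test(t2, test)
            p1 = {frozenset((c.group_a, c.group_b)): c.p_adj
                  for c in r1.comparisons}
            p2 = {frozenset((c.group_a, c.group_b)): c.p_adj
                  for c in r2.comparisons}
            assert p1.keys() == p2.keys()
            for key in p1:
                assert p1[key] == pytest.approx(p2[key], abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            run_pairwise_test(self._table({"A": [1, 2]}), "Wilcoxon")

    def test_one_sided_tukey_unsupported(self):
        table = self._table({"A": [1, 2, 3], "B": [4, 5, 6]})
        with pytest.raises(ValueError, match="one-sided"):
            run_pairwise_test(table, "TukeyHSD", sidedness="greater")

    def test_tukey_rejects_extra_adjustment(self):
        table = self._table({"A": [1, 2, 3], "B": [4, 5, 6]})
        with pytest.raises(ValueError, match="studentized"):
            run_pairwise_test(table, "TukeyHSD", adjust_method="holm")

    def test_per_cell_independence(self, design):
        # tests run per structure; each cell has its own family
        results = make_results({"A": [10, 12, 14], "B": [50, 55, 60]})
        table = filter_results(
            results,
            AnalysisSelection(structure_include=["Total", "IH"]),
            design,
        )
        reports = run_pairwise_tests(table, "Wilcoxon")
        assert set(reports) == {("Total",), ("IH",)}
        assert all(len(r.comparisons) == 1 for r in reports.values())


def _comparisons_from_pattern(groups, significant):
    return [
        Comparison(a, b, 0.0, 0.001 if (a, b) in significant else 0.5,
                   0.001 if (a, b) in significant else 0.5)
        for a, b in itertools.combinations(groups, 2)
    ]


class TestCompactLetterDisplay:
    def test_full_separation(self):
        groups = ["A", "B", "C"]
        comps = _comparisons_from_pattern(
            groups, {("A", "B"), ("A", "C"), ("B", "C")}
        )
        assert compact_letter_display(comps) == {"A": "a", "B": "b", "C": "c"}

    def test_single_class(self):
        comps = _comparisons_from_pattern(["A", "B", "C"], set())
        assert compact_letter_display(comps) == {"A": "a", "B": "a", "C": "a"}

    def test_chain_pattern(self):
        comps = _comparisons_from_pattern(["A", "B", "C"], {("A", "C")})
        assert compact_letter_display(comps) == {"A": "a", "B": "ab", "C": "b"}

    def test_conflicting_duplicate_pair(self):
        comps = [
            Comparison("A", "B", 0.0, 0.5, 0.5),
            Comparison("B", "A", 0.0, 0.01, 0.01),
        ]
        with pytest.raises(ValueError, match="conflicting"):
            compact_letter_display(comps)

    def test_missing_pair_rejected(self):
        comps = [Comparison("A", "B", 0.0, 0.5, 0.5)]
        comps.append(Comparison("A", "C", 0.0, 0.5, 0.5))
        with pytest.raises(ValueError, match="cover"):
            compact_letter_display(comps)

    def test_share_letter_iff_not_significant_exhaustive(self):
        """Exhaustive significance patterns for 3-5 groups."""
        for k in range(3, 6):
            groups = [f"g{i}" for i in range(k)]
            pairs = list(itertools.combinations(groups, 2))
            for bits in range(2 ** len(pairs)):
                significant = {
                    pairs[i] for i in range(len(pairs)) if bits >> i & 1
                }
                letters = compact_letter_display(
                    _comparisons_from_pattern(groups, significant)
                )
                for a, b in pairs:
                    shared = set(letters[a]) & set(letters[b])
                    assert bool(shared) == ((a, b) not in significant), (
                        f"k={k} pattern={significant} letters={letters}"
                    )

    def test_share_letter_iff_not_significant_random_large(self, rng):
        """Seeded random patterns for 6-8 groups."""
        for k in (6, 7, 8):
            groups = [f"g{i}" for i in range(k)]
            pairs = list(itertools.combinations(groups, 2))
            for _ in range(120):
                significant = {p for p in pairs if rng.random() < 0.4}
                letters = compact_letter_display(
                    _comparisons_from_pattern(groups, significant)
                )
                for a, b in pairs:
                    shared = set(letters[a]) & set(letters[b])
                    assert bool(shared) == ((a, b) not in significant)


class TestAsteriskAnnotation:
    def _comps(self, p_by_group, reference="A"):
        return [
            Comparison(reference, g, 0.0, p, p) for g, p in p_by_group.items()
        ]

    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.2, "ns"),
            (0.05, "ns"),  # strict inequality at the boundary
            (0.049, "*"),
            (0.01, "*"),
            (0.009, "**"),
            (0.001, "**"),
            (0.0005, "***"),
        ],
    )
    def test_thresholds(self, p, expected):
        ann = asterisk_annotation(self._comps({"B": p}), "A")
        assert ann["B"] == expected
        assert ann["A"] == ""

    def test_missing_reference(self):
        with pytest.raises(ValueError, match="reference"):
            asterisk_annotation(self._comps({"B": 0.5}), "Z")


class TestExportStats:
    def _reports(self, design):
        results = make_results(
            {"A": [10, 12, 14], "B": [50, 55, 60], "C": [20, 25, 30]}
        )
        table = filter_results(
            results,
            AnalysisSelection(structure_include=["Total", "A"]),
            design,
        )
        return run_pairwise_tests(table, "Dunn", stat_display="letters")

    def test_sheet_per_cell_and_rows(self, design, tmp_path):
        reports = self._reports(design)
        out = tmp_path / "stats.xlsx"
        export_stats(reports, out)
        wb = openpyxl.load_workbook(out)
        assert set(wb.sheetnames) == {"Total", "A"}
        ws = wb["Total"]
        header_row = 6
        assert ws.cell(header_row, 1).value == "Group A"
        n_pairs = 0
        r = header_row + 1
        while ws.cell(r, 1).value:
            n_pairs += 1
            r += 1
        assert n_pairs == 3  # C(3, 2)

    def test_reexport_byte_identical(self, design, tmp_path):
        reports = self._reports(design)
        p1, p2 = tmp_path / "s1.xlsx", tmp_path / "s2.xlsx"
        export_stats(reports, p1)
        export_stats(reports, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_csv_mirror(self, design, tmp_path):
        reports = self._reports(design)
        out = tmp_path / "stats.csv"
        export_stats(reports, out)
        df = pd.read_csv(out)
        assert set(df["cell"]) == {"Total", "A"}
        assert len(df) == 6  # 2 cells x 3 pairs
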