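"""Filter simulated results and compare conditions pairwise.

Runs the Kruskal-Wallis post-hoc (Dunn) z test with Holm adjustment on
total colonization and arbuscule levels, then prints compact letter
groups: conditions sharing a letter are not significantly different at
alpha = 0.05.
"""

from mycoscore import (
    AnalysisSelection,
    default_spec,
    experiment_results,
    filter_results,
    run_pairwise_tests,
    simulate_experiment,
)

experiment = simulate_experiment(default_spec(seed=42))
results = experiment_results(experiment)

selection = AnalysisSelection(structure_include=["Total", "A"])
table = filter_results(results, selection, experiment.design)

reports = run_pairwise_tests(
    table, "Dunn", adjust_method="holm", stat_display="letters"
)
for (structure,), report in reports.items():
    print(f"\n{structure} — {report.test_name}, {report.adjust_method} "
          f"adjustment:")
    for c in report.comparisons:
        print(f"  {c.group_a} vs {c.group_b}:  z = {c.statistic:6.3f}  "
              f"p = {c.p_raw:.4f}  p.adj = {c.p_adj:.4f}")
    print("  letters:", ", ".join(
        f"{g}={report.annotation[g]}" for g in report.groups))
# Condition A is the uncolonized mock control, B the wild type, C the
# impaired mutant; with 6 plants per condition the mock separates from
# the wild type while the mutant may share a letter with either.
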