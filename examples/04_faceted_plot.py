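"""Render the simulated experiment as annotated, faceted bar plots.

One panel per structure, conditions on the x axis, bars at the group
mean with standard-error whiskers, individual datapoints overlaid, and
compact letter groups above the bars.  Writes colonization.png plus a
JSON sidecar echoing the configuration.
"""

from mycoscore import (
    AnalysisSelection,
    PlotConfig,
    default_spec,
    experiment_results,
    filter_results,
    make_plot,
    run_pairwise_tests,
    simulate_experiment,
)

experiment = simulate_experiment(default_spec(seed=42))
table = filter_results(
    experiment_results(experiment),
    AnalysisSelection(structure_include=["Total", "IH", "A"]),
    experiment.design,
)
reports = run_pairwise_tests(table, "Dunn", stat_display="letters")

config = PlotConfig(
    graph_type="Facets",
    graph_object="bars",
    show_datapoints=True,
    palette="viridis",
    output="colonization.png",
)
make_plot(table, {key: r.annotation for key, r in reports.items()}, config)
print("wrote colonization.png and colonization.png.json")
# Bar heights equal group means of percent colonization; the letters
# above the bars summarize the Holm-adjusted Dunn comparisons.
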