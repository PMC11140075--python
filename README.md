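# mycoscore

Recording, scoring, statistics and plotting for arbuscular mycorrhizal
(AM) root colonization assays.

Microscopic quantification of AM colonization — scoring the presence or
absence of fungal structures at root intersections or fields of view —
remains the gold standard for studying this symbiosis, but recording
and processing the data is tedious. `mycoscore` provides, for plant and
fungal biologists running such assays:

* a **workbook-shaped container** for presence/absence scoring of the
  six structures (extraradical hyphae EH, hyphopodia H, intraradical
  hyphae IH, arbuscules A, vesicles V, spores S): 26 lettered sheets of
  15 counting tables (390 biological replicates), a throwaway "Test"
  sheet, a condition table for up to 4 experimental variables and 78
  letter-coded combinations, and a blind map for observer-blind
  scoring — saved as XLSX or exported as tidy long-format CSV;
* automatic **percent root length colonization** (RLC) per replicate,
  with proofreading warnings (empty table, suspiciously few counts,
  override conflicts, unassigned conditions) and a no-fungus override
  to distinguish true zeros from unscored tables;
* a **statistics layer**: condition/structure filtering, up to three
  facet variables, pairwise TukeyHSD / Wilcoxon rank-sum / Dunn
  (Kruskal–Wallis post-hoc) tests with Holm, Bonferroni, BH, BY or
  Hochberg adjustment, compact letter displays and asterisk annotation;
* **faceted bar/box plots** with datapoints, sample sizes and
  statistical annotations; and
* a seeded **simulator** with known ground truth for end-to-end testing.

## The core quantities

For a replicate scored at `n` points, the RLC of structure `s` is

    RLC_s = 100 · (#points where s observed) / n

and the total colonization is the union percentage over the
intraradical structures,

    RLC_Total = 100 · (#points where any of {IH, A, V, S} observed) / n ,

so `Total` is bounded below by every intraradical structure and above
by their sum. Pairwise Dunn comparisons between conditions use the
tie-corrected z on pooled mid-ranks,

    z_ij = (r̄_i − r̄_j) / sqrt( (N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j) ) ,

followed by the chosen p-value adjustment; TukeyHSD controls the
family-wise rate through the studentized range itself. Compact letter
displays are built by insert-and-absorb so that two conditions share a
letter exactly when their adjusted p ≥ α.

## Worked example

`examples/03_pairwise_statistics.py` simulates the default experiment
(a mock-inoculated control A, a colonized wild type B and an impaired
mutant C; 6 plants each, 100 points per plant) and compares total
colonization:

```
Total — Dunn, holm adjustment:
  A vs B:  z = -3.970  p = 0.0001  p.adj = 0.0002
  A vs C:  z = -1.985  p = 0.0472  p.adj = 0.0943
  B vs C:  z =  1.985  p = 0.0472  p.adj = 0.0943
  letters: A=a, B=b, C=ab
```

The mock control differs from the wild type (adjusted p = 0.0002, no
shared letter), while the mutant, intermediate at this sample size,
shares a letter with both. `examples/04_faceted_plot.py` renders the
same data as annotated bar panels; the other examples cover
programmatic scoring and workbook round trips.

A shell workflow is available too:

```sh
mycoscore simulate --out exp.xlsx --seed 42
mycoscore validate exp.xlsx
mycoscore analyze exp.xlsx --structure-include Total,A --graph-stat-test Dunn \
    --stat-output --stat-file stats.xlsx
mycoscore plot exp.xlsx --structure-include Total --graph-object boxes \
    --graph-file fig.png
```

`mycoscore analyze --help` lists how the workbook-analysis variable
names (Condition_Include, Graph_Stat_Test, …) map onto options.

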