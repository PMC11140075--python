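# Methods

## Scoring model and colonization arithmetic

A counting table records one biological replicate: a boolean grid of
`n_points × 6` presence/absence marks, column order EH, H, IH, A, V, S.
The default denominator is 100 points (fields of view or eyepiece
intersections), stored per table so that experiments may mix
denominators. Percent root length colonization is `100·count/n` per
structure; `Total` is the percentage of points carrying at least one
*intraradical* structure (IH, A, V, S) — a union over rows, not a sum
of percentages. Extraradical hyphae and hyphopodia are surface/medium
structures and are excluded from `Total`; this is the convention of
magnified-intersection scoring, where total colonization measures
internal fungal occupancy. `Total` therefore satisfies
`max_s RLC_s ≤ RLC_Total ≤ min(100, Σ_s RLC_s)` over the intraradical
structures, and is invariant to permutation of point order.

The no-fungus override records a fully scored, truly empty sample; it
forces an all-zero, *complete* result, whereas a table with neither
marks nor override is flagged incomplete and produces an
`EMPTY_NO_OVERRIDE` warning. The "too few counts" warning fires at
1..T total marks with T = 2 by default (configurable): one or two
isolated keystrokes are plausible accidents, while genuinely sparse
samples typically still accumulate several marks over 100 points.

Multi-slide replicates are combined by `average_slides` as the
unweighted mean of slide percentages (denominators are summed for
bookkeeping). Mean-of-percentages equals the pooled-count percentage
only when slide denominators are equal; with unequal denominators the
two differ and the mean-of-percentages convention is used deliberately,
weighting slides equally as sampling units.

## Workbook dialect

The canonical workbook holds sheets `Conditions`, `Blinds`, `Test`,
`A`–`Z`, `AM Results`, `Information + Warnings` (31 in total; all
present even when empty). Counting tables occupy fixed 8-column blocks
side by side (15 per sheet): a header row (table index, condition,
blind label, override), a points row, a structure header row, then one
row per point with mark cells holding the literal `1` or nothing. Any
other mark-cell value is rejected on read with the offending cell named
(`A!B4`). `AM Results` and `Information + Warnings` are derived sheets,
recomputed on every write; metadata key/value pairs live at the top of
the warnings sheet. Capacities — 26 lettered sheets × 15 tables = 390
replicates, 15 test tables, 4 variables, 78 condition codes — are
enforced on write and read. Condition codes are assigned A–Z, AA–AZ,
BA–BZ (exactly 78 = 26·3). Workbook output is deterministic: document
properties and zip timestamps are pinned to a fixed epoch, so identical
experiments serialize byte-identically.

A table normally carries either a condition code or a blind label;
after blind resolution it carries both (the label retained for
provenance), which is valid exactly when the pair agrees with the
design's blind map.

The tidy CSV export is one row per (replicate, structure) plus a Total
row: UTF-8, comma-separated, `.`-decimal, RLC printed to one decimal.
The CSV direction is lossy by design: importing reconstructs
per-structure counts *and* the Total union size (marks are re-laid
contiguously, overlapping just enough to reproduce the union) but not
individual mark positions, variable names (they return as
`variable_1..4`), test tables, metadata, or the distinction between an
unscored empty table and an overridden one. Export → import → export is
byte-idempotent.

## Statistics

Tests run independently within each structure × facet cell, matching
the faceted display: no pooling across facets, one p-value family per
cell. Cells that end up with a single condition (a facet level
containing one condition) are skipped by the sweep; requesting a test
on such a cell directly is an error.

* **TukeyHSD** delegates to statsmodels' studentized-range
  implementation; its family-wise control is intrinsic, so requesting
  an extra adjustment is an error. Zero-variance degenerate inputs
  (which the studentized range leaves undefined) are resolved by the
  mean contrast: p = 1 for equal means, 0 otherwise. One-sided Tukey
  is rejected.
* **Wilcoxon** is the pairwise two-sample rank-sum (Mann–Whitney) test
  via scipy, exact where scipy's auto policy allows, with a note
  appended when ties force the normal approximation; two identical
  (exchangeable) samples give p = 1.
* **Dunn** is implemented in-package: tie-corrected z comparisons on
  pooled mid-ranks (the standard Kruskal–Wallis post-hoc). The test
  suite checks it to 1e-10 against a second, independently written
  oracle that computes mid-ranks by manual sorting.

Adjustments (Holm default for the rank tests; also Bonferroni, BH, BY,
Hochberg, none) delegate to statsmodels' `multipletests`. Under a
2,000-replicate global null (three groups of six, continuous data) the
Holm-adjusted pairwise-Wilcoxon family-wise error measured by the
acceptance script is ≈ 0.04, within the ≤ 0.07 bound asserted by the
test suite.

Compact letter displays use insert-and-absorb: start with one class
holding all groups; for each significant pair split every class
containing both; absorb non-maximal classes. This guarantees two
groups share a letter iff their adjusted p ≥ α; the suite verifies the
property exhaustively for families of up to 5 groups (all 2^C(k,2)
significance patterns) and on seeded random patterns for 6–8 groups,
where exhaustive enumeration (2^28 patterns at k = 8) is not practical.
Letters follow first-use order over the groups' display order.
Asterisk annotation against a reference condition uses strict
thresholds p < 0.05/0.01/0.001 → `*`/`**`/`***`, `ns` otherwise —
p = 0.05 exactly is `ns`.

## Plots

Bars show the group mean with a standard-error-of-the-mean whisker
(ddof = 1; single observations get no whisker); boxes are standard
median/IQR/1.5·IQR. The y axis is fixed to 0–105 so that data geometry
never exceeds 100 while annotation text has headroom. Datapoint jitter
is drawn from a seeded generator (width 0.2 of the group slot), making
renders byte-deterministic for a fixed config. Default palette is
viridis sampled evenly on [begin, end] = [0, 0.85] (the trimmed end
avoids near-white bars); a single group samples at `begin`. PNG honors
the configured dpi; PDF/SVG are vector. A JSON sidecar echoing the
configuration is written next to every saved figure.

## Simulator

Each point is an independent Bernoulli trial per structure with
biologically motivated nesting: IH is the entry event with probability
`p_ih`; A, V, S occur only at IH-positive points with conditional
probabilities, so their marked points are subsets of the IH set and
E[RLC_Total] = E[RLC_IH] = 100·p_ih (σ = 0), E[RLC_A] =
100·p_ih·p_a_given_ih, etc. EH and H are independent marginals.
Between-plant heterogeneity is a plant-level Gaussian effect (s.d. σ)
on the logit of `p_ih`, shared by all of a plant's slides; σ = 0 gives
pure binomial counts (verified by a χ² goodness of fit on 500 tables),
larger σ inflates between-plant variance beyond the binomial
prediction. Degenerate p = 0 or 1 bypass the logit. All-empty simulated
tables get the no-fungus override (they were "scored" and found empty).

The default spec models a three-condition experiment — mock control
(p_ih = 0), colonized wild type (p_ih = 0.55, arbuscules conditional
0.6) and an impaired mutant (p_ih = 0.2) — with 6 plants per condition,
100 points per plant and σ = 0.4, sizes and effect magnitudes typical
of published AM colonization assays. `recover_parameters` compares
observed condition means against the σ = 0 expectations with
Monte-Carlo standard errors; for σ > 0 the expectation is nonlinear in
the random effect and the report flags rather than corrects the
resulting bias.

What the simulator does *not* emulate: spatial correlation of
colonization along a root beyond the plant effect, scorer error,
structure misclassification, and unequal denominators between slides.
Passing tests therefore demonstrate the correctness of the arithmetic,
serialization and statistical machinery under the stated generative
model, not robustness to those real-data features.

## Problem sizes and numerical choices

The test suite exercises 1,000 random tables for the RLC brute-force
check, 200 randomized experiments for workbook round trips (small
tables, 1–8 points, so the property is cheap to check broadly), 50
random datasets for the Dunn oracle, and a 2,000-replicate null for
the family-wise error rate; the acceptance script uses the same sizes
except 50 round-trip experiments with up to 30 points. Equality checks
on RLC are exact (the values are ratios of small integers times 100);
the Dunn oracle tolerance is 1e-10; Monte-Carlo assertions use 3
standard errors. Ties in rank tests use mid-ranks with the standard
tie-correction terms throughout.
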