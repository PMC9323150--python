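# Methods

## The statistics being computed

The unit of observation is a mineral species with an ideal IMA-style
formula. Only element *identity* matters downstream: a formula is reduced
to its set of constituent elements (stoichiometric counts are parsed and
kept for validation, but no statistic weights by them). For each element
`e` present in the dataset we tabulate:

* `n_minerals` — species whose formula contains `e`;
* `n_localities` — the sum of per-mineral locality counts over those
  species. Locality identity is not tracked across minerals in typical
  database exports, so shared localities are double-counted; the sum is an
  upper bound on distinct localities and is documented as such rather than
  guessed at.
* `n_mineral_elements` (chemical breadth) — the union of the element sets
  of `e`'s minerals, minus `e`, counted.

Before trend fitting, two exclusion rules apply: a configurable list of
short-lived radioactive elements (default {Tc, Po, At, Ra, Pu}; extendable
to Pm, Fr, Ac, Pa, Np and others via configuration) and a minimum-species
rule with strict "fewer than" semantics — the default threshold 5 retains
an element with exactly five minerals.

Four simple OLS regressions are then fit: breadth against log10 species
count, breadth against log10 locality count, log10 crustal weight-percent
abundance against breadth (elements without an abundance value — C, H and
N in the standard bulk-continental-crust compilation — are dropped from
this fit only), and atomic number against breadth. Logs are base 10; base
affects the slope but neither R² nor p. R² is the plain (unadjusted)
coefficient of determination, and the reported p is the two-sided t-test
of zero slope. Trend outliers are elements whose *externally* studentized
residual exceeds a threshold, default 2.0: this operationalizes "forms
minerals with more/fewer partners than the trend predicts" as a
quantitative rule. Residual diagnostics (Shapiro–Wilk normality,
Breusch–Pagan heteroscedasticity, a log-transform recommendation when
normality is rejected, a small-sample caveat below n = 8) are intentionally
minimal — a sanity check, not a full assumption-audit battery.

## Formula parsing

The parser accepts nested parenthesized/bracketed groups (depth is
unbounded), integer and decimal subscripts (decimals stored as exact
rationals), hydration/adduct segments introduced by a middle dot or bullet
with a leading segment multiplier, and comma-grouped site occupancies.
Unicode subscript digits are normalized to ASCII; superscript runs and
caret markup are oxidation-state annotations and are removed — charge
never changes element identity, as are `2+`/`3−` digit-sign pairs inline.

Decisions where common formula dialects are genuinely ambiguous:

* **Site occupancies** `(Fe,Mg)`: all listed elements are included, each
  receiving the group's stoichiometric count. Dropping minority occupants
  would undercount co-occurrence. A stricter mode
  (`occupancy_ambiguous=True`, available on the parser and the table
  reader) instead rejects such formulas, so a dataset can be analyzed
  under both readings.
* **Ambiguity markers**: variable subscripts (`x`, `n`, `1−x`), numeric
  ranges (`2-3`), placeholder pseudo-symbols (REE, Ln, M, An) and vacancy
  squares mark a formula as *ambiguous*. Ambiguous formulas never raise;
  they parse to an empty element set with a reason and are excluded from
  analysis (the pipeline diverts them to a rejects file with counts).
  Structurally malformed text (unbalanced brackets, tokens that are
  neither elements nor known placeholders) raises a parse error naming
  the position.
* **ASCII periods**: a `·`/`•` is always a segment separator, but an
  ASCII `.` flanked by digits is read as a decimal point (`Ca0.5`), so a
  hydrate written `...O4.2H2O` parses with a 4.2 subscript. Element
  identity — the only thing downstream statistics consume — is unaffected;
  only the bookkeeping stoichiometry differs. Writing hydrates with the
  middle dot avoids the corner entirely.

## Networks

The bipartite graph has mineral nodes and element nodes; each included
mineral contributes one unweighted edge per constituent element (edges are
unweighted because nothing in the analysis motivates a weighting).
Optional slicing: a focal-element set keeps minerals containing at least
one focal element; an age threshold keeps minerals with maximum known age
`>= T` Ga (configurable to strict `>`; the choice only matters at exact
era ties, and `>= 0` must include all dated minerals). Minerals without an
age appear in unthresholded networks and never in thresholded ones.

Louvain community detection runs on the bipartite graph directly — mineral
and element nodes are partitioned together, no unipartite projection —
with resolution 1.0 and a fixed default seed (7140, an arbitrary recorded
constant) so runs are reproducible. The reported modularity is standard
Newman modularity of the returned assignment, recomputable independently
from the graph; the test suite checks this identity exactly, and on an
8-node two-block instance checks the partition against exhaustive
enumeration of all set partitions. Community ids are canonicalized by
descending community size, ties broken by smallest member, so outputs are
comparable across runs. GraphML exports carry `node_type`, `max_age_ga`
and `community` attributes and round-trip to an isomorphic network.

## The synthetic universe

The generator emulates the *shape* of a mineral-database export so every
stage is testable with known ground truth: formula strings that exercise
the real parser (subscripts, one optional parenthesized group, hydration
segments only when H and O are constituents, so rendering round-trips
exactly); heavy-tailed per-element species counts; locality counts that
scale log-normally with the geometric-mean abundance of constituents; ages
drawn from a small set of era thresholds. Elements are drawn per mineral
without replacement with probability proportional to
`abundance ** gamma`, a truncated-Poisson element count on [1, max], and
an anchor element forced into a fixed fraction of minerals — the single
hub with maximal breadth that oxygen is in real tables.

The canned "paper-like" configuration freezes these choices: 73 familiar
mineral-forming elements; a deterministic log10 abundance grid over
[-3, 0.5] weight percent assigned descending along a rough real-world
prominence ordering (so S, C, H, N are common and Br, I, platinoids rare);
1500 minerals; mean 3 elements per mineral (max 8); gamma = 1.0; oxygen
anchored into 60% of minerals at the top abundance; ages on
{3.5, 2.3, 1.7, 0.6, 0} Ga with weights {.05, .10, .15, .20, .50}. Two
ground-truth outliers are injected through selection-weight multipliers
at pinned abundances: As ×3000 at 2.5·10⁻⁴ wt% (far more partners than
its abundance predicts) and Sc ×0.005 at 30 wt% (far fewer). The grid is
deterministic rather than redrawn per seed because seed-to-seed variance
in the total selection weight otherwise moves the injected outliers in
and out of significance; with it, recovery of both outliers with correct
signs held in 100/100 generator seeds, and the species/locality trends
sit near R² ≈ 0.95/0.9. The universe size (1500 minerals over 73
elements) keeps breadth well below saturation — with too few elements
every common element co-occurs with everything and the trends carry no
information.

What the generator does **not** emulate: charge balance, site chemistry,
polymorphism, locality geography, or any mechanism of mineral evolution —
only the statistical couplings the analysis consumes. Passing tests on
synthetic data therefore demonstrate that the pipeline recovers structure
that is present, not that real mineral data has that structure.

## Numerical and degenerate-input conventions

* Exact fits (zero residual variance) define studentized residuals as 0
  and report p = 0 for a nonzero slope; a constant response reports
  R² = 0.
* Log transforms refuse non-positive values, naming the offending
  elements; regressions require n ≥ 3, outlier calling n ≥ 4 (the
  pipeline reports no outliers rather than failing on tiny fits).
* Empty networks are representable and exportable; connectivity is
  undefined (an error) on them; a missing focal element yields an empty
  network with a warning, not an error.
* Rendered synthetic formulas are asserted to re-parse to exactly the
  element set used to render them.
* All randomness flows from explicit integer seeds through NumPy
  generators; pipeline reruns with the same configuration are
  byte-identical.

## Known limitations

* `n_localities` double-counts localities shared between minerals of the
  same element (see above); comparisons against sources that deduplicate
  will differ.
* The parser targets ideal-formula dialects; exotic markup beyond the
  normalizations above (isotope labels, structural site superscripts) is
  rejected rather than guessed.
* The full-scale reproduction test against an archived mineral-database
  snapshot requires that snapshot to be supplied by the user; the
  repository ships no mineral data.
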