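# Methods

## The inference chain

`herbnet` implements the standard network-pharmacology chain for proposing
mechanisms of a multi-component herbal medicine against a disease:

1. **ADME screen.** Each candidate compound carries two database-precomputed
   pharmacokinetic scores: oral bioavailability OB (percent, 0–100) and
   drug-likeness DL (unitless, 0–1). Compounds with OB ≥ 30 and DL ≥ 0.18
   are "active ingredients". Both inequalities are inclusive by default
   (the convention is stated with ≥); a strict mode exists for sensitivity
   analysis. Compounds with a missing score are rejected and logged, never
   silently kept.

2. **Therapeutic targets.** The drug-target set is the union of the active
   compounds' targets; the disease set is the union of disease-gene lists
   from one or more database exports. The therapeutic-target set is their
   intersection. All set algebra runs on normalized gene symbols
   (uppercased, hyphen-free, Greek letters transliterated, resolved through
   a small user-extensible alias table), because database exports disagree
   on symbol style and the intersection size is only meaningful after
   harmonization. An `alias_near_misses` report surfaces symbols that an
   alias entry would have matched, making curation gaps visible.

3. **Typed networks.** All graphs are simple and undirected; nodes carry a
   class label (compound / target / pathway / protein).
   - C-T: bipartite compound–target graph over all targets of the actives.
   - C-OT: the same restricted to therapeutic targets; compounds left
     without targets are dropped with a warning.
   - PPI: confidence-scored protein–protein edges among therapeutic
     targets, kept when the score is ≥ 0.7 ("high confidence"); proteins
     with no surviving edge are excluded by default (`keep_isolates`
     retains them), matching how interaction databases report connected
     query proteins only.
   - C-T-P: tripartite graph over a selected pathway list; targets are
     kept if they belong to ≥ 1 selected pathway, compounds if they still
     reach a kept target; edges are compound–target pairs plus
     target–pathway memberships, never compound–pathway, so every edge has
     exactly one target endpoint (hence #edges = Σ target degrees).

4. **Topology and selection.** DC is the raw degree count; BC is Brandes
   betweenness on unweighted shortest paths, endpoints excluded,
   normalized by (n−1)(n−2)/2 — the NetworkAnalyzer convention under which
   published BC tables with values ≪ 1 were produced. On disconnected
   graphs, pair dependencies accumulate within components while the
   normalization keeps the full n; this deliberately shrinks BC on
   fragmented PPI networks and is documented because it changes values
   there. Raw (unnormalized) BC is available by flag.

   Node selection is one parametrized rule: a node passes when its DC
   and/or BC (per `combine` ∈ {AND, OR, DC_ONLY}) exceed
   `multiplier × statistic` of the table (per class when `per_class`),
   strictly by default. The hub screen is (median, ×2, AND, strict); the
   above-average screen is (mean, ×1, AND, strict, per-class). Selection
   always uses full floating-point precision; rounding is for reports only.

   *Known rule ambiguity.* Published hub lists are not always consistent
   with a strict AND reading of the 2×-median rule (nodes can pass the DC
   threshold while failing BC yet still be listed). The pipeline therefore
   surfaces a "rule inconsistency" warning in the run report whenever the
   AND screen excludes nodes that DC alone would select, and `combine`
   lets users reproduce either reading; the bundled reference hub list is
   reproduced by DC_ONLY, and the C-T-P target selection likewise defaults
   to DC_ONLY (its compound and pathway selections reproduce under strict
   AND). The intended rule cannot be inferred from conventions alone, so
   it is configurable, not guessed.

5. **Enrichment.** Over-representation of each annotated gene set is
   scored by the hypergeometric upper tail P(X ≥ k) with X ~
   Hypergeom(N, K, n): universe N, set size K and query size n all
   measured inside the declared universe. Benjamini–Hochberg adjusted
   p-values are always computed; the default screen keeps raw p < 0.05
   (mirroring the common portal convention) with `use_adjusted` switching
   the screen to FDR. The universe is explicit — all genes annotated in
   the collection (default), the drug-target set, or the query itself —
   never inferred. A case-insensitive substring blocklist implements the
   otherwise-manual removal of off-topic terms before the top-N cut; it
   ships empty. Only terms with k ≥ 1 are reported; ties in p break by
   term id so output is deterministic.

## Synthetic data: what it emulates, what it does not

`simulate` generates every input with exact structural counts: the number
of screen-passing compounds, the drug/disease/overlap target-set sizes,
the per-compound degrees (explicit list or uniform-integer spec, with
every drug target covered by ≥ 1 compound), the interaction edge count and
its high-confidence fraction, and the pathway collection. Exactness is
constructive (the overlap set is chosen first and padded; the
high-confidence edge count is `round(fraction × edges)`), so
pipeline-recovery tests are deterministic. Planted enrichment is the one
stochastic element: a planted term draws Binomial(size, strength) members
from the query, so strength equal to the query's background frequency
degenerates to (approximately) the null process — this is what makes the
rank-uniformity check meaningful.

Defaults mirror a published herb-vs-disease study shape: 60 compounds / 11
active, the 11 printed compound degrees, 126 drug targets, 2207 disease
genes, 83 overlapping, 500 scored edges of which exactly 383 clear 0.7,
90 pathway sets of 10–60 genes, one planted term at strength 0.6.

What the generator does **not** emulate: chemistry (OB/DL are sampled
uniformly in the passing/failing ranges, not computed from structure);
heavy-tailed PPI degree distributions (edges are uniform random pairs, so
the simulated PPI is degree-homogeneous and the 2×-median hub screen
typically selects few or no nodes — real interactomes are scale-free and
do produce hubs); correlated pathway membership (terms are sampled
independently, real annotations overlap hierarchically); and symbol-style
noise (tokens are `G000001`-style, so alias handling is exercised by
dedicated unit tests, not by the simulator). Passing pipeline tests
therefore demonstrate correctness of the set algebra, graph construction,
counting and statistics — not that real database exports are clean.

## Numerical choices

- Hypergeometric tails via the survival function evaluated in log space;
  k = 0 returns exactly 1. Verified exhaustively against exact rational
  PMF summation for every valid instance with N ≤ 20 (tolerance 1e-12).
- Brandes betweenness verified against an independent brute-force oracle
  that enumerates all shortest paths between all pairs, over 200 random
  graphs of ≤ 8 nodes (tolerance 1e-12), including disconnected graphs.
- BH adjustment verified against hand-computed step-up vectors and a
  reimplementation of the step-up recursion; it is permutation-equivariant
  and order-preserving.
- Median of an even-count class is the midpoint of the two central order
  statistics.
- Reports print BC at 8 decimals and class means at the conventional 2–3
  decimals; all thresholding uses full precision.
- Degenerate inputs: empty compound tables, empty maps, disjoint sets,
  empty networks, n < 3 betweenness (defined as 0) and top_n = 0 (C-T-P
  stage skipped with a notice) all produce empty-but-valid outputs rather
  than errors; truly invalid inputs (malformed rows, out-of-range scores,
  unknown pathway ids, empty universes) raise typed errors naming the
  location.

### Type-I error of the discrete screen

The hypergeometric test is discrete and conservative: its attainable level
at α = 0.05 is P(p ≤ α) = Σ pmf over the rejection region, which is
strictly below α and depends on (K, n, N). A calibration check that
compared the observed null rejection rate to a binomial band centred on
0.05 would therefore test the discreteness of the distribution, not the
implementation. The null-calibration test instead computes the exact
attainable level per simulated term with an independent combinatorial
oracle and checks the observed rejection count against ±1.96 σ of that
exact expectation (1000 null terms), plus a one-sided check that the rate
does not exceed the nominal level's upper binomial bound.

## Problem sizes

The test suite and the acceptance script run the published-table
computations at their natural size (11/34/20-row tables, 83-target
networks) and the synthetic studies at two scales: the study-shaped
default (60 compounds, 2207 disease genes, 500 edges, 90 pathways) for
end-to-end reproduction, and a scaled-down configuration (30 compounds,
120 disease genes, 80 edges, 30 pathways) for the 20-seed
parameter-recovery sweep, which keeps the whole suite in a few seconds.

## Known limitations

- Symbol normalization is intentionally shallow (no Entrez/UniProt
  mapping); the alias table is the only harmonization mechanism.
- Only degree and betweenness centrality are provided; shortest paths are
  unweighted.
- The enrichment statistic is the plain hypergeometric upper tail; the
  EASE-style deflated score used by some portals is not implemented, so
  p-values from such portals are not numerically comparable.
- The score scale of interaction files must be declared (`unit` or
  `thousand`); it is never guessed from magnitude, because silent
  misscaling would corrupt the 0.7 cutoff.
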