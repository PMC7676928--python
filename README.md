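# herbnet

Network pharmacology of multi-component herbal medicines: a tested,
reusable implementation of the inference chain that proposes molecular
mechanisms for an herb acting on a disease.

Multi-component remedies act through many compounds hitting many protein
targets at once, so the standard analysis is set- and graph-theoretic
rather than single-molecule. `herbnet` is for computational biologists and
pharmacology researchers who have database exports (compound tables with
ADME scores, compound→target maps, disease gene lists, scored
protein–protein interaction edges, pathway annotations) and want the whole
chain — reproducibly, offline, and with every threshold explicit:

1. **ADME screen** — keep compounds with oral bioavailability OB ≥ 30% and
   drug-likeness DL ≥ 0.18 ("active ingredients").
2. **Therapeutic targets** — T = T_drug ∩ T_disease on normalized gene
   symbols, where T_drug = ∪ᵢ targets(compoundᵢ).
3. **Typed networks** — bipartite compound–target (C-T) and
   compound–overlapping-target (C-OT) graphs; a high-confidence PPI graph
   (score ≥ 0.7) among therapeutic targets; a tripartite
   compound–target–pathway (C-T-P) graph over the screened pathways.
4. **Topology & selection** — degree centrality DC(v) and Brandes
   betweenness BC(v) = Σ_{s≠v≠t} σ_st(v)/σ_st, normalized by (n−1)(n−2)/2.
   Hub targets satisfy DC > 2·median(DC) and BC > 2·median(BC); C-T-P
   key nodes exceed their class mean.
5. **Pathway enrichment** — hypergeometric over-representation
   p = P(X ≥ k), X ~ Hypergeom(N, K, n), with Benjamini–Hochberg
   adjustment, p < 0.05 screening, blocklist and top-N selection.

A synthetic-data generator (`herbnet.simulate`) produces every input with
exactly controlled structure (active count, overlap size, high-confidence
edge count, planted enriched terms), so the full pipeline runs and is
testable without any database access. The per-node topology tables of a
published case study (*Prunella vulgaris* against subacute thyroiditis)
are bundled under `herbnet.reference` as the printed-value check.

## Worked example

`examples/06_published_tables.py` recomputes the published selections from
the bundled 65-row C-T-P centrality table (11 compounds, 34 targets, 20
pathways) and the 18-row hub table:

```text
compound mean DC =  9.18   mean BC = 0.049
target   mean DC =  7.03   mean BC = 0.021
pathway  mean DC =  6.90   mean BC = 0.011
sum of target degrees = 239 = number of C-T-P edges
above-average compounds (4): Quercetin, Luteolin, Kaempferol, Beta-sitosterol
above-average targets   (15): PIK3CG, MAPK1, MAPK14, TNF, ESR1, ...
above-average pathways  (5): PI3K-Akt signaling pathway, ...
hub targets: 18 of 83 therapeutic targets = 21.69%
```

Reading the numbers: every C-T-P edge has exactly one target endpoint, so
the target-degree sum *is* the edge count (239). The class means are the
selection thresholds; the four compounds exceeding both their class means
(quercetin, luteolin, kaempferol, beta-sitosterol) and the leading
targets (PIK3CG, MAPK1, ...) and pathways (PI3K-Akt, TNF signaling) form
the proposed mechanism. The hub screen keeps 18 of the 83 therapeutic
targets (21.69%).

The other examples each run one capability end-to-end on synthetic data —
ADME screening, target intersection (126 ∩ 2207 → 83), network
construction and the hub rule, planted-signal enrichment, and the full
pipeline (`run_pipeline`, which writes GraphML networks, centrality TSVs,
an enrichment table and a JSON run report):

```bash
python examples/05_full_pipeline.py
```

There is also a thin CLI (`herbnet filter|overlap|network|topology|select|
enrich|simulate|run`) for shell use; `herbnet run --config run.yaml
--out-dir results/` executes the whole chain from one YAML file.

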