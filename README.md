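# konet

Community-level metabolic network analysis for metagenomics. `konet` treats
a microbial community as a single "supraorganism": starting from read-level
functional annotations (KEGG Orthology hits per sequencing read), it
estimates enzymatic-gene abundances, reconstructs a directed enzyme-level
metabolic network, induces per-sample state-specific networks (SSNs), and
scores which enzymes differ between two host states (e.g. obese vs lean gut
microbiomes).

It is written for microbiome researchers who have per-sample KO annotation
tables (from any annotation service) and a reaction reference, and want
network-level answers offline — no web API calls are made.

## The model

**Abundance estimation.** Each read contributes total weight 1. A read whose
single best hit carries several KO annotations splits its count evenly
between them; a read with several best hits at the same e-value splits its
count evenly between the unique KOs of all tied references. With A_sk the
resulting count of enzyme k in sample s, relative abundances divide A_sk by
the sample's total over enzymatic reads, removing depth differences.

**Reference network.** Nodes are KOs. A directed edge A → B exists when some
product metabolite of a reaction catalyzed by A is a substrate metabolite of
a reaction catalyzed by B (reversible reactions contribute both
orientations). Each edge records the (compound, reaction, reaction) evidence
that created it. An SSN is the vertex-induced subgraph over the KOs detected
in one sample, with abundances as node attributes.

**Topology.** Degree, directed betweenness centrality, clustering
coefficient (undirected projection) and PageRank per node, plus Pearson and
Spearman correlation of each metric with abundance.

**Differential scoring** between states 1 and 2, per enzyme k:

- OR: odds ratio
  `OR_k = [Σ_{s∈1} A_sk / Σ_{s∈1} Σ_{i≠k} A_si] / [Σ_{s∈2} A_sk / Σ_{s∈2} Σ_{i≠k} A_si]`,
  score `|log2 OR_k|`;
- RANK: rank enzymes within each sample (1 = most abundant, average ranks on
  ties), score `|mean rank in state1 − mean rank in state2|`;
- JSD: base-2 Jensen–Shannon divergence between the Bernoulli distributions
  (p_k, 1−p_k) and (q_k, 1−q_k) of the per-state mean relative abundances,
  bounded in [0, 1].

Enriched enzymes (more abundant in state 1) are colored red in the exported
community network, depleted ones green.

## Worked example

A seeded synthetic study (12 KOs, 3 samples per state, 500 reads per
sample) with KO `K00003` planted at a 4-fold (log2 fold 2) enrichment in
state 1:

```python
import konet as K

cfg = K.SimulationConfig(n_kos=12, n_compounds=15, n_reactions=25,
                         n_samples_per_state=3, n_reads=500,
                         planted_ko="K00003", planted_log2_fold=2.0, seed=7)
profiles, labels, truth = K.generate_profiles(cfg)
table = K.build_abundance_table(profiles, labels)

reactions, _ = K.generate_reference(cfg)
reference = K.construct_metabolic_network(reactions)
print(f"reference network: {len(reference)} KOs, "
      f"{reference.graph.number_of_edges()} edges")

ssns = [K.construct_ssn(table, s, reference) for s in table.sample_ids]
topo = K.analyze_topology(ssns[0])
c = topo.correlations["degree"]
print(f"abundance ~ degree: spearman rho = {c.spearman_r:.3f} (p = {c.spearman_p:.3g})")

net, result = K.differential_analyze(ssns, table, labels, method="or")
print(result.top(3)[["score", "direction", "log2_or"]])
```

prints

```
reference network: 11 KOs, 85 edges
abundance ~ degree: spearman rho = -0.465 (p = 0.149)
           score  direction   log2_or
K00003  2.204085   enriched  2.204085
K00011  0.516543   depleted -0.516543
K00006  0.448959  unchanged -0.448959
```

The planted enzyme tops the OR ranking with an estimated log2 odds ratio of
2.20 against a true value of 2.00 (3 small samples per state; at the
package's default study size of 20 samples × 10⁴ reads the estimate lands
within a few hundredths). The abundance–degree correlation is weak and
non-significant here, as it should be: the simulation assigns abundance
independently of network position. `K00006` moved less than the default
direction-call threshold (the 0.9 quantile of nonzero scores) and is left
"unchanged".

The same flow runs from the shell:

```sh
konet simulate cfg.json -o fix/
konet abundance fix/state*_s*.tsv --sample-id ... --state ... -o abund.biom
konet refnet fix/reactions.tsv -o ref.graphml
konet ssn --biom abund.biom --reactions fix/reactions.tsv --sample state1_s00 -o ssn.graphml
konet topology ssn.graphml -o topo.tsv
konet diff --biom abund.biom --reactions fix/reactions.tsv \
      --state1 state1 --state2 state2 --method or -o diff.tsv \
      --network-out diffnet.graphml
```

Abundance tables are exchanged as BIOM 1.0 JSON; networks as GraphML or
Cytoscape.js JSON (loadable in Cytoscape for exploration).

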