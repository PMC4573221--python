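# Methods

This note records the modelling choices behind `konet`, the parameters that
matter, and what the synthetic benchmark does and does not establish.

## Abundance estimation

A read's annotation hits are grouped by read id. Only hits at the read's
minimum e-value are kept; "the same e-value" is decided with a relative
tolerance of 1e-9 on the parsed floats, because annotation pipelines print
rounded exponents and exact binary equality would split ties that the
source data intends. The unique KO ids pooled across the kept hits (a KO
appearing on two tied references gets one share, not two) each receive
weight `1/n_pooled`, so every KO-assigned read contributes total weight
exactly 1 — the invariant the tests enforce to 1e-9.

Relative abundance divides each sample's per-KO weight by the sample's
total weight. The denominator is the split-weight mass — equivalently the
number of KO-assigned reads — rather than the raw read count; this is the
only denominator under which the relative rows sum to 1, which every
downstream score assumes. Samples with no enzymatic hits keep an all-zero
row and are reported, not dropped. An optional maximum-e-value filter
exists for users who want a significance cutoff; none is applied by
default, since best-hit selection already discards weaker alignments.

## Reference network construction

The edge rule is literal: A → B iff some compound is an effective product
of a reaction catalyzed by A and an effective substrate of one catalyzed by
B. Three choices were genuinely open:

- **Reversibility.** The reaction-table dialect carries an explicit
  direction column (`=>` / `<=>`); a reversible reaction's effective
  products and substrates are both the union of its two compound sets.
  Dropping direction information would arbitrarily inflate or deflate
  connectivity, so the choice lives in the data file and is handled
  deterministically.
- **Currency metabolites.** Nothing is excluded by default — the rule is
  applied as stated — but `exclude_compounds` is exposed because ubiquitous
  cofactors (ATP, H2O) otherwise make the graph near-complete and
  biologically vacuous. Excluding a compound can only remove edges, a
  property the tests check.
- **Self-loops.** A KO feeding itself through a shared compound says
  nothing about inter-enzyme structure, so self-loops default off;
  `allow_self_loops=True` restores them.

Parallel evidence (several compounds or reaction pairs connecting the same
enzyme pair) collapses onto one directed edge carrying the full evidence
list, and every evidence triple re-verifies against the input reactions.

The construction is indexed (compound → producing/consuming reactions); the
test suite and the synthetic module carry an independent quadratic
enumeration over all ordered reaction pairs, and the two must agree exactly
on randomized tables.

## State-specific networks

An SSN is exactly the vertex-induced subgraph of the reference over the
KOs whose relative abundance exceeds `min_abundance` (default 0, i.e.
presence). Node attributes store the relative abundance — the scale all
scores are defined on — with the raw split-weight count alongside. Detected
KOs without any known reaction cannot enter the graph; they are listed on
the returned network rather than silently dropped. Raising the threshold is
monotone: node and edge sets only shrink.

## Topology

Degree is in-degree + out-degree; betweenness respects edge direction,
excludes endpoints, shares shortest-path multiplicity fractionally, and is
reported both raw and normalized by (n−1)(n−2) since conventions differ
across tools. Clustering is computed on the undirected projection — a
directed triangle census has seven motif classes, which is not what a
triangle count through a node means. PageRank uses damping 0.85 (the
conventional default), uniform teleport, uniform redistribution of dangling
mass, and a power iteration declared converged when the L1 change falls
below 1e-10 (at most 1000 iterations, failure is an error naming the
count); it is validated against a direct linear solve of the stationarity
system. Correlations between abundance and each metric are reported with
both Pearson and Spearman statistics, since neither is canonical for this
purpose; with fewer than 3 nodes or a constant vector they are NaN, not an
error.

## Differential scores

The OR formula is evaluated on relative abundances (it is invariant to the
per-sample scale, so counts would give the same value). A pseudocount,
default 1e-6 on the relative scale, is added to every numerator and
denominator sum: it keeps KOs absent from one state finite while
perturbing well-measured odds by less than one part in 10⁴. Pseudocount 0
evaluates the bare formula; zero-in-one-state KOs then score +inf and are
flagged rather than masked.

RANK uses average ranks on ties, which places all zero-abundance KOs in one
tied block at the bottom; the score is invariant under any strictly
monotone per-sample transformation of abundances.

JSD as a divergence is defined between distributions, yet a per-enzyme
score is wanted; the construction adopted here summarizes enzyme k in a
state as the Bernoulli distribution over its mean relative abundance and
takes the base-2 JSD between the two states' distributions. This keeps the
score per-KO, symmetric, and bounded in [0, 1] with 0 iff the means agree.
It is one defensible reading, documented as such.

Scores are descriptive. No p-values or multiplicity corrections are
attached — the scores order enzymes, they do not test hypotheses. The
"significantly enriched/depleted" coloring therefore needs a cutoff: by
default the 0.9 quantile of the nonzero scores (roughly: color the top
decile of moving enzymes), overridable as an absolute value. The direct
scoring functions use threshold 0 so that any nonzero score carries a
direction call; the quantile default applies when building the colored
community network. In that network (union of all SSN nodes and edges),
enriched-in-state1 nodes are `#FF0000`, depleted `#00AA00`, unchanged
`#CCCCCC`. The two states are taken from the label map in first-seen order.

## Synthetic data generator

The generator emulates the structure of annotation data, not sequencing
itself: no read sequences, alignment errors, or taxonomic composition.
Per-state KO probabilities follow a lognormal(0, 1) rank-abundance vector
(a realistic skewed community profile); in state 1 the planted KO's
probability is scaled by `2^planted_log2_fold` and the vector renormalized.
Defaults — 50 KOs, 20 samples per state, 10⁴ reads per sample, 10%
multi-KO subjects, 10% tied best hits, one planted KO at log2 fold 1 —
describe a small but realistically deep two-state comparison.

Multi-KO and tied reads draw their second KO independently from the same
state distribution, which makes the expected split weight of every KO equal
to its true probability: the even-split estimator stays unbiased under
splitting, so planted-effect recovery measures the pipeline, not a
generator artifact. Tied e-values are written as byte-identical decimal
strings so the tie detector is exercised through the file dialect. The
planted KO is guaranteed to catalyze at least one reaction so the effect is
visible in the network stage. A single integer seed drives every stream,
with per-sample substreams at fixed offsets for cross-machine
reproducibility.

Consequently, passing tests show that the estimator, network construction
and scores behave correctly under the stated sampling model; they do not
show robustness to annotation bias, chimeric reads, copy-number variation
or compositional effects present in real metagenomes.

## Numerical choices and degenerate inputs

- e-value tie tolerance 1e-9 (relative); e-value 0 ties only with 0.
- Relative rows sum to 1 within 1e-9; all-zero samples stay zero.
- JSD is clipped into [0, 1] to absorb float rounding at the boundary.
- Empty reaction lists give the empty network; empty SSNs give empty
  topology results; correlations on degenerate vectors are NaN.
- BIOM files are written as 1.0 JSON (sparse); the reader also accepts
  dense 1.0 matrices. Counts survive a round trip to 1e-9.
- GraphML flattens edge-evidence triples to `compound|r1|r2;...` strings
  (GraphML attributes are scalars); the reader restores the lists.

## Benchmark problem sizes

The randomized oracle checks use ≤ 30 reactions / ≤ 16 KOs per table (200
tables) and ≤ 10-node graphs (100 graphs) — small enough for exhaustive
enumeration to stay trustworthy, large enough to cover reversible mixes,
multi-KO reactions and disconnected graphs. The planted-effect benchmark
runs at the generator's default study size; with 2 × 10⁵ reads per state
the sampling standard error of the log2 odds-ratio estimate is ≈ 0.03, so
the |bias| < 0.2 acceptance band tests correctness, not luck.

## Known limitations

- Pairwise state comparisons only; no covariates, no >2-state designs.
- No stoichiometry, flux balance, or compound-level (bipartite) views.
- Abundances are not corrected for gene copy number or genome size.
- The per-enzyme JSD construction is an interpretation (see above).
- BIOM 2.x (HDF5) is not written; use the 1.0 JSON dialect.
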