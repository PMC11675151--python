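# Methods

## Problem and model

`gatv2epi` predicts whether a candidate enhancer–promoter pair physically
interacts, treating the task as **edge classification on a bipartite
regulatory graph**. All enhancers and promoters of a chromosome are nodes;
candidate pairs — experimentally supported interactions (positives) and
distance-matched sampled non-interactions (negatives) — are undirected
edges.

Each node carries a 7×21 matrix of epigenomic signal: seven markers
(H3K27me3, H3K36me3, H3K4me1, H3K4me3, H3K9me3, CTCF, DNase, in that fixed
row order) by 21 genomic windows — the element interval itself (window 0)
plus ten abutting 2 kb windows on each side. The model is

1. **Type-specific CNN encoders.** Independent convolutional modules for
   enhancers and promoters. The kernel is (1, k): it slides along the
   window axis only and never mixes markers. LeakyReLU, max-pooling along
   windows, flatten, and a dense projection produce a 32-dimensional
   embedding. The node input is the embedding concatenated with the node's
   degree (raw count in the sample graph) and a one-hot type code —
   enhancer (0, 1), promoter (1, 0).
2. **Dynamic multi-head graph attention (GATv2 ordering).** For each
   directed neighbor pair the head concatenates
   (query features, neighbor features, edge features), applies a learned
   linear map, LeakyReLU, then projects onto an attention vector. Because
   the nonlinearity sits *between* the two learned maps, attention
   rankings over a fixed neighbor set depend on the query node — the
   property that separates dynamic from static attention (the test suite
   constructs a fixture demonstrating it). Scores are softmax-normalized
   per query; messages are attention-weighted transformed pair features;
   ELU is the update nonlinearity; four heads are concatenated by default
   (mean aggregation available).
3. **Edge attention classifier.** The concatenated endpoint embeddings and
   edge features are gated elementwise by a learned edge-attention vector,
   passed through ELU and a linear layer to one logit per edge. A
   dot-product (scalar-gate) variant is available behind
   `ModelConfig.edge_scalar_gate`; the elementwise form is the default
   because it preserves per-dimension information entering the final
   linear layer.

Edge features are the genomic distance rescaled to [0, 1] over the
admissible range [(d − 42 000)/(500 000 − 42 000)] and the **edge type**:
the label for training edges, a neutral sentinel of 0.5 for validation and
test edges. Masking validation edges as well as test edges keeps model
selection honest. No self-loops are added; neighborhoods are exactly the
sample edges.

The combined training objective is

    L(p, y) = w · BCE(σ(p), y) + (1 − w) · max(0, 1 − y′ p),   y′ = 2y − 1

with w = 0.5 by default; BCE is computed in the numerically stable
softplus form. Evaluation reports ROC AUC (trapezoidal), area under the
precision–recall curve (step integration), and TPR / FPR / precision at a
0.5 threshold on σ(p). FPR is FP/(FP+TN) — the fraction of true negatives
called positive.

## Sample preparation

* Positives: label-1 rows of a BENGI-style enhancer–gene table, duplicates
  collapsed (multiple evidence lines for one pair count once).
* Promoters: TSS −1500/+500 bp, strand-aware, clamped at chromosome
  bounds; the first TSS of a gene is taken as canonical.
* Distance: |enhancer midpoint − TSS|. The midpoint anchor is stable under
  enhancer-length variation; the metric is recorded in the preparation
  report so a boundary-based alternative can be configured.
* Distance filter: 42 kb ≤ d ≤ 500 kb, both bounds inclusive ("within the
  range" read as a closed interval).
* Negatives: for each enhancer in the positive set, promoters within the
  same distance band that it is not known to contact; a per-enhancer quota
  equal to its positive count, sampled without replacement, with
  shortfalls redistributed among enhancers that still have candidates.
  This yields #negatives ≤ #positives, with equality whenever candidates
  suffice. (Published per-cell-line tables report slightly more negatives
  than positives, which a per-enhancer quota cannot produce; the exact
  bookkeeping there is unspecified, so the quota rule is implemented as
  stated.)

## Connectivity-based splitting

Connected components are computed over the union of positive and negative
edges, so leakage-freedom is strict: a node incident to a test edge can
never appear in training. Components are assigned whole to train/val/test
at a 3:1:1 edge-count ratio per chromosome by greedy largest-first bin
packing (each component goes to the split with the largest remaining
deficit; equal-size components are shuffled deterministically by seed). A
chromosome with fewer than three components goes entirely to train, with a
warning. Feature normalization — per-marker z-score then min–max to
[0, 1] — is fitted on training-split nodes only and applied everywhere,
with out-of-range values clipped; a constant marker maps to 0.

Whether node degree should be computed before or after negative-edge
addition is genuinely open; the full sample graph is used, and the choice
is visible in `EPIGraph.degree`.

## Numerics and training

The network is implemented on a small reverse-mode autodiff engine
(`gatv2epi.nn`, float64, numpy). Gradients are verified against central
finite differences, and the full forward pass against an independent
straight-line re-implementation (≤1e-5) in the test suite. Training uses
Adam with one full-subgraph pass per chromosome per epoch and shared
parameters across subgraphs. Because that gives only `n_chromosomes`
optimizer steps per epoch, the default learning rate is 5e-3 — larger than
typical minibatch defaults; 1e-3 demonstrably under-trains within a
50-epoch budget under this batching. Early stopping monitors validation
AUC with patience 20 and restores the best-validation parameters; if no
usable validation AUC exists (no validation edges, or a single-class
validation set) the final parameters are kept. Per-neighborhood softmax
subtracts the per-segment maximum (exact, since softmax is
shift-invariant). Max-pool gradients route to the first maximum on ties.
Training is deterministic under the seed up to float reduction order.

Unstated architecture sizes are configuration defaults: 8 conv channels,
kernel 3, pool 2, embedding 32, 4 heads × 8 dims (concat), LeakyReLU slope
0.2, dropout 0.

## Synthetic data generator

The generator emulates the statistical regime of Hi-C-derived
enhancer–promoter benchmarks, not their sequences:

* **Domain structure.** Elements are placed, non-overlapping, inside
  ~1 Mb regulatory domains separated by 700 kb gaps (wider than the 500 kb
  pairing cap), each element at least 21 window-widths from chromosome
  ends. Real EPI networks are archipelagos of small components; without
  domain gaps, negative edges percolate along a uniformly populated
  chromosome into one giant component per chromosome and connectivity
  splitting degenerates.
* **Asymmetric universes.** 260 enhancers vs 460 promoters per default
  fixture: annotated promoters far outnumber those appearing in the
  positive set, as in real annotation-vs-benchmark proportions. An
  `interacting_fraction` (default 0.8) bounds the pool of elements
  eligible for planted components, leaving isolated elements for null
  comparisons.
* **Component topology.** Mix of one-to-one (0.45), one-to-many (0.35,
  biased toward promoter hubs of degree 2–8 — observed promoter degrees
  run much higher than enhancer degrees) and many-to-many (0.2)
  components; on default conditions ~75–85 % of enhancers contact one or
  two promoters. Ground-truth component ids are recorded and must equal a
  brute-force BFS of the written positive graph.
* **Distances.** Positive partners are drawn with probability
  ∝ exp(−d/70 kb) within [42, 500] kb, mimicking the decay of 3D contact
  frequency with linear distance.
* **Signal.** Peak tracks are sparse: each element carries peaks over its
  central windows (−2..+2), and scattered background peaks (~one per
  25 kb, 0.5–1.5 kb wide) cover the rest. Elements in positive pairs have
  their central-peak mean elevated by `signal_effect` (default 1.5 = 5×
  the noise SD of 0.3), decaying linearly outward over windows −2..+2 —
  window 0 strongest, matching the expectation that feature importance
  peaks at the element itself and decays outward. All signals are
  folded-Gaussian noise around a baseline of 1.0, floored at 1e-3.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: DNA sequence, marker-specific signal shapes and
cross-marker correlation structure, replicate noise, chromatin-state
heterogeneity along the genome, trans interactions, and any pair-specific
3D-contact signal beyond element-level enrichment plus distance. On this
synthetic regime the learnable signal for an edge is (a) whether both
endpoints are interaction-enriched, (b) the distance feature, and (c)
sample-graph topology; real-data performance cannot be inferred from the
synthetic numbers.

Fixtures are deterministic under the config seed — identical configs
produce byte-identical files.

## Problem sizes

The default study runs two 16 Mb chromosomes, 720 elements, ≈300 positive
and ≈300 negative pairs split 3:1:1 (≈120 test edges), and 50 training
epochs; the acceptance script runs this twice (once with shuffled labels
as a null control) in well under a minute on one CPU. These sizes were
chosen so that a full run is quick to reproduce while keeping ≥100
held-out edges for stable AUC estimates.

## Known limitations

* Single attention layer; deeper stacks and dropout > 0 are configurable
  but not defaults.
* The per-enhancer negative quota cannot reproduce published totals where
  negatives exceed positives (see above).
* The bipartite clustering coefficient uses the pairwise
  intersection-over-union (Latapy) form, averaged over distance-2
  neighbors; the behavioral anchors (0 for isolated pairs, 1 for complete
  2×2 clusters) pin this choice, but other BCC variants exist.
* A reported largest-subgraph average degree of 6.67 at 25 nodes in the
  source material would imply ~83 edges in a bipartite component; this
  package computes the standard 2E/V, under which such a value would be
  unusually dense.
* Trans (cross-chromosome) pairs are rejected; multi-edges are collapsed.
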