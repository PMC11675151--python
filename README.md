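# gatv2epi

Enhancer–promoter interaction (EPI) prediction with a dynamic graph
attention network, plus the surrounding pipeline: sample preparation from
BENGI-style pair tables, windowed epigenomic feature extraction,
leakage-free connectivity-based dataset splitting, training/evaluation,
and EPI-network topology statistics.

## The problem

Enhancers regulate genes over tens to hundreds of kilobases, and the
regulatory wiring is not one-to-one: one enhancer can contact several
promoters and one promoter can be driven by many enhancers. Pairwise
classifiers ignore that network structure, and random train/test splits
let the same elements appear on both sides, inflating reported accuracy.
This package treats EPI prediction as **edge classification on a
bipartite graph**: enhancers and promoters are nodes carrying local
epigenomic signal, candidate pairs are edges, and whole connected
components are assigned to train/validation/test so no node or edge is
ever shared between splits.

It is aimed at computational regulatory-genomics work: benchmarking EPI
classifiers under leakage-free splits, analyzing EPI-network topology, and
experimenting with graph architectures on controlled synthetic data.

## The model

Each element is described by a 7×21 matrix: seven markers (H3K27me3,
H3K36me3, H3K4me1, H3K4me3, H3K9me3, CTCF, DNase) over the element itself
plus ten 2 kb windows per side. A type-specific CNN (kernel (1, k): no
cross-marker mixing) embeds the matrix:

    x_conv = LeakyReLU(W_conv * x + b);  x_pool = MaxPool(x_conv)
    x_cnn  = W_fc · Flatten(x_pool) + b_fc

The node vector is x = concat(x_cnn, degree, type one-hot), with enhancer
type (0, 1) and promoter (1, 0). For an edge (i, j) with edge features
e_ij (scaled distance; edge type, masked to 0.5 on held-out edges), each
attention head scores

    e(x_i, x_j) = aᵀ · LeakyReLU(W · concat(x_i, x_j, e_ij))
    α_ij = softmax_j e(x_i, x_j)
    x_i′ = ELU( Σ_j α_ij W·concat(x_i, x_j, e_ij) )

with the nonlinearity between the two learned maps (GATv2 ordering), so
attention rankings depend on the query node. Heads are concatenated, and
edges are classified by

    p = W_clas · ELU(a_e ⊙ concat(x_i′, x_j′, e_ij)) + b_clas

trained with a combined loss L = w·BCE(σ(p), y) + (1−w)·max(0, 1−y′p),
y′ = 2y − 1, w = 0.5. See `docs/methods.md` for assumptions, defaults and
numerical details.

## Worked example

The synthetic generator plants a ground-truth EPI network (one-to-one,
one-to-many and many-to-many components inside ~1 Mb regulatory domains)
and marker tracks whose central windows are enriched at truly interacting
elements (effect = 5× noise SD by default):

```python
import pandas as pd
from gatv2epi import (SyntheticConfig, generate_fixture, prepare_samples,
                      WindowScheme, featurize_elements, map_gene_to_promoter,
                      build_dataset, ModelConfig, TrainConfig, train, evaluate)

config = SyntheticConfig(seed=1)          # two 16 Mb chromosomes, 720 elements
fixture = generate_fixture(config)
chrom_sizes = {c: config.chrom_length for c in config.chrom_names()}

samples, report = prepare_samples(fixture.pairs, fixture.enhancers,
                                  fixture.tss, chrom_sizes, seed=1)
print(f"positives={report['positives_after_distance_filter']} "
      f"negatives={report['negatives_sampled']}")

promoters = map_gene_to_promoter(fixture.tss, chrom_sizes)
elements = pd.concat([fixture.enhancers[["chrom", "start", "end", "id"]],
                      promoters.rename(columns={"gene_id": "id"})
                               [["chrom", "start", "end", "id"]]],
                     ignore_index=True)
features = featurize_elements(elements, fixture.tracks, WindowScheme(),
                              chrom_sizes)

graphs, plan, stats = build_dataset(samples, features, ratios=(3, 1, 1), seed=1)
print("train shares per chromosome:",
      {c: round(s["train"], 2) for c, s in plan.shares.items()})

model, history = train(graphs, ModelConfig(seed=1), TrainConfig(epochs=50, seed=1))
metrics = evaluate(model, graphs, split="test")
print(f"test AUC={metrics['auc']:.3f}  AUPR={metrics['aupr']:.3f}  "
      f"TPR={metrics['tpr']:.3f}  FPR={metrics['fpr']:.3f}")
```

Output:

```
positives=299 negatives=299
train shares per chromosome: {'chr1': 0.6, 'chr2': 0.6}
test AUC=0.954  AUPR=0.956  TPR=0.881  FPR=0.153
```

299 balanced pairs pass the 42–500 kb distance filter; each chromosome's
components split 60/20/20 by edge count with zero node or edge leakage;
and a 50-epoch run separates held-out edges (AUC 0.954) — held-out edges
have their edge-type feature masked, so the model relies on node signal,
distance and topology. Training the same model on shuffled labels yields
validation AUC ≈ 0.48, confirming the signal is the planted one.

The same pipeline is available from the shell:

```sh
gatv2epi simulate --seed 1 --out fixture/
gatv2epi prepare --pairs fixture/pairs.tsv --enhancers fixture/enhancers.bed \
    --tss fixture/tss.tsv --chrom-length 16000000 --seed 1 --out prep/
gatv2epi featurize --samples prep/samples.tsv --enhancers fixture/enhancers.bed \
    --tss fixture/tss.tsv --tracks fixture/ --chrom-length 16000000 \
    --out features.npz
gatv2epi split-train --samples prep/samples.tsv --features features.npz \
    --epochs 50 --seed 1 --out run/
gatv2epi netstats fixture/pairs.tsv --out stats/
```

Real data plug in the same way: enhancers as BED, TSSs as a TSV
(`gene_id chrom pos strand`, 1-based positions), pairs as a BENGI-style
TSV, and one narrowPeak-like BED per marker with signalValue in column 7.

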