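"""Per-chromosome EPI graphs, connectivity-based splitting, edge masking.

Candidate pairs (positive and negative) become edges of an undirected
bipartite graph per chromosome.  Connected components — computed over the
union of positive and negative edges — are the unit of train/val/test
assignment: every component lands wholly in one split, so no node or edge
is ever shared between splits.  Edge features are the rescaled genomic
distance and the edge type (the label for training edges, a neutral 0.5
sentinel for validation and test edges).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .features import NormalizationStats, apply_normalization, fit_normalization
from .sample_prep import DISTANCE_HI, DISTANCE_LO

EDGE_TYPE_SENTINEL = 0.5
SPLITS = ("train", "val", "test")


@dataclass
class EPIGraph:
    """One chromosome's sample graph in array form.

    Nodes are ordered enhancers-first; ``edge_index`` stores
    ``(enhancer_node, promoter_node)`` per sample edge.
    """

    chrom: str
    node_ids: list
    node_etype: np.ndarray       # 'e' / 'p' per node
    node_feats: np.ndarray       # (N, 7, 21)
    degree: np.ndarray           # (N,)
    type_onehot: np.ndarray      # (N, 2): enhancer (0,1), promoter (1,0)
    node_component: np.ndarray   # component label per node
    edge_index: np.ndarray       # (E, 2) int
    edge_label: np.ndarray       # (E,)
    edge_distance: np.ndarray    # (E,) bp
    edge_feat: np.ndarray        # (E, 2): scaled distance, edge type
    edge_split: np.ndarray       # (E,) str
    edge_component: np.ndarray   # (E,) component label

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)

    @property
    def n_enhancers(self) -> int:
        return int(np.sum(self.node_etype == "e"))


@dataclass
class SplitPlan:
    """Component -> split assignment plus achieved per-chromosome shares."""
    assignment: dict = field(default_factory=dict)   # (chrom, comp) -> split
    shares: dict = field(default_factory=dict)       # chrom -> {split: edge share}


def scale_distance(d, lo: int = DISTANCE_LO, hi: int = DISTANCE_HI) -> np.ndarray:
    """Rescale a genomic distance to [0, 1] over the admissible range."""
    return (np.asarray(d, dtype=float) - lo) / (hi - lo)


def connected_components(edges: pd.DataFrame) -> dict[str, str]:
    """Label connected components of a sample-edge table.

    Components are computed over positive and negative edges alike; the
    label is the smallest node id in the component (canonical under node
    order permutation).  Returns ``{node_id: component_label}``.
    """
    g = nx.Graph()
    g.add_edges_from(zip(edges["enhancer_id"], edges["promoter_id"]))
    labels = {}
    for comp in nx.connected_components(g):
        rep = min(comp)
        for node in comp:
            labels[node] = rep
    return labels


def split_by_connectivity(component_sizes: dict, ratios=(3, 1, 1),
                          seed: int = 0) -> SplitPlan:
    """Assign whole components to train/val/test at the target edge ratio.

    ``component_sizes`` maps chrom -> {component: edge count}.  Greedy
    largest-first bin packing per chromosome: components are sorted by
    descending edge count (ties shuffled deterministically by seed, then
    ordered by component id) and each goes to the split with the largest
    remaining deficit against its target share.  A chromosome with fewer
    than 3 components goes entirely to train, with a warning.
    """
    fr = np.asarray(ratios, dtype=float)
    fr = fr / fr.sum()
    rng = np.random.default_rng(seed)
    plan = SplitPlan()
    for chrom in sorted(component_sizes):
        comps = component_sizes[chrom]
        if len(comps) < 3:
            warnings.warn(f"{chrom}: fewer than 3 components; all assigned to train")
            for c in comps:
                plan.assignment[(chrom, c)] = "train"
            plan.shares[chrom] = {"train": 1.0, "val": 0.0, "test": 0.0}
            continue
        items = sorted(comps.items())
        perm = rng.permutation(len(items))
        items = [items[i] for i in perm]
        items.sort(key=lambda kv: -kv[1])  # stable: equal sizes keep shuffled order
        total = sum(comps.values())
        assigned = {s: 0 for s in SPLITS}
        for comp, size in items:
            deficit = {s: fr[i] * total - assigned[s] for i, s in enumerate(SPLITS)}
            best = max(SPLITS, key=lambda s: deficit[s])
            plan.assignment[(chrom, comp)] = best
            assigned[best] += size
        plan.shares[chrom] = {s: assigned[s] / total for s in SPLITS}
    return plan


def structural_node_features(etype: np.ndarray, edge_index: np.ndarray,
                             n_nodes: int):
    """Degrees and one-hot types for the sample graph.

    Enhancers encode as (0, 1), promoters as (1, 0); degree counts incident
    sample edges (positive and negative).
    """
    degree = np.zeros(n_nodes, dtype=np.int64)
    for i, j in edge_index:
        degree[i] += 1
        degree[j] += 1
    onehot = np.zeros((n_nodes, 2))
    onehot[etype == "e", 1] = 1.0
    onehot[etype == "p", 0] = 1.0
    return degree, onehot


def build_graph(samples: pd.DataFrame, features: dict,
                chrom: str | None = None) -> list[EPIGraph]:
    """Assemble one :class:`EPIGraph` per chromosome from a sample table.

    Every endpoint id must have a feature matrix in ``features``; a dangling
    id raises with the full missing list.  Edge type features start out as
    the raw label; apply a split plan and :func:`mask_edge_type` before
    feeding a model.
    """
    needed = set(samples.enhancer_id) | set(samples.promoter_id)
    missing = sorted(needed - set(features))
    if missing:
        raise KeyError(f"missing feature matrices for: {missing}")
    graphs = []
    items = samples.groupby("chrom", sort=True)
    for ch, grp in items:
        if chrom is not None and ch != chrom:
            continue
        enh_ids = sorted(set(grp.enhancer_id))
        prom_ids = sorted(set(grp.promoter_id))
        node_ids = enh_ids + prom_ids
        idx = {nid: i for i, nid in enumerate(node_ids)}
        etype = np.array(["e"] * len(enh_ids) + ["p"] * len(prom_ids))
        edge_index = np.array([[idx[e], idx[p]] for e, p in
                               zip(grp.enhancer_id, grp.promoter_id)], dtype=int)
        degree, onehot = structural_node_features(etype, edge_index, len(node_ids))
        comp = connected_components(grp)
        node_comp = np.array([comp[n] for n in node_ids])
        edge_comp = np.array([comp[e] for e in grp.enhancer_id])
        label = grp.label.to_numpy(float)
        dist = grp.distance.to_numpy(float)
        split = grp["split"].to_numpy(str) if "split" in grp else \
            np.array(["unassigned"] * len(grp))
        edge_feat = np.column_stack([scale_distance(dist), label.copy()])
        feats = np.stack([np.asarray(features[n], dtype=float) for n in node_ids])
        graphs.append(EPIGraph(
            chrom=ch, node_ids=node_ids, node_etype=etype, node_feats=feats,
            degree=degree, type_onehot=onehot, node_component=node_comp,
            edge_index=edge_index, edge_label=label, edge_distance=dist,
            edge_feat=edge_feat, edge_split=split, edge_component=edge_comp))
    return graphs


def apply_split(graphs: list[EPIGraph], plan: SplitPlan) -> None:
    """Stamp each edge's split from its component assignment (in place)."""
    for g in graphs:
        g.edge_split = np.array([
            plan.assignment.get((g.chrom, c), "train") for c in g.edge_component])


def mask_edge_type(graph: EPIGraph) -> EPIGraph:
    """Replace the edge-type feature of val/test edges with the sentinel.

    Train edges keep the label as their type feature; validation and test
    edges see 0.5 so the model never receives held-out labels.  Idempotent.
    """
    held = np.isin(graph.edge_split, ("val", "test"))
    graph.edge_feat[:, 1] = np.where(held, EDGE_TYPE_SENTINEL, graph.edge_label)
    return graph


def build_dataset(samples: pd.DataFrame, features: dict, ratios=(3, 1, 1),
                  seed: int = 0):
    """Graphs + split + leakage-free normalization, end to end.

    Builds per-chromosome graphs, splits components 3:1:1 by edge count,
    fits feature normalization on training-split nodes only, applies it to
    all nodes and masks held-out edge types.  Returns
    ``(graphs, plan, stats)``.
    """
    graphs = build_graph(samples, features)
    sizes: dict[str, dict] = {}
    for g in graphs:
        counts: dict = {}
        for c in g.edge_component:
            counts[c] = counts.get(c, 0) + 1
        sizes[g.chrom] = counts
    plan = split_by_connectivity(sizes, ratios=ratios, seed=seed)
    apply_split(graphs, plan)

    train_mats = []
    for g in graphs:
        node_split = {}
        for (i, j), s in zip(g.edge_index, g.edge_split):
            node_split[i] = s
            node_split[j] = s
        for i, s in node_split.items():
            if s == "train":
                train_mats.append(g.node_feats[i])
    stats = fit_normalization(train_mats, fitted_on="train")
    for g in graphs:
        g.node_feats = np.stack([apply_normalization(m, stats)
                                 for m in g.node_feats])
        mask_edge_type(g)
    return graphs, plan, stats


def check_split_integrity(graphs: list[EPIGraph]) -> dict:
    """Count node/edge overlap between splits (must be zero everywhere)."""
    node_sets = {s: set() for s in SPLITS}
    edge_sets = {s: set() for s in SPLITS}
    for g in graphs:
        for (i, j), s in zip(g.edge_index, g.edge_split):
            if s not in node_sets:
                continue
            node_sets[s].add((g.chrom, g.node_ids[i]))
            node_sets[s].add((g.chrom, g.node_ids[j]))
            edge_sets[s].add((g.chrom, g.node_ids[i], g.node_ids[j]))
    report = {}
    for a in SPLITS:
        for b in SPLITS:
            if a < b:
                report[f"shared_nodes_{a}_{b}"] = len(node_sets[a] & node_sets[b])
                report[f"shared_edges_{a}_{b}"] = len(edge_sets[a] & edge_sets[b])
    return report
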