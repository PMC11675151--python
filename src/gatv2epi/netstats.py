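"""Topology statistics of the enhancer--promoter regulatory network.

All statistics here operate on the *positive* interaction graph (the
regulatory network itself); sampled negatives are artifacts of classifier
training and are excluded.  Provides per-type degree distributions, the
bipartite clustering coefficient, connected-subgraph summaries,
cross-dataset interaction intersection, and random-forest feature
importance over the 7 x 21 marker-window matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .io import MARKERS

_QUANTILES = (0.25, 0.5, 0.75, 0.9, 1.0)


def _adjacency(pairs: pd.DataFrame) -> tuple[dict, dict]:
    """Neighbor sets per enhancer and per promoter from a positive-pair table."""
    enh: dict[str, set] = {}
    prom: dict[str, set] = {}
    for e, p in zip(pairs["enhancer_id"], pairs[_prom_col(pairs)]):
        enh.setdefault(e, set()).add(p)
        prom.setdefault(p, set()).add(e)
    return enh, prom


def _prom_col(pairs: pd.DataFrame) -> str:
    for c in ("promoter_id", "gene_id"):
        if c in pairs.columns:
            return c
    raise ValueError("pair table needs a promoter_id or gene_id column")


def degree_distributions(pairs: pd.DataFrame) -> dict:
    """Degree tables for enhancers and promoters in the positive graph.

    Returns ``{"enhancer": frame, "promoter": frame, "summary": frame}``;
    the degree frames map degree -> node count, the summary holds quantiles.
    """
    enh, prom = _adjacency(pairs.drop_duplicates(
        subset=["enhancer_id", _prom_col(pairs)]))
    out = {}
    summaries = []
    for name, adj in (("enhancer", enh), ("promoter", prom)):
        degs = np.array(sorted(len(v) for v in adj.values()))
        counts = pd.Series(degs).value_counts().sort_index()
        out[name] = pd.DataFrame({"degree": counts.index.to_numpy(),
                                  "n_nodes": counts.to_numpy()})
        row = {"etype": name, "n_nodes": len(degs),
               "mean": float(degs.mean()) if len(degs) else np.nan}
        for q in _QUANTILES:
            row[f"q{int(q * 100)}"] = float(np.quantile(degs, q)) if len(degs) else np.nan
        summaries.append(row)
    out["summary"] = pd.DataFrame(summaries)
    return out


def bipartite_clustering(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-node bipartite clustering coefficient (BCC).

    Pairwise coefficient between same-type nodes u, v:
    ``cc(u, v) = |N(u) & N(v)| / |N(u) | N(v)|`` (intersection over union of
    neighborhoods); a node's BCC is the mean of ``cc`` over its distance-2
    neighbors.  Nodes of an isolated interaction pair have no distance-2
    neighbors and score 0; a fully interlinked 2x2 cluster scores 1.
    """
    enh, prom = _adjacency(pairs.drop_duplicates(
        subset=["enhancer_id", _prom_col(pairs)]))
    rows = []
    for etype, adj, other in (("enhancer", enh, prom), ("promoter", prom, enh)):
        for u, nbrs in sorted(adj.items()):
            second = set()
            for w in nbrs:
                second |= other[w]
            second.discard(u)
            if not second:
                rows.append((u, etype, 0.0))
                continue
            ccs = [len(nbrs & adj[v]) / len(nbrs | adj[v]) for v in sorted(second)]
            rows.append((u, etype, float(np.mean(ccs))))
    return pd.DataFrame(rows, columns=["node_id", "etype", "bcc"])


def component_stats(pairs: pd.DataFrame) -> pd.DataFrame:
    """Node count, edge count and average degree (2E/V) per connected
    subgraph of the positive network, sorted by node count descending."""
    import networkx as nx

    pairs = pairs.drop_duplicates(subset=["enhancer_id", _prom_col(pairs)])
    g = nx.Graph()
    g.add_edges_from(zip(pairs["enhancer_id"], pairs[_prom_col(pairs)]))
    rows = []
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        v, e = sub.number_of_nodes(), sub.number_of_edges()
        rows.append((min(comp), v, e, 2.0 * e / v))
    df = pd.DataFrame(rows, columns=["component_id", "node_count",
                                     "edge_count", "average_degree"])
    return df.sort_values(["node_count", "component_id"],
                          ascending=[False, True]).reset_index(drop=True)


def epi_intersection(pair_sets: dict) -> dict:
    """Shared/unique interaction counts across datasets.

    ``pair_sets`` maps dataset name -> pair table; pairs are keyed by
    (enhancer_id, promoter/gene id).  Reports per-dataset totals, unique
    counts and proportions, pairwise shared counts, the full intersection
    size, and the list of pairs shared by all datasets.
    """
    sets = {}
    for name, df in pair_sets.items():
        sets[name] = set(zip(df["enhancer_id"], df[_prom_col(df)]))
    names = sorted(sets)
    report: dict = {"datasets": {}, "pairwise_shared": {}, "all_shared": None}
    for name in names:
        others = set().union(*(sets[o] for o in names if o != name)) \
            if len(names) > 1 else set()
        unique = sets[name] - others
        total = len(sets[name])
        report["datasets"][name] = {
            "total": total,
            "unique": len(unique),
            "unique_proportion": len(unique) / total if total else 0.0,
            "shared_with_any": total - len(unique),
        }
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            report["pairwise_shared"][f"{a}&{b}"] = len(sets[a] & sets[b])
    common = set.intersection(*sets.values()) if sets else set()
    report["all_shared"] = len(common)
    report["all_shared_pairs"] = sorted(common)
    return report


def feature_importance(matrices: dict, positive_pairs: pd.DataFrame,
                       etype: str, elements: pd.DataFrame,
                       seed: int = 0, n_estimators: int = 300) -> np.ndarray:
    """Random-forest importance of each marker-window feature, as (7, 21).

    The classifier separates elements that participate in at least one
    positive interaction from those that do not, using the flattened 147
    feature values.  Impurity-based importances (summing to 1) are reshaped
    to marker x window.
    """
    if etype == "enhancer":
        interacting = set(positive_pairs["enhancer_id"])
    elif etype == "promoter":
        interacting = set(positive_pairs[_prom_col(positive_pairs)])
    else:
        raise ValueError("etype must be 'enhancer' or 'promoter'")
    ids = [i for i in elements["id"] if i in matrices]
    X = np.stack([np.asarray(matrices[i], dtype=float).reshape(-1) for i in ids])
    y = np.array([1 if i in interacting else 0 for i in ids])
    if len(np.unique(y)) < 2:
        raise ValueError("need both interacting and non-interacting elements")
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                n_jobs=1)
    rf.fit(X, y)
    return rf.feature_importances_.reshape(len(MARKERS), -1)
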