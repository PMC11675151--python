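"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written in the most naive way possible
(loops, per-base scans, pair counting) and shares no code with the package
internals it checks.
"""

from __future__ import annotations

import numpy as np


def bfs_components(edges):
    """Connected components of an undirected edge list, by plain BFS.

    Returns a list of frozensets of nodes.
    """
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    seen, comps = set(), []
    for start in adj:
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            n = queue.pop()
            if n in comp:
                continue
            comp.add(n)
            queue.extend(adj[n] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def per_base_mean(track_rows, intervals):
    """Per-base mean of stacked peak signal over an interval set.

    ``track_rows`` is an iterable of (start, end, signal); uncovered bases
    contribute 0; the denominator is the total interval length.
    """
    total, length = 0.0, 0
    for a, b in intervals:
        for base in range(int(a), int(b)):
            s = 0.0
            for ps, pe, v in track_rows:
                if ps <= base < pe:
                    s += v
            total += s
            length += 1
    return total / length if length else 0.0


def mann_whitney_auc(labels, scores):
    """AUC as the normalized Mann-Whitney U statistic (pair counting)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def forward_straightline(params, config, graph):
    """Straight-line re-implementation of the full model forward pass.

    Per-node CNN (explicit convolution loops), concatenation with degree and
    type, per-head dynamic attention with per-query softmax, head
    aggregation, and the gated edge classifier.  ``params`` maps the
    package's parameter names to plain numpy arrays.
    """
    c = config
    slope = c.leaky_slope

    def leaky(x):
        return np.where(x > 0, x, slope * x)

    def elu(x):
        return np.where(x > 0, x, np.exp(np.minimum(x, 0.0)) - 1.0)

    def cnn(mat, t):
        K, b = params[f"cnn_{t}_K"], params[f"cnn_{t}_b"]
        Wfc, bfc = params[f"cnn_{t}_Wfc"], params[f"cnn_{t}_bfc"]
        C, k = K.shape
        wout = c.n_windows - k + 1
        conv = np.zeros((C, c.n_markers, wout))
        for ch in range(C):
            for r in range(c.n_markers):
                for w in range(wout):
                    conv[ch, r, w] = sum(K[ch, t2] * mat[r, w + t2]
                                         for t2 in range(k)) + b[ch]
        act = leaky(conv)
        wp = wout // c.pool
        pooled = np.zeros((C, c.n_markers, wp))
        for ch in range(C):
            for r in range(c.n_markers):
                for i in range(wp):
                    pooled[ch, r, i] = act[ch, r, i * c.pool:(i + 1) * c.pool].max()
        return pooled.reshape(-1) @ Wfc + bfc

    n = graph.n_nodes
    x = np.zeros((n, c.node_dim))
    for i in range(n):
        t = "e" if graph.node_etype[i] == "e" else "p"
        emb = cnn(graph.node_feats[i], t)
        x[i] = np.concatenate([emb, [graph.degree[i]], graph.type_onehot[i]])

    # directed neighbor lists
    nbrs: dict = {i: [] for i in range(n)}
    for eidx, (u, v) in enumerate(graph.edge_index):
        nbrs[u].append((v, eidx))
        nbrs[v].append((u, eidx))

    head_outs = []
    for h in range(c.heads):
        W, a = params[f"att_{h}_W"], params[f"att_{h}_a"]
        out = np.zeros((n, c.head_dim))
        for i in range(n):
            if not nbrs[i]:
                continue
            scores, wz = [], []
            for j, eidx in nbrs[i]:
                z = np.concatenate([x[i], x[j], graph.edge_feat[eidx]])
                t = z @ W
                scores.append(leaky(t) @ a)
                wz.append(t)
            scores = np.array(scores)
            alpha = np.exp(scores - scores.max())
            alpha = alpha / alpha.sum()
            out[i] = elu(sum(al * t for al, t in zip(alpha, wz)))
        head_outs.append(out)
    if c.head_agg == "concat":
        xp = np.concatenate(head_outs, axis=1)
    else:
        xp = sum(head_outs) / c.heads

    logits = np.zeros(len(graph.edge_index))
    for eidx, (u, v) in enumerate(graph.edge_index):
        ep = np.concatenate([xp[u], xp[v], graph.edge_feat[eidx]])
        if c.edge_scalar_gate:
            logits[eidx] = elu(ep @ params["edge_a"]) * params["clf_W"][0] \
                + params["clf_b"][0]
        else:
            logits[eidx] = elu(params["edge_a"] * ep) @ params["clf_W"] \
                + params["clf_b"][0]
    return logits
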