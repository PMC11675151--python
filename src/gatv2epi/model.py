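"""The EPI edge classifier: per-node CNN encoders, dynamic graph attention
(GATv2-style), and an edge attention classifier.

Architecture
------------
Each node's (7, 21) marker-window matrix passes through a type-specific CNN
(independent modules for enhancers and promoters): a convolution with
kernel ``(1, k)`` sliding only along the window axis (no cross-marker
mixing), LeakyReLU, max-pooling along windows, flatten, and a dense
projection to the embedding.  The embedding is concatenated with the node's
degree and a one-hot type code — enhancer (0, 1), promoter (1, 0).

For every directed neighbor pair the attention head concatenates
``(x_i, x_j, e_ij)``, applies a shared linear map, LeakyReLU, and projects
onto an attention vector; because the nonlinearity sits between the two
learned maps the resulting scores are *dynamic* — the ranking over a fixed
neighbor set depends on the query node.  Scores are softmax-normalized per
query node, messages are the attention-weighted transformed pair features,
and heads are concatenated (or averaged).  Edges are scored by gating the
concatenated endpoint embeddings and edge features with a learned edge
attention vector (elementwise, ELU) followed by a linear layer producing
one logit per edge.

No self-loops are added: neighborhoods are exactly the sample edges.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .graph import EPIGraph
from .nn import Tensor, concat, segment_softmax, segment_sum


@dataclass
class ModelConfig:
    """Architecture hyperparameters (all seedable, none data-dependent)."""
    n_markers: int = 7
    n_windows: int = 21
    conv_channels: int = 8
    kernel_size: int = 3
    pool: int = 2
    embed_dim: int = 32
    heads: int = 4
    head_dim: int = 8
    head_agg: str = "concat"          # 'concat' | 'mean'
    edge_feat_dim: int = 2
    leaky_slope: float = 0.2
    dropout: float = 0.0
    edge_scalar_gate: bool = False    # dot-product gate variant of the classifier
    seed: int = 0

    def __post_init__(self):
        if self.heads < 1:
            raise ValueError("need at least one attention head")
        if self.head_agg not in ("concat", "mean"):
            raise ValueError("head_agg must be 'concat' or 'mean'")

    @property
    def conv_width(self) -> int:
        return self.n_windows - self.kernel_size + 1

    @property
    def pooled_width(self) -> int:
        return self.conv_width // self.pool

    @property
    def node_dim(self) -> int:
        return self.embed_dim + 1 + 2  # embedding + degree + type one-hot

    @property
    def pair_dim(self) -> int:
        return 2 * self.node_dim + self.edge_feat_dim

    @property
    def updated_dim(self) -> int:
        return self.heads * self.head_dim if self.head_agg == "concat" \
            else self.head_dim

    @property
    def classifier_dim(self) -> int:
        return 2 * self.updated_dim + self.edge_feat_dim


class GATv2EPIModel:
    """Holds all parameters and runs the forward pass on an :class:`EPIGraph`."""

    def __init__(self, config: ModelConfig, params: dict | None = None):
        self.config = config
        self.params = params if params is not None else self._init_params()

    # -- parameters ------------------------------------------------------

    def _init_params(self) -> dict:
        c = self.config
        rng = np.random.default_rng(c.seed)
        p: dict[str, Tensor] = {}
        flat = c.conv_channels * c.n_markers * c.pooled_width
        for t in ("e", "p"):
            p[f"cnn_{t}_K"] = nn.parameter(nn.glorot(rng, (c.conv_channels,
                                                           c.kernel_size)))
            p[f"cnn_{t}_b"] = nn.parameter(np.zeros(c.conv_channels))
            p[f"cnn_{t}_Wfc"] = nn.parameter(nn.glorot(rng, (flat, c.embed_dim)))
            p[f"cnn_{t}_bfc"] = nn.parameter(np.zeros(c.embed_dim))
        for h in range(c.heads):
            p[f"att_{h}_W"] = nn.parameter(nn.glorot(rng, (c.pair_dim,
                                                           c.head_dim)))
            p[f"att_{h}_a"] = nn.parameter(nn.glorot(rng, (c.head_dim,)))
        gate_dim = c.classifier_dim
        p["edge_a"] = nn.parameter(nn.glorot(rng, (gate_dim,)))
        if c.edge_scalar_gate:
            p["clf_W"] = nn.parameter(nn.glorot(rng, (1,)))
        else:
            p["clf_W"] = nn.parameter(nn.glorot(rng, (gate_dim,)))
        p["clf_b"] = nn.parameter(np.zeros(1))
        return p

    def parameters(self) -> list:
        return [self.params[k] for k in sorted(self.params)]

    # -- submodules ------------------------------------------------------

    def cnn_encode(self, matrices: np.ndarray, etype: str) -> Tensor:
        """Encode (N, 7, 21) matrices with the enhancer or promoter CNN."""
        c = self.config
        mats = np.asarray(matrices, dtype=float)
        if mats.ndim == 2:
            mats = mats[None]
        if mats.shape[1:] != (c.n_markers, c.n_windows):
            raise ValueError(f"expected (*, {c.n_markers}, {c.n_windows}) input, "
                             f"got {mats.shape}")
        if etype not in ("e", "p"):
            raise ValueError("etype must be 'e' or 'p'")
        x = Tensor(mats)
        n = mats.shape[0]
        K = self.params[f"cnn_{etype}_K"]
        b = self.params[f"cnn_{etype}_b"]
        wout = c.conv_width
        conv = None
        for t in range(c.kernel_size):
            sl = x[:, :, t:t + wout].reshape(n, 1, c.n_markers, wout)
            term = sl * K[:, t].reshape(1, c.conv_channels, 1, 1)
            conv = term if conv is None else conv + term
        conv = conv + b.reshape(1, c.conv_channels, 1, 1)
        act = conv.leaky_relu(c.leaky_slope)
        trim = c.pooled_width * c.pool
        pooled = act[:, :, :, :trim].reshape(
            n, c.conv_channels, c.n_markers, c.pooled_width, c.pool).max_last()
        flat = pooled.reshape(n, c.conv_channels * c.n_markers * c.pooled_width)
        return flat @ self.params[f"cnn_{etype}_Wfc"] + \
            self.params[f"cnn_{etype}_bfc"]

    def node_inputs(self, graph: EPIGraph, rng: np.random.Generator | None = None
                    ) -> Tensor:
        """CNN embeddings concatenated with degree and type one-hot."""
        ne = graph.n_enhancers
        emb_e = self.cnn_encode(graph.node_feats[:ne], "e")
        emb_p = self.cnn_encode(graph.node_feats[ne:], "p")
        emb = concat([emb_e, emb_p], axis=0)
        x = concat([emb,
                    Tensor(graph.degree.astype(float)[:, None]),
                    Tensor(graph.type_onehot)], axis=1)
        if rng is not None and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            mask = rng.random(x.shape) < keep
            x = x * Tensor(mask / keep)
        return x

    def _attention_layer(self, x: Tensor, graph: EPIGraph):
        """Multi-head dynamic attention update; returns (x', internals)."""
        c = self.config
        n = graph.n_nodes
        ei = graph.edge_index
        src = np.concatenate([ei[:, 0], ei[:, 1]])   # query node i
        nbr = np.concatenate([ei[:, 1], ei[:, 0]])   # neighbor j
        efeat = np.vstack([graph.edge_feat, graph.edge_feat])
        z = concat([x[src], x[nbr], Tensor(efeat)], axis=1)
        heads, internals = [], []
        for h in range(c.heads):
            wz = z @ self.params[f"att_{h}_W"]
            scores = wz.leaky_relu(c.leaky_slope) @ self.params[f"att_{h}_a"]
            alpha = segment_softmax(scores, src, n)
            msg = alpha.reshape(-1, 1) * wz
            heads.append(segment_sum(msg, src, n).elu())
            internals.append({"alpha": alpha, "src": src, "nbr": nbr})
        if c.head_agg == "concat":
            xp = concat(heads, axis=1)
        else:
            acc = heads[0]
            for hd in heads[1:]:
                acc = acc + hd
            xp = acc * (1.0 / c.heads)
        return xp, internals

    def classify_edges(self, xp: Tensor, graph: EPIGraph) -> Tensor:
        """One logit per sample edge, enhancer embedding first."""
        ei = graph.edge_index
        eprime = concat([xp[ei[:, 0]], xp[ei[:, 1]], Tensor(graph.edge_feat)],
                        axis=1)
        if self.config.edge_scalar_gate:
            gated = (eprime @ self.params["edge_a"]).elu()
            logits = gated * self.params["clf_W"][0] + self.params["clf_b"][0]
        else:
            gated = (eprime * self.params["edge_a"]).elu()
            logits = gated @ self.params["clf_W"] + self.params["clf_b"][0]
        return logits

    # -- full forward ----------------------------------------------------

    def forward(self, graph: EPIGraph, rng: np.random.Generator | None = None,
                return_attention: bool = False):
        """Logits for every edge of ``graph`` (optionally with attention)."""
        x = self.node_inputs(graph, rng=rng)
        xp, internals = self._attention_layer(x, graph)
        logits = self.classify_edges(xp, graph)
        if return_attention:
            return logits, internals
        return logits

    def predict_proba(self, graph: EPIGraph) -> np.ndarray:
        return self.forward(graph).sigmoid().data

    def attention_weights(self, graph: EPIGraph) -> list[dict]:
        """Per-head attention weights as plain arrays (for inspection)."""
        _, internals = self.forward(graph, return_attention=True)
        return [{"alpha": d["alpha"].data, "src": d["src"], "nbr": d["nbr"]}
                for d in internals]

    # -- persistence -----------------------------------------------------

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=float).copy()

    def save(self, path) -> None:
        arrays = {f"param_{k}": v.data for k, v in self.params.items()}
        np.savez(path, config=np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "GATv2EPIModel":
        with np.load(path) as data:
            cfg = ModelConfig(**json.loads(bytes(data["config"]).decode()))
            model = cls(cfg)
            for k in list(data.keys()):
                if k.startswith("param_"):
                    model.params[k[6:]].data = data[k].astype(float)
        return model
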