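"""Training loop and evaluation metrics for the EPI edge classifier.

Training iterates over the per-chromosome subgraphs with a single shared
parameter set (one optimizer step per subgraph per epoch), minimizing a
combined loss

    L(p, y) = w * BCE(sigma(p), y) + (1 - w) * Hinge(p, 2y - 1)

on training-split edges only.  Validation AUC drives early stopping; the
best-validation parameters are restored at the end.

Evaluation reports ROC AUC, area under the precision--recall curve, and
confusion-based rates at a fixed probability threshold.  The false positive
rate is FP / (FP + TN) — the proportion of actual negatives called
positive.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .graph import EPIGraph
from .model import GATv2EPIModel, ModelConfig
from .nn import Adam, Tensor


@dataclass
class LossConfig:
    """Weighting of the combined objective; ``w`` is the BCE share."""
    w: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")


@dataclass
class TrainConfig:
    epochs: int = 50
    # with full-subgraph batching there are only n_chromosomes optimizer
    # steps per epoch, so the step size is larger than typical minibatch
    # defaults
    lr: float = 5e-3
    optimizer: str = "adam"
    seed: int = 0
    patience: int = 20
    loss: LossConfig = field(default_factory=LossConfig)
    # During training, this fraction of training edges per epoch has its
    # edge-type feature replaced by the neutral sentinel, so the classifier
    # cannot rely purely on the type feature it will not see at test time.
    edge_type_dropout: float = 0.0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def combined_loss(logits, labels, config: LossConfig | float = 0.5) -> Tensor:
    """Mean of w*BCE + (1-w)*hinge over a batch of edges.

    ``logits`` are raw scores (pre-sigmoid); ``labels`` in {0, 1}.  BCE uses
    the stable softplus form; the hinge term maps labels to {-1, +1}.
    """
    w = config.w if isinstance(config, LossConfig) else float(config)
    if not isinstance(logits, Tensor):
        logits = Tensor(logits)
    y = np.asarray(labels, dtype=float)
    if y.size == 0:
        raise ValueError("empty batch")
    # BCE(sigma(p), y) = softplus(p) - y*p, elementwise
    bce = (logits.softplus() - logits * Tensor(y)).mean()
    ysign = Tensor(2.0 * y - 1.0)
    hinge = (1.0 - ysign * logits).relu().mean()
    return bce * w + hinge * (1.0 - w)


def _scores_for_split(model: GATv2EPIModel, graphs: list[EPIGraph], split: str):
    scores, labels = [], []
    for g in graphs:
        mask = g.edge_split == split
        if not np.any(mask):
            continue
        prob = model.predict_proba(g)
        scores.append(prob[mask])
        labels.append(g.edge_label[mask])
    if not scores:
        return np.empty(0), np.empty(0)
    return np.concatenate(scores), np.concatenate(labels)


def _auc_or_none(labels, scores):
    if len(labels) == 0 or len(np.unique(labels)) < 2:
        return None
    return float(roc_auc_score(labels, scores))


def param_hash(model: GATv2EPIModel) -> str:
    h = hashlib.sha256()
    for k in sorted(model.params):
        h.update(k.encode())
        h.update(np.ascontiguousarray(model.params[k].data).tobytes())
    return h.hexdigest()


def train(graphs: list[EPIGraph], model_config: ModelConfig,
          train_config: TrainConfig):
    """Fit one shared model across all chromosome subgraphs.

    Loss and gradients come from training-split edges only; validation
    edges are scored with masked edge types (the graphs carry the mask) and
    never contribute gradient.  Returns ``(model, history)`` with the
    best-validation parameters restored.
    """
    n_train = sum(int(np.sum(g.edge_split == "train")) for g in graphs)
    if n_train == 0:
        raise ValueError("no training edges in any graph")
    model = GATv2EPIModel(model_config)
    opt = Adam(model.parameters(), lr=train_config.lr)
    rng = np.random.default_rng(train_config.seed)
    history = {"train_loss": [], "val_auc": []}
    best_auc, best_state, best_epoch = -np.inf, None, 0
    stale = 0

    for epoch in range(train_config.epochs):
        epoch_loss, n_batches = 0.0, 0
        for g in graphs:
            mask = g.edge_split == "train"
            if not np.any(mask):
                continue
            if train_config.edge_type_dropout > 0:
                saved = g.edge_feat[:, 1].copy()
                drop = mask & (rng.random(len(mask)) < train_config.edge_type_dropout)
                g.edge_feat[drop, 1] = 0.5
            drop_rng = rng if model_config.dropout > 0 else None
            logits = model.forward(g, rng=drop_rng)
            loss = combined_loss(logits[np.flatnonzero(mask)],
                                 g.edge_label[mask], train_config.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
            if train_config.edge_type_dropout > 0:
                g.edge_feat[:, 1] = saved
        history["train_loss"].append(epoch_loss / max(n_batches, 1))

        val_scores, val_labels = _scores_for_split(model, graphs, "val")
        val_auc = _auc_or_none(val_labels, val_scores)
        history["val_auc"].append(val_auc)
        if val_auc is not None and val_auc > best_auc:
            best_auc, best_state, best_epoch = val_auc, model.state_dict(), epoch
            stale = 0
        else:
            stale += 1
        if stale > train_config.patience:
            break

    if best_state is not None:   # otherwise keep the final parameters
        model.load_state_dict(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_auc"] = None if best_auc == -np.inf else float(best_auc)
    return model, history


def evaluate(model: GATv2EPIModel, graphs: list[EPIGraph], split: str = "test",
             threshold: float = 0.5) -> dict:
    """Metrics on the held-out edges of ``split``.

    AUC integrates the ROC curve over all score thresholds; AUPR uses
    precision--recall step integration.  TPR/FPR/precision are reported at
    ``threshold`` on the sigmoid scores.  With a single-class subset the
    curve metrics are reported as None with a warning entry.
    """
    scores, labels = _scores_for_split(model, graphs, split)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    out = {"split": split, "threshold": threshold, "n_pos": n_pos, "n_neg": n_neg}
    if n_pos == 0 or n_neg == 0:
        out.update({"auc": None, "aupr": None, "tpr": None, "fpr": None,
                    "precision": None,
                    "warning": "single-class subset; curve metrics undefined"})
        return out
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    out.update({
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "tpr": tp / (tp + fn),
        "fpr": fp / (fp + tn),
        "precision": tp / (tp + fp) if (tp + fp) else 0.0,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    })
    return out
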