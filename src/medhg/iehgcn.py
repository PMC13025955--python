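"""Interpretable heterogeneous graph convolutional network (ie-HGCN).

Three stacked heterogeneous convolution layers.  In each layer, every node
type projects its own representation (self relation) and receives
row-normalized, projected messages from each adjacent node type; the
projected blocks are mixed per node by softmax-normalized type-level
attention computed from key/query maps and a learnable attention vector:

    Z_self = H_prev[t] @ W_self                     (self projection)
    Z_rel  = A_hat[t<-s] @ H_prev[s] @ W_rel        (neighbor projection)
    e_rel  = ELU([Z_rel W_k || Z_self W_q] @ w_a)   (attention logit, per node)
    a      = softmax over {self} + neighbor relations, per node
    H_next = ELU(a_self * Z_self + sum_rel a_rel * Z_rel)

The final encounter representation has two columns and is passed through a
row softmax to yield outcome probabilities; training minimizes binary
cross-entropy with Adam, mini-batching the loss over labeled training
encounters while message passing always runs on the full graph
(transductive).  Node types without input features (providers, care units,
and encounters in the featureless ablation) receive trainable per-node
embedding vectors; an identity one-hot mode is available for exactness
checks.

The per-node attention coefficients are retained after every forward pass:
their per-layer means are the raw material of meta-path importance
analysis.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autodiff import Adam, Tensor, concat, spmm
from .evalstats import auroc
from .hetgraph import ENC, HetGraph, row_normalize

SELF = "self"
EPS = 1e-7


def _xavier(rng, n_in, n_out):
    s = np.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-s, s, size=(n_in, n_out)), requires_grad=True)


@dataclass
class LayerParams:
    """Trainable parameters of one heterogeneous convolution layer."""

    w_self: dict = field(default_factory=dict)   # target -> (d_in, d_out)
    w_rel: dict = field(default_factory=dict)    # (src, target) -> (d_in_src, d_out)
    w_key: dict = field(default_factory=dict)    # (target, rel) -> (d_out, d_a)
    w_query: dict = field(default_factory=dict)  # target -> (d_out, d_a)
    w_attn: dict = field(default_factory=dict)   # target -> (2*d_a, 1)

    def tensors(self):
        for d in (self.w_self, self.w_rel, self.w_key, self.w_query, self.w_attn):
            yield from d.values()


def project(H_prev: dict, layer: LayerParams, norm_adj: dict) -> dict:
    """Per-(target, relation) projected blocks Z.

    Returns ``{(target, SELF): Z_self, (target, src): Z_rel, ...}``.
    """
    Z = {}
    for target, W in layer.w_self.items():
        Z[(target, SELF)] = H_prev[target] @ W
    for (src, target), W in layer.w_rel.items():
        Z[(target, src)] = spmm(norm_adj[(target, src)], H_prev[src]) @ W
    return Z


def type_attention(Z_self: Tensor, Z_rels: dict, layer: LayerParams,
                   target: str):
    """Per-node softmax attention over {self} + neighbor relations.

    Returns ``(coeffs, order)`` where ``coeffs`` is an (n, R) Tensor whose
    rows sum to one and ``order`` names the relation behind each column.
    """
    order = [SELF] + sorted(Z_rels)
    if not order:
        raise ValueError("at least one relation required")
    wq = layer.w_query[target]
    wa = layer.w_attn[target]
    query = Z_self @ wq
    logits = []
    for rel in order:
        z = Z_self if rel == SELF else Z_rels[rel]
        key = z @ layer.w_key[(target, rel)]
        logits.append((concat([key, query], axis=1) @ wa).elu())
    return concat(logits, axis=1).softmax(axis=1), order


def layer_forward(H_prev: dict, layer: LayerParams, graph: HetGraph,
                  norm_adj: dict):
    """One heterogeneous convolution step for every node type.

    Returns ``(H_next, attention)`` where ``attention[target]`` is a dict
    relation -> per-node coefficient vector (numpy, detached).
    """
    Z = project(H_prev, layer, norm_adj)
    H_next, attention = {}, {}
    for target in layer.w_self:
        Z_self = Z[(target, SELF)]
        Z_rels = {src: Z[(target, src)] for (tgt, src) in Z
                  if tgt == target and src != SELF}
        coeffs, order = type_attention(Z_self, Z_rels, layer, target)
        mixed = coeffs.col(0) * Z_self
        for j, rel in enumerate(order[1:], start=1):
            mixed = mixed + coeffs.col(j) * Z_rels[rel]
        H_next[target] = mixed.elu()
        attention[target] = {rel: coeffs.value[:, j].copy()
                             for j, rel in enumerate(order)}
    return H_next, attention


def bce_loss(y, p) -> float:
    """Reference binary cross-entropy on plain arrays (clamped at 1e-7)."""
    y = np.asarray(y, float)
    p = np.clip(np.asarray(p, float), EPS, 1 - EPS)
    if len(y) != len(p):
        raise ValueError("length mismatch between labels and probabilities")
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


@dataclass
class TrainReport:
    epoch_losses: list = field(default_factory=list)
    val_aurocs: list = field(default_factory=list)
    best_epoch: int = -1
    stopping_reason: str = ""
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    @property
    def best_val_auroc(self) -> float:
        return max(self.val_aurocs) if self.val_aurocs else float("nan")

    def as_dict(self) -> dict:
        return {"epoch_losses": self.epoch_losses, "val_aurocs": self.val_aurocs,
                "best_epoch": self.best_epoch, "stopping_reason": self.stopping_reason,
                "seed": self.seed, "hyperparams": self.hyperparams}


class IEHGCNClassifier(BaseEstimator, ClassifierMixin):
    """ie-HGCN binary outcome classifier over a heterogeneous graph.

    Parameters
    ----------
    hidden_dim : width of the two hidden layers (the output layer is 2-wide).
    attn_dim : width of the attention key/query space.
    lr, weight_decay : Adam step size and L2 penalty.
    embed_weight_decay : separate L2 penalty for the per-node embeddings of
        featureless types (defaults to ``weight_decay``).
    embed_dim : width of the per-node embeddings of featureless types
        (defaults to ``hidden_dim``); small values limit how much label
        noise individual provider nodes can memorize.
    snapshot_attention : optional ``(start_epoch, every)``; when set, the
        per-node attention record is averaged over evaluation-mode
        forwards taken every ``every`` epochs from ``start_epoch`` on, and
        stored as ``attention_snapshot_``.  Averaging over trailing epochs
        smooths stochastic-gradient noise out of the coefficients used for
        meta-path analysis.
    dropout : dropout rate applied to layer inputs in training mode.
    batch_norm : standardize pre-activation hidden features per batch.
    batch_size : labeled encounters per loss mini-batch (full-graph passes).
    max_epochs, patience : early stopping on validation AUROC.
    embedding_mode : "trainable" per-node vectors or "onehot" identity inputs
        for featureless node types.

    Fitted attributes: ``layers_`` (list of LayerParams), ``embeddings_``,
    ``train_report_``, ``attention_`` (record of the last full forward),
    ``classes_``.
    """

    def __init__(self, hidden_dim=32, attn_dim=16, lr=1e-2, weight_decay=1e-5,
                 embed_weight_decay=None, embed_dim=None, dropout=0.0,
                 batch_norm=False, batch_size=512, max_epochs=100, patience=10,
                 seed=0, embedding_mode="trainable", n_layers=3,
                 snapshot_attention=None):
        self.hidden_dim = hidden_dim
        self.attn_dim = attn_dim
        self.embed_dim = embed_dim
        self.snapshot_attention = snapshot_attention
        self.lr = lr
        self.weight_decay = weight_decay
        self.embed_weight_decay = embed_weight_decay
        self.dropout = dropout
        self.batch_norm = batch_norm
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.embedding_mode = embedding_mode
        self.n_layers = n_layers

    # -- construction --------------------------------------------------------
    def _init_params(self, graph: HetGraph, rng):
        types = graph.schema.types
        in_dims = {}
        self.embeddings_ = {}
        for t in types:
            n_t = graph.schema.n_nodes(t)
            if t == ENC and graph.enc_features is not None:
                in_dims[t] = graph.enc_features.shape[1]
            elif self.embedding_mode == "onehot":
                in_dims[t] = n_t
            else:
                d_e = self.embed_dim or self.hidden_dim
                in_dims[t] = d_e
                self.embeddings_[t] = Tensor(
                    rng.normal(0, 0.1, size=(n_t, d_e)),
                    requires_grad=True)
        out_dims = [self.hidden_dim] * (self.n_layers - 1) + [2]
        self.layers_ = []
        for l, d_out in enumerate(out_dims):
            lp = LayerParams()
            for t in types:
                d_in = in_dims[t] if l == 0 else out_dims[l - 1]
                lp.w_self[t] = _xavier(rng, d_in, d_out)
                lp.w_query[t] = _xavier(rng, d_out, self.attn_dim)
                lp.w_attn[t] = _xavier(rng, 2 * self.attn_dim, 1)
                lp.w_key[(t, SELF)] = _xavier(rng, d_out, self.attn_dim)
                for s in graph.neighbors_of(t):
                    d_in_s = in_dims[s] if l == 0 else out_dims[l - 1]
                    lp.w_rel[(s, t)] = _xavier(rng, d_in_s, d_out)
                    lp.w_key[(t, s)] = _xavier(rng, d_out, self.attn_dim)
            self.layers_.append(lp)
        # per-(layer, target) bias absorbs constant message components so
        # always-present neighbor types cannot serve as free intercepts
        self._bias = {(l, t): Tensor(np.zeros((1, d)), requires_grad=True)
                      for l, d in enumerate(out_dims) for t in types}
        if self.batch_norm:
            self._bn_gamma = {(l, t): Tensor(np.ones((1, d)), requires_grad=True)
                              for l, d in enumerate(out_dims) for t in types}
            self._bn_beta = {(l, t): Tensor(np.zeros((1, d)), requires_grad=True)
                             for l, d in enumerate(out_dims) for t in types}

    def _norm_adj(self, graph: HetGraph) -> dict:
        out = {}
        for t in graph.schema.types:
            for s in graph.neighbors_of(t):
                out[(t, s)] = row_normalize(graph.adjacency(t, s))
        return out

    def _inputs(self, graph: HetGraph) -> dict:
        H = {}
        for t in graph.schema.types:
            if t == ENC and graph.enc_features is not None:
                H[t] = Tensor(graph.enc_features)
            elif self.embedding_mode == "onehot":
                H[t] = Tensor(np.eye(graph.schema.n_nodes(t)))
            else:
                H[t] = self.embeddings_[t]
        return H

    def _parameters(self):
        params = list(self.embeddings_.values())
        for lp in self.layers_:
            params.extend(lp.tensors())
        params.extend(self._bias.values())
        if self.batch_norm:
            params.extend(self._bn_gamma.values())
            params.extend(self._bn_beta.values())
        return params

    def _weight_decays(self):
        """Per-parameter L2, in the order of ``_parameters()``."""
        ew = self.weight_decay if self.embed_weight_decay is None \
            else self.embed_weight_decay
        decays = [ew] * len(self.embeddings_)
        for lp in self.layers_:
            decays.extend(self.weight_decay for _ in lp.tensors())
        decays.extend(0.0 for _ in self._bias)  # biases are not penalized
        if self.batch_norm:
            decays.extend(0.0 for _ in self._bn_gamma)
            decays.extend(0.0 for _ in self._bn_beta)
        return decays

    def initialize(self, graph: HetGraph):
        """Initialize parameters for ``graph`` without training (random model)."""
        self._init_params(graph, np.random.default_rng(self.seed))
        self.classes_ = np.array([0, 1])
        return self

    # -- forward -------------------------------------------------------------
    def forward(self, graph: HetGraph, norm_adj=None, training=False, rng=None):
        """Full-graph forward; returns (logits Tensor (n_enc, 2), attention)."""
        norm_adj = norm_adj if norm_adj is not None else self._norm_adj(graph)
        H = self._inputs(graph)
        attention = []
        for l, lp in enumerate(self.layers_):
            if training and self.dropout > 0:
                keep = 1.0 - self.dropout
                H = {t: h * Tensor((rng.random(h.shape) < keep) / keep)
                     for t, h in H.items()}
            Z = project(H, lp, norm_adj)
            H_next, attn = {}, {}
            for target in lp.w_self:
                Z_self = Z[(target, SELF)]
                Z_rels = {src: Z[(target, src)] for (tgt, src) in Z
                          if tgt == target and src != SELF}
                coeffs, order = type_attention(Z_self, Z_rels, lp, target)
                mixed = coeffs.col(0) * Z_self
                for j, rel in enumerate(order[1:], start=1):
                    mixed = mixed + coeffs.col(j) * Z_rels[rel]
                mixed = mixed + self._bias[(l, target)]
                if self.batch_norm:
                    mu = mixed.mean(axis=0, keepdims=True)
                    var = ((mixed - mu) ** 2.0).mean(axis=0, keepdims=True)
                    mixed = (mixed - mu) * ((var + 1e-5) ** -0.5)
                    mixed = mixed * self._bn_gamma[(l, target)] + self._bn_beta[(l, target)]
                H_next[target] = mixed.elu()
                attn[target] = {rel: coeffs.value[:, j].copy()
                                for j, rel in enumerate(order)}
            H = H_next
            attention.append(attn)
        self.attention_ = attention
        return H[ENC], attention

    # -- training ------------------------------------------------------------
    def fit(self, graph: HetGraph, y, splits=None):
        """Train on the labeled training encounters of ``splits``.

        ``y`` is a binary vector aligned with the graph's encounter order
        (or a mapping encounter_id -> label).  ``splits`` may be a
        SplitIndices, a dict of id lists, or None (all encounters train,
        no early stopping).
        """
        y = self._align_labels(graph, y)
        train_idx, val_idx = self._split_positions(graph, splits)
        if len(train_idx) == 0:
            raise ValueError("empty training split")
        rng = np.random.default_rng(self.seed)
        self._init_params(graph, rng)
        norm_adj = self._norm_adj(graph)
        opt = Adam(self._parameters(), lr=self.lr,
                   weight_decay=self._weight_decays())
        report = TrainReport(seed=self.seed, hyperparams=self.get_params())
        best_auc, best_state, best_epoch, stale = -np.inf, None, -1, 0
        snap_acc, snap_n = None, 0
        for epoch in range(self.max_epochs):
            order = rng.permutation(train_idx)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                batch = order[start:start + self.batch_size]
                logits, _ = self.forward(graph, norm_adj, training=True, rng=rng)
                p = logits.softmax(axis=1).col(1).take_rows(batch).clip(EPS, 1 - EPS)
                yb = Tensor(y[batch].reshape(-1, 1))
                loss = -(yb * p.log() + (1.0 - yb) * (1.0 - p).log()).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.value)
                n_batches += 1
            report.epoch_losses.append(epoch_loss / n_batches)
            if self.snapshot_attention is not None:
                start, every = self.snapshot_attention
                if epoch >= start and (epoch - start) % every == 0:
                    _, att = self.forward(graph, norm_adj)
                    if snap_acc is None:
                        snap_acc = [{t: {r: v.copy() for r, v in rels.items()}
                                     for t, rels in layer.items()}
                                    for layer in att]
                    else:
                        for la, lb in zip(snap_acc, att):
                            for t in la:
                                for r in la[t]:
                                    la[t][r] += lb[t][r]
                    snap_n += 1
            if len(val_idx):
                probs = self._probs(graph, norm_adj)
                try:
                    val_auc = auroc(y[val_idx], probs[val_idx])
                except ValueError:
                    val_auc = 0.5
                report.val_aurocs.append(val_auc)
                if val_auc > best_auc:
                    best_auc, best_epoch, stale = val_auc, epoch, 0
                    best_state = [p.value.copy() for p in self._parameters()]
                else:
                    stale += 1
                    if stale >= self.patience:
                        report.stopping_reason = "early_stopping"
                        break
        if not report.stopping_reason:
            report.stopping_reason = "max_epochs"
        if best_state is not None:
            for p, v in zip(self._parameters(), best_state):
                p.value = v
        report.best_epoch = best_epoch if best_epoch >= 0 else len(report.epoch_losses) - 1
        self.attention_snapshot_ = None
        if snap_acc is not None and snap_n > 0:
            self.attention_snapshot_ = [
                {t: {r: v / snap_n for r, v in rels.items()}
                 for t, rels in layer.items()} for layer in snap_acc]
        self.train_report_ = report
        self.classes_ = np.array([0, 1])
        self._norm_adj_cache = norm_adj
        return self

    @staticmethod
    def _align_labels(graph, y):
        if isinstance(y, dict) or hasattr(y, "loc") and hasattr(y, "index"):
            return np.array([int(y[e]) for e in graph.schema.ids[ENC]])
        y = np.asarray(y, int)
        if len(y) != graph.n_encounters:
            raise ValueError("label vector does not match the encounter count")
        return y

    @staticmethod
    def _split_positions(graph, splits):
        n = graph.n_encounters
        if splits is None:
            return np.arange(n), np.array([], dtype=int)
        if hasattr(splits, "train"):
            train_ids, val_ids = splits.train, splits.validation
        else:
            train_ids = splits["train"]
            val_ids = splits.get("validation", [])
        pos = {e: i for i, e in enumerate(graph.schema.ids[ENC])}
        return (np.array([pos[e] for e in train_ids], dtype=int),
                np.array([pos[e] for e in val_ids], dtype=int))

    def _probs(self, graph, norm_adj=None):
        logits, _ = self.forward(graph, norm_adj, training=False)
        z = logits.value - logits.value.max(axis=1, keepdims=True)
        e = np.exp(z)
        return (e / e.sum(axis=1, keepdims=True))[:, 1]

    def predict_proba(self, graph: HetGraph):
        p1 = self._probs(graph, getattr(self, "_norm_adj_cache", None))
        return np.column_stack([1 - p1, p1])

    def predict(self, graph: HetGraph):
        return (self.predict_proba(graph)[:, 1] >= 0.5).astype(int)


def predict(model: IEHGCNClassifier, graph: HetGraph):
    """Positive-class probability per encounter."""
    return model.predict_proba(graph)[:, 1]


def train(graph: HetGraph, labels, splits, hyperparams=None, seed: int = 0):
    """Functional wrapper: fit an ``IEHGCNClassifier`` and return it + report."""
    model = IEHGCNClassifier(seed=seed, **(hyperparams or {}))
    model.fit(graph, labels, splits)
    return model, model.train_report_


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

#: search ranges used by default (model hyperparameter grid)
DEFAULT_SEARCH_SPACE = {
    "lr": ("loguniform", 1e-7, 1e-1),
    "weight_decay": ("loguniform", 1e-7, 1e-1),
    "dropout": ("uniform", 0.0, 0.8),
    "batch_norm": ("choice", [True, False]),
    "hidden_dim": ("choice", [32, 64, 128, 256]),
    "attn_dim": ("choice", [8, 16, 32, 64, 128]),
}


def _sample_config(space, rng):
    cfg = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "loguniform":
            cfg[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "uniform":
            cfg[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "choice":
            cfg[name] = spec[1][rng.integers(len(spec[1]))]
        else:
            raise ValueError(f"unknown space kind {kind!r}")
    return cfg

def _tpe_sample(space, trials, rng, gamma=0.25, n_candidates=16):
    """One tree-structured Parzen estimator proposal.

    Trials are split at the gamma-quantile of the score into good/bad sets;
    for each numeric parameter a Gaussian kernel density is placed on each
    observed value and candidates maximize the good/bad density ratio.
    """
    scores = np.array([t["score"] for t in trials])
    n_good = max(1, int(np.ceil(gamma * len(trials))))
    good_idx = np.argsort(-scores)[:n_good]
    good = [trials[i]["config"] for i in good_idx]
    bad = [trials[i]["config"] for i in range(len(trials)) if i not in set(good_idx)]
    cfg = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "choice":
            vals = [g[name] for g in good]
            counts = {c: vals.count(c) + 1 for c in spec[1]}
            probs = np.array([counts[c] for c in spec[1]], float)
            cfg[name] = spec[1][rng.choice(len(spec[1]), p=probs / probs.sum())]
            continue
        log = kind == "loguniform"
        tx = (lambda v: np.log(v)) if log else (lambda v: v)
        lo, hi = tx(spec[1]), tx(spec[2])
        gvals = np.array([tx(g[name]) for g in good])
        bvals = np.array([tx(b[name]) for b in bad]) if bad else np.array([])
        bw = max((hi - lo) / 10.0, 1e-12)

        def dens(x, centers):
            if len(centers) == 0:
                return np.full_like(x, 1.0 / (hi - lo))
            d = np.exp(-0.5 * ((x[:, None] - centers[None, :]) / bw) ** 2)
            return d.mean(axis=1) / (bw * np.sqrt(2 * np.pi)) + 1e-12

        cand = gvals[rng.integers(len(gvals), size=n_candidates)] \
            + rng.normal(0, bw, n_candidates)
        cand = np.clip(cand, lo, hi)
        ratio = dens(cand, gvals) / dens(cand, bvals)
        best = cand[np.argmax(ratio)]
        cfg[name] = float(np.exp(best)) if log else float(best)
    return cfg


def tune(graph: HetGraph, labels, splits, search_space=None, n_trials: int = 10,
         strategy: str = "random", seed: int = 0, fixed=None):
    """Maximize validation AUROC over the hyperparameter space.

    Returns ``(best_config, trial_log)``; the log records every trial's
    configuration and score.  ``strategy`` is "random" or "tpe" (random
    warm-up for the first 5 trials, Parzen proposals afterwards).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    space = search_space or DEFAULT_SEARCH_SPACE
    rng = np.random.default_rng(seed)
    trials = []
    for t in range(n_trials):
        if strategy == "tpe" and len(trials) >= 5:
            cfg = _tpe_sample(space, trials, rng)
        else:
            cfg = _sample_config(space, rng)
        hp = {**cfg, **(fixed or {})}
        model = IEHGCNClassifier(seed=seed + t, **hp)
        model.fit(graph, labels, splits)
        score = model.train_report_.best_val_auroc
        trials.append({"config": cfg, "score": float(score)})
    best = max(trials, key=lambda t: t["score"])
    return copy.deepcopy(best["config"]), trials
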