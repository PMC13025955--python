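"""Model interpretation: meta-path importance and local feature attribution.

Meta-path analysis (MPA) reads the trained model's type-level attention.
For every layer and target type the per-node attention coefficients are
averaged over nodes; a meta-path (a chain of node types starting at the
encounter type, e.g. Encounter-AcuteCareUnit-Encounter) gets the product of
the mean coefficients of its relations, taken from the output layer inward,
padded with the terminal type's self-relation coefficients on the remaining
inner layers.  Full-length relation sequences therefore carry a total
importance of exactly one (products of softmax-normalized coefficients).

Local attributions over encounter features use a permutation-sampling
Shapley estimator and a LIME-style weighted linear surrogate; both hold the
graph fixed and perturb a single encounter's feature row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hetgraph import ENC, HetGraph
from .iehgcn import SELF, IEHGCNClassifier


# ---------------------------------------------------------------------------
# meta-path analysis
# ---------------------------------------------------------------------------

def mean_attention(model: IEHGCNClassifier, graph: HetGraph) -> list:
    """Per-layer, per-target-type mean attention coefficients.

    Returns a list over layers of ``{target: {relation: mean coefficient}}``
    where relation is ``"self"`` or a source node type.  Neighbor-relation
    coefficients are averaged over the nodes that actually carry at least
    one edge of that relation (the mean coefficient *of the edges*): a
    node with no neighbors of a type receives a softmax coefficient for
    that type that says nothing about its influence.  The self relation
    averages over all nodes.  Each (layer, target) map is renormalized to
    sum to one, preserving conservation of the downstream products.

    If the model recorded trailing-epoch attention snapshots
    (``snapshot_attention``), the averaged record is used instead of a
    fresh forward pass.
    """
    if not hasattr(model, "layers_"):
        raise ValueError("model is not trained")
    attention = getattr(model, "attention_snapshot_", None)
    if attention is None:
        _, attention = model.forward(graph, training=False)
    out = []
    for layer in attention:
        lay = {}
        for target, rels in layer.items():
            means = {}
            for rel, coeffs in rels.items():
                if rel == SELF:
                    means[rel] = float(np.mean(coeffs))
                else:
                    deg = np.asarray(graph.adjacency(target, rel)
                                     .sum(axis=1)).ravel()
                    has = deg > 0
                    means[rel] = float(np.mean(coeffs[has])) if has.any() else 0.0
            total = sum(means.values())
            lay[target] = {r: m / total for r, m in means.items()}
        out.append(lay)
    return out


@dataclass
class MetaPath:
    node_types: tuple          # (ENC, ..., terminal), named encounter-first
    importance: float
    length: int

    @property
    def name(self) -> str:
        return "-".join(self.node_types)


def metapath_importance(mean_attn: list, max_length: int | None = None,
                        target: str = ENC) -> list:
    """Ranked meta-paths reachable from the target type.

    ``mean_attn`` comes from :func:`mean_attention` (one entry per layer,
    output layer last).  A path of length ``k`` scores the product of the
    mean coefficients of its ``k`` edges, read from the output layer
    inward — the coefficients *along the sequence of edges* and nothing
    else, so paths of different terminal types are compared on their own
    edges only.  The length-0 pure-feature path scores the product of the
    target's self coefficients across all layers.
    """
    L = len(mean_attn)
    max_length = L if max_length is None else max_length
    if max_length > L:
        raise ValueError(f"max_length {max_length} exceeds model depth {L}")
    layers_outward = mean_attn[::-1]  # output layer first
    self_chain = 1.0
    for d in range(L):
        self_chain *= layers_outward[d][target][SELF]
    paths = [MetaPath((target,), self_chain, 0)]

    def walk(node_type, depth, prod, chain):
        if depth > 0:
            paths.append(MetaPath(tuple(chain), prod, depth))
        if depth >= max_length:
            return
        for rel, coeff in layers_outward[depth][node_type].items():
            if rel == SELF:
                continue
            walk(rel, depth + 1, prod * coeff, chain + [rel])

    walk(target, 0, 1.0, [target])
    paths.sort(key=lambda p: -p.importance)
    return paths


def full_sequence_importances(mean_attn: list, target: str = ENC) -> dict:
    """Importance of every full-length relation-choice sequence.

    Enumerates all choices (self or neighbor) at every layer from the
    output inward; the values sum to one by construction.
    """
    L = len(mean_attn)
    layers_outward = mean_attn[::-1]
    out = {}

    def walk(node_type, depth, prod, seq):
        if depth == L:
            out[tuple(seq)] = prod
            return
        for rel, coeff in layers_outward[depth][node_type].items():
            nxt = node_type if rel == SELF else rel
            walk(nxt, depth + 1, prod * coeff, seq + [rel])

    walk(target, 0, 1.0, [])
    return out


# ---------------------------------------------------------------------------
# local attribution
# ---------------------------------------------------------------------------

@dataclass
class AttributionReport:
    values: np.ndarray
    method: str
    n_samples: int
    seed: int
    feature_names: list = field(default_factory=list)
    intercept: float = 0.0
    background: str = ""

    def as_dict(self) -> dict:
        names = self.feature_names or [f"x{i}" for i in range(len(self.values))]
        return {"method": self.method, "n_samples": self.n_samples,
                "seed": self.seed, "intercept": self.intercept,
                "background": self.background,
                "attributions": dict(zip(names, map(float, self.values)))}


def shapley_attribution(predict_fn, instance, background, n_permutations: int,
                        seed: int = 0, feature_names=None) -> AttributionReport:
    """Permutation-sampling Shapley values for one instance.

    ``predict_fn`` maps an (m, F) array to a probability vector;
    ``background`` is an (B, F) reference sample.  Each permutation draws
    one background row and walks the features in permuted order, crediting
    each feature with the change in prediction when its value switches from
    the background's to the instance's.  The attribution sum telescopes to
    f(instance) - f(background_row) per permutation, so efficiency holds
    exactly in expectation over the background.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    instance = np.asarray(instance, float).ravel()
    background = np.atleast_2d(np.asarray(background, float))
    if background.size == 0:
        raise ValueError("background is empty")
    F = len(instance)
    rng = np.random.default_rng(seed)
    phi = np.zeros(F)
    for _ in range(n_permutations):
        b = background[rng.integers(len(background))]
        order = rng.permutation(F)
        z = b.copy()
        prev = float(predict_fn(z[None, :])[0])
        # build all intermediate states, evaluate in one batch
        states = np.empty((F, F))
        for pos, j in enumerate(order):
            z[j] = instance[j]
            states[pos] = z
        preds = np.asarray(predict_fn(states), float).ravel()
        contrib = np.diff(np.concatenate([[prev], preds]))
        phi[order] += contrib
    phi /= n_permutations
    return AttributionReport(values=phi, method="shapley",
                             n_samples=n_permutations, seed=seed,
                             feature_names=list(feature_names or []),
                             background=f"{len(background)} reference rows")


def lime_explain(predict_fn, instance, n_samples: int, kernel_width: float,
                 seed: int = 0, perturb_scale: float | None = None,
                 feature_names=None) -> AttributionReport:
    """Local linear surrogate around one instance.

    Gaussian perturbations of scale ``perturb_scale`` (defaults to
    ``kernel_width``) are drawn around the instance, weighted by the
    exponential proximity kernel exp(-d^2 / (2 w^2)), and a weighted
    least-squares linear model is fitted; its coefficients are returned.
    A rank-deficient weighted design falls back to a tiny ridge penalty
    with a logged warning.
    """
    instance = np.asarray(instance, float).ravel()
    F = len(instance)
    if n_samples < F + 1:
        raise ValueError("n_samples must be >= number of features + 1")
    scale = kernel_width if perturb_scale is None else perturb_scale
    rng = np.random.default_rng(seed)
    X = instance[None, :] + scale * rng.standard_normal((n_samples, F))
    yv = np.asarray(predict_fn(X), float).ravel()
    d2 = ((X - instance[None, :]) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2.0 * kernel_width ** 2))
    sw = np.sqrt(w)
    design = np.column_stack([np.ones(n_samples), X - instance[None, :]])
    A = design * sw[:, None]
    b = yv * sw
    if np.linalg.matrix_rank(A) < F + 1:
        warnings.warn("singular weighted design; falling back to ridge")
        coef = np.linalg.solve(A.T @ A + 1e-8 * np.eye(F + 1), A.T @ b)
    else:
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return AttributionReport(values=coef[1:], method="surrogate",
                             n_samples=n_samples, seed=seed,
                             feature_names=list(feature_names or []),
                             intercept=float(coef[0]),
                             background="gaussian perturbations around instance")


def encounter_predict_fn(model: IEHGCNClassifier, graph: HetGraph,
                         encounter_id) -> tuple:
    """predict_fn over one encounter's feature row with the graph held fixed.

    Returns ``(fn, row)`` where ``fn`` maps an (m, F) array of candidate
    feature rows to the model's positive-class probability for that
    encounter.
    """
    if graph.enc_features is None:
        raise ValueError("graph has no encounter features")
    idx = graph.schema.ids[ENC].index(encounter_id)
    base = graph.enc_features.copy()

    def fn(rows):
        rows = np.atleast_2d(np.asarray(rows, float))
        out = np.empty(len(rows))
        for i, r in enumerate(rows):
            base[idx] = r
            feats_graph = HetGraph(schema=graph.schema, relations=graph.relations,
                                   enc_features=base, feature_names=graph.feature_names)
            out[i] = model.predict_proba(feats_graph)[idx, 1]
        return out

    return fn, graph.enc_features[idx].copy()
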