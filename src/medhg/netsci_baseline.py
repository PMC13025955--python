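"""Network-science feature battery and tabular machine-learning baselines.

The comparison arm represents care coordination with classical graph
metrics instead of learned embeddings: a single holistic provider-to-
provider interaction graph (undirected; edge weight = number of shared
encounters) and one small directed transfer graph per encounter (nodes =
care-unit types, edges = observed unit-to-unit moves).  Per-node metrics
(degree and weighted degree, betweenness / closeness / eigenvector
centrality, average neighbor-degree connectivity, local clustering, HITS
authority, PageRank) are aggregated per encounter into max / min / mean /
median / IQR summaries, joined with graph-level density, node count and
total edge weight, and fed to logistic regression, a 3-hidden-layer ReLU
MLP or gradient-boosted trees.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .evalstats import classification_metrics

NODE_METRICS = ("degree", "weighted_degree", "betweenness", "closeness",
                "eigenvector", "avg_degree_connectivity", "clustering",
                "authority", "pagerank")
AGGREGATIONS = ("max", "min", "mean", "median", "iqr")


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_provider_graph(assignments: pd.DataFrame, encounter_ids=None) -> nx.Graph:
    """Holistic provider co-occurrence graph over the given encounters.

    Every provider pair sharing an encounter gains +1 edge weight; no
    self-loops.  ``encounter_ids=None`` uses all encounters.
    """
    g = nx.Graph()
    if len(assignments) == 0:
        return g
    asg = assignments
    if encounter_ids is not None:
        asg = asg[asg["encounter_id"].isin(set(encounter_ids))]
    for _, group in asg.groupby("encounter_id"):
        providers = sorted(set(group["provider_id"]))
        g.add_nodes_from(providers)
        for a, b in combinations(providers, 2):
            w = g.edges[a, b]["weight"] + 1 if g.has_edge(a, b) else 1
            g.add_edge(a, b, weight=w)
    return g


def build_transfer_graph(transfers: pd.DataFrame, encounter_id) -> nx.DiGraph:
    """Directed unit-to-unit transfer graph of one encounter.

    Consecutive stays become directed edges with multiplicity; repeat
    stays in the same unit (self-transitions) are not drawn as edges.
    """
    sub = transfers[transfers["encounter_id"] == encounter_id]
    sub = sub.sort_values("sequence_index")
    seq = sub["sequence_index"].tolist()
    if seq != list(range(len(seq))):
        raise ValueError(
            f"non-contiguous transfer sequence for encounter {encounter_id!r}: {seq}")
    g = nx.DiGraph()
    units = sub["unit_type"].tolist()
    g.add_nodes_from(units)
    for u, v in zip(units[:-1], units[1:]):
        if u == v:
            continue  # re-entry raises the stay count, not an edge
        w = g.edges[u, v]["weight"] + 1 if g.has_edge(u, v) else 1
        g.add_edge(u, v, weight=w)
    return g


# ---------------------------------------------------------------------------
# metric battery
# ---------------------------------------------------------------------------

def _safe(fn, default):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # tiny graphs trip solver warnings
            return fn()
    except Exception:
        return default


def graph_metrics(graph) -> tuple:
    """Per-node metric table and graph-level scalars.

    Returns ``(per_node: DataFrame indexed by node, scalars: dict)``.
    Degenerate graphs degrade gracefully: an empty graph yields an empty
    table and zero scalars; metrics that fail to converge report zeros.
    """
    n = graph.number_of_nodes()
    scalars = {
        "density": float(nx.density(graph)) if n > 1 else 0.0,
        "n_nodes": float(n),
        "weighted_edges": float(sum(d.get("weight", 1.0)
                                    for _, _, d in graph.edges(data=True))),
    }
    if n == 0:
        return pd.DataFrame(columns=list(NODE_METRICS)), scalars
    nodes = list(graph.nodes)
    zeros = {v: 0.0 for v in nodes}
    deg = dict(graph.degree())
    wdeg = dict(graph.degree(weight="weight"))
    betw = _safe(lambda: nx.betweenness_centrality(graph), zeros)
    clos = _safe(lambda: nx.closeness_centrality(graph), zeros)
    eig = _safe(lambda: nx.eigenvector_centrality_numpy(graph, weight="weight"),
                zeros)
    adc_by_degree = _safe(lambda: nx.average_degree_connectivity(graph), {})
    adc = {v: float(adc_by_degree.get(deg[v], 0.0)) for v in nodes}
    clus = _safe(lambda: nx.clustering(graph.to_undirected() if graph.is_directed()
                                       else graph), zeros)
    hubs_auth = _safe(lambda: nx.hits(graph, max_iter=1000)[1], zeros)
    pr = _safe(lambda: nx.pagerank(graph, alpha=0.85, weight="weight",
                                   tol=1e-12, max_iter=1000), zeros)
    per_node = pd.DataFrame({
        "degree": pd.Series(deg, dtype=float),
        "weighted_degree": pd.Series(wdeg, dtype=float),
        "betweenness": pd.Series(betw, dtype=float),
        "closeness": pd.Series(clos, dtype=float),
        "eigenvector": pd.Series(eig, dtype=float).abs(),
        "avg_degree_connectivity": pd.Series(adc, dtype=float),
        "clustering": pd.Series(clus, dtype=float),
        "authority": pd.Series(hubs_auth, dtype=float),
        "pagerank": pd.Series(pr, dtype=float),
    }).loc[nodes]
    return per_node, scalars


def aggregate_metrics(per_node: pd.DataFrame, prefix: str = "") -> dict:
    """Five summaries per metric column; empty input -> zeros plus a flag."""
    out = {}
    empty = len(per_node) == 0
    out[f"{prefix}empty"] = 1.0 if empty else 0.0
    for metric in per_node.columns if not empty else NODE_METRICS:
        vals = per_node[metric].to_numpy(float) if not empty else None
        if empty:
            for agg in AGGREGATIONS:
                out[f"{prefix}{metric}_{agg}"] = 0.0
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out[f"{prefix}{metric}_max"] = float(vals.max())
        out[f"{prefix}{metric}_min"] = float(vals.min())
        out[f"{prefix}{metric}_mean"] = float(vals.mean())
        out[f"{prefix}{metric}_median"] = float(med)
        out[f"{prefix}{metric}_iqr"] = float(q3 - q1)
    return out


def network_feature_rows(assignments: pd.DataFrame, transfers: pd.DataFrame,
                         encounter_ids, provider_graph: nx.Graph | None = None
                         ) -> pd.DataFrame:
    """Per-encounter network feature rows from both graph sources.

    Provider metrics are computed on the induced subgraph of the
    encounter's own providers within the holistic graph; transfer metrics
    on the encounter's standalone transfer digraph.
    """
    pg = provider_graph if provider_graph is not None else \
        build_provider_graph(assignments)
    # sorted rosters keep node iteration order independent of hash seeds,
    # so metric floating-point is reproducible across processes
    by_enc = assignments.groupby("encounter_id")["provider_id"] \
        .apply(lambda s: sorted(set(s)))
    trf_encounters = set(transfers["encounter_id"]) if len(transfers) else set()
    rows = {}
    for enc in encounter_ids:
        feats = {}
        providers = by_enc.get(enc, [])
        sub = pg.subgraph([p for p in providers if p in pg])
        per_node, scalars = graph_metrics(sub)
        feats.update(aggregate_metrics(per_node, prefix="prov_"))
        feats.update({f"prov_{k}": v for k, v in scalars.items()})
        if enc in trf_encounters:
            tg = build_transfer_graph(transfers, enc)
        else:
            tg = nx.DiGraph()
        per_node, scalars = graph_metrics(tg)
        feats.update(aggregate_metrics(per_node, prefix="trf_"))
        feats.update({f"trf_{k}": v for k, v in scalars.items()})
        rows[enc] = feats
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "encounter_id"
    return out


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

#: random-search spaces for baseline tuning (model hyperparameter grid)
BASELINE_SPACES = {
    "lr": {"C": ("loguniform", 1e-6, 50.0),
           "class_weight": ("choice", ["balanced", None])},
    "mlp": {"alpha": ("loguniform", 1e-4, 0.99),
            "learning_rate": ("choice", ["constant", "adaptive"])},
    "gbt": {"n_estimators": ("int", 50, 600),
            "learning_rate": ("uniform", 0.01, 0.3),
            "max_depth": ("int", 3, 15),
            "subsample": ("uniform", 0.6, 1.0),
            "colsample_bytree": ("uniform", 0.5, 1.0)},
}


def _sample(space, rng):
    cfg = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "loguniform":
            cfg[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "uniform":
            cfg[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "int":
            cfg[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "choice":
            cfg[name] = spec[1][rng.integers(len(spec[1]))]
    return cfg


def _make_model(model_kind: str, cfg: dict, seed: int):
    if model_kind == "lr":
        return LogisticRegression(solver="newton-cg", penalty="l2",
                                  max_iter=500, C=cfg.get("C", 1.0),
                                  class_weight=cfg.get("class_weight"),
                                  random_state=seed)
    if model_kind == "mlp":
        return MLPClassifier(hidden_layer_sizes=(64, 64, 64), activation="relu",
                             solver="adam", learning_rate_init=1e-3,
                             max_iter=200, batch_size=200,
                             alpha=cfg.get("alpha", 1e-4),
                             learning_rate=cfg.get("learning_rate", "constant"),
                             random_state=seed)
    if model_kind == "gbt":
        from xgboost import XGBClassifier
        return XGBClassifier(reg_lambda=1.0, reg_alpha=0.0,
                             n_estimators=cfg.get("n_estimators", 200),
                             learning_rate=cfg.get("learning_rate", 0.1),
                             max_depth=cfg.get("max_depth", 6),
                             subsample=cfg.get("subsample", 1.0),
                             colsample_bytree=cfg.get("colsample_bytree", 1.0),
                             random_state=seed, n_jobs=1,
                             eval_metric="logloss", verbosity=0)
    raise ValueError(f"unknown model kind {model_kind!r}")


def fit_baseline(features: pd.DataFrame, labels, splits, model_kind: str = "gbt",
                 n_trials: int = 0, seed: int = 0, threshold: float = 0.5):
    """Fit and evaluate one tabular baseline.

    ``features`` is indexed by encounter id with no missing values;
    ``labels`` maps encounter id -> {0,1}; ``splits`` provides
    train/validation/test id lists.  With ``n_trials > 0`` a seeded random
    search maximizes validation AUROC before the final fit.  Returns
    ``(fitted model, MetricsReport on the test split)``.
    """
    if features.isna().any().any():
        raise ValueError("feature matrix contains missing values")
    lab = labels if isinstance(labels, (pd.Series, dict)) else \
        pd.Series(np.asarray(labels), index=features.index)
    train_ids, val_ids, test_ids = (list(splits.train), list(splits.validation),
                                    list(splits.test)) if hasattr(splits, "train") \
        else (list(splits["train"]), list(splits["validation"]), list(splits["test"]))
    Xtr = features.loc[train_ids].to_numpy(float)
    ytr = np.array([int(lab[i]) for i in train_ids])
    if len(np.unique(ytr)) < 2:
        raise ValueError("single-class training labels")
    Xva = features.loc[val_ids].to_numpy(float)
    yva = np.array([int(lab[i]) for i in val_ids])
    rng = np.random.default_rng(seed)
    best_cfg, best_auc = {}, -np.inf
    if n_trials > 0:
        from .evalstats import auroc as _auroc
        for t in range(n_trials):
            cfg = _sample(BASELINE_SPACES[model_kind], rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = _make_model(model_kind, cfg, seed)
                m.fit(Xtr, ytr)
            try:
                score = _auroc(yva, m.predict_proba(Xva)[:, 1])
            except ValueError:
                score = 0.5
            if score > best_auc:
                best_auc, best_cfg = score, cfg
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = _make_model(model_kind, best_cfg, seed)
        model.fit(Xtr, ytr)
    Xte = features.loc[test_ids].to_numpy(float)
    yte = np.array([int(lab[i]) for i in test_ids])
    report = classification_metrics(yte, model.predict_proba(Xte)[:, 1],
                                    threshold=threshold)
    return model, report
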