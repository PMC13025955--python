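"""Heterogeneous graph construction: encounters, provider roles, care units.

Node types: one encounter type (``ENC``), five provider subgroups and three
care-unit acuity levels.  Edges only run between encounters and the other
two classes: an encounter is linked to every provider assigned to it
(weight 1 per distinct pair) and to every unit type it stayed in pre-op
(weight = number of stays).  Providers and care units carry no input
features; only the encounter feature matrix enters the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse as sp

ENC = "ENC"
PROVIDER_NODE_TYPES = {
    "surgical_team": "P_surgical",
    "other_clinician": "P_other_clin",
    "nurse": "P_nurse",
    "technician": "P_tech",
    "other": "P_other",
}
UNIT_NODE_TYPES = {
    "intermediate": "C_intermediate",
    "intensive": "C_intensive",
    "acute": "C_acute",
}
ALL_NODE_TYPES = (ENC, *PROVIDER_NODE_TYPES.values(), *UNIT_NODE_TYPES.values())


@dataclass
class NodeSchema:
    """Per-type node id rosters with dense 0-based index maps."""

    ids: dict = field(default_factory=dict)  # type -> list of ids

    @property
    def types(self):
        return [t for t in ALL_NODE_TYPES if t in self.ids]

    def index(self, node_type: str) -> dict:
        return {nid: i for i, nid in enumerate(self.ids[node_type])}

    def n_nodes(self, node_type: str) -> int:
        return len(self.ids[node_type])


@dataclass
class HetGraph:
    """Typed adjacency container.

    Relations are stored once with the encounter type first; ``adjacency``
    mirrors transposes on access, so ``A[Γ−Ω] = A[Ω−Γ].T`` always holds.
    """

    schema: NodeSchema
    relations: dict  # (ENC, other_type) -> csr count matrix, rows = ENC
    enc_features: np.ndarray | None = None
    feature_names: list = field(default_factory=list)

    def adjacency(self, type_a: str, type_b: str):
        if (type_a, type_b) in self.relations:
            return self.relations[(type_a, type_b)]
        if (type_b, type_a) in self.relations:
            return self.relations[(type_b, type_a)].T.tocsr()
        raise KeyError(f"no relation between {type_a!r} and {type_b!r}")

    def neighbors_of(self, node_type: str):
        """Node types adjacent to ``node_type`` through a stored relation."""
        out = []
        for a, b in self.relations:
            if a == node_type:
                out.append(b)
            elif b == node_type:
                out.append(a)
        return sorted(set(out))

    @property
    def n_encounters(self) -> int:
        return self.schema.n_nodes(ENC)


def build_heterograph(encounters: pd.DataFrame, assignments: pd.DataFrame,
                      transfers: pd.DataFrame,
                      feature_matrix: pd.DataFrame | None = None) -> HetGraph:
    """Assemble the typed graph from the three event tables.

    Encounter node order follows the encounter table; provider/care-unit
    rosters are sorted for determinism.  Unrecognized provider role strings
    fall into the catch-all "other" subgroup.
    """
    enc_ids = encounters["encounter_id"].tolist()
    enc_index = {e: i for i, e in enumerate(enc_ids)}
    schema = NodeSchema(ids={ENC: enc_ids})
    relations = {}

    if len(assignments):
        unknown = set(assignments["encounter_id"]) - set(enc_index)
        if unknown:
            raise KeyError(f"assignment references unknown encounter {sorted(unknown)[0]!r}")
        asg = assignments.drop_duplicates(["encounter_id", "provider_id"])
        role = asg["role"].where(asg["role"].isin(PROVIDER_NODE_TYPES), "other")
        for role_name, ntype in PROVIDER_NODE_TYPES.items():
            sub = asg[role == role_name]
            if sub.empty:
                continue
            pids = sorted(sub["provider_id"].unique().tolist())
            pidx = {p: j for j, p in enumerate(pids)}
            rows = sub["encounter_id"].map(enc_index).to_numpy()
            cols = sub["provider_id"].map(pidx).to_numpy()
            A = sp.csr_matrix((np.ones(len(sub)), (rows, cols)),
                              shape=(len(enc_ids), len(pids)))
            schema.ids[ntype] = pids
            relations[(ENC, ntype)] = A

    if len(transfers):
        unknown = set(transfers["encounter_id"]) - set(enc_index)
        if unknown:
            raise KeyError(f"transfer references unknown encounter {sorted(unknown)[0]!r}")
        for unit, ntype in UNIT_NODE_TYPES.items():
            sub = transfers[transfers["unit_type"] == unit]
            if sub.empty:
                continue
            rows = sub["encounter_id"].map(enc_index).to_numpy()
            A = sp.csr_matrix((np.ones(len(sub)), (rows, np.zeros(len(sub), int))),
                              shape=(len(enc_ids), 1))
            schema.ids[ntype] = [unit]
            relations[(ENC, ntype)] = A

    feats, names = None, []
    if feature_matrix is not None:
        missing = set(enc_ids) - set(feature_matrix.index)
        if missing:
            raise KeyError(f"feature matrix lacks encounter {sorted(missing)[0]!r}")
        fm = feature_matrix.loc[enc_ids]
        feats = fm.to_numpy(dtype=float)
        names = list(fm.columns)
    return HetGraph(schema=schema, relations=relations,
                    enc_features=feats, feature_names=names)


def row_normalize(A):
    """Row-stochastic rescaling; all-zero rows pass through unchanged."""
    A = sp.csr_matrix(A, dtype=float)
    if A.nnz and A.data.min() < 0:
        raise ValueError("adjacency entries must be non-negative")
    rowsum = np.asarray(A.sum(axis=1)).ravel()
    inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
    return sp.diags(inv) @ A


def subgraph(g: HetGraph, keep_types, use_enc_features: bool = True) -> HetGraph:
    """Restrict to the given node types (the encounter type is mandatory).

    With ``use_enc_features=False`` the encounter feature matrix is removed;
    the model then falls back to its featureless-node convention (trainable
    per-node embeddings) for encounters too.
    """
    keep = set(keep_types)
    if ENC not in keep:
        raise ValueError("keep_types must contain the encounter type")
    schema = NodeSchema(ids={t: v for t, v in g.schema.ids.items() if t in keep})
    relations = {k: v for k, v in g.relations.items()
                 if k[0] in keep and k[1] in keep}
    feats = g.enc_features if use_enc_features else None
    names = list(g.feature_names) if use_enc_features else []
    return HetGraph(schema=schema, relations=relations,
                    enc_features=feats, feature_names=names)


def save_graph(g: HetGraph, outdir) -> None:
    """Serialize as relation triplet CSVs plus a JSON schema (human-diffable)."""
    import json
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"node_ids": {t: [str(x) for x in ids] for t, ids in g.schema.ids.items()},
                "relations": [], "feature_names": g.feature_names}
    for (a, b), A in g.relations.items():
        name = f"rel_{a}__{b}.csv"
        coo = A.tocoo()
        pd.DataFrame({"row": coo.row, "col": coo.col, "weight": coo.data}
                     ).to_csv(outdir / name, index=False)
        manifest["relations"].append({"a": a, "b": b, "file": name,
                                      "shape": list(A.shape)})
    if g.enc_features is not None:
        pd.DataFrame(g.enc_features, columns=g.feature_names,
                     index=g.schema.ids[ENC]).to_csv(outdir / "enc_features.csv")
    (outdir / "schema.json").write_text(json.dumps(manifest, indent=1))


def load_graph(indir) -> HetGraph:
    import json
    from pathlib import Path
    indir = Path(indir)
    manifest = json.loads((indir / "schema.json").read_text())
    schema = NodeSchema(ids=manifest["node_ids"])
    relations = {}
    for rel in manifest["relations"]:
        df = pd.read_csv(indir / rel["file"])
        relations[(rel["a"], rel["b"])] = sp.csr_matrix(
            (df["weight"], (df["row"], df["col"])), shape=tuple(rel["shape"]))
    feats, names = None, manifest.get("feature_names", [])
    fpath = indir / "enc_features.csv"
    if fpath.exists():
        fm = pd.read_csv(fpath, index_col=0)
        feats = fm.to_numpy(float)
        names = list(fm.columns)
    return HetGraph(schema=schema, relations=relations,
                    enc_features=feats, feature_names=names)
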