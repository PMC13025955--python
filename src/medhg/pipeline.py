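"""End-to-end experiment orchestration with a reproducibility manifest.

Stages run in dependency order: simulate -> prepare (labels, features,
splits) -> build-graph -> train -> evaluate -> explain -> baseline.  Every
stage's inputs and outputs are content-digested into a run manifest; all
randomness flows from named seeds in the experiment configuration, so a
rerun with the same configuration reproduces identical digests for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_features, evalstats, hetgraph, iehgcn, metapath_explain
from . import netsci_baseline, synthetic_ehr

log = logging.getLogger("medhg")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[medhg %(levelname)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

OUTCOMES = ("plos", "mort30", "mort90")


@dataclass
class ExperimentConfig:
    outcome: str = "plos"
    seed: int = 0
    out_dir: str = "medhg_run"
    synthetic: dict = field(default_factory=dict)     # SyntheticConfig overrides
    hyperparams: dict = field(default_factory=dict)   # IEHGCNClassifier overrides
    split_ratios: tuple = (8, 1, 1)
    group_by: str = "encounter"
    resample: str = "none"
    mask_spec: dict = field(default_factory=dict)
    ablation: str = "full"          # full | providers | units
    use_enc_features: bool = True
    baseline: str = "gbt"
    baseline_trials: int = 0
    threshold: float = 0.5

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if cfg.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {cfg.outcome!r}; choose from {OUTCOMES}")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _digest(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        return hashlib.sha256(obj.to_csv(index=False).encode()).hexdigest()
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str)
                          .encode()).hexdigest()


@dataclass
class RunManifest:
    stages: dict = field(default_factory=dict)
    seed: int = 0
    version: str = "0.1.0"
    failed_stage: str | None = None

    def record(self, stage: str, **info):
        info["wall_s"] = round(info.pop("wall_s", 0.0), 3)
        self.stages[stage] = info
        log.info("stage %s done (%.2fs)", stage, info["wall_s"])

    def write(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "version": self.version,
             "failed_stage": self.failed_stage, "stages": self.stages}, indent=1))


def run_experiment(config: ExperimentConfig) -> RunManifest:
    """Execute the full pipeline; the manifest is written even on failure."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    stage = "simulate"
    try:
        t0 = time.time()
        syn_cfg = synthetic_ehr.SyntheticConfig(
            **{**config.synthetic, "seed": config.seed})
        enc, asg, trf = synthetic_ehr.generate_cohort(syn_cfg)
        synthetic_ehr.tables_to_csv(enc, asg, trf, out / "tables")
        manifest.record(stage, digest=synthetic_ehr.tables_digest(enc, asg, trf),
                        n_encounters=len(enc), wall_s=time.time() - t0)

        stage = "prepare"
        t0 = time.time()
        if config.mask_spec:
            enc = cohort_features.mask_features(enc, config.mask_spec,
                                                seed=config.seed + 1)
        splits = cohort_features.split_indices(
            enc, ratios=config.split_ratios, seed=config.seed,
            group_by=config.group_by)
        labels_df = cohort_features.derive_outcomes(
            enc, reference_rows=splits.train)
        labels = labels_df.set_index("encounter_id")[config.outcome]
        matrix, featurizer = cohort_features.build_feature_matrix(
            enc, splits.train)
        train_ids = cohort_features.resample_training(
            splits.train, labels.loc[splits.train], config.resample,
            seed=config.seed + 2) if config.resample != "none" else splits.train
        matrix.to_csv(out / "features.csv")
        labels_df.to_csv(out / "labels.csv", index=False)
        (out / "split.json").write_text(json.dumps(splits.as_dict()))
        (out / "featurizer.json").write_text(
            json.dumps(featurizer.fitted_stats(), indent=1))
        manifest.record(stage, digest=_digest(matrix.reset_index()),
                        labels_digest=_digest(labels_df),
                        split_digest=_digest(splits.as_dict()),
                        threshold_days=float(labels_df["plos_threshold_days"].iloc[0]),
                        wall_s=time.time() - t0)

        stage = "build-graph"
        t0 = time.time()
        graph = hetgraph.build_heterograph(enc, asg, trf, matrix)
        if config.ablation == "providers":
            keep = {hetgraph.ENC, *hetgraph.PROVIDER_NODE_TYPES.values()}
            graph = hetgraph.subgraph(graph, keep, config.use_enc_features)
        elif config.ablation == "units":
            keep = {hetgraph.ENC, *hetgraph.UNIT_NODE_TYPES.values()}
            graph = hetgraph.subgraph(graph, keep, config.use_enc_features)
        elif not config.use_enc_features:
            graph = hetgraph.subgraph(graph, set(graph.schema.types), False)
        hetgraph.save_graph(graph, out / "graph")
        manifest.record(stage, node_counts={t: graph.schema.n_nodes(t)
                                            for t in graph.schema.types},
                        wall_s=time.time() - t0)

        stage = "train"
        t0 = time.time()
        model, report = iehgcn.train(
            graph, labels, splits,
            hyperparams=config.hyperparams, seed=config.seed)
        if config.resample != "none":
            # refit with the resampled multiset of training encounters
            model = iehgcn.IEHGCNClassifier(seed=config.seed, **config.hyperparams)
            model.fit(graph, labels, {"train": train_ids,
                                      "validation": splits.validation})
            report = model.train_report_
        (out / "train_report.json").write_text(json.dumps(report.as_dict(), indent=1))
        manifest.record(stage, best_epoch=report.best_epoch,
                        best_val_auroc=report.best_val_auroc,
                        wall_s=time.time() - t0)

        stage = "evaluate"
        t0 = time.time()
        probs = model.predict_proba(graph)[:, 1]
        pos = {e: i for i, e in enumerate(graph.schema.ids[hetgraph.ENC])}
        test_idx = np.array([pos[e] for e in splits.test])
        y_test = labels.loc[splits.test].to_numpy(int)
        metrics = evalstats.classification_metrics(
            y_test, probs[test_idx], threshold=config.threshold)
        try:
            metrics.ci["auroc"] = evalstats.bootstrap_ci(
                y_test, probs[test_idx], "auroc", n_boot=200, seed=config.seed)
            metrics.n_boot = 200
        except ValueError:
            pass
        (out / "metrics.json").write_text(json.dumps(metrics.as_dict(), indent=1))
        manifest.record(stage, auroc=metrics.auroc, recall=metrics.recall,
                        wall_s=time.time() - t0)

        stage = "explain"
        t0 = time.time()
        mean_attn = metapath_explain.mean_attention(model, graph)
        paths = metapath_explain.metapath_importance(mean_attn)
        path_rows = [{"path": p.name, "length": p.length,
                      "importance": p.importance} for p in paths]
        (out / "metapaths.json").write_text(json.dumps(path_rows, indent=1))
        manifest.record(stage, top_path=path_rows[0]["path"] if path_rows else None,
                        wall_s=time.time() - t0)

        stage = "baseline"
        t0 = time.time()
        net_feats = netsci_baseline.network_feature_rows(
            asg, trf, enc["encounter_id"].tolist())
        all_feats = matrix.join(net_feats, how="left").fillna(0.0)
        _, base_report = netsci_baseline.fit_baseline(
            all_feats, labels, splits, model_kind=config.baseline,
            n_trials=config.baseline_trials, seed=config.seed,
            threshold=config.threshold)
        (out / "baseline_metrics.json").write_text(
            json.dumps(base_report.as_dict(), indent=1))
        manifest.record(stage, auroc=base_report.auroc,
                        recall=base_report.recall, wall_s=time.time() - t0)
    except Exception as e:
        manifest.failed_stage = stage
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    manifest.write(out / "manifest.json")
    return manifest
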