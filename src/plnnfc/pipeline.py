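"""End-to-end orchestration: simulate -> features -> CV -> interpret ->
decision features -> hacking evaluation -> group statistics.

One global seed fans out to deterministic per-stage seeds so stages can be
rerun in isolation; every run writes its resolved configuration and a
machine-readable summary next to the artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .connectivity import EdgeIndexMap, LabeledDataset
from .decision import decision_feature_set, sweep
from .groupstats import group_stats, significance_summary
from .io import save_features, save_model
from .linearize import local_linear, verify_faithfulness
from .metrics import cross_validate
from .model import ModelConfig
from .perturb import cpp_nlci, random_set_cpp
from .synthetic import CohortSpec, planted_truth, simulate_dataset

log = logging.getLogger("plnnfc")

__all__ = ["RunConfig", "run_pipeline", "interpret_heldout", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived by hashing the stage name."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    model: ModelConfig | None = None
    cv_folds: int = 5
    K: int = 10
    epsilon: float = 0.70
    ranking: str = "abs"
    K_grid: list[int] = field(default_factory=lambda: list(range(5, 301, 5)))
    epsilon_grid: list[float] = field(default_factory=lambda: [0.70, 0.75, 0.80, 0.85, 0.90, 0.95])
    n_random_sets: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in raw:
            raw["cohort"] = CohortSpec(**{
                **raw["cohort"],
                "planted_edges": [tuple(e) for e in raw["cohort"].get(
                    "planted_edges", CohortSpec().planted_edges)],
            })
        if "model" in raw and raw["model"] is not None:
            raw["model"] = ModelConfig(**raw["model"])
        return cls(**raw)

    def resolved_model(self, d: int) -> ModelConfig:
        if self.model is not None:
            return self.model
        # scaled-down defaults for simulated cohorts
        return ModelConfig(
            layer_widths=[d, 16, 8, 1],
            dropout_rate=0.2,
            epochs=150,
            batch_size=32,
            seed=stage_seed(self.seed, "train"),
        )


def interpret_heldout(cv_result, X: np.ndarray):
    """One local linear model per subject, from the fold model that held it out."""
    llms = [None] * X.shape[0]
    for model, te in zip(cv_result.fold_models, cv_result.test_indices):
        for i in te:
            llms[i] = local_linear(model, X[i])
    return llms


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage on a simulated cohort and persist all artifacts.

    Returns the summary dict (also written as summary.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config

    def dump_cfg():
        doc = {
            "cohort": {**cfg.cohort.__dict__,
                       "planted_edges": [list(e) for e in cfg.cohort.planted_edges]},
            "model": cfg.model.__dict__ if cfg.model else None,
            **{k: getattr(cfg, k) for k in
               ("cv_folds", "K", "epsilon", "ranking", "K_grid", "epsilon_grid",
                "n_random_sets", "seed")},
        }
        (out / "config_resolved.yaml").write_text(yaml.safe_dump(doc))

    dump_cfg()

    log.info("stage=simulate p=%d n/group=%d", cfg.cohort.p, cfg.cohort.n_per_group)
    cohort_spec = CohortSpec(**{**cfg.cohort.__dict__, "seed": stage_seed(cfg.seed, "cohort")})
    ds = simulate_dataset(cohort_spec)
    save_features(ds, out / "features.csv")
    imap = EdgeIndexMap(ds.p)
    imap.to_frame().to_csv(out / "edge_index_map.csv", index=False)
    truth = planted_truth(cohort_spec, imap)

    log.info("stage=cv folds=%d", cfg.cv_folds)
    mcfg = cfg.resolved_model(ds.d)
    cv = cross_validate(ds.X, ds.y, mcfg, k=cfg.cv_folds, seed=stage_seed(cfg.seed, "cv"))
    summary_cv = cv.summary()
    for i, m in enumerate(cv.fold_models):
        save_model(m, out / f"model_fold{i}.h5")

    log.info("stage=interpret")
    llms = interpret_heldout(cv, ds.X)
    residual = max(
        verify_faithfulness(m, ds.X[te])
        for m, te in zip(cv.fold_models, cv.test_indices)
    )
    log.info("max linearization residual %.3e", residual)

    log.info("stage=decision-features K=%d eps=%.2f", cfg.K, cfg.epsilon)
    dfs = decision_feature_set(llms, cfg.K, cfg.epsilon, cfg.ranking)
    tbl = dfs.to_frame()
    pairs = [imap.pair(int(k)) for k in dfs.features]
    tbl["roi_i"] = [p[0] for p in pairs]
    tbl["roi_j"] = [p[1] for p in pairs]
    tbl.to_csv(out / "decision_features.csv", index=False)

    sw = sweep(llms, cfg.K_grid, cfg.epsilon_grid, cfg.ranking)
    sw.to_csv(out / "sweep.csv", index=False)

    log.info("stage=hack |F|=%d", dfs.features.size)
    hack = {}
    if dfs.features.size:
        reports = [
            cpp_nlci(m, ds.X[te], dfs.features, ds.y[te])
            for m, te in zip(cv.fold_models, cv.test_indices)
        ]
        rand = np.concatenate([
            random_set_cpp(m, ds.X[te], ds.y[te], dfs.features.size,
                           cfg.n_random_sets, stage_seed(cfg.seed, f"rand{i}"))
            for i, (m, te) in enumerate(zip(cv.fold_models, cv.test_indices))
        ])
        hack = {
            "feature_set_size": int(dfs.features.size),
            "mean_cpp": float(np.mean([r.mean_cpp for r in reports])),
            "nlci": int(np.sum([r.nlci for r in reports])),
            "post_sensitivity": float(np.mean([r.post_sensitivity for r in reports])),
            "post_accuracy": float(np.mean([r.post_accuracy for r in reports])),
            "random_cpp_median": float(np.median(rand)),
        }
        (out / "hack_report.json").write_text(json.dumps(hack, indent=2))

        gs = group_stats(ds, dfs.features)
        gs.to_csv(out / "group_stats.csv", index=False)
        sig = significance_summary(gs)
    else:
        sig = {"n_significant": 0, "n_not_significant": 0, "alpha": 0.05, "corrected": False}

    recovered = int(np.intersect1d(dfs.features, truth).size)
    summary = {
        "n_subjects": ds.n,
        "n_features": ds.d,
        "cv": {k: {"mean": v[0], "std": v[1]} for k, v in summary_cv.items()},
        "max_linearization_residual": float(residual),
        "decision_features": [int(k) for k in dfs.features],
        "planted_features": [int(k) for k in truth],
        "planted_recovered": recovered,
        "hack": hack,
        "group_stats_significance": sig,
        "seed": cfg.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
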