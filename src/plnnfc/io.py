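"""Artifact I/O: model checkpoints (HDF5), feature tables and manifests (CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectivity import LabeledDataset, RoiTimeSeries
from .model import BatchNormParams, ModelConfig, TrainedModel

__all__ = [
    "save_model",
    "load_model",
    "save_features",
    "load_features",
    "read_manifest",
    "write_cohort",
]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single HDF5 file: all dense and BN parameters plus the JSON config."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(model.config.__dict__)
        for l in range(model.n_layers):
            g = f.create_group(f"layer{l}")
            g.create_dataset("W", data=model.weights[l])
            g.create_dataset("b", data=model.biases[l])
            bn = model.bn[l]
            if bn is not None:
                for name in ("gamma", "beta", "running_mean", "running_var"):
                    g.create_dataset(name, data=getattr(bn, name))
        if model.feature_mean is not None:
            f.create_dataset("feature_mean", data=model.feature_mean)
            f.create_dataset("feature_scale", data=model.feature_scale)


def load_model(path: str | Path) -> TrainedModel:
    with h5py.File(path, "r") as f:
        config = ModelConfig(**json.loads(f.attrs["config"]))
        weights, biases, bn = [], [], []
        n_layers = len(config.layer_widths) - 1
        for l in range(n_layers):
            g = f[f"layer{l}"]
            weights.append(g["W"][...])
            biases.append(g["b"][...])
            if "gamma" in g:
                bn.append(
                    BatchNormParams(
                        gamma=g["gamma"][...],
                        beta=g["beta"][...],
                        running_mean=g["running_mean"][...],
                        running_var=g["running_var"][...],
                    )
                )
            else:
                bn.append(None)
        fm = f["feature_mean"][...] if "feature_mean" in f else None
        fs = f["feature_scale"][...] if "feature_scale" in f else None
    return TrainedModel(config, weights, biases, bn, feature_mean=fm, feature_scale=fs)


def save_features(dataset: LabeledDataset, path: str | Path) -> None:
    """Feature table CSV: subject_id, label, p, then one column per feature."""
    df = pd.DataFrame(dataset.X, columns=[f"f{k}" for k in range(dataset.d)])
    df.insert(0, "subject_id", dataset.subject_ids)
    df.insert(1, "label", dataset.y)
    df.insert(2, "p", dataset.p)
    df.to_csv(path, index=False)


def load_features(path: str | Path) -> LabeledDataset:
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    feat_cols.sort(key=lambda c: int(c[1:]))
    return LabeledDataset(
        X=df[feat_cols].to_numpy(float),
        y=df["label"].to_numpy(int),
        subject_ids=df["subject_id"].astype(str).tolist(),
        p=int(df["p"].iloc[0]),
    )


def read_manifest(path: str | Path) -> list[tuple[str, Path, int]]:
    """Manifest CSV (subject_id, path, label); paths resolved relative to it."""
    base = Path(path).parent
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        out.append((str(row["subject_id"]), p if p.is_absolute() else base / p, int(row["label"])))
    return out


def write_cohort(
    series: list[RoiTimeSeries], labels: list[int], out_dir: str | Path
) -> Path:
    """One TSV time series per subject plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, lab in zip(series, labels):
        fname = f"{ts.subject_id}.tsv"
        np.savetxt(out_dir / fname, ts.data, delimiter="\t")
        rows.append({"subject_id": ts.subject_id, "path": fname, "label": lab})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
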