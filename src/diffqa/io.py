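"""On-disk interchange: feature store, manifests, score tables, reports.

Difference maps are kept in one HDF5 container keyed by
``"{target_id}/{model_id}"``; each dataset carries the matrix plus the
sequence length, filter threshold, and distance-atom convention, so a store
is self-describing and inference can refuse incompatible checkpoints.
Tabular interchange is TSV throughout.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .maps import DifferenceMap, ModelRecord
from .metrics import EvalReport, MetricError, PoolModel, TargetPool
from .network import QualityPrediction
from .training import TrainHistory

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["target_id", "model_id", "length", "feature_key", "true_gdtts"]


class FeatureStore:
    """HDF5-backed store of difference maps with featurization metadata."""

    def __init__(self, path, mode: str = "r",
                 threshold: Optional[float] = None,
                 atom_convention: Optional[str] = None):
        self.path = Path(path)
        self._h5 = h5py.File(self.path, mode)
        if mode in ("w", "w-", "x"):
            self._h5.attrs["threshold"] = float(threshold)
            self._h5.attrs["atom_convention"] = str(atom_convention)

    @property
    def threshold(self) -> float:
        return float(self._h5.attrs["threshold"])

    @property
    def atom_convention(self) -> str:
        return str(self._h5.attrs["atom_convention"])

    def put(self, record: ModelRecord) -> str:
        key = f"{record.target_id}/{record.model_id}"
        ds = self._h5.create_dataset(
            key, data=record.difference_map.values.astype(np.float32)
        )
        ds.attrs["length"] = record.length
        if record.true_gdtts is not None:
            ds.attrs["true_gdtts"] = float(record.true_gdtts)
        return key

    def get(self, key: str) -> ModelRecord:
        ds = self._h5[key]
        target_id, model_id = key.split("/", 1)
        true = ds.attrs.get("true_gdtts")
        return ModelRecord(
            target_id, model_id,
            DifferenceMap(np.asarray(ds[...], dtype=np.float64)),
            true_gdtts=None if true is None else float(true),
            meta={"threshold": self.threshold,
                  "atom_convention": self.atom_convention},
        )

    def keys(self) -> list[str]:
        out = []
        self._h5.visititems(
            lambda name, obj: out.append(name)
            if isinstance(obj, h5py.Dataset) else None
        )
        return sorted(out)

    def close(self) -> None:
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def write_feature_manifest(path, rows: Sequence[dict]) -> None:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df["true_gdtts"] = df["true_gdtts"].map(
        lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v))
        else f"{v:.6f}"
    )
    df.to_csv(path, sep="\t", index=False)


def read_feature_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "model_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest lacks columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def write_predictions(path, predictions: Sequence[QualityPrediction]) -> None:
    pd.DataFrame(
        [{"target_id": p.target_id, "model_id": p.model_id,
          "predicted_gdtts": f"{p.predicted_gdtts:.6f}"} for p in predictions]
    ).to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "model_id": str})
    need = {"target_id", "model_id", "predicted_gdtts"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: predictions table needs columns {sorted(need)}")
    return df


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"target_id": str, "model_id": str})
    value_col = next(
        (c for c in ("true_gdtts", "true_quality") if c in df.columns), None
    )
    if value_col is None or not {"target_id", "model_id"} <= set(df.columns):
        raise ValueError(
            f"{path}: labels table needs target_id, model_id and "
            "true_gdtts/true_quality columns"
        )
    return df.rename(columns={value_col: "true_gdtts"})


def pools_from_tables(predictions: pd.DataFrame,
                      labels: pd.DataFrame) -> list[TargetPool]:
    """Join predictions with labels on (target_id, model_id) into pools."""
    merged = predictions.merge(labels, on=["target_id", "model_id"],
                               how="outer", indicator="join_side")
    bad = merged[merged["join_side"] != "both"]
    if len(bad):
        offenders = [
            f"{r.target_id}/{r.model_id} "
            f"({'no label' if r.join_side == 'left_only' else 'no prediction'})"
            for r in bad.head(10).itertuples()
        ]
        raise MetricError(
            f"{len(bad)} unmatched join keys between predictions and labels; "
            f"first offenders: {offenders}"
        )
    pools = []
    for target_id, grp in merged.groupby("target_id", sort=True):
        models = [
            PoolModel(r.model_id, float(r.true_gdtts), float(r.predicted_gdtts))
            for r in grp.sort_values("model_id").itertuples()
        ]
        pools.append(TargetPool(str(target_id), models))
    return pools


# ---------------------------------------------------------------------------
# Reports and history
# ---------------------------------------------------------------------------

def write_history(path, history: TrainHistory) -> None:
    rows = history.to_rows()
    df = pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss"])
    df["train_loss"] = df["train_loss"].map(lambda v: f"{v:.8f}")
    df["val_loss"] = df["val_loss"].map(
        lambda v: "" if v == "" else f"{v:.8f}"
    )
    df.to_csv(path, sep="\t", index=False)


def write_report(out_dir, report: EvalReport) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(report.per_target).to_csv(
        out / "per_target.tsv", sep="\t", index=False, float_format="%.6f"
    )
    with open(out / "summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, allow_nan=True)
        fh.write("\n")


def plot_report(out_dir, report: EvalReport, pools) -> None:
    """Best-vs-selected scatter and ranking-loss histogram (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    best = [p.best_true for p in pools]
    selected = [p.selected().true_gdtts for p in pools]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(selected, best, s=18, alpha=0.7)
    lim = [0, 1.02]
    ax.plot(lim, lim, color="goldenrod", lw=1, label="zero-loss line")
    ax.set_xlabel("true score of selected model")
    ax.set_ylabel("true score of best model")
    ax.set_xlim(lim), ax.set_ylim(lim)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "best_vs_selected.png", dpi=120)
    plt.close(fig)

    losses = [t["ranking_loss"] for t in report.per_target]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(losses, bins=20)
    ax.axvline(report.mean_ranking_loss, color="black", ls="--", lw=1,
               label=f"mean = {report.mean_ranking_loss:.3f}")
    ax.set_xlabel("ranking loss")
    ax.set_ylabel("targets")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out / "loss_histogram.png", dpi=120)
    plt.close(fig)
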