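"""Scikit-learn style estimator wrapping the quality network.

``MapQualityRegressor`` takes a list of upper-triangular distance-difference
maps (arbitrary, possibly differing side lengths) and regresses the global
quality score of each underlying structural model.  It follows the
scikit-learn protocol (``fit`` / ``predict`` / ``get_params``), so it
composes with sklearn model selection; the lower-level functional surface
(``build_network``, ``train``, ``predict``) remains available for pipelines
that manage records and checkpoints themselves.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .maps import DifferenceMap, ModelRecord
from .network import NetworkConfig, SECNN, build_network
from .network import predict as predict_records
from .training import TrainConfig, make_length_batches, split_batches, train


def _as_records(X, y=None) -> list[ModelRecord]:
    records = []
    for i, item in enumerate(X):
        if isinstance(item, ModelRecord):
            rec = item
            if y is not None:
                rec = ModelRecord(rec.target_id, rec.model_id,
                                  rec.difference_map, true_gdtts=float(y[i]))
            records.append(rec)
        else:
            dm = item if isinstance(item, DifferenceMap) else DifferenceMap(
                np.asarray(item, dtype=np.float64)
            )
            records.append(ModelRecord(
                target_id=f"t{i:06d}", model_id=f"m{i:06d}",
                difference_map=dm,
                true_gdtts=None if y is None else float(y[i]),
            ))
    return records


class MapQualityRegressor(BaseEstimator, RegressorMixin):
    """Channel-attentive CNN regressor for distance-difference maps.

    Parameters mirror the network and optimization configuration: four conv
    blocks (``conv_channels`` wide, ``conv_strides`` spatial steps), SE
    attention at ``se_block_positions`` with bottleneck ratio ``se_ratio``,
    four dense blocks ``dense_sizes`` ending in one output, smooth-L1 loss
    under Adam with a constant ``learning_rate``.  During ``fit`` the data
    are grouped into same-length batches and each batch contributes
    ``split_fraction`` of its members to the training split and the rest to
    an internal validation split used for best-epoch selection.

    Attributes
    ----------
    network_ : SECNN
        The trained network (weights of the best validation epoch).
    history_ : TrainHistory
        Per-epoch train/validation smooth-L1 losses.
    train_indices_, val_indices_ : list[int]
        Positions of X assigned to each internal split.
    """

    def __init__(
        self,
        conv_channels: tuple[int, ...] = (16, 32, 64, 256),
        conv_strides: tuple[int, ...] = (1, 2, 2, 2),
        kernel_size: int = 3,
        se_ratio: int = 16,
        se_block_positions: tuple[int, ...] = (1, 2),
        dense_sizes: tuple[int, ...] = (256, 64, 16, 1),
        negative_slope: float = 0.01,
        dtype: str = "float32",
        learning_rate: float = 5e-5,
        adam_beta1: float = 0.9,
        adam_beta2: float = 0.999,
        batch_size: int = 16,
        epochs: int = 120,
        split_fraction: float = 0.8,
        seed: int = 0,
    ):
        self.conv_channels = conv_channels
        self.conv_strides = conv_strides
        self.kernel_size = kernel_size
        self.se_ratio = se_ratio
        self.se_block_positions = se_block_positions
        self.dense_sizes = dense_sizes
        self.negative_slope = negative_slope
        self.dtype = dtype
        self.learning_rate = learning_rate
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.batch_size = batch_size
        self.epochs = epochs
        self.split_fraction = split_fraction
        self.seed = seed

    # ------------------------------------------------------------------

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            conv_channels=tuple(self.conv_channels),
            conv_strides=tuple(self.conv_strides),
            kernel_size=self.kernel_size,
            se_ratio=self.se_ratio,
            se_block_positions=tuple(self.se_block_positions),
            dense_sizes=tuple(self.dense_sizes),
            negative_slope=self.negative_slope,
            seed=self.seed,
            dtype=self.dtype,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            adam_beta1=self.adam_beta1,
            adam_beta2=self.adam_beta2,
            batch_size=self.batch_size,
            epochs=self.epochs,
            split_fraction=self.split_fraction,
            seed=self.seed,
        )

    def fit(self, X: Sequence, y: Optional[Sequence[float]] = None):
        records = _as_records(X, y)
        if any(r.true_gdtts is None for r in records):
            raise ValueError("fit requires a quality label for every map")
        index_of = {id(r): i for i, r in enumerate(records)}
        batches = make_length_batches(records, self.batch_size, seed=self.seed)
        train_recs, val_recs = split_batches(batches, self.split_fraction,
                                             seed=self.seed + 1)
        self.train_indices_ = [index_of[id(r)] for r in train_recs]
        self.val_indices_ = [index_of[id(r)] for r in val_recs]
        network = build_network(self.network_config())
        self.network_, self.history_ = train(network, train_recs, val_recs,
                                             self.train_config())
        return self

    def predict(self, X: Sequence) -> np.ndarray:
        check_is_fitted(self, "network_")
        records = _as_records(X)
        preds = predict_records(self.network_, records, self.batch_size)
        return np.array([p.predicted_gdtts for p in preds])

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "network_")
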