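"""QSAR models mapping SMILES to pIC50.

Two families:

- :class:`SmilesGruRegressor` — integer-encoded SMILES tokens through an
  embedding layer, stacked GRU cells, a ReLU dense layer and a linear
  output. Labels are standardized on the training portion only; training
  early-stops on a held-out validation split.
- :class:`EcfpRegressor` — classical baselines (SVR, random forest, KNN)
  and :class:`FcnnEcfpRegressor` (fully connected net with dropout) over
  4096-bit radius-3 Morgan fingerprints.

``train_qsar`` runs the evaluation protocol: 15% held-out test split, then
5-fold cross-validation over the remaining 85% (fold k is the validation
set for model k), reporting test MSE and Q^2 per fold. The fitted result
is a :class:`QsarEnsemble` whose prediction is the fold-mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

from . import smiles_data as sd
from .metrics import ecfp_bit_vector, featurize_ecfp  # noqa: F401 (re-export)
from .nn import Adam, Dense, Embedding, GRUStack, clip_gradients

__all__ = [
    "LabelScaler", "standardize_labels", "evaluate_qsar", "QsarReport",
    "SmilesGruRegressor", "EcfpRegressor", "FcnnEcfpRegressor",
    "QsarEnsemble", "train_qsar", "predict_activity", "featurize_ecfp",
]


@dataclass
class LabelScaler:
    """Standardization of regression labels (pIC50 units)."""

    mean: float
    std: float

    @classmethod
    def fit(cls, y: np.ndarray) -> "LabelScaler":
        y = np.asarray(y, dtype=float)
        if y.size < 2:
            raise ValueError("need at least two labels")
        std = float(np.std(y))
        if std == 0:
            raise ValueError("labels are constant; cannot standardize")
        return cls(mean=float(np.mean(y)), std=std)

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.mean) / self.std

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.std + self.mean


def standardize_labels(y) -> tuple[LabelScaler, np.ndarray]:
    """Fit a scaler and return (scaler, standardized labels)."""
    scaler = LabelScaler.fit(np.asarray(y, dtype=float))
    return scaler, scaler.transform(y)


def evaluate_qsar(y_true, y_pred) -> tuple[float, float]:
    """(MSE, Q^2) of held-out predictions.

    Q^2 = 1 - SS_res / SS_tot with SS_tot taken around the mean of
    ``y_true`` (the evaluation-set mean).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal-length, size >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true has zero variance")
    residual = y_true - y_pred
    mse = float(np.mean(residual ** 2))
    q2 = 1.0 - float(np.sum(residual ** 2)) / ss_tot
    return mse, q2


@dataclass
class QsarReport:
    mse: float
    q2: float
    per_fold: list[tuple[float, float]]


# ---------------------------------------------------------------------------
# SMILES -> GRU regressor
# ---------------------------------------------------------------------------

class SmilesGruRegressor(BaseEstimator, RegressorMixin):
    """Recurrent QSAR model over integer-encoded SMILES tokens.

    Architecture: embedding (embedding_dim) -> gru_layers x GRU(gru_units)
    -> dense ReLU (dense_units) -> linear output. Trained with Adam on MSE
    of standardized labels, elementwise gradient clipping, and early
    stopping on an internal validation split (``validation_fraction``)
    with the given ``patience``; the best-validation weights are restored.
    """

    def __init__(self, embedding_dim: int = 128, gru_layers: int = 2,
                 gru_units: int = 128, dense_units: int = 128,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 200, patience: int = 10,
                 validation_fraction: float = 0.15, clip_bound: float = 3.0,
                 random_state: int = 0) -> None:
        self.embedding_dim = embedding_dim
        self.gru_layers = gru_layers
        self.gru_units = gru_units
        self.dense_units = dense_units
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.clip_bound = clip_bound
        self.random_state = random_state

    # -- encoding ------------------------------------------------------------

    def _encode(self, smiles_list) -> tuple[np.ndarray, np.ndarray]:
        """Integer-encode a batch, padded to the batch maximum length."""
        token_ids = []
        for smiles in smiles_list:
            ids = self.vocab_.to_ids(sd.tokenize(smiles))
            if not ids:
                raise ValueError(f"empty token sequence for {smiles!r}")
            token_ids.append(ids)
        lengths = np.array([len(t) for t in token_ids])
        out = np.full((len(token_ids), int(lengths.max())),
                      self.vocab_.pad_id, dtype=np.int64)
        for i, ids in enumerate(token_ids):
            out[i, : len(ids)] = ids
        return out, lengths

    # -- forward/backward ----------------------------------------------------

    def _forward(self, ids: np.ndarray, lengths: np.ndarray
                 ) -> tuple[np.ndarray, dict]:
        vectors, emb_cache = self._emb.forward(ids)
        hidden, gru_cache = self._gru.forward(vectors)
        rows = np.arange(ids.shape[0])
        last_h = hidden[rows, lengths - 1, :]
        dense_out, dense_cache = self._dense.forward(last_h)
        pred, out_cache = self._out.forward(dense_out)
        cache = {"emb": emb_cache, "gru": gru_cache, "dense": dense_cache,
                 "out": out_cache, "lengths": lengths,
                 "hidden_shape": hidden.shape}
        return pred[:, 0], cache

    def _backward(self, dpred: np.ndarray, cache: dict) -> dict:
        out_grads, ddense = self._out.backward(dpred[:, None], cache["out"])
        dense_grads, dlast_h = self._dense.backward(ddense, cache["dense"])
        dh_seq = np.zeros(cache["hidden_shape"])
        rows = np.arange(dlast_h.shape[0])
        dh_seq[rows, cache["lengths"] - 1, :] = dlast_h
        gru_grads, dvectors = self._gru.backward(dh_seq, cache["gru"])
        emb_grads = self._emb.backward(dvectors, cache["emb"])
        return {**emb_grads, **gru_grads, **dense_grads, **out_grads}

    # -- training ------------------------------------------------------------

    def fit(self, X, y):
        smiles = list(X)
        y = np.asarray(y, dtype=float)
        if len(smiles) != y.size:
            raise ValueError("X and y length mismatch")
        rng = np.random.default_rng(self.random_state)
        self.vocab_ = sd.Vocabulary.from_corpus(smiles)
        init_rng = np.random.default_rng(rng.integers(2**31))
        self._emb = Embedding(self.vocab_.size, self.embedding_dim, init_rng)
        self._gru = GRUStack(self.embedding_dim, self.gru_units,
                             self.gru_layers, init_rng)
        self._dense = Dense(self.gru_units, self.dense_units, init_rng,
                            name="dense", relu=True)
        self._out = Dense(self.dense_units, 1, init_rng, name="out")
        self.params_ = {**self._emb.params, **self._gru.params,
                        **self._dense.params, **self._out.params}

        idx = rng.permutation(len(smiles))
        n_val = max(1, int(round(self.validation_fraction * len(smiles))))
        val_idx, train_idx = idx[:n_val], idx[n_val:]
        # scaler fitted on the training portion only (no leakage)
        self.scaler_ = LabelScaler.fit(y[train_idx])
        z = self.scaler_.transform(y)

        train_smiles = [smiles[i] for i in train_idx]
        val_smiles = [smiles[i] for i in val_idx]
        z_train, z_val = z[train_idx], z[val_idx]

        opt = Adam(lr=self.learning_rate)
        best_val = np.inf
        best_params = None
        stall = 0
        self.history_ = []
        n = len(train_smiles)
        for _ in range(self.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                ids, lengths = self._encode([train_smiles[i] for i in sel])
                pred, cache = self._forward(ids, lengths)
                err = pred - z_train[sel]
                losses.append(float(np.mean(err ** 2)))
                dpred = 2.0 * err / err.size
                grads = self._backward(dpred, cache)
                opt.step(self.params_, clip_gradients(grads, self.clip_bound))
            val_pred = self._predict_standardized(val_smiles)
            val_mse = float(np.mean((val_pred - z_val) ** 2))
            self.history_.append({"train_mse": float(np.mean(losses)),
                                  "val_mse": val_mse})
            if val_mse < best_val - 1e-9:
                best_val = val_mse
                best_params = {k: v.copy() for k, v in self.params_.items()}
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_params is not None:
            for k in self.params_:
                self.params_[k][...] = best_params[k]
        return self

    def _predict_standardized(self, smiles_list) -> np.ndarray:
        preds = np.empty(len(smiles_list))
        for start in range(0, len(smiles_list), 256):
            chunk = smiles_list[start:start + 256]
            ids, lengths = self._encode(chunk)
            preds[start:start + len(chunk)], _ = self._forward(ids, lengths)
        return preds

    def predict(self, X) -> np.ndarray:
        smiles = [X] if isinstance(X, str) else list(X)
        z = self._predict_standardized(smiles)
        return self.scaler_.inverse(z)


# ---------------------------------------------------------------------------
# ECFP baselines
# ---------------------------------------------------------------------------

class FcnnEcfpRegressor(BaseEstimator, RegressorMixin):
    """Fully connected net over ECFP bits with inter-layer dropout.

    Hidden ReLU layers (8000/4000/2000 at full scale) with inverted dropout
    between them, linear output, Adam on MSE of standardized labels, early
    stopping on a validation split.
    """

    def __init__(self, hidden=(8000, 4000, 2000), dropout: float = 0.25,
                 learning_rate: float = 1e-3, batch_size: int = 32,
                 max_epochs: int = 200, patience: int = 10,
                 validation_fraction: float = 0.15, clip_bound: float = 3.0,
                 random_state: int = 0) -> None:
        self.hidden = hidden
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.clip_bound = clip_bound
        self.random_state = random_state

    def _forward(self, x: np.ndarray, train: bool,
                 rng: np.random.Generator | None) -> tuple[np.ndarray, list]:
        caches = []
        out = x
        for i, layer in enumerate(self._layers):
            out, cache = layer.forward(out)
            if train and self.dropout > 0 and i < len(self._layers) - 1:
                keep = 1.0 - self.dropout
                mask = (rng.random(out.shape) < keep) / keep
                out = out * mask
                cache["drop_mask"] = mask
            caches.append(cache)
        return out[:, 0], caches

    def _backward(self, dpred: np.ndarray, caches: list) -> dict:
        grads: dict = {}
        d = dpred[:, None]
        for layer, cache in zip(reversed(self._layers), reversed(caches)):
            if "drop_mask" in cache:
                d = d * cache["drop_mask"]
            layer_grads, d = layer.backward(d, cache)
            grads.update(layer_grads)
        return grads

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.random_state)
        init_rng = np.random.default_rng(rng.integers(2**31))
        dims = [x.shape[1], *self.hidden, 1]
        self._layers = [
            Dense(dims[i], dims[i + 1], init_rng, name=f"fc{i}",
                  relu=(i < len(dims) - 2))
            for i in range(len(dims) - 1)
        ]
        self.params_ = {}
        for layer in self._layers:
            self.params_.update(layer.params)

        idx = rng.permutation(len(y))
        n_val = max(1, int(round(self.validation_fraction * len(y))))
        val_idx, train_idx = idx[:n_val], idx[n_val:]
        self.scaler_ = LabelScaler.fit(y[train_idx])
        z = self.scaler_.transform(y)

        opt = Adam(lr=self.learning_rate)
        best_val, best_params, stall = np.inf, None, 0
        n = len(train_idx)
        for _ in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                sel = train_idx[order[start:start + self.batch_size]]
                pred, caches = self._forward(x[sel], True, rng)
                err = pred - z[sel]
                dpred = 2.0 * err / err.size
                grads = self._backward(dpred, caches)
                opt.step(self.params_, clip_gradients(grads, self.clip_bound))
            val_pred, _ = self._forward(x[val_idx], False, None)
            val_mse = float(np.mean((val_pred - z[val_idx]) ** 2))
            if val_mse < best_val - 1e-9:
                best_val = val_mse
                best_params = {k: v.copy() for k, v in self.params_.items()}
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_params is not None:
            for k in self.params_:
                self.params_[k][...] = best_params[k]
        return self

    def predict(self, X) -> np.ndarray:
        pred, _ = self._forward(np.asarray(X, dtype=float), False, None)
        return self.scaler_.inverse(pred)


class EcfpRegressor(BaseEstimator, RegressorMixin):
    """Classical QSAR baselines over Morgan fingerprint bits.

    model_kind: "svr_ecfp" (poly kernel, C=0.125, gamma=8), "rf_ecfp"
    (500 trees, sqrt features), "knn_ecfp" (k=11, Euclidean) or
    "fcnn_ecfp" (delegates to :class:`FcnnEcfpRegressor`). Accepts SMILES
    and featurizes internally; labels standardized on the training data.
    """

    def __init__(self, model_kind: str = "svr_ecfp", svr_c: float = 0.125,
                 svr_gamma: float = 8.0, rf_estimators: int = 500,
                 knn_k: int = 11, fcnn_hidden=(8000, 4000, 2000),
                 fcnn_dropout: float = 0.25, random_state: int = 0) -> None:
        self.model_kind = model_kind
        self.svr_c = svr_c
        self.svr_gamma = svr_gamma
        self.rf_estimators = rf_estimators
        self.knn_k = knn_k
        self.fcnn_hidden = fcnn_hidden
        self.fcnn_dropout = fcnn_dropout
        self.random_state = random_state

    def _make(self):
        if self.model_kind == "svr_ecfp":
            return SVR(kernel="poly", C=self.svr_c, gamma=self.svr_gamma)
        if self.model_kind == "rf_ecfp":
            return RandomForestRegressor(n_estimators=self.rf_estimators,
                                         max_features="sqrt",
                                         random_state=self.random_state)
        if self.model_kind == "knn_ecfp":
            return KNeighborsRegressor(n_neighbors=self.knn_k,
                                       metric="euclidean")
        if self.model_kind == "fcnn_ecfp":
            return FcnnEcfpRegressor(hidden=self.fcnn_hidden,
                                     dropout=self.fcnn_dropout,
                                     random_state=self.random_state)
        raise ValueError(f"unknown model_kind {self.model_kind!r}")

    def fit(self, X, y):
        features = np.stack([ecfp_bit_vector(s) for s in X])
        y = np.asarray(y, dtype=float)
        self.model_ = self._make()
        if self.model_kind == "fcnn_ecfp":
            # neural baseline standardizes internally (train portion only)
            self.model_.fit(features, y)
            self.scaler_ = self.model_.scaler_
        else:
            self.scaler_, z = standardize_labels(y)
            self.model_.fit(features, z)
        return self

    def predict(self, X) -> np.ndarray:
        smiles = [X] if isinstance(X, str) else list(X)
        features = np.stack([ecfp_bit_vector(s) for s in smiles])
        if self.model_kind == "fcnn_ecfp":
            return self.model_.predict(features)
        return self.scaler_.inverse(self.model_.predict(features))


# ---------------------------------------------------------------------------
# Cross-validation protocol and ensemble
# ---------------------------------------------------------------------------

@dataclass
class QsarEnsemble:
    """Fold models plus the evaluation report; prediction is the fold mean."""

    models: list
    report: QsarReport
    test_smiles: list[str]
    test_labels: np.ndarray
    trainval_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None
    fold_validation_indices: list[np.ndarray] | None = None

    def predict(self, X) -> np.ndarray:
        smiles = [X] if isinstance(X, str) else list(X)
        preds = np.stack([m.predict(smiles) for m in self.models])
        return preds.mean(axis=0)

    def __call__(self, smiles: str) -> float:
        return float(self.predict(smiles)[0])


def _make_estimator(model_kind: str, config: dict | None, seed: int):
    config = dict(config or {})
    if model_kind == "smiles_rnn":
        return SmilesGruRegressor(random_state=seed, **config)
    return EcfpRegressor(model_kind=model_kind, random_state=seed, **config)


def train_qsar(data, model_kind: str = "smiles_rnn",
               config: dict | None = None, seed: int = 0,
               test_fraction: float = 0.15, folds: int = 5,
               min_records: int = 50) -> QsarEnsemble:
    """Full QSAR protocol on (smiles, pIC50) data.

    data: DataFrame with columns smiles/pIC50, or an iterable of pairs.
    Splits off ``test_fraction`` as the held-out test set, partitions the
    remainder into ``folds`` disjoint folds, trains one model per fold
    (the fold itself serves as that model's validation data where the
    estimator uses one), and evaluates every fold model on the held-out
    test set. The report averages per-fold (MSE, Q^2).
    """
    if isinstance(data, pd.DataFrame):
        smiles = data["smiles"].tolist()
        y = data["pIC50"].to_numpy(dtype=float)
    else:
        pairs = list(data)
        smiles = [p[0] for p in pairs]
        y = np.asarray([p[1] for p in pairs], dtype=float)
    if len(smiles) < min_records:
        raise ValueError(f"need at least {min_records} records, got {len(smiles)}")
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")

    idx_trainval, idx_test = train_test_split(
        np.arange(len(smiles)), test_size=test_fraction, random_state=seed)
    test_smiles = [smiles[i] for i in idx_test]
    y_test = y[idx_test]

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    models = []
    per_fold: list[tuple[float, float]] = []
    fold_val: list[np.ndarray] = []
    for fold_id, (fit_rel, val_rel) in enumerate(kf.split(idx_trainval)):
        fit_idx = idx_trainval[fit_rel]
        fold_val.append(idx_trainval[val_rel])
        est = _make_estimator(model_kind, config, seed + fold_id)
        est.fit([smiles[i] for i in fit_idx], y[fit_idx])
        pred = est.predict(test_smiles)
        per_fold.append(evaluate_qsar(y_test, pred))
        models.append(est)
    mse = float(np.mean([m for m, _ in per_fold]))
    q2 = float(np.mean([q for _, q in per_fold]))
    report = QsarReport(mse=mse, q2=q2, per_fold=per_fold)
    return QsarEnsemble(models=models, report=report,
                        test_smiles=test_smiles, test_labels=y_test,
                        trainval_indices=idx_trainval, test_indices=idx_test,
                        fold_validation_indices=fold_val)


def predict_activity(ensemble: QsarEnsemble, smiles: str) -> float:
    """Fold-ensemble mean pIC50 prediction for one SMILES."""
    return float(ensemble.predict(smiles)[0])
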