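"""Per-residue disorder classifiers.

Two scikit-learn-style estimators share the same feature space:

* :class:`DisorderNet` — a small feedforward network (default 64- and 8-unit
  hidden layers with ReLU, sigmoid output, dropout 0.2 after the input and
  after the first hidden layer), trained with Adam on class-weighted binary
  cross-entropy and early-stopped on validation ROC-AUC. Implemented directly
  in numpy so training is fully deterministic given a seed.
* :class:`DisorderLogistic` — the logistic-regression twin on the identical
  features, wrapping scikit-learn's solver.

Binary calls use the strict rule "propensity > threshold"; the threshold is
selected on validation data to maximise F1 over the candidate set of all
unique predicted propensities.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score


def _check_two_classes(y: np.ndarray, context: str) -> None:
    if np.unique(y).size < 2:
        raise ValueError(f"{context}: labels contain a single class")


def select_threshold(propensities: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximising F1 on validation data.

    Candidates are all unique propensities; a residue is called positive when
    its propensity is strictly greater than the threshold. Ties in F1 are
    broken toward the smaller threshold.
    """
    prop = np.asarray(propensities, dtype=float)
    y = np.asarray(labels)
    if prop.shape != y.shape:
        raise ValueError("propensities and labels must have equal length")
    _check_two_classes(y, "select_threshold")
    order = np.argsort(prop, kind="stable")
    sp, sl = prop[order], y[order].astype(float)
    suffix_pos = np.concatenate([np.cumsum(sl[::-1])[::-1], [0.0]])
    total_pos = suffix_pos[0]
    uniq = np.unique(sp)
    # residues with propensity > t start at searchsorted(side="right")
    starts = np.searchsorted(sp, uniq, side="right")
    tp = suffix_pos[starts]
    n_pred = len(sp) - starts
    f1 = np.where(n_pred + total_pos > 0, 2 * tp / (n_pred + total_pos), 0.0)
    best = np.argmax(f1)  # argmax keeps the first (smallest) threshold on ties
    return float(uniq[best])


def binarize(propensities: np.ndarray, threshold: float) -> np.ndarray:
    """Strictly-greater-than thresholding to a 0/1 track."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    return (np.asarray(propensities, dtype=float) > threshold).astype(np.int8)


def _f1_from_threshold(prop: np.ndarray, y: np.ndarray, t: float) -> float:
    pred = prop > t
    tp = float(np.sum(pred & (y == 1)))
    denom = pred.sum() + (y == 1).sum()
    return 2 * tp / denom if denom else 0.0


class DisorderNet(BaseEstimator, ClassifierMixin):
    """Feedforward per-residue disorder classifier (numpy implementation).

    Parameters
    ----------
    hidden_layer_sizes : widths of the hidden layers (default ``(64, 8)``).
    dropout : dropout rate applied after the input and after the first hidden
        layer during training (default 0.2).
    learning_rate, batch_size, max_epochs, patience : Adam step size,
        minibatch size, epoch cap, and early-stopping patience in epochs
        without validation-AUC improvement.
    validation_fraction : residue fraction held out for early stopping when
        no explicit validation set is passed to :meth:`fit`.
    seed : controls initialisation, shuffling and dropout masks; the same
        seed and data reproduce propensities exactly.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (64, 8),
        dropout: float = 0.2,
        learning_rate: float = 1e-3,
        batch_size: int = 256,
        max_epochs: int = 200,
        patience: int = 10,
        validation_fraction: float = 0.1,
        seed: int = 0,
    ) -> None:
        self.hidden_layer_sizes = hidden_layer_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed

    # ---- architecture helpers -------------------------------------------

    def _layer_dims(self, input_dim: int) -> list[int]:
        return [input_dim, *self.hidden_layer_sizes, 1]

    def n_parameters(self, input_dim: int | None = None) -> int:
        dims = self._layer_dims(input_dim or self.n_features_in_)
        return sum(dims[i] * dims[i + 1] + dims[i + 1] for i in range(len(dims) - 1))

    def _init_params(self, input_dim: int, rng: np.random.Generator):
        dims = self._layer_dims(input_dim)
        W, b = [], []
        for i in range(len(dims) - 1):
            scale = np.sqrt(2.0 / dims[i])  # He init for the ReLU stack
            W.append(rng.normal(0.0, scale, size=(dims[i], dims[i + 1])))
            b.append(np.zeros(dims[i + 1]))
        return W, b

    def _forward(self, X, W, b, rng=None):
        """Forward pass; with ``rng`` set, applies inverted dropout and
        returns the cached activations for backprop."""
        drop_after = {0, 1}  # after input and after first hidden layer
        a = X
        cache = []
        for i in range(len(W)):
            if rng is not None and i in drop_after and self.dropout > 0:
                mask = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
                a = a * mask
            z = a @ W[i] + b[i]
            if i < len(W) - 1:
                out = np.maximum(z, 0.0)
            else:
                out = 1.0 / (1.0 + np.exp(-z))
            cache.append((a, z))
            a = out
        return a[:, 0], cache

    # ---- training -------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        _check_two_classes(y, "DisorderNet.fit")
        rng = np.random.default_rng(self.seed)

        if X_val is None:
            n_val = max(2, int(round(self.validation_fraction * len(y))))
            perm = rng.permutation(len(y))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
            if np.unique(y[val_idx]).size < 2 or np.unique(y[train_idx]).size < 2:
                # fall back to a stratified split
                pos = np.flatnonzero(y == 1)
                neg = np.flatnonzero(y == 0)
                val_idx = np.concatenate([pos[: max(1, len(pos) // 10)], neg[: max(1, len(neg) // 10)]])
                train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
            X_val, y_val = X[val_idx], y[val_idx]
            X, y = X[train_idx], y[train_idx]
        else:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val).astype(float).ravel()
        _check_two_classes(y_val, "DisorderNet.fit (validation)")

        if sample_weight is None:
            # inverse class-frequency weights, normalised to mean 1
            pos_frac = y.mean()
            sample_weight = np.where(y == 1, 0.5 / pos_frac, 0.5 / (1 - pos_frac))
        sample_weight = np.asarray(sample_weight, dtype=float)

        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        W, b = self._init_params(X.shape[1], rng)
        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(x) for x in b]
        vb = [np.zeros_like(x) for x in b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        best_auc, best_epoch, since_best = -np.inf, -1, 0
        best_W = [w.copy() for w in W]
        best_b = [x.copy() for x in b]
        history = []
        n = len(y)

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb, wb = X[idx], y[idx], sample_weight[idx]
                p, cache = self._forward(xb, W, b, rng=rng)
                # d(weighted BCE)/dz at the sigmoid output
                delta = (wb * (p - yb) / len(idx))[:, None]
                for i in range(len(W) - 1, -1, -1):
                    a_in, z = cache[i]
                    gW = a_in.T @ delta
                    gb = delta.sum(axis=0)
                    if i > 0:
                        delta = (delta @ W[i].T) * (cache[i][0] > 0)
                    step_i = step  # same Adam step count for all layers
                    mW[i] = beta1 * mW[i] + (1 - beta1) * gW
                    vW[i] = beta2 * vW[i] + (1 - beta2) * gW**2
                    mb[i] = beta1 * mb[i] + (1 - beta1) * gb
                    vb[i] = beta2 * vb[i] + (1 - beta2) * gb**2
                    t = step_i + 1
                    mhW = mW[i] / (1 - beta1**t)
                    vhW = vW[i] / (1 - beta2**t)
                    mhb = mb[i] / (1 - beta1**t)
                    vhb = vb[i] / (1 - beta2**t)
                    W[i] -= self.learning_rate * mhW / (np.sqrt(vhW) + eps)
                    b[i] -= self.learning_rate * mhb / (np.sqrt(vhb) + eps)
                step += 1
            val_prop, _ = self._forward(X_val, W, b)
            auc = roc_auc_score(y_val, val_prop)
            history.append(auc)
            if auc > best_auc:
                best_auc, best_epoch, since_best = auc, epoch, 0
                best_W = [w.copy() for w in W]
                best_b = [x.copy() for x in b]
            else:
                since_best += 1
                if since_best >= self.patience:
                    break

        self.coefs_ = best_W
        self.intercepts_ = best_b
        self.best_epoch_ = best_epoch
        self.validation_auc_ = float(best_auc)
        self.validation_auc_history_ = history
        val_prop = self.propensity(X_val)
        self.threshold_ = select_threshold(val_prop, y_val.astype(int))
        return self

    # ---- prediction ------------------------------------------------------

    def _check_dim(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1] if X.ndim == 2 else X.shape} "
                f"does not match model input dimension {self.n_features_in_}"
            )
        return X

    def propensity(self, X) -> np.ndarray:
        """Per-residue disorder propensities in [0,1] (dropout disabled)."""
        X = self._check_dim(X)
        p, _ = self._forward(X, self.coefs_, self.intercepts_)
        return p

    def predict_proba(self, X) -> np.ndarray:
        p = self.propensity(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return binarize(self.propensity(X), self.threshold_)

    # ---- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "kind": "dnn",
            "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.get_params().items()},
            "threshold": self.threshold_,
            "n_features_in": int(self.n_features_in_),
            "provenance_hash": getattr(self, "provenance_hash_", None),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        arrays = {}
        for i, (w, x) in enumerate(zip(self.coefs_, self.intercepts_)):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = x
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "DisorderNet":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        params = meta["params"]
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        model = cls(**params)
        data = np.load(directory / "weights.npz")
        n_layers = len([k for k in data.files if k.startswith("W")])
        model.coefs_ = [data[f"W{i}"] for i in range(n_layers)]
        model.intercepts_ = [data[f"b{i}"] for i in range(n_layers)]
        model.threshold_ = meta["threshold"]
        model.n_features_in_ = meta["n_features_in"]
        model.classes_ = np.array([0, 1])
        if meta.get("provenance_hash"):
            model.provenance_hash_ = meta["provenance_hash"]
        return model


class DisorderLogistic(BaseEstimator, ClassifierMixin):
    """Logistic-regression twin of :class:`DisorderNet` on identical features."""

    def __init__(self, C: float = 1.0, max_iter: int = 2000, seed: int = 0) -> None:
        self.C = C
        self.max_iter = max_iter
        self.seed = seed

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        _check_two_classes(y, "DisorderLogistic.fit")
        self._lr = LogisticRegression(
            C=self.C, max_iter=self.max_iter, class_weight="balanced",
            random_state=self.seed,
        )
        self._lr.fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        if X_val is not None:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val).astype(int).ravel()
            val_prop = self.propensity(X_val)
            self.validation_auc_ = float(roc_auc_score(y_val, val_prop))
            self.threshold_ = select_threshold(val_prop, y_val)
        else:
            self.threshold_ = select_threshold(self.propensity(X), y)
        return self

    def propensity(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model input {self.n_features_in_}"
            )
        return self._lr.predict_proba(X)[:, 1]

    def predict_proba(self, X) -> np.ndarray:
        p = self.propensity(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return binarize(self.propensity(X), self.threshold_)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "kind": "logistic",
            "params": self.get_params(),
            "threshold": self.threshold_,
            "n_features_in": int(self.n_features_in_),
            "provenance_hash": getattr(self, "provenance_hash_", None),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        np.savez(
            directory / "weights.npz", coef=self._lr.coef_, intercept=self._lr.intercept_
        )

    @classmethod
    def load(cls, directory: str | Path) -> "DisorderLogistic":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        model = cls(**meta["params"])
        data = np.load(directory / "weights.npz")
        lr = LogisticRegression()
        lr.coef_ = data["coef"]
        lr.intercept_ = data["intercept"]
        lr.classes_ = np.array([0, 1])
        model._lr = lr
        model.threshold_ = meta["threshold"]
        model.n_features_in_ = meta["n_features_in"]
        model.classes_ = np.array([0, 1])
        if meta.get("provenance_hash"):
            model.provenance_hash_ = meta["provenance_hash"]
        return model


def load_disorder_model(directory: str | Path):
    """Load either disorder-model kind from its model directory."""
    meta = json.loads((Path(directory) / "model.json").read_text())
    cls = {"dnn": DisorderNet, "logistic": DisorderLogistic}[meta["kind"]]
    return cls.load(directory)


def grid_search(candidates, X, y, X_val, y_val):
    """Train each candidate estimator and return the best by validation AUC.

    Ties are broken toward fewer parameters, then earlier position in the
    candidate list. Returns ``(best_fitted_estimator, results)`` where
    results is a list of ``(candidate_index, validation_auc)``.
    """
    if not candidates:
        raise ValueError("empty candidate grid")
    results = []
    fitted = []
    for est in candidates:
        est.fit(X, y, X_val, y_val)
        fitted.append(est)
        results.append(est.validation_auc_)

    def sort_key(i):
        est = fitted[i]
        n_par = est.n_parameters() if hasattr(est, "n_parameters") else est.n_features_in_ + 1
        return (-results[i], n_par, i)

    best = min(range(len(fitted)), key=sort_key)
    return fitted[best], list(enumerate(results))
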