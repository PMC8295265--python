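"""Disorder-function models: four random forests aligned with predicted IDRs.

One forest per function (protein binding, DNA binding, RNA binding, linker).
Training rows are residues the disorder model calls disordered; positives are
those inside a region annotated with the function, negatives the remaining
predicted-disordered residues. At prediction time function propensities are
reported only inside predicted IDRs (zero elsewhere), which guarantees that a
function call never contradicts the disorder call.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .disorder import binarize, select_threshold
from .encoding import FUNCTION_ENCODING, ProfileEncoder
from .types import FUNCTION_LABELS, Profile, RegionAnnotation


def annotation_track(
    regions: list[RegionAnnotation], protein_id: str, length: int, label: str
) -> np.ndarray:
    """0/1 track of a protein's regions carrying one label (overlaps unioned)."""
    track = np.zeros(length, dtype=np.int8)
    for r in regions:
        if r.protein_id != protein_id or r.label != label:
            continue
        if r.end > length:
            raise ValueError(
                f"{protein_id}: region ({r.start},{r.end}) exceeds length {length}"
            )
        track[r.start - 1 : r.end] = 1
    return track


def build_function_training_set(
    profiles: list[Profile],
    disorder_binary: dict[str, np.ndarray],
    annotations: list[RegionAnnotation],
    function: str,
    encoder: ProfileEncoder | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Features + labels for one function, restricted to putative IDR residues.

    Rows are residues with a predicted disorder binary of 1; the label is 1
    iff the residue lies inside a region annotated with the function.
    """
    if function not in FUNCTION_LABELS:
        raise ValueError(f"unknown function {function!r}")
    encoder = encoder or ProfileEncoder(
        residue_window=FUNCTION_ENCODING.residue_window,
        average_window=FUNCTION_ENCODING.average_window,
    )
    X_parts, y_parts = [], []
    for profile in profiles:
        mask = np.asarray(disorder_binary[profile.protein_id]).astype(bool)
        if len(mask) != len(profile):
            raise ValueError(f"{profile.protein_id}: disorder track length mismatch")
        if not mask.any():
            continue  # predicted fully structured: contributes no rows
        features = encoder.encode_profile(profile).values
        labels = annotation_track(annotations, profile.protein_id, len(profile), function)
        X_parts.append(features[mask])
        y_parts.append(labels[mask])
    if not X_parts:
        raise ValueError("no predicted-disordered residues in the training set")
    return np.vstack(X_parts), np.concatenate(y_parts)


class FunctionForest(BaseEstimator, ClassifierMixin):
    """Random-forest classifier for one disorder function.

    Hyper-parameters (number of trees and tree depth) are selected by grid
    search maximising mean ROC-AUC under stratified k-fold cross-validation
    (3 folds by default); the binary threshold maximises F1 on the winning
    grid point's out-of-fold predictions; the final forest is refit on all
    rows.
    """

    def __init__(
        self,
        function: str = "protein_binding",
        n_estimators_grid: tuple[int, ...] = (100, 250, 500),
        max_depth_grid: tuple[int | None, ...] = (5, 10, None),
        cv_folds: int = 3,
        seed: int = 0,
    ) -> None:
        self.function = function
        self.n_estimators_grid = n_estimators_grid
        self.max_depth_grid = max_depth_grid
        self.cv_folds = cv_folds
        self.seed = seed

    def _forest(self, n_estimators: int, max_depth: int | None) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_estimators,
            max_depth=max_depth,
            random_state=self.seed,
            n_jobs=1,
        )

    def fit(self, X, y):
        if self.function not in FUNCTION_LABELS:
            raise ValueError(f"unknown function {self.function!r}")
        if not self.n_estimators_grid or not self.max_depth_grid:
            raise ValueError("hyper-parameter grids must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        if np.unique(y).size < 2:
            raise ValueError(f"{self.function}: training labels contain a single class")

        cv = StratifiedKFold(n_splits=self.cv_folds, shuffle=True, random_state=self.seed)
        grid = [(n, d) for n in self.n_estimators_grid for d in self.max_depth_grid]
        self.cv_results_ = []
        best_score, best_point = -np.inf, grid[0]
        for n, d in grid:
            aucs = []
            for train_idx, test_idx in cv.split(X, y):
                forest = self._forest(n, d)
                forest.fit(X[train_idx], y[train_idx])
                prop = forest.predict_proba(X[test_idx])[:, 1]
                aucs.append(roc_auc_score(y[test_idx], prop))
            score = float(np.mean(aucs))
            self.cv_results_.append({"n_estimators": n, "max_depth": d, "mean_auc": score})
            if score > best_score:
                best_score, best_point = score, (n, d)

        self.best_params_ = {"n_estimators": best_point[0], "max_depth": best_point[1]}
        self.cv_auc_ = best_score
        oof = cross_val_predict(
            self._forest(*best_point), X, y, cv=cv, method="predict_proba", n_jobs=1
        )[:, 1]
        self.threshold_ = select_threshold(oof, y)
        self.forest_ = self._forest(*best_point).fit(X, y)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    @property
    def feature_importances_(self) -> np.ndarray:
        return self.forest_.feature_importances_

    def propensity(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension {X.shape[1]} != model input {self.n_features_in_}"
            )
        return self.forest_.predict_proba(X)[:, 1]

    def predict_proba(self, X) -> np.ndarray:
        p = self.propensity(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return binarize(self.propensity(X), self.threshold_)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "kind": "function_rf",
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.get_params().items()
            },
            "threshold": self.threshold_,
            "best_params": self.best_params_,
            "n_features_in": int(self.n_features_in_),
            "provenance_hash": getattr(self, "provenance_hash_", None),
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        joblib.dump(self.forest_, directory / "forest.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "FunctionForest":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        params = meta["params"]
        params["n_estimators_grid"] = tuple(params["n_estimators_grid"])
        params["max_depth_grid"] = tuple(params["max_depth_grid"])
        model = cls(**params)
        model.forest_ = joblib.load(directory / "forest.joblib")
        model.threshold_ = meta["threshold"]
        model.best_params_ = meta["best_params"]
        model.n_features_in_ = meta["n_features_in"]
        model.classes_ = np.array([0, 1])
        if meta.get("provenance_hash"):
            model.provenance_hash_ = meta["provenance_hash"]
        return model


def predict_functions(
    models: dict[str, FunctionForest],
    profile: Profile,
    disorder_binary: np.ndarray,
    encoder: ProfileEncoder | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Four aligned function tracks for one protein.

    Inside predicted IDRs the propensity is the forest output and the binary
    call uses the model threshold; outside, both are exactly zero.
    """
    missing = [f for f in FUNCTION_LABELS if f not in models]
    if missing:
        raise ValueError(f"missing function models: {missing}")
    encoder = encoder or ProfileEncoder(
        residue_window=FUNCTION_ENCODING.residue_window,
        average_window=FUNCTION_ENCODING.average_window,
    )
    mask = np.asarray(disorder_binary).astype(bool)
    if len(mask) != len(profile):
        raise ValueError(f"{profile.protein_id}: disorder track length mismatch")
    L = len(profile)
    propensities: dict[str, np.ndarray] = {}
    binaries: dict[str, np.ndarray] = {}
    features = encoder.encode_profile(profile).values[mask] if mask.any() else None
    for f in FUNCTION_LABELS:
        prop = np.zeros(L)
        binary = np.zeros(L, dtype=np.int8)
        if features is not None and len(features):
            p = models[f].propensity(features)
            prop[mask] = p
            binary[mask] = binarize(p, models[f].threshold_)
        propensities[f] = prop
        binaries[f] = binary
    return propensities, binaries
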