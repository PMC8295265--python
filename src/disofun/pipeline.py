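"""End-to-end predictor: profile -> encoded features -> disorder propensity
-> thresholded IDRs -> per-IDR function propensities.

The pipeline owns the two encoders (disorder task: residue window 5, average
window 15; function task: residue window 1, average window 11), one disorder
model and the four function forests, and persists them as one directory with
a provenance hash of the schema + encoding configuration. Prediction refuses
to run when a loaded model's provenance does not match the encoder.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .disorder import DisorderLogistic, DisorderNet, binarize, load_disorder_model
from .encoding import DISORDER_ENCODING, FUNCTION_ENCODING, EncodingConfig, ProfileEncoder
from .functions import FunctionForest, build_function_training_set, predict_functions
from .profiles import ProfileSchema, default_schema
from .types import FUNCTION_LABELS, PredictionResult, Profile


def _encoder(config: EncodingConfig, schema: ProfileSchema | None) -> ProfileEncoder:
    return ProfileEncoder(
        residue_window=config.residue_window,
        average_window=config.average_window,
        include_protein_level=config.include_protein_level,
        excluded_groups=tuple(sorted(config.excluded_groups)),
        excluded_levels=tuple(sorted(config.excluded_levels)),
        schema=schema,
    ).fit()


def stack_features(
    encoder: ProfileEncoder, profiles: list[Profile], tracks: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Encode profiles and concatenate the matching per-residue labels."""
    X, y = [], []
    for p in profiles:
        t = np.asarray(tracks[p.protein_id])
        if len(t) != len(p):
            raise ValueError(f"{p.protein_id}: label track length mismatch")
        X.append(encoder.encode_profile(p).values)
        y.append(t)
    return np.vstack(X), np.concatenate(y)


class DisorderFunctionPipeline:
    """Couples the disorder model with the four IDR-function forests."""

    def __init__(
        self,
        disorder_model=None,
        schema: ProfileSchema | None = None,
        disorder_encoding: EncodingConfig = DISORDER_ENCODING,
        function_encoding: EncodingConfig = FUNCTION_ENCODING,
        n_estimators_grid: tuple[int, ...] = (100, 250, 500),
        max_depth_grid: tuple[int | None, ...] = (5, 10, None),
        cv_folds: int = 3,
        train_functions: bool = True,
        seed: int = 0,
    ) -> None:
        self.disorder_model = disorder_model
        self.schema = schema
        self.disorder_encoding = disorder_encoding
        self.function_encoding = function_encoding
        self.n_estimators_grid = n_estimators_grid
        self.max_depth_grid = max_depth_grid
        self.cv_folds = cv_folds
        self.train_functions = train_functions
        self.seed = seed

    # ------------------------------------------------------------------

    def fit(
        self,
        profiles: list[Profile],
        disorder_tracks: dict[str, np.ndarray],
        annotations=None,
        val_profiles: list[Profile] | None = None,
        val_tracks: dict[str, np.ndarray] | None = None,
    ) -> "DisorderFunctionPipeline":
        schema = self.schema or default_schema()
        self.disorder_encoder_ = _encoder(self.disorder_encoding, self.schema)
        self.function_encoder_ = _encoder(self.function_encoding, self.schema)

        X, y = stack_features(self.disorder_encoder_, profiles, disorder_tracks)
        if val_profiles is not None:
            X_val, y_val = stack_features(self.disorder_encoder_, val_profiles, val_tracks)
        else:
            X_val = y_val = None
        self.disorder_model_ = self.disorder_model or DisorderNet(seed=self.seed)
        self.disorder_model_.fit(X, y, X_val, y_val)
        self.disorder_model_.provenance_hash_ = self.disorder_encoder_.provenance_hash_

        self.function_models_: dict[str, FunctionForest] = {}
        if self.train_functions:
            if annotations is None:
                raise ValueError("function training requires region annotations")
            predicted = {
                p.protein_id: self.disorder_model_.predict(
                    self.disorder_encoder_.encode_profile(p).values
                )
                for p in profiles
            }
            for f in FUNCTION_LABELS:
                Xf, yf = build_function_training_set(
                    profiles, predicted, annotations, f, self.function_encoder_
                )
                forest = FunctionForest(
                    function=f,
                    n_estimators_grid=self.n_estimators_grid,
                    max_depth_grid=self.max_depth_grid,
                    cv_folds=self.cv_folds,
                    seed=self.seed,
                )
                forest.fit(Xf, yf)
                forest.provenance_hash_ = self.function_encoder_.provenance_hash_
                self.function_models_[f] = forest
        return self

    # ------------------------------------------------------------------

    def _check_provenance(self) -> None:
        expect = self.disorder_encoder_.provenance_hash_
        got = getattr(self.disorder_model_, "provenance_hash_", expect)
        if got != expect:
            raise ValueError(
                "disorder model was trained under a different schema/encoding "
                f"(model {got}, encoder {expect})"
            )
        if self.function_models_:
            expect_f = self.function_encoder_.provenance_hash_
            for f, m in self.function_models_.items():
                got_f = getattr(m, "provenance_hash_", expect_f)
                if got_f != expect_f:
                    raise ValueError(
                        f"function model {f!r} trained under a different "
                        f"schema/encoding (model {got_f}, encoder {expect_f})"
                    )

    def predict(self, profile: Profile, sequence: str) -> PredictionResult:
        self._check_provenance()
        if len(sequence) != len(profile):
            raise ValueError(
                f"{profile.protein_id}: sequence length {len(sequence)} vs "
                f"profile rows {len(profile)}"
            )
        X = self.disorder_encoder_.encode_profile(profile).values
        propensity = self.disorder_model_.propensity(X)
        binary = binarize(propensity, self.disorder_model_.threshold_)
        if self.function_models_:
            f_prop, f_bin = predict_functions(
                self.function_models_, profile, binary, self.function_encoder_
            )
        else:
            L = len(profile)
            f_prop = {f: np.zeros(L) for f in FUNCTION_LABELS}
            f_bin = {f: np.zeros(L, dtype=np.int8) for f in FUNCTION_LABELS}
        return PredictionResult(
            protein_id=profile.protein_id,
            sequence=sequence,
            disorder_propensity=propensity,
            disorder_binary=binary,
            function_propensity=f_prop,
            function_binary=f_bin,
        )

    # ------------------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        schema = self.schema or default_schema()
        (directory / "schema.txt").write_text(schema.to_text())
        meta = {
            "seed": self.seed,
            "disorder_encoding": json.loads(self.disorder_encoding.to_json()),
            "function_encoding": json.loads(self.function_encoding.to_json()),
            "disorder_provenance": self.disorder_encoder_.provenance_hash_,
            "function_provenance": self.function_encoder_.provenance_hash_,
            "functions": sorted(self.function_models_),
        }
        (directory / "pipeline.json").write_text(json.dumps(meta, indent=1))
        self.disorder_model_.save(directory / "disorder")
        for f, m in self.function_models_.items():
            m.save(directory / "functions" / f)

    @classmethod
    def load(cls, directory: str | Path) -> "DisorderFunctionPipeline":
        directory = Path(directory)
        meta = json.loads((directory / "pipeline.json").read_text())
        schema = ProfileSchema.from_text((directory / "schema.txt").read_text())
        pipe = cls(
            schema=schema,
            disorder_encoding=EncodingConfig.from_json(
                json.dumps(meta["disorder_encoding"])
            ),
            function_encoding=EncodingConfig.from_json(
                json.dumps(meta["function_encoding"])
            ),
            seed=meta["seed"],
        )
        pipe.disorder_encoder_ = _encoder(pipe.disorder_encoding, schema)
        pipe.function_encoder_ = _encoder(pipe.function_encoding, schema)
        pipe.disorder_model_ = load_disorder_model(directory / "disorder")
        pipe.function_models_ = {
            f: FunctionForest.load(directory / "functions" / f)
            for f in meta["functions"]
        }
        return pipe
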