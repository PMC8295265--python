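"""Shared fixtures: simulated corpora and models trained once per session."""

from __future__ import annotations

import numpy as np
import pytest

import disofun as d
from disofun.pipeline import _encoder, stack_features

SEED = 1


@pytest.fixture(scope="session")
def suite():
    """The named synthetic fixture datasets, generated once."""
    return d.fixture_suite(SEED)


@pytest.fixture(scope="session")
def separable_split(suite):
    return suite["separable"].split((0.6, 0.2, 0.2))


@pytest.fixture(scope="session")
def disorder_encoder():
    return _encoder(d.DISORDER_ENCODING, None)


@pytest.fixture(scope="session")
def separable_features(separable_split, disorder_encoder):
    return [
        stack_features(disorder_encoder, s.profiles, s.tracks("disorder"))
        for s in separable_split
    ]


@pytest.fixture(scope="session")
def separable_net(separable_features):
    (X, y), (Xv, yv), _ = separable_features
    return d.DisorderNet(max_epochs=60, seed=SEED).fit(X, y, Xv, yv)


@pytest.fixture(scope="session")
def separable_logistic(separable_features):
    (X, y), (Xv, yv), _ = separable_features
    return d.DisorderLogistic(seed=SEED).fit(X, y, Xv, yv)


@pytest.fixture(scope="session")
def null_split(suite):
    return suite["null"].split((0.6, 0.2, 0.2))


@pytest.fixture(scope="session")
def null_net(null_split, disorder_encoder):
    tr, va, _ = null_split
    X, y = stack_features(disorder_encoder, tr.profiles, tr.tracks("disorder"))
    Xv, yv = stack_features(disorder_encoder, va.profiles, va.tracks("disorder"))
    return d.DisorderNet(max_epochs=30, seed=SEED).fit(X, y, Xv, yv)


@pytest.fixture(scope="session")
def function_toy_split(suite):
    return suite["function_toy"].split((0.6, 0.2, 0.2))


@pytest.fixture(scope="session")
def function_pipeline(function_toy_split):
    tr, va, _ = function_toy_split
    pipe = d.DisorderFunctionPipeline(
        disorder_model=d.DisorderNet(max_epochs=40, seed=SEED),
        n_estimators_grid=(100,),
        max_depth_grid=(10,),
        seed=SEED,
    )
    pipe.fit(
        tr.profiles, tr.tracks("disorder"), tr.annotations,
        va.profiles, va.tracks("disorder"),
    )
    return pipe


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
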