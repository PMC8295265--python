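"""Three-level feature encoding of a sequence profile.

Each residue is described at three aggregation levels:

* residue level — the raw profile rows in a small window centred on the
  residue (5 residues for the disorder task, 1 for the function task);
* window level — the per-channel mean over a larger window (15 residues for
  disorder, 11 for functions);
* protein level — the per-channel sequence averages plus normalised sequence
  length and the residue's distances to the two termini, expressing a chain's
  overall bias toward disorder.

With the default 45-channel schema and the disorder-task windows this yields
5*45 + 45 + (45+3) = 318 features per residue.

Out-of-range window slots are filled with the protein-level channel mean
rather than zero, so a constant profile encodes to constant features and no
artificial "low signal" appears at the termini.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .profiles import ProfileSchema, default_schema
from .types import Profile

LEVELS = ("residue", "window", "protein")

#: Sequence lengths are normalised by this cap.
LENGTH_CAP = 10_000


@dataclass(frozen=True)
class EncodingConfig:
    """Window sizes and exclusions controlling the three-level encoding."""

    residue_window: int = 5
    average_window: int = 15
    include_protein_level: bool = True
    excluded_groups: frozenset[str] = field(default_factory=frozenset)
    excluded_levels: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "excluded_groups", frozenset(self.excluded_groups))
        object.__setattr__(self, "excluded_levels", frozenset(self.excluded_levels))
        for w, name in ((self.residue_window, "residue_window"), (self.average_window, "average_window")):
            if w < 1 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and positive, got {w}")
        if self.residue_window > self.average_window:
            raise ValueError("residue_window must not exceed average_window")
        bad = self.excluded_levels - set(LEVELS)
        if bad:
            raise ValueError(f"unknown levels {sorted(bad)}")
        if not self.levels:
            raise ValueError("cannot exclude all three encoding levels")

    @property
    def levels(self) -> tuple[str, ...]:
        """Active levels after exclusions, in canonical order."""
        active = [lv for lv in LEVELS if lv not in self.excluded_levels]
        if not self.include_protein_level and "protein" in active:
            active.remove("protein")
        return tuple(active)

    def to_json(self) -> str:
        return json.dumps(
            {
                "residue_window": self.residue_window,
                "average_window": self.average_window,
                "include_protein_level": self.include_protein_level,
                "excluded_groups": sorted(self.excluded_groups),
                "excluded_levels": sorted(self.excluded_levels),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "EncodingConfig":
        d = json.loads(text)
        return cls(
            residue_window=d["residue_window"],
            average_window=d["average_window"],
            include_protein_level=d["include_protein_level"],
            excluded_groups=frozenset(d["excluded_groups"]),
            excluded_levels=frozenset(d["excluded_levels"]),
        )


#: Window sizes used for the two prediction tasks.
DISORDER_ENCODING = EncodingConfig(residue_window=5, average_window=15)
FUNCTION_ENCODING = EncodingConfig(residue_window=1, average_window=11)


@dataclass
class FeatureMatrix:
    """Per-residue feature rows for one protein, with provenance-bearing names."""

    protein_id: str
    values: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.columns):
            raise ValueError("feature matrix width does not match column names")

    def __len__(self) -> int:
        return self.values.shape[0]


def window_slice(track: np.ndarray, center: int, width: int, fill: float) -> np.ndarray:
    """Values of a per-residue track at the ``width`` positions centred on
    ``center`` (1-based); positions outside the chain yield ``fill``."""
    if width < 1 or width % 2 == 0:
        raise ValueError(f"window width must be odd and positive, got {width}")
    track = np.asarray(track, dtype=float)
    L = len(track)
    if not (1 <= center <= L):
        raise ValueError(f"center {center} outside chain of length {L}")
    w = (width - 1) // 2
    out = np.full(width, float(fill))
    lo = max(center - 1 - w, 0)
    hi = min(center + w, L)
    out[lo - (center - 1 - w) : hi - (center - 1 - w)] = track[lo:hi]
    return out


def protein_level_features(profile: Profile) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Protein-level feature components.

    Returns the per-channel means (broadcast to every residue), the
    length feature min(L, cap)/cap, and the per-residue normalised distances
    to the N- and C-terminus, (i-1)/L and (L-i)/L.
    """
    L = len(profile)
    means = profile.values.mean(axis=0)
    length_feature = min(L, LENGTH_CAP) / LENGTH_CAP
    positions = np.arange(1, L + 1)
    n_dist = (positions - 1) / L
    c_dist = (L - positions) / L
    return means, length_feature, n_dist, c_dist


def _mean_padded(values: np.ndarray, half: int, means: np.ndarray) -> np.ndarray:
    """Stack ``half`` rows of channel means above and below the profile."""
    if half == 0:
        return values
    pad = np.tile(means, (half, 1))
    return np.vstack([pad, values, pad])


def encode(
    profile: Profile,
    config: EncodingConfig = DISORDER_ENCODING,
    schema: ProfileSchema | None = None,
) -> FeatureMatrix:
    """Encode a profile into the per-residue feature matrix.

    Feature order: residue-level block (window position-major, channel-minor),
    window-level block, protein-level block (channel means, length, terminus
    distances). Excluded groups drop their channels at every level; excluded
    levels drop whole blocks.
    """
    schema = schema or default_schema()
    schema.validate(profile)
    kept = schema.without_groups(set(config.excluded_groups))
    idx = [schema.index(c) for c in kept]
    V = profile.values[:, idx]
    L, P = V.shape
    means = V.mean(axis=0)

    blocks: list[np.ndarray] = []
    names: list[str] = []
    levels = config.levels

    if "residue" in levels:
        w = (config.residue_window - 1) // 2
        padded = _mean_padded(V, w, means)
        for offset in range(-w, w + 1):
            blocks.append(padded[w + offset : w + offset + L])
            names += [f"res[{offset:+d}]:{c}" for c in kept]

    if "window" in levels:
        a = (config.average_window - 1) // 2
        padded = _mean_padded(V, a, means)
        csum = np.vstack([np.zeros(P), np.cumsum(padded, axis=0)])
        win = (csum[config.average_window :] - csum[: -config.average_window or None])
        blocks.append(win / config.average_window)
        names += [f"win{config.average_window}:{c}" for c in kept]

    if "protein" in levels:
        ch_means, length_feature, n_dist, c_dist = protein_level_features(
            Profile(profile.protein_id, V, kept)
        )
        blocks.append(np.tile(ch_means, (L, 1)))
        names += [f"prot:mean:{c}" for c in kept]
        blocks.append(
            np.column_stack([np.full(L, length_feature), n_dist, c_dist])
        )
        names += ["prot:length", "prot:n_dist", "prot:c_dist"]

    return FeatureMatrix(profile.protein_id, np.hstack(blocks), tuple(names))


def n_features(config: EncodingConfig, schema: ProfileSchema | None = None) -> int:
    """Closed-form feature count: r*P + P + (P+3) over surviving channels."""
    schema = schema or default_schema()
    P = len(schema.without_groups(set(config.excluded_groups)))
    total = 0
    if "residue" in config.levels:
        total += config.residue_window * P
    if "window" in config.levels:
        total += P
    if "protein" in config.levels:
        total += P + 3
    return total


def provenance_hash(schema: ProfileSchema, config: EncodingConfig) -> str:
    """Stable digest of schema + encoding config, stored with trained models."""
    payload = schema.to_text() + "\n" + config.to_json()
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class ProfileEncoder(BaseEstimator, TransformerMixin):
    """Transformer wrapping :func:`encode` for scikit-learn composition.

    ``transform`` accepts a single :class:`Profile` or a list of them and
    returns the vertically stacked feature array; :meth:`encode_profile`
    returns the named per-protein :class:`FeatureMatrix`.
    """

    def __init__(
        self,
        residue_window: int = 5,
        average_window: int = 15,
        include_protein_level: bool = True,
        excluded_groups: tuple[str, ...] = (),
        excluded_levels: tuple[str, ...] = (),
        schema: ProfileSchema | None = None,
    ) -> None:
        self.residue_window = residue_window
        self.average_window = average_window
        self.include_protein_level = include_protein_level
        self.excluded_groups = excluded_groups
        self.excluded_levels = excluded_levels
        self.schema = schema

    @property
    def config(self) -> EncodingConfig:
        return EncodingConfig(
            residue_window=self.residue_window,
            average_window=self.average_window,
            include_protein_level=self.include_protein_level,
            excluded_groups=frozenset(self.excluded_groups),
            excluded_levels=frozenset(self.excluded_levels),
        )

    def _schema(self) -> ProfileSchema:
        return self.schema or default_schema()

    def fit(self, X=None, y=None) -> "ProfileEncoder":
        self.n_features_ = n_features(self.config, self._schema())
        self.provenance_hash_ = provenance_hash(self._schema(), self.config)
        return self

    def encode_profile(self, profile: Profile) -> FeatureMatrix:
        return encode(profile, self.config, self._schema())

    def transform(self, X) -> np.ndarray:
        profiles = [X] if isinstance(X, Profile) else list(X)
        return np.vstack([self.encode_profile(p).values for p in profiles])

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        schema = self._schema()
        dummy = Profile(
            "dummy", np.zeros((1, schema.n_channels)), schema.channels
        )
        return np.asarray(encode(dummy, self.config, schema).columns, dtype=object)
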