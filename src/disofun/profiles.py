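"""Sequence-profile schema and the profile-derived quantities computed in-house.

A profile row holds, per residue, the outputs of upstream sequence-analysis
tools (PSSM from an iterative database search, three-state secondary-structure
probabilities, baseline disorder propensities, disorder-function propensities)
plus four sequence-derived physicochemical scalars. This package consumes such
rows from tab-separated tables; the only channels it computes itself are the
entropy-based conservation score, the logistic squashing of raw PSSM scores,
and the physicochemical scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AMINO_ACIDS, Profile

GROUP_NAMES = (
    "pssm",
    "conservation",
    "secondary_structure",
    "iupred",
    "function_predictors",
    "physchem",
)

# Per-residue physicochemical indices over the 20 standard amino acids:
# Kyte-Doolittle hydropathy, net formal charge at neutral pH, Grantham
# polarity, and residue volume (A^3). Each is min-max scaled to [0,1] over
# the 20 letters before use; X gets the scaled mean.
_HYDROPATHY = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}
_CHARGE = {aa: 0.0 for aa in AMINO_ACIDS} | {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1}
_POLARITY = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0, "H": 10.4,
    "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5,
    "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}
_VOLUME = {
    "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9, "G": 60.1,
    "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7, "M": 162.9, "N": 114.1,
    "P": 112.7, "Q": 143.8, "R": 173.4, "S": 89.0, "T": 116.1, "V": 140.0,
    "W": 227.8, "Y": 193.6,
}


def _scaled_index(raw: dict[str, float]) -> dict[str, float]:
    vals = np.array([raw[aa] for aa in AMINO_ACIDS])
    lo, hi = vals.min(), vals.max()
    scaled = {aa: float((raw[aa] - lo) / (hi - lo)) for aa in AMINO_ACIDS}
    scaled["X"] = float(np.mean(list(scaled.values())))
    return scaled


PHYSCHEM_INDICES: dict[str, dict[str, float]] = {
    "hydrophobicity": _scaled_index(_HYDROPATHY),
    "charge": _scaled_index(_CHARGE),
    "polarity": _scaled_index(_POLARITY),
    "volume": _scaled_index(_VOLUME),
}


@dataclass(frozen=True)
class ProfileSchema:
    """Named, grouped, range-annotated channel layout of a profile.

    Every channel belongs to exactly one group; groups are the unit of
    ablation (a whole group of channels is dropped at every encoding level).
    """

    channels: tuple[str, ...]
    groups: dict[str, tuple[str, ...]]
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel names in schema")
        seen: dict[str, str] = {}
        for g, members in self.groups.items():
            for c in members:
                if c not in self.channels:
                    raise ValueError(f"group {g!r} names unknown channel {c!r}")
                if c in seen:
                    raise ValueError(f"channel {c!r} in both {seen[c]!r} and {g!r}")
                seen[c] = g
        missing = set(self.channels) - set(seen)
        if missing:
            raise ValueError(f"channels without a group: {sorted(missing)}")
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(
            self, "groups", {g: tuple(m) for g, m in self.groups.items()}
        )
        ranges = dict(self.ranges)
        for c in self.channels:
            ranges.setdefault(c, (0.0, 1.0))
        object.__setattr__(self, "ranges", ranges)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, channel: str) -> int:
        return self.channels.index(channel)

    def group_of(self, channel: str) -> str:
        for g, members in self.groups.items():
            if channel in members:
                return g
        raise KeyError(channel)

    def without_groups(self, excluded: set[str]) -> tuple[str, ...]:
        """Channel names that survive removal of the given groups, in order."""
        unknown = set(excluded) - set(self.groups)
        if unknown:
            raise KeyError(f"schema has no groups {sorted(unknown)}")
        dropped = {c for g in excluded for c in self.groups[g]}
        return tuple(c for c in self.channels if c not in dropped)

    def validate(self, profile: Profile) -> None:
        """Check channel names, order and per-channel value ranges."""
        if profile.channels != self.channels:
            raise ValueError(
                f"{profile.protein_id}: profile channels do not match schema"
            )
        for j, c in enumerate(self.channels):
            lo, hi = self.ranges[c]
            col = profile.values[:, j]
            if col.min() < lo - 1e-9 or col.max() > hi + 1e-9:
                raise ValueError(
                    f"{profile.protein_id}: channel {c!r} outside declared range [{lo},{hi}]"
                )

    def to_text(self) -> str:
        lines = ["# channel\tgroup\tlow\thigh"]
        for c in self.channels:
            lo, hi = self.ranges[c]
            lines.append(f"{c}\t{self.group_of(c)}\t{lo:g}\t{hi:g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ProfileSchema":
        channels: list[str] = []
        groups: dict[str, list[str]] = {}
        ranges: dict[str, tuple[float, float]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, group, lo, hi = line.split("\t")
            channels.append(name)
            groups.setdefault(group, []).append(name)
            ranges[name] = (float(lo), float(hi))
        return cls(tuple(channels), {g: tuple(m) for g, m in groups.items()}, ranges)


def default_schema() -> ProfileSchema:
    """The default 45-channel profile schema.

    20 logistic-scaled PSSM columns, 1 conservation score, 6 secondary-
    structure channels (3 probabilities + 3 binary calls), 4 baseline-disorder
    channels (long/short propensity + binary), 10 disorder-function channels
    (protein/DNA/RNA-binding and MoRF and linker propensities with binary
    calls), and 4 physicochemical scalars. All channels live in [0,1].
    """
    pssm = tuple(f"pssm_{aa}" for aa in AMINO_ACIDS)
    ss = ("ss_prob_H", "ss_prob_E", "ss_prob_C", "ss_bin_H", "ss_bin_E", "ss_bin_C")
    iupred = ("iupred_long", "iupred_short", "iupred_long_bin", "iupred_short_bin")
    funcs = (
        "disordpbind_protein", "disordpbind_dna", "disordpbind_rna",
        "disordpbind_protein_bin", "disordpbind_dna_bin", "disordpbind_rna_bin",
        "fmorfpred", "fmorfpred_bin", "dflpred", "dflpred_bin",
    )
    phys = tuple(PHYSCHEM_INDICES)
    groups = {
        "pssm": pssm,
        "conservation": ("conservation",),
        "secondary_structure": ss,
        "iupred": iupred,
        "function_predictors": funcs,
        "physchem": phys,
    }
    channels = pssm + ("conservation",) + ss + iupred + funcs + phys
    return ProfileSchema(channels, groups)


def scale_pssm(pssm_row: np.ndarray) -> np.ndarray:
    """Squash raw PSSM substitution scores elementwise to [0,1] via the logistic."""
    row = np.asarray(pssm_row, dtype=float)
    if not np.isfinite(row).all():
        raise ValueError("PSSM scores must be finite")
    return 1.0 / (1.0 + np.exp(-row))


def pssm_conservation(pssm_row: np.ndarray) -> float:
    """Entropy-based conservation of one PSSM row, in [0,1].

    The 20 substitution scores are softmax-normalised to a probability vector
    p; the score is 1 - H(p)/ln(20), i.e. 0 for a flat row (no conservation)
    and approaching 1 as the distribution concentrates on a single letter.
    Invariant to adding a constant to all 20 scores.
    """
    row = np.asarray(pssm_row, dtype=float)
    if row.shape != (20,):
        raise ValueError(f"expected 20 PSSM scores, got shape {row.shape}")
    if not np.isfinite(row).all():
        raise ValueError("PSSM scores must be finite")
    z = row - row.max()
    p = np.exp(z)
    p /= p.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return 1.0 - entropy / np.log(20.0)


def physchem_values(sequence: str) -> np.ndarray:
    """L x 4 matrix of the scaled physicochemical indices for a sequence."""
    cols = [
        [PHYSCHEM_INDICES[name][aa] for aa in sequence] for name in PHYSCHEM_INDICES
    ]
    return np.array(cols, dtype=float).T
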