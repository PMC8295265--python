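"""Core domain objects shared across the package.

The unit of prediction is a protein chain; annotations are 1-based inclusive
intervals in the DisProt style; profiles are per-residue matrices of upstream
predictor outputs and sequence-derived scalars.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DISORDER_LABEL = "disorder"
FUNCTION_LABELS = ("protein_binding", "dna_binding", "rna_binding", "linker")
ALL_LABELS = (DISORDER_LABEL,) + FUNCTION_LABELS


@dataclass(frozen=True)
class ProteinRecord:
    """A protein chain: identifier plus sequence over the 20 letters + X."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"protein id must be non-empty without whitespace: {self.id!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"protein {self.id}: invalid letters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RegionAnnotation:
    """A labelled interval on a protein, 1-based inclusive at both ends."""

    protein_id: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in ALL_LABELS:
            raise ValueError(f"unknown region label {self.label!r}; expected one of {ALL_LABELS}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.protein_id}: invalid interval ({self.start},{self.end}); "
                "need 1 <= start <= end"
            )


@dataclass(frozen=True)
class LabelTrack:
    """Per-residue 0/1 track for one annotation label on one protein."""

    protein_id: str
    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int8)
        if v.ndim != 1 or not np.isin(v, (0, 1)).all():
            raise ValueError(f"{self.protein_id}: label track must be a 1-D 0/1 array")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Profile:
    """L x P matrix of per-residue channel values for one protein.

    Rows follow sequence order; columns follow the schema's channel order.
    """

    protein_id: str
    values: np.ndarray
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"{self.protein_id}: profile must be 2-D, got shape {v.shape}")
        if v.shape[1] != len(self.channels):
            raise ValueError(
                f"{self.protein_id}: {v.shape[1]} columns vs {len(self.channels)} channel names"
            )
        if v.shape[0] < 1:
            raise ValueError(f"{self.protein_id}: empty profile")
        if not np.isfinite(v).all():
            raise ValueError(f"{self.protein_id}: profile contains non-finite values")
        self.values = v
        self.channels = tuple(self.channels)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class PredictionResult:
    """Aligned per-residue outputs: disorder plus the four function tracks.

    Function calls are constrained to predicted disordered residues: a residue
    with ``disorder_binary == 0`` always has zero propensity and binary for
    every function (the alignment guarantee of the coupled architecture).
    """

    protein_id: str
    sequence: str
    disorder_propensity: np.ndarray
    disorder_binary: np.ndarray
    function_propensity: dict[str, np.ndarray] = field(default_factory=dict)
    function_binary: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = len(self.sequence)
        self.disorder_propensity = np.asarray(self.disorder_propensity, dtype=float)
        self.disorder_binary = np.asarray(self.disorder_binary, dtype=np.int8)
        tracks = [self.disorder_propensity, self.disorder_binary]
        if set(self.function_propensity) != set(self.function_binary):
            raise ValueError(f"{self.protein_id}: mismatched function track sets")
        for f in self.function_propensity:
            if f not in FUNCTION_LABELS:
                raise ValueError(f"{self.protein_id}: unknown function {f!r}")
            self.function_propensity[f] = np.asarray(self.function_propensity[f], dtype=float)
            self.function_binary[f] = np.asarray(self.function_binary[f], dtype=np.int8)
            tracks += [self.function_propensity[f], self.function_binary[f]]
        for t in tracks:
            if len(t) != L:
                raise ValueError(
                    f"{self.protein_id}: track length {len(t)} != sequence length {L}"
                )
        structured = self.disorder_binary == 0
        for f, b in self.function_binary.items():
            if (b[structured] != 0).any() or (self.function_propensity[f][structured] != 0).any():
                raise ValueError(
                    f"{self.protein_id}: function {f!r} called outside predicted disorder"
                )

    def __len__(self) -> int:
        return len(self.sequence)
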