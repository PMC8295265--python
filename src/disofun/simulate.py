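"""Synthetic proteins, profiles and annotations for training and testing.

The generator emulates the statistical structure the pipeline assumes about
curated disorder data: segmental disorder from a two-state Markov chain, a
controllable fraction of fully disordered chains, profile channels linked to
the disorder or function labels with a chosen effect size, a per-protein
disorder-bias offset shared by the informative channels (the feature that
makes protein-level encodings genuinely useful), and function regions carved
strictly inside disordered segments. It makes no attempt to mimic the amino-
acid composition of real IDRs or the score distributions of real upstream
tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import write_annotations, write_fasta, write_profile_table
from .profiles import ProfileSchema, default_schema, physchem_values, PHYSCHEM_INDICES
from .types import (
    AMINO_ACIDS,
    DISORDER_LABEL,
    FUNCTION_LABELS,
    Profile,
    ProteinRecord,
    RegionAnnotation,
)


@dataclass(frozen=True)
class SimParams:
    """Knobs of the generator; defaults model a DisProt-like training corpus."""

    n_proteins: int = 200
    length_range: tuple[int, int] = (60, 200)
    p_stay_disorder: float = 0.95
    p_stay_order: float = 0.95
    protein_bias_sd: float = 0.05
    fully_disordered_fraction: float = 0.05
    #: channel name -> (target label, effect size); target is "disorder" or a function
    channel_effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    noise_sd: float = 0.1
    #: per-function probability that a disordered segment carries a sub-region
    function_coverage: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self, schema: ProfileSchema) -> None:
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")
        for p_name in ("p_stay_disorder", "p_stay_order", "fully_disordered_fraction"):
            v = getattr(self, p_name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{p_name} must be in [0,1], got {v}")
        for ch, (target, _) in self.channel_effects.items():
            if ch not in schema.channels:
                raise ValueError(f"effect on unknown channel {ch!r}")
            if target != DISORDER_LABEL and target not in FUNCTION_LABELS:
                raise ValueError(f"effect targets unknown label {target!r}")
        for f, c in self.function_coverage.items():
            if f not in FUNCTION_LABELS:
                raise ValueError(f"coverage for unknown function {f!r}")
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"coverage for {f!r} must be in [0,1], got {c}")

    def stationary_disorder_fraction(self) -> float:
        """Stationary disorder probability of the two-state chain."""
        a = 1.0 - self.p_stay_order   # order -> disorder
        b = 1.0 - self.p_stay_disorder  # disorder -> order
        if a + b == 0:
            return 0.5
        return a / (a + b)

    def to_json(self) -> str:
        d = asdict(self)
        d["length_range"] = list(d["length_range"])
        d["channel_effects"] = {k: list(v) for k, v in d["channel_effects"].items()}
        return json.dumps(d, indent=1, sort_keys=True)


@dataclass
class SimDataset:
    """One simulated corpus in the package's on-disk dialects."""

    proteins: list[ProteinRecord]
    profiles: list[Profile]
    annotations: list[RegionAnnotation]
    params: SimParams
    schema: ProfileSchema

    def tracks(self, label: str) -> dict[str, np.ndarray]:
        """Per-protein 0/1 truth track for one label, derived from annotations."""
        lengths = {p.id: len(p) for p in self.proteins}
        out = {pid: np.zeros(L, dtype=np.int8) for pid, L in lengths.items()}
        for r in self.annotations:
            if r.label == label:
                out[r.protein_id][r.start - 1 : r.end] = 1
        return out

    def split(self, fractions: tuple[float, ...]) -> list["SimDataset"]:
        """Split by protein, in order, into consecutive blocks."""
        n = len(self.proteins)
        bounds = np.cumsum([int(round(f * n)) for f in fractions[:-1]])
        chunks = np.split(np.arange(n), bounds)
        out = []
        for idx in chunks:
            ids = {self.proteins[i].id for i in idx}
            out.append(
                SimDataset(
                    proteins=[self.proteins[i] for i in idx],
                    profiles=[self.profiles[i] for i in idx],
                    annotations=[r for r in self.annotations if r.protein_id in ids],
                    params=self.params,
                    schema=self.schema,
                )
            )
        return out

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        (directory / "profiles").mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, directory / "proteins.fasta")
        write_annotations(self.annotations, directory / "annotations.tsv")
        for profile in self.profiles:
            write_profile_table(profile, directory / "profiles" / f"{profile.protein_id}.tsv")
        (directory / "params.json").write_text(self.params.to_json())
        (directory / "schema.txt").write_text(self.schema.to_text())


def _segments(track: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s as 1-based inclusive (start, end) intervals."""
    padded = np.concatenate([[0], track, [0]])
    starts = np.flatnonzero(np.diff(padded) == 1) + 1
    ends = np.flatnonzero(np.diff(padded) == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _markov_track(L: int, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    pi = params.stationary_disorder_fraction()
    track = np.empty(L, dtype=np.int8)
    u = rng.random(L)
    track[0] = u[0] < pi
    for i in range(1, L):
        stay = params.p_stay_disorder if track[i - 1] else params.p_stay_order
        track[i] = track[i - 1] if u[i] < stay else 1 - track[i - 1]
    return track


def simulate(params: SimParams, schema: ProfileSchema | None = None) -> SimDataset:
    """Generate a corpus of proteins, profiles and annotations.

    Per protein: length uniform in range; a disorder track from the two-state
    chain (or all-disordered with the configured probability); a per-protein
    bias b ~ N(0, protein_bias_sd) shared by all informative channels;
    informative channel values clip01(effect * target_label + b + noise);
    physicochemical channels computed from the sequence unless they carry a
    planted effect; remaining channels Uniform(0,1); function regions as
    contiguous sub-intervals of disordered segments. Fully reproducible from
    the seed.
    """
    schema = schema or default_schema()
    params.validate(schema)
    rng = np.random.default_rng(params.seed)
    lo, hi = params.length_range
    letters = np.array(list(AMINO_ACIDS))
    physchem_set = set(PHYSCHEM_INDICES)

    proteins: list[ProteinRecord] = []
    profiles: list[Profile] = []
    annotations: list[RegionAnnotation] = []

    width = len(str(params.n_proteins))
    for k in range(params.n_proteins):
        pid = f"sim{k:0{width}d}"
        L = int(rng.integers(lo, hi + 1))
        sequence = "".join(rng.choice(letters, size=L))
        if rng.random() < params.fully_disordered_fraction:
            disorder = np.ones(L, dtype=np.int8)
        else:
            disorder = _markov_track(L, params, rng)
        bias = rng.normal(0.0, params.protein_bias_sd)

        segments = _segments(disorder)
        for start, end in segments:
            annotations.append(RegionAnnotation(pid, start, end, DISORDER_LABEL))

        func_tracks: dict[str, np.ndarray] = {
            f: np.zeros(L, dtype=np.int8) for f in FUNCTION_LABELS
        }
        for f, coverage in params.function_coverage.items():
            for start, end in segments:
                if rng.random() >= coverage:
                    continue
                seg_len = end - start + 1
                sub_len = int(rng.integers(1, seg_len + 1))
                offset = int(rng.integers(0, seg_len - sub_len + 1))
                s, e = start + offset, start + offset + sub_len - 1
                annotations.append(RegionAnnotation(pid, s, e, f))
                func_tracks[f][s - 1 : e] = 1

        values = rng.random((L, schema.n_channels))
        phys = physchem_values(sequence)
        for j, ch in enumerate(schema.channels):
            if ch in params.channel_effects:
                target, effect = params.channel_effects[ch]
                y = disorder if target == DISORDER_LABEL else func_tracks[target]
                raw = effect * y + bias + rng.normal(0.0, params.noise_sd, L)
                values[:, j] = np.clip(raw, 0.0, 1.0)
            elif ch in physchem_set:
                values[:, j] = phys[:, list(PHYSCHEM_INDICES).index(ch)]

        proteins.append(ProteinRecord(id=pid, sequence=sequence))
        profiles.append(Profile(protein_id=pid, values=values, channels=schema.channels))

    return SimDataset(proteins, profiles, annotations, params, schema)


def fixture_params(seed: int = 0) -> dict[str, SimParams]:
    """Parameter sets for the named fixtures used across the test surface."""
    base_seed = int(seed) % (2**31 - 5)
    return {
        # strong single-channel disorder signal, low noise
        "separable": SimParams(
            n_proteins=200,
            length_range=(60, 200),
            channel_effects={"iupred_long": (DISORDER_LABEL, 0.8)},
            noise_sd=0.1,
            protein_bias_sd=0.05,
            fully_disordered_fraction=0.05,
            seed=base_seed,
        ),
        # labels carry no signal at all
        "null": SimParams(
            n_proteins=120,
            length_range=(60, 160),
            channel_effects={},
            noise_sd=0.1,
            protein_bias_sd=0.05,
            fully_disordered_fraction=0.05,
            seed=base_seed + 1,
        ),
        # weak residue signal confounded by a large per-protein bias: the
        # protein-level encoding is needed to subtract the offset
        "protein_level_signal": SimParams(
            n_proteins=200,
            length_range=(60, 160),
            p_stay_disorder=0.95,
            p_stay_order=0.97,
            channel_effects={
                "hydrophobicity": (DISORDER_LABEL, 0.4),
                "charge": (DISORDER_LABEL, 0.4),
            },
            noise_sd=0.2,
            protein_bias_sd=0.4,
            fully_disordered_fraction=0.05,
            seed=base_seed + 2,
        ),
        # one informative channel per function on top of a separable
        # disorder signal
        "function_toy": SimParams(
            n_proteins=160,
            length_range=(80, 200),
            channel_effects={
                "iupred_long": (DISORDER_LABEL, 0.8),
                "disordpbind_protein": ("protein_binding", 0.8),
                "disordpbind_dna": ("dna_binding", 0.8),
                "disordpbind_rna": ("rna_binding", 0.8),
                "dflpred": ("linker", 0.8),
            },
            function_coverage={f: 0.6 for f in FUNCTION_LABELS},
            noise_sd=0.1,
            protein_bias_sd=0.05,
            fully_disordered_fraction=0.05,
            seed=base_seed + 3,
        ),
    }


def fixture_suite(seed: int = 0) -> dict[str, SimDataset]:
    """Deterministic bundle of the named fixture datasets."""
    return {name: simulate(p) for name, p in fixture_params(seed).items()}
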