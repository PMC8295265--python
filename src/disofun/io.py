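"""Readers and writers for every on-disk artifact.

Formats: FASTA sequences (via Biopython), DisProt-style region annotations as
4-column TSV (protein_id, start, end, label; 1-based inclusive), per-residue
profile tables as TSV with a named channel header, and per-protein prediction
CSVs with one row per residue.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .profiles import ProfileSchema
from .types import (
    ALL_LABELS,
    AMINO_ACIDS,
    FUNCTION_LABELS,
    LabelTrack,
    PredictionResult,
    Profile,
    ProteinRecord,
    RegionAnnotation,
)

_NONSTANDARD = re.compile(f"[^{AMINO_ACIDS}]")

ANNOTATION_COLUMNS = ["protein_id", "start", "end", "label"]

#: Column layout of the prediction CSV, after position and residue.
PREDICTION_TRACKS = ["disorder"] + list(FUNCTION_LABELS)


def clean_sequence(raw: str) -> str:
    """Upper-case and map any letter outside the 20 standard ones to X."""
    return _NONSTANDARD.sub("X", raw.upper())


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read FASTA into protein records, in file order.

    Sequences are upper-cased with non-standard letters mapped to X.
    Raises on an empty file, duplicate ids, or sequence data before the
    first header.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first:
            raise ValueError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise ValueError(f"{path}: sequence data before the first FASTA header")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=clean_sequence(str(rec.seq))))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_annotations(path: str | Path) -> list[RegionAnnotation]:
    """Read the 4-column region-annotation TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "label": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation file missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        if row.label not in ALL_LABELS:
            raise ValueError(f"{path}: unknown label {row.label!r}")
        out.append(RegionAnnotation(row.protein_id, int(row.start), int(row.end), row.label))
    return out


def write_annotations(regions: list[RegionAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.protein_id, r.start, r.end, r.label) for r in regions],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def regions_to_track(
    regions: list[RegionAnnotation], label: str, protein: ProteinRecord
) -> LabelTrack:
    """Collapse a protein's regions with one label into a 0/1 residue track.

    Positions inside any region are 1 (overlaps union); everything else is 0
    — residues are treated as structured/non-functional unless annotated.
    """
    L = len(protein)
    values = np.zeros(L, dtype=np.int8)
    for r in regions:
        if r.protein_id != protein.id:
            raise ValueError(f"region on {r.protein_id!r} given for protein {protein.id!r}")
        if r.label != label:
            raise ValueError(f"region label {r.label!r} != requested {label!r}")
        if r.end > L:
            raise ValueError(
                f"{protein.id}: region ({r.start},{r.end}) exceeds sequence length {L}"
            )
        values[r.start - 1 : r.end] = 1
    return LabelTrack(protein_id=protein.id, label=label, values=values)


def read_profile_table(
    path: str | Path, schema: ProfileSchema, expected_length: int | None = None
) -> Profile:
    """Read a per-residue profile table and align its columns to the schema.

    The file is TSV with a header of channel names and one row per residue;
    columns may appear in any order. Raises if a schema channel is missing,
    any cell is non-numeric/non-finite, or the row count disagrees with the
    declared sequence length.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in schema.channels if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: profile table missing channel {missing[0]!r}")
    values = np.empty((len(df), schema.n_channels), dtype=float)
    for j, c in enumerate(schema.channels):
        col = pd.to_numeric(df[c], errors="coerce").to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isfinite(col))
        if bad.size:
            raise ValueError(
                f"{path}: non-numeric value at row {bad[0] + 1}, column {c!r}"
            )
        values[:, j] = col
    if expected_length is not None and len(df) != expected_length:
        raise ValueError(
            f"{path}: {len(df)} profile rows vs declared sequence length {expected_length}"
        )
    protein_id = path.stem.removesuffix(".profile")
    profile = Profile(protein_id=protein_id, values=values, channels=schema.channels)
    schema.validate(profile)
    return profile


def write_profile_table(profile: Profile, path: str | Path) -> None:
    df = pd.DataFrame(profile.values, columns=list(profile.channels))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _track_columns(track: str) -> tuple[str, str]:
    return f"{track}_propensity", f"{track}_binary"


def write_prediction_csv(result: PredictionResult, path: str | Path) -> None:
    """Write one protein's prediction as CSV, one row per residue.

    Columns: position (1-based), residue, then propensity/binary pairs for
    disorder and the four functions. Propensities carry 3 decimals.
    """
    L = len(result)
    data: dict[str, object] = {
        "position": np.arange(1, L + 1),
        "residue": list(result.sequence),
    }
    pcol, bcol = _track_columns("disorder")
    data[pcol] = np.round(result.disorder_propensity, 3)
    data[bcol] = result.disorder_binary
    for f in FUNCTION_LABELS:
        pcol, bcol = _track_columns(f)
        prop = result.function_propensity.get(f, np.zeros(L))
        binary = result.function_binary.get(f, np.zeros(L, dtype=np.int8))
        if len(prop) != L or len(binary) != L:
            raise ValueError(f"{result.protein_id}: track length mismatch for {f!r}")
        data[pcol] = np.round(prop, 3)
        data[bcol] = binary
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.3f")


def read_prediction_csv(path: str | Path, protein_id: str | None = None) -> PredictionResult:
    path = Path(path)
    df = pd.read_csv(path)
    sequence = "".join(df["residue"].astype(str))
    return PredictionResult(
        protein_id=protein_id or path.stem,
        sequence=sequence,
        disorder_propensity=df["disorder_propensity"].to_numpy(),
        disorder_binary=df["disorder_binary"].to_numpy(),
        function_propensity={
            f: df[f"{f}_propensity"].to_numpy() for f in FUNCTION_LABELS
        },
        function_binary={f: df[f"{f}_binary"].to_numpy() for f in FUNCTION_LABELS},
    )
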