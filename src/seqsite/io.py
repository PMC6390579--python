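"""Readers, writers and checkpointing.

Formats:

* FASTA for sequences (read via Biopython; lowercase normalized).
* A per-residue feature-table TSV dialect, one row per residue:
  ``protein_id  pos  residue  pssm_1..pssm_20  rsa  ss_h ss_e ss_c
  phi  psi  cs_re  cs_jsd  [label]`` with a mandatory header, 1-based
  contiguous positions and ``.`` marking absent labels.
* NPZ checkpoints holding every weight tensor bit-exactly plus a JSON
  metadata block (format version, config snapshot, provenance and a
  training-state summary).
* Prediction TSVs (threshold recorded in a comment header) and JSON
  manifests / evaluation summaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .features import AMINO_ACIDS, DUMMY_RESIDUE, ProteinRecord
from .network import NetworkConfig, PredictionResult, Weights

__all__ = [
    "Checkpoint",
    "CHECKPOINT_VERSION",
    "FEATURE_TABLE_COLUMNS",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "write_predictions",
    "save_checkpoint",
    "load_checkpoint",
    "write_corpus",
]

CHECKPOINT_VERSION = "1"

_RAW_COLS = (
    [f"pssm_{i}" for i in range(1, 21)]
    + ["rsa", "ss_h", "ss_e", "ss_c", "phi", "psi", "cs_re", "cs_jsd"]
)
FEATURE_TABLE_COLUMNS = ["protein_id", "pos", "residue"] + _RAW_COLS + ["label"]

_VALID_LETTERS = set(AMINO_ACIDS) | {DUMMY_RESIDUE}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read protein sequences; lowercase is normalized to uppercase.

    Duplicate ids and illegal residue letters are rejected with the line
    number at which they occur.  An empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    seen: dict[str, int] = {}
    with open(path) as fh:
        current_id = None
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current_id = line[1:].split()[0] if line[1:].split() else ""
                if not current_id:
                    raise ValueError(f"{path}:{lineno}: empty FASTA header")
                if current_id in seen:
                    raise ValueError(
                        f"{path}:{lineno}: duplicate id {current_id!r} "
                        f"(first seen at line {seen[current_id]})")
                seen[current_id] = lineno
            else:
                if current_id is None:
                    raise ValueError(f"{path}:{lineno}: sequence before any header")
                bad = set(line.upper()) - _VALID_LETTERS
                if bad:
                    raise ValueError(
                        f"{path}:{lineno}: illegal residue letter(s) "
                        f"{sorted(bad)} in {current_id!r}")
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        warnings.warn(f"{path}: no FASTA records found")
    return records


def write_fasta(proteins: Sequence[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(proteins: Sequence[ProteinRecord], path) -> None:
    """Write raw per-residue features (and labels when present) as TSV."""
    frames = []
    for p in proteins:
        if p.features is None:
            raise ValueError(f"protein {p.id!r} carries no raw features")
        f = np.asarray(p.features, dtype=float)
        df = pd.DataFrame(f, columns=_RAW_COLS)
        df.insert(0, "protein_id", p.id)
        df.insert(1, "pos", np.arange(1, len(p) + 1))
        df.insert(2, "residue", list(p.sequence))
        df["label"] = (
            [str(int(v)) for v in p.labels] if p.labels is not None else "."
        )
        frames.append(df)
    # %.17g guarantees a lossless float64 text round-trip
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path, fasta: Sequence[ProteinRecord] | None = None) -> list[ProteinRecord]:
    """Read the feature-table TSV back into protein records.

    Rows are ordered deterministically by (protein_id, pos); positions must
    be contiguous 1..L within each protein.  If ``fasta`` records are given,
    the residue column is checked against them.  A label column that is
    entirely ``.`` (or absent) yields unlabeled records for prediction-only
    use; partially labeled proteins are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"label": str},
                     float_precision="round_trip")
    required = set(FEATURE_TABLE_COLUMNS) - {"label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing feature-table columns {sorted(missing)}")
    has_label = "label" in df.columns
    df = df.sort_values(["protein_id", "pos"], kind="mergesort").reset_index(drop=True)
    by_fasta = {p.id: p.sequence for p in fasta} if fasta is not None else None
    records = []
    for pid, grp in df.groupby("protein_id", sort=False):
        pos = grp["pos"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(grp) + 1)):
            raise ValueError(f"{path}: positions of {pid!r} are not contiguous 1..L")
        seq = "".join(grp["residue"].astype(str))
        bad = set(seq.upper()) - _VALID_LETTERS
        if bad:
            raise ValueError(f"{path}: illegal residue letter(s) {sorted(bad)} in {pid!r}")
        if by_fasta is not None:
            if pid not in by_fasta:
                raise ValueError(f"{path}: protein {pid!r} absent from FASTA")
            if seq.upper() != by_fasta[pid]:
                raise ValueError(f"{path}: residue column of {pid!r} disagrees with FASTA")
        feats = grp[_RAW_COLS].to_numpy(dtype=float)
        labels = None
        if has_label:
            raw = grp["label"].astype(str)
            if (raw == ".").all():
                labels = None
            elif (raw == ".").any():
                raise ValueError(f"{path}: protein {pid!r} is only partially labeled")
            else:
                vals = raw.astype(int).to_numpy()
                if not np.isin(vals, (0, 1)).all():
                    raise ValueError(f"{path}: labels of {pid!r} must be 0/1")
                labels = vals
        records.append(ProteinRecord(id=str(pid), sequence=seq.upper(),
                                     labels=labels, features=feats))
    return records


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def write_predictions(results: Sequence[PredictionResult], proteins: Mapping[str, str], path) -> None:
    """Write per-residue predictions as TSV; the threshold is recorded in a
    comment line above the header."""
    if not results:
        raise ValueError("no predictions to write")
    thr = results[0].threshold
    with open(path, "w") as fh:
        fh.write(f"# threshold={thr}\n")
        fh.write("protein_id\tpos\tresidue\tp_positive\tlabel_pred\n")
        for r in results:
            seq = proteins[r.protein_id]
            for i in range(len(r.labels)):
                fh.write(
                    f"{r.protein_id}\t{i + 1}\t{seq[i]}\t"
                    f"{r.positive_probability[i]!r}\t{r.labels[i]}\n")


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    """A serialized model: config snapshot, weights, version, provenance."""

    config: NetworkConfig
    weights: Weights
    version: str = CHECKPOINT_VERSION
    provenance: dict = field(default_factory=dict)
    training_summary: dict = field(default_factory=dict)


def save_checkpoint(
    path,
    weights: Weights,
    provenance: Mapping | None = None,
    training_summary: Mapping | None = None,
) -> None:
    """Serialize weights bit-exactly (float64 NPZ) with JSON metadata."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": weights.config.to_dict(),
        "provenance": dict(provenance or {}),
        "training_summary": dict(training_summary or {}),
        "names": weights.names(),
    }
    arrays = {f"w::{n}": weights.params[n].data for n in weights.names()}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Checkpoint:
    """Load a checkpoint; version or shape mismatches are rejected cleanly."""
    from .network import init_weights  # local import to avoid cycle at module load

    try:
        with np.load(path) as data:
            if "__meta__" not in data:
                raise ValueError(f"{path}: not a seqsite checkpoint (missing metadata)")
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            arrays = {k[3:]: data[k] for k in data.files if k.startswith("w::")}
    except (OSError, ValueError, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read checkpoint {path}: {exc}") from exc
    if meta.get("version") != CHECKPOINT_VERSION:
        raise ValueError(
            f"{path}: checkpoint format version {meta.get('version')!r} "
            f"is not supported (expected {CHECKPOINT_VERSION!r})")
    config = NetworkConfig.from_dict(meta["config"])
    weights = init_weights(config, np.random.default_rng(0))
    weights.load_state_dict(arrays)
    return Checkpoint(config=config, weights=weights, version=meta["version"],
                      provenance=meta.get("provenance", {}),
                      training_summary=meta.get("training_summary", {}))


# ---------------------------------------------------------------------------
# corpus bundle
# ---------------------------------------------------------------------------

def write_corpus(corpus, out_dir) -> dict[str, Path]:
    """Write a synthetic corpus as FASTA + feature TSV + JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "corpus.fasta",
        "features": out / "features.tsv",
        "manifest": out / "manifest.json",
    }
    write_fasta(corpus.proteins, paths["fasta"])
    write_feature_table(corpus.proteins, paths["features"])
    with open(paths["manifest"], "w") as fh:
        json.dump(corpus.manifest(), fh, indent=2)
    return paths
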