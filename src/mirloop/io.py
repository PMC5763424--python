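"""File I/O: FASTA records, label manifests, dot-bracket files, feature
tables, and run provenance stamps."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .folding import SecondaryStructure, pairs_from_dotbracket
from .records import RnaRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "read_structures",
    "write_structures",
    "read_feature_csv",
    "write_feature_csv",
    "provenance",
]


def read_fasta(path) -> list[RnaRecord]:
    """Read FASTA into canonicalized records, order preserved.

    Multi-line sequences are accepted; lowercase and DNA-style T are
    canonicalized.  Empty files and duplicate ids are rejected with
    explicit messages.
    """
    records: list[RnaRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        try:
            records.append(RnaRecord(id=entry.id, sequence=str(entry.seq)))
        except ValueError as exc:
            raise ValueError(f"record {entry.id!r}: {exc}") from exc
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def read_labels(path) -> pd.DataFrame:
    """Read a tab-separated label manifest with at least ``id`` and ``label``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("id", "label"):
        if col not in df.columns:
            raise ValueError(f"label file {path} missing column {col!r}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate id {dup!r} in label file {path}")
    return df


def write_labels(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_structures(path) -> dict[str, str]:
    """Read dot-bracket triples (``>id`` / sequence / structure lines).

    Returns ``{id: dotbracket}``; each structure is validated as balanced
    and length-matched to its sequence line.
    """
    structures: dict[str, str] = {}
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise ValueError(f"expected '>' header at line {i + 1} of {path}")
        if i + 2 >= len(lines):
            raise ValueError(f"truncated record {header!r} in {path}")
        rec_id = header[1:].split()[0]
        seq, db = lines[i + 1], lines[i + 2]
        if len(seq) != len(db):
            raise ValueError(
                f"record {rec_id!r}: sequence and structure lengths differ"
            )
        pairs_from_dotbracket(db)  # validates balance
        if rec_id in structures:
            raise ValueError(f"duplicate structure id {rec_id!r} in {path}")
        structures[rec_id] = db
        i += 3
    return structures


def write_structures(records, structures, path) -> None:
    """Write dot-bracket triples for parallel record/structure lists."""
    with open(path, "w") as fh:
        for rec, st in zip(records, structures):
            fh.write(f">{rec.id}\n{rec.sequence}\n{st.dotbracket}\n")


def provenance(seed, config: dict) -> dict:
    """Provenance stamp for output artifacts: version, seed, config hash."""
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    return {"tool": "mirloop", "version": __version__, "seed": seed,
            "config_hash": digest}


def write_feature_csv(frame: pd.DataFrame, path, seed=None, config=None) -> None:
    """Write a feature table with a ``#``-prefixed provenance header line."""
    stamp = provenance(seed, config or {})
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(stamp)}\n")
        frame.to_csv(fh)


def read_feature_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col="id")
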