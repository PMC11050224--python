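"""Standard-format I/O: FASTA (optionally gzipped), BED, TSV, JSON.

All genomic intervals are 0-based half-open (BED convention).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_bed",
    "write_tsv",
    "read_tsv",
    "write_json",
    "track_to_frame",
]


def read_fasta(path) -> list[SeqRecord]:
    """Parse a (possibly gzipped) FASTA file; raises on empty input."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    try:
        with opener(path, "rt") as fh:
            records = list(SeqIO.parse(fh, "fasta"))
    except OSError as exc:
        raise ValueError(f"cannot read FASTA {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records) -> None:
    """Write records ((name, seq) pairs or SeqRecords) wrapped at 60 columns."""
    recs = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            recs.append(rec)
        else:
            name, seq = rec
            recs.append(SeqRecord(Seq(seq), id=name, description=""))
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def write_bed(path, rows) -> None:
    """Write BED lines from (chrom, start, end, name[, score[, strand]]) tuples."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_tsv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def track_to_frame(track) -> pd.DataFrame:
    """Monomer track as a tidy table (one row per instance)."""
    return pd.DataFrame(
        {
            "start": [m.start for m in track.instances],
            "end": [m.end for m in track.instances],
            "strand": [m.strand for m in track.instances],
            "family_id": [m.family_id for m in track.instances],
            "divergence": [m.divergence for m in track.instances],
            "enumeration_index": [m.enumeration_index for m in track.instances],
        }
    )
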