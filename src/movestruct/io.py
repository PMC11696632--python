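"""File formats: FASTA/FASTQ input, index serialization, query output.

The on-disk index is a single JSON container with a magic string and a format
version, holding the table columns, thresholds, optional repositioning
pointers and the record table.  The round trip is field-exact, so query
output before and after a save/load cycle is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .index import MoveIndex
from .move_table import MoveTable
from .queries import QueryResult
from .thresholds import ThresholdSet

MAGIC = "MOVESTRUCT-INDEX"
FORMAT_VERSION = 1


class IndexFormatError(ValueError):
    """The file is not a readable index (bad magic, version or truncation)."""


# -- sequence input ---------------------------------------------------------


def read_fasta(path: "str | Path") -> list[tuple[str, str]]:
    """Multi-FASTA records as (name, sequence); name is the header up to whitespace."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return records


def read_reads(path: "str | Path") -> list[tuple[str, str]]:
    """Reads from FASTA or FASTQ, sniffed from the first non-blank character."""
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line[0]
                break
    fmt = "fastq" if first == "@" else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def write_fasta(records: list[tuple[str, str]], path: "str | Path", width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(records: list[tuple[str, str]], path: "str | Path") -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


# -- query output -----------------------------------------------------------


def write_pml_output(results: list[QueryResult], path: "str | Path") -> None:
    """One record per read: a '>' header line, then space-separated PMLs."""
    with open(path, "w") as fh:
        for res in results:
            fh.write(f">{res.name}\n")
            fh.write(" ".join(str(int(v)) for v in res.pmls) + "\n")


def write_count_output(rows: list[tuple[str, int]], path: "str | Path") -> None:
    """TSV with columns read_name, count."""
    with open(path, "w") as fh:
        fh.write("read_name\tcount\n")
        for name, cnt in rows:
            fh.write(f"{name}\t{cnt}\n")


# -- index container --------------------------------------------------------


def serialize_index(index: MoveIndex, path: "str | Path") -> None:
    t = index.table
    payload = {
        "magic": MAGIC,
        "version": FORMAT_VERSION,
        "mode": t.mode,
        "alphabet": "$ACGT",
        "n": t.n,
        "r_original": t.r_original,
        "rows": t.n_rows,
        "d": t.d,
        "has_thresholds": index.thresholds is not None,
        "has_pointers": index.repos_ptrs is not None,
        "includes_rc": index.includes_rc,
        "c_codes": t.c_codes.tolist(),
        "l": t.l.tolist(),
        "p": t.p.tolist(),
        "pi": t.pi.tolist(),
        "xi": t.xi.tolist(),
        "thresholds": index.thresholds.values.tolist(),
        "thresholds_present": index.thresholds.present.tolist(),
        "repos_ptrs": index.repos_ptrs.tolist() if index.repos_ptrs is not None else None,
        "records": [[name, int(s), int(e)] for name, s, e in index.record_boundaries],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def deserialize_index(path: "str | Path") -> MoveIndex:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise IndexFormatError(f"not a readable index file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("magic") != MAGIC:
        raise IndexFormatError("bad magic: not a movestruct index file")
    if payload.get("version") != FORMAT_VERSION:
        raise IndexFormatError(
            f"unsupported index format version {payload.get('version')!r} "
            f"(expected {FORMAT_VERSION})"
        )
    table = MoveTable(
        c_codes=np.array(payload["c_codes"], dtype=np.uint8),
        l=np.array(payload["l"], dtype=np.int64),
        p=np.array(payload["p"], dtype=np.int64),
        pi=np.array(payload["pi"], dtype=np.int64),
        xi=np.array(payload["xi"], dtype=np.int64),
        n=int(payload["n"]),
        r_original=int(payload["r_original"]),
        mode=payload["mode"],
        d=payload["d"],
    )
    table.validate()
    thr = ThresholdSet(
        values=np.array(payload["thresholds"], dtype=np.int64).reshape(table.n_rows, -1),
        present=np.array(payload["thresholds_present"], dtype=bool),
        n=table.n,
    )
    ptrs = (
        np.array(payload["repos_ptrs"], dtype=np.int64)
        if payload.get("repos_ptrs") is not None
        else None
    )
    records = [(name, int(s), int(e)) for name, s, e in payload["records"]]
    return MoveIndex(
        table=table,
        thresholds=thr,
        repos_ptrs=ptrs,
        record_boundaries=records,
        includes_rc=bool(payload["includes_rc"]),
    )
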