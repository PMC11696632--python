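"""Synthetic pangenomes and reads.

A pangenome is emulated as one uniform-random base genome plus mutated copies
(per-base substitutions, optional single-base indels).  Near-identical copies
are what make run-length compression pay off: the BWT run count ``r`` grows
with the amount of *distinct* sequence, not total length, so ``n/r`` climbs
as copies are added.  ``r_growth_experiment`` reproduces that trend in
miniature, alongside a distinct canonical k-mer count.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._alphabet import DNA, revcomp
from .text_index import IndexText, build_suffix_array, build_text, bwt_from_sa

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_pangenome(
    base_len: int,
    n_copies: int,
    mut_rate: float,
    indel_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """One random base genome plus ``n_copies - 1`` mutated copies.

    Substitutions flip a base to a uniformly random *different* base with
    probability ``mut_rate`` per position; with probability ``indel_rate`` a
    position instead suffers a single-base deletion or insertion (equal odds).
    """
    if base_len < 1:
        raise ValueError("base_len must be >= 1")
    if not (0 <= mut_rate <= 1 and 0 <= indel_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, size=base_len, dtype=np.int64)
    records = [("copy0", _to_str(base))]
    for k in range(1, n_copies):
        seq = base.copy()
        sub_mask = rng.random(base_len) < mut_rate
        if sub_mask.any():
            # shift by 1..3 mod 4: always a different base
            shifts = rng.integers(1, 4, size=int(sub_mask.sum()))
            seq[sub_mask] = (seq[sub_mask] + shifts) % 4
        if indel_rate > 0:
            out: list[int] = []
            indel_mask = rng.random(base_len) < indel_rate
            inserts = rng.integers(0, 4, size=base_len)
            deletes = rng.random(base_len) < 0.5
            for i in range(base_len):
                if indel_mask[i]:
                    if deletes[i]:
                        continue
                    out.append(int(inserts[i]))
                out.append(int(seq[i]))
            seq = np.array(out, dtype=np.int64)
        records.append((f"copy{k}", _to_str(seq)))
    return records


def sample_reads(
    t: IndexText,
    n_reads: int,
    read_len: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Reads drawn uniformly from the records, from either strand.

    A read never spans a record boundary or the sentinel.  With
    ``error_rate=0`` every read is an exact substring of the indexed text
    (the index holds both strands, so reverse-strand reads are covered too).
    Errors are per-base substitutions to a random different base.
    """
    rng = np.random.default_rng(seed)
    # sample only forward-record intervals; strand is handled by revcomp
    fw = [b for b in t.record_boundaries if not b[0].endswith("_rc")] or t.record_boundaries
    eligible = [(name, s, e) for name, s, e in fw if e - s >= read_len]
    if not eligible:
        raise ValueError(f"no record is at least {read_len} bp long")
    weights = np.array([e - s - read_len + 1 for _, s, e in eligible], dtype=float)
    weights /= weights.sum()
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        ri = int(rng.choice(len(eligible), p=weights))
        name, s, e = eligible[ri]
        start = int(rng.integers(s, e - read_len + 1))
        seq = t.text[start : start + read_len]
        strand = "+"
        # reverse-strand reads are exact substrings only when the index holds RC
        if t.includes_rc and rng.random() < 0.5:
            seq = revcomp(seq)
            strand = "-"
        if error_rate > 0:
            chars = list(seq)
            err = rng.random(read_len) < error_rate
            for pos in np.flatnonzero(err):
                alt = [b for b in DNA if b != chars[pos]]
                chars[pos] = alt[int(rng.integers(0, 3))]
            seq = "".join(chars)
        reads.append((f"read{i}_{name}_{start}{strand}", seq))
    return reads


def random_reads(n_reads: int, read_len: int, seed: int = 0) -> list[tuple[str, str]]:
    """Off-target reads: uniform random DNA, unrelated to any reference."""
    rng = np.random.default_rng(seed)
    return [
        (f"rand{i}", _to_str(rng.integers(0, 4, size=read_len, dtype=np.int64)))
        for i in range(n_reads)
    ]


def count_canonical_kmers(records: list[tuple[str, str]], k: int = 31) -> int:
    """Distinct canonical k-mers (lexicographic min of k-mer and reverse complement)."""
    seen: set[str] = set()
    for _, seq in records:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            rc = revcomp(kmer)
            seen.add(kmer if kmer <= rc else rc)
    return len(seen)


def r_growth_experiment(
    copies_list: list[int],
    mut_rate: float,
    seed: int = 0,
    base_len: int = 2000,
    k: int = 31,
    indel_rate: float = 0.0,
) -> pd.DataFrame:
    """Index size vs pangenome size: n, r and n/r for nested copy counts.

    Copy sets are nested (the 8-copy pangenome contains the 4-copy one), so
    each row adds genomes to the previous row's collection.  ``n/r`` is the
    rough compression ratio; it grows with the number of near-identical
    copies while the distinct canonical k-mer count grows sub-linearly.
    """
    if list(copies_list) != sorted(copies_list) or len(set(copies_list)) != len(copies_list):
        raise ValueError("copies_list must be strictly increasing")
    all_records = simulate_pangenome(
        base_len, max(copies_list), mut_rate, indel_rate=indel_rate, seed=seed
    )
    rows = []
    for copies in copies_list:
        records = all_records[:copies]
        text = build_text(records, include_rc=True)
        sa = build_suffix_array(text)
        bwt = bwt_from_sa(text, sa)
        rows.append(
            {
                "copies": copies,
                "n": text.n,
                "r": bwt.r,
                "n_over_r": text.n / bwt.r,
                "distinct_kmers": count_canonical_kmers(records, k=k),
            }
        )
    return pd.DataFrame(rows)
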