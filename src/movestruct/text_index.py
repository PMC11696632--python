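"""Indexed text construction and ground-truth (brute-force) structures.

This module owns everything the index is *checked against*: the concatenated
reference text, its suffix array, the BWT, the LCP array, a rank/C-array
oracle, and naive implementations of LF, matching statistics and occurrence
counting.  The move-structure modules are validated against these oracles;
none of them is used on the query hot path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._alphabet import ALPHABET, CHAR_TO_CODE, DNA, SENTINEL, decode, encode, revcomp

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when input records violate the alphabet policy."""


@dataclass
class IndexText:
    """The concatenated reference text the index is built over.

    ``text`` is the forward records, optionally followed by the reverse
    complement of each record (same order), terminated by a single sentinel
    ``$`` that appears nowhere else and compares smaller than every base.
    ``record_boundaries`` holds half-open ``(name, start, end)`` intervals
    into ``text`` (reverse-complement segments carry a ``_rc`` suffix).
    """

    text: str
    n: int
    record_boundaries: list[tuple[str, int, int]] = field(default_factory=list)
    includes_rc: bool = True

    def validate(self) -> None:
        if not self.text.endswith(SENTINEL) or SENTINEL in self.text[:-1]:
            raise ValueError("text must contain exactly one sentinel, at the end")
        if self.n != len(self.text):
            raise ValueError("n does not match text length")
        encode(self.text)  # raises on characters outside $ACGT


def build_text(
    records: list[tuple[str, str]],
    include_rc: bool = True,
    alphabet_policy: str = "strip",
) -> IndexText:
    """Concatenate named DNA records into a single sentinel-terminated text.

    Parameters
    ----------
    records
        ``(name, sequence)`` pairs; sequences are uppercased.
    include_rc
        Append the reverse complement of each record after the forward
        records, so that reads from either strand can be queried forward-only.
    alphabet_policy
        ``"strip"`` removes non-ACGT characters with a warning; ``"reject"``
        raises :class:`ValidationError` naming the record and offset.
    """
    if alphabet_policy not in ("strip", "reject"):
        raise ValueError(f"unknown alphabet policy {alphabet_policy!r}")
    if not records:
        raise ValidationError("no input records")

    cleaned: list[tuple[str, str]] = []
    for name, seq in records:
        seq = seq.upper()
        if any(c not in DNA for c in seq):
            if alphabet_policy == "reject":
                off = next(i for i, c in enumerate(seq) if c not in DNA)
                raise ValidationError(
                    f"record {name!r}: non-ACGT character {seq[off]!r} at offset {off}"
                )
            kept = "".join(c for c in seq if c in DNA)
            logger.warning(
                "record %r: stripped %d non-ACGT character(s)", name, len(seq) - len(kept)
            )
            seq = kept
        if not seq:
            raise ValidationError(f"record {name!r} is empty after alphabet policy")
        cleaned.append((name, seq))

    parts: list[str] = []
    boundaries: list[tuple[str, int, int]] = []
    pos = 0
    for name, seq in cleaned:
        parts.append(seq)
        boundaries.append((name, pos, pos + len(seq)))
        pos += len(seq)
    if include_rc:
        for name, seq in cleaned:
            rc = revcomp(seq)
            parts.append(rc)
            boundaries.append((name + "_rc", pos, pos + len(rc)))
            pos += len(rc)
    text = "".join(parts) + SENTINEL
    return IndexText(text=text, n=len(text), record_boundaries=boundaries, includes_rc=include_rc)


def _as_text(t: "IndexText | str") -> str:
    return t.text if isinstance(t, IndexText) else t


def build_suffix_array(t: "IndexText | str") -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy-vectorised).

    ``sa[k]`` is the start offset of the k-th lexicographically smallest
    suffix.  With the unique smallest sentinel at the end, sorted suffixes
    coincide with sorted rotations.
    """
    text = _as_text(t)
    n = len(text)
    rank = encode(text).astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    k = 1
    while k < n:
        # sort by (rank[i], rank[i+k]) with out-of-range treated as -1
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        sa = np.lexsort((key2, rank))
        r1, r2 = rank[sa], key2[sa]
        boundary = np.ones(n, dtype=bool)
        boundary[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = np.cumsum(boundary) - 1
        if rank[sa[-1]] == n - 1:  # all ranks distinct: fully sorted
            break
        k *= 2
    return sa


def bwt_from_sa(t: "IndexText | str", sa: np.ndarray) -> "BwtString":
    """BWT: last column of the sorted-rotation matrix, ``bwt[k] = text[sa[k]-1]``."""
    text = _as_text(t)
    n = len(text)
    prev = (np.asarray(sa, dtype=np.int64) - 1) % n
    codes = encode(text)[prev]
    bwt = decode(codes)
    r = 1 + int(np.count_nonzero(codes[1:] != codes[:-1])) if n > 1 else 1
    return BwtString(bwt=bwt, r=r)


def lcp_from_sa(t: "IndexText | str", sa: np.ndarray) -> np.ndarray:
    """LCP array via Kasai's algorithm; ``lcp[k]`` compares suffixes ``sa[k-1]``, ``sa[k]``."""
    text = _as_text(t)
    n = len(text)
    sa = np.asarray(sa, dtype=np.int64)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        k = rank[i]
        if k == 0:
            h = 0
            continue
        j = sa[k - 1]
        while i + h < n and j + h < n and text[i + h] == text[j + h]:
            h += 1
        lcp[k] = h
        if h:
            h -= 1
    return lcp


@dataclass
class BwtString:
    """A BWT with its run count ``r`` (maximal same-character substrings)."""

    bwt: str
    r: int


class RankOracle:
    """C-array and prefix-rank structure over a BWT string.

    ``C[c]`` counts characters strictly smaller than ``c`` in the text;
    ``rank(c, j)`` counts occurrences of ``c`` in ``bwt[0:j)``.  Backed by
    per-character cumulative-count arrays — simple and exact, used as the
    ground truth the move table is checked against.
    """

    def __init__(self, bwt: str):
        codes = encode(bwt)
        n = len(codes)
        self.n = n
        onehot = codes[:, None] == np.arange(len(ALPHABET))[None, :]
        # _cum[j, c] = occurrences of code c in bwt[0:j)
        self._cum = np.zeros((n + 1, len(ALPHABET)), dtype=np.int64)
        np.cumsum(onehot, axis=0, out=self._cum[1:])
        totals = self._cum[-1]
        self.C = {
            ch: int(totals[:i].sum()) for i, ch in enumerate(ALPHABET)
        }
        self.counts = {ch: int(totals[i]) for i, ch in enumerate(ALPHABET)}

    def rank(self, c: str, j: int) -> int:
        return int(self._cum[j, CHAR_TO_CODE[c]])


def lf_oracle(bwt: "BwtString | str", ranks: RankOracle, j: int) -> int:
    """Ground-truth LF: ``C[bwt[j]] + rank(bwt[j], j)``.

    Maps a position in the last column of the sorted-rotation matrix to the
    position of the same text character in the first column.
    """
    s = bwt.bwt if isinstance(bwt, BwtString) else bwt
    if not 0 <= j < len(s):
        raise IndexError(f"offset {j} out of range [0, {len(s)})")
    c = s[j]
    return ranks.C[c] + ranks.rank(c, j)


def lf_array(bwt: "BwtString | str", ranks: RankOracle) -> np.ndarray:
    """Vectorised LF over every offset (``lf_oracle`` applied to 0..n-1)."""
    s = bwt.bwt if isinstance(bwt, BwtString) else bwt
    codes = encode(s)
    C = np.array([ranks.C[ch] for ch in ALPHABET], dtype=np.int64)
    ranks_at = ranks._cum[np.arange(len(s)), codes]
    return C[codes] + ranks_at


def matching_statistics_oracle(t: "IndexText | str", P: str) -> np.ndarray:
    """Matching statistics by exhaustive substring search.

    ``MS[i]`` is the length of the longest prefix of ``P[i:]`` that occurs in
    the text (sentinel excluded).  Uses ``MS[i+1] >= MS[i] - 1`` to extend a
    sliding match left-to-right; every candidate is verified with a direct
    substring search, independent of any index structure.
    """
    body = _as_text(t).rstrip(SENTINEL)
    m = len(P)
    ms = np.zeros(m, dtype=np.int64)
    ell = 0
    for i in range(m):
        if ell:  # carry over: P[i:i+ell] is known to occur
            ell -= 1
        while i + ell < m and body.find(P[i : i + ell + 1]) >= 0:
            ell += 1
        ms[i] = ell
    return ms


def count_oracle(t: "IndexText | str", P: str) -> int:
    """Naive overlapping-occurrence count of ``P`` in the text (sentinel excluded)."""
    if not P:
        raise ValueError("empty pattern")
    body = _as_text(t).rstrip(SENTINEL)
    cnt = 0
    start = body.find(P)
    while start >= 0:
        cnt += 1
        start = body.find(P, start + 1)
    return cnt
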