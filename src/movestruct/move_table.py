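"""The move structure table and LF-mapping with fast-forwards.

One table row per BWT run.  Row ``i`` stores the run character ``c``, run
length ``l``, the global BWT offset of the run head ``p``, the LF-mapping of
the run head ``pi`` and the index ``xi`` of the run containing ``pi``.  An LF
step from offset ``j`` inside run ``i`` is then

    j' = pi[i] + (j - p[i])
    i' = fast_forward from xi[i] until the row interval contains j'

so navigation never touches the BWT string itself — only table rows, and the
fast-forward touches them sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from ._alphabet import ALPHABET, CHAR_TO_CODE
from .text_index import BwtString, RankOracle, lf_oracle


class BwtPosition(NamedTuple):
    """The index's cursor: a run index paired with a global BWT offset."""

    run: int
    offset: int


@dataclass
class Counters:
    """Per-query operation counters (fast-forwards, repositioning scans...)."""

    lf_steps: int = 0
    fast_forwards: int = 0
    reposition_scans: int = 0
    case2_events: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "lf_steps": self.lf_steps,
            "fast_forwards": self.fast_forwards,
            "reposition_scans": self.reposition_scans,
            "case2_events": self.case2_events,
        }


class MoveTableError(ValueError):
    """Raised when table construction inputs are inconsistent."""


@dataclass
class MoveTable:
    """Columnar storage of the move structure's table M.

    ``c_codes``, ``l``, ``p``, ``pi``, ``xi`` are parallel arrays, one entry
    per row; rows are sorted by ``p`` and their intervals ``[p, p+l)``
    partition ``[0, n)``.  ``thresholds`` and ``repos_ptrs`` are populated by
    the thresholds module after (optional) run splitting.
    """

    c_codes: np.ndarray  # uint8 alphabet codes
    l: np.ndarray  # int64 run lengths
    p: np.ndarray  # int64 run head offsets
    pi: np.ndarray  # int64 LF of run head
    xi: np.ndarray  # int64 run index containing pi
    n: int
    r_original: int
    mode: str = "default"  # "default" or "constant"
    d: int | None = None  # splitting parameter (constant mode)
    thresholds: "np.ndarray | None" = None  # (rows, sigma) absolute offsets
    repos_ptrs: "np.ndarray | None" = None  # (rows, sigma, 2) run indices, -1 = none
    char_counts: np.ndarray = field(default=None)  # per-code totals
    C: np.ndarray = field(default=None)  # per-code count of smaller chars

    def __post_init__(self) -> None:
        if self.char_counts is None:
            counts = np.zeros(len(ALPHABET), dtype=np.int64)
            np.add.at(counts, self.c_codes.astype(np.int64), self.l)
            self.char_counts = counts
        if self.C is None:
            self.C = np.concatenate(([0], np.cumsum(self.char_counts)[:-1]))

    @property
    def n_rows(self) -> int:
        return len(self.p)

    def char_at(self, pos: BwtPosition) -> int:
        """Alphabet code of the BWT character at ``pos``."""
        return int(self.c_codes[pos.run])

    def row_interval(self, i: int) -> tuple[int, int]:
        return int(self.p[i]), int(self.p[i] + self.l[i])

    def validate(self) -> None:
        if int(self.l.sum()) != self.n:
            raise MoveTableError("row lengths do not sum to n")
        if not np.all(self.p[1:] == self.p[:-1] + self.l[:-1]) or self.p[0] != 0:
            raise MoveTableError("row intervals do not partition [0, n)")
        inside = (self.p[self.xi] <= self.pi) & (self.pi < self.p[self.xi] + self.l[self.xi])
        if not inside.all():
            raise MoveTableError("xi does not point at the run containing pi")


def run_length_encode(bwt: "BwtString | str") -> list[tuple[str, int, int]]:
    """Maximal runs of the BWT as ``(character, length, start offset)`` triples."""
    s = bwt.bwt if isinstance(bwt, BwtString) else bwt
    if not s:
        raise ValueError("empty BWT")
    runs: list[tuple[str, int, int]] = []
    start = 0
    for k in range(1, len(s) + 1):
        if k == len(s) or s[k] != s[start]:
            runs.append((s[start], k - start, start))
            start = k
    return runs


def build_move_table(
    runs: list[tuple[str, int, int]],
    bwt: "BwtString | str",
    ranks: RankOracle,
) -> MoveTable:
    """Assemble the table M from the run-length-encoded BWT.

    ``pi`` is the LF of each run head (computed with the rank oracle) and
    ``xi`` locates ``pi`` among the row intervals.
    """
    s = bwt.bwt if isinstance(bwt, BwtString) else bwt
    n = len(s)
    p = np.array([r[2] for r in runs], dtype=np.int64)
    l = np.array([r[1] for r in runs], dtype=np.int64)
    if int(l.sum()) != n or "".join(c * ln for c, ln, _ in runs) != s:
        raise MoveTableError("runs are inconsistent with the BWT")
    c_codes = np.array([CHAR_TO_CODE[r[0]] for r in runs], dtype=np.uint8)
    pi = np.array([lf_oracle(s, ranks, int(head)) for head in p], dtype=np.int64)
    xi = np.searchsorted(p, pi, side="right") - 1
    table = MoveTable(
        c_codes=c_codes, l=l, p=p, pi=pi, xi=xi.astype(np.int64), n=n, r_original=len(runs)
    )
    table.validate()
    return table


def fast_forward(
    M: MoveTable, i: int, j_target: int, counters: Counters | None = None
) -> int:
    """Advance sequentially from row ``i`` to the row whose interval holds ``j_target``.

    The caller guarantees ``M.p[i] <= j_target``; the scan only ever moves
    forward, mirroring the sequential-access pattern the structure is built
    around.  The number of rows skipped is added to the fast-forward counter.
    """
    if j_target >= M.n:
        raise IndexError(f"offset {j_target} out of range [0, {M.n})")
    p, l = M.p, M.l
    start = i
    while j_target >= p[i] + l[i]:
        i += 1
    if counters is not None:
        counters.fast_forwards += i - start
    return i


def lf_move(M: MoveTable, pos: BwtPosition, counters: Counters | None = None) -> BwtPosition:
    """One LF-mapping step on the table: arithmetic plus a fast-forward."""
    i, j = pos
    if not (0 <= i < M.n_rows and M.p[i] <= j < M.p[i] + M.l[i]):
        raise ValueError(f"invalid position {pos}")
    j_new = int(M.pi[i] + (j - M.p[i]))
    i_new = fast_forward(M, int(M.xi[i]), j_new, counters)
    if counters is not None:
        counters.lf_steps += 1
    return BwtPosition(i_new, j_new)


def position_at(M: MoveTable, j: int) -> BwtPosition:
    """Cursor for an arbitrary BWT offset (binary search over row heads)."""
    if not 0 <= j < M.n:
        raise IndexError(f"offset {j} out of range [0, {M.n})")
    i = int(np.searchsorted(M.p, j, side="right")) - 1
    return BwtPosition(i, j)
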