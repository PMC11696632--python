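"""Matching queries on the move structure.

Two query algorithms:

* **Pseudo-matching lengths (PMLs)** — a one-pass, right-to-left sweep over a
  read that maintains a running match length.  When the BWT character under
  the cursor equals the read character (case 1) the length grows and the
  cursor takes an LF step; on a mismatch (case 2) the length resets to zero
  and the cursor repositions to the nearest offset carrying the read
  character (threshold-chosen side) before the LF step.  PMLs lower-bound the
  matching statistics and are the standard read-classification signal for
  run-length-compressed indexes.

* **Backward-search counting** — maintains the interval of sorted-rotation
  rows prefixed by ever-longer suffixes of the pattern, moving a top and a
  bottom pointer.  Pointer updates are forced-direction repositionings (top
  goes down to ``jdn``, bottom goes up to ``jup``) followed by LF steps; the
  final interval width is the occurrence count.

``batch_query`` runs many PML queries through a single round-robin loop that
advances each read by one character per turn — the scheduling contract used
to hide memory latency, with results identical to sequential processing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._alphabet import CHAR_TO_CODE, SENTINEL
from .move_table import BwtPosition, Counters, MoveTable, lf_move, position_at
from .text_index import IndexText, RankOracle
from .thresholds import (
    ThresholdSet,
    _range_min,
    _scan_down,
    _scan_up,
    reposition_pointer,
    reposition_scan,
)


class BwmRange(NamedTuple):
    """Inclusive [top, bottom] interval of sorted-rotation rows."""

    top: BwtPosition
    bottom: BwtPosition
    empty: bool = False

    @property
    def width(self) -> int:
        return 0 if self.empty else self.bottom.offset - self.top.offset + 1


EMPTY_RANGE = BwmRange(BwtPosition(0, 0), BwtPosition(0, 0), empty=True)


@dataclass
class QueryResult:
    """Per-read output: a PML vector or an occurrence count, plus counters."""

    name: str
    pmls: np.ndarray | None = None
    count: int | None = None
    counters: Counters | None = None


class ConfigurationError(RuntimeError):
    """Index is missing a structure the requested query needs."""


def _query_code(c: str) -> int:
    """Alphabet code for a query character; -1 for anything outside ACGT.

    The sentinel is a first-class index character but never a legal query
    character: reads containing ``$``, ``N`` or any other symbol get a zero
    PML at that position.
    """
    code = CHAR_TO_CODE.get(c.upper(), -1)
    return -1 if c.upper() == SENTINEL else code


def compute_pmls(
    M: MoveTable,
    thr: ThresholdSet,
    read: str,
    start: BwtPosition | None = None,
    ptrs: np.ndarray | None = None,
    name: str = "",
) -> QueryResult:
    """Pseudo-matching lengths of a read, left-to-right in read orientation.

    The cursor starts at ``start`` (default: offset 0, an arbitrary choice
    made deterministic) and consumes the read right-to-left.  ``ptrs``
    selects constant-mode repositioning; otherwise runs are scanned.
    Characters absent from the index (including non-ACGT) reset the match
    length and leave the cursor in place.
    """
    if thr is None:
        raise ConfigurationError("PML queries require thresholds; build the index with them")
    counters = Counters()
    m = len(read)
    pmls = np.zeros(m, dtype=np.int64)
    if m == 0:
        return QueryResult(name=name, pmls=pmls, counters=counters)
    pos = start if start is not None else position_at(M, 0)
    ell = 0
    for i in range(m - 1, -1, -1):
        code = _query_code(read[i])
        if code < 0 or not thr.present[code]:
            ell = 0
            pmls[i] = 0
            continue
        if M.c_codes[pos.run] == code:  # case 1: extend the match
            ell += 1
            pmls[i] = ell
        else:  # case 2: reset and reposition
            counters.case2_events += 1
            ell = 0
            pmls[i] = 0
            c = read[i].upper()
            if ptrs is not None:
                pos = reposition_pointer(M, pos, c, ptrs, thr, counters)
            else:
                pos = reposition_scan(M, pos, c, thr, counters)
        pos = lf_move(M, pos, counters)
    return QueryResult(name=name, pmls=pmls, counters=counters)


def compute_pmls_reference(
    t: IndexText,
    sa: np.ndarray,
    bwt: str,
    lcp: np.ndarray,
    ranks: RankOracle,
    read: str,
    start_offset: int = 0,
) -> np.ndarray:
    """PMLs computed directly on the plain BWT with rank structures.

    Independent of the move table: the cursor is a bare BWT offset, LF is the
    C-array/rank formula, and repositioning picks the longer-LCP side of the
    nearest occurrences (ties upward).  Used to cross-check both table modes.
    """
    from ._alphabet import encode

    codes = encode(bwt)
    occ_by_code = [np.flatnonzero(codes == c) for c in range(len(CHAR_TO_CODE))]
    C = {c: ranks.C[c] for c in ranks.C}
    m = len(read)
    pmls = np.zeros(m, dtype=np.int64)
    j = start_offset
    ell = 0
    for i in range(m - 1, -1, -1):
        code = _query_code(read[i])
        if code < 0 or occ_by_code[code].size == 0:
            ell = 0
            continue
        if codes[j] == code:
            ell += 1
            pmls[i] = ell
        else:
            ell = 0
            occ = occ_by_code[code]
            k = int(np.searchsorted(occ, j))
            jup = int(occ[k - 1]) if k > 0 else None
            jdn = int(occ[k]) if k < occ.size else None
            if jup is None:
                j = jdn
            elif jdn is None:
                j = jup
            else:
                lcp_up = _range_min(lcp, jup + 1, j)
                lcp_dn = _range_min(lcp, j + 1, jdn)
                j = jup if lcp_up >= lcp_dn else jdn
        c = bwt[j]
        j = C[c] + ranks.rank(c, j)
    return pmls


def init_range(M: MoveTable, c: str) -> BwmRange:
    """Interval of sorted-rotation rows prefixed by the single character ``c``.

    This is the character's block in the first (F) column: offsets
    ``[C[c], C[c] + count(c) - 1]``.
    """
    code = _query_code(c)
    if code < 0 or M.char_counts[code] == 0:
        return EMPTY_RANGE
    lo = int(M.C[code])
    hi = lo + int(M.char_counts[code]) - 1
    return BwmRange(position_at(M, lo), position_at(M, hi))


def backward_extend(
    M: MoveTable,
    rng: BwmRange,
    c: str,
    counters: Counters | None = None,
) -> BwmRange:
    """Extend the matched suffix by one character to the left.

    The top pointer repositions downward (to the first in-range offset
    carrying ``c``) and the bottom pointer upward (to the last); the
    direction is forced by the pointer's role, not by thresholds.  Both then
    take LF steps.  Returns the empty range when ``c`` does not occur inside
    ``[top, bottom]``.
    """
    if rng.empty:
        raise ValueError("cannot extend an empty range")
    code = _query_code(c)
    if code < 0 or M.char_counts[code] == 0:
        return EMPTY_RANGE
    top, bottom = rng.top, rng.bottom
    if M.c_codes[top.run] != code:
        target = _scan_down(M, top.run, code)
        if counters is not None and target is not None:
            counters.reposition_scans += target.run - top.run
        if target is None or target.offset > bottom.offset:
            return EMPTY_RANGE
        top = target
    if M.c_codes[bottom.run] != code:
        target = _scan_up(M, bottom.run, code)
        if counters is not None and target is not None:
            counters.reposition_scans += bottom.run - target.run
        if target is None or target.offset < top.offset:
            return EMPTY_RANGE
        bottom = target
    return BwmRange(lf_move(M, top, counters), lf_move(M, bottom, counters))


def count(M: MoveTable, P: str, counters: Counters | None = None) -> int:
    """Number of occurrences of ``P`` in the indexed text, by backward search.

    Patterns containing characters outside the index alphabet cannot occur
    and count 0.
    """
    if not P:
        raise ValueError("empty pattern")
    rng = init_range(M, P[-1])
    for i in range(len(P) - 2, -1, -1):
        if rng.empty:
            return 0
        rng = backward_extend(M, rng, P[i], counters)
    return rng.width


def batch_query(
    M: MoveTable,
    thr: ThresholdSet,
    reads: list[tuple[str, str]],
    batch_size: int = 16,
    ptrs: np.ndarray | None = None,
    start: BwtPosition | None = None,
) -> list[QueryResult]:
    """PMLs for many reads via a round-robin loop over ``batch_size`` slots.

    A single loop advances each in-flight read by one character per turn and
    loads the next read into a slot as soon as one is exhausted — the
    schedule that lets an implementation prefetch the next LF destination row
    while other reads are serviced.  Results are identical to per-read
    processing and are emitted in input order regardless of ``batch_size``.
    """
    if batch_size < 1:
        raise ValueError("batch size must be >= 1")
    if thr is None:
        raise ConfigurationError("PML queries require thresholds")
    start_pos = start if start is not None else position_at(M, 0)
    results: list[QueryResult | None] = [None] * len(reads)

    class _Slot:
        __slots__ = ("idx", "read", "i", "ell", "pos", "pmls", "counters")

        def __init__(self, idx: int) -> None:
            self.idx = idx
            self.read = reads[idx][1]
            self.i = len(self.read) - 1
            self.ell = 0
            self.pos = start_pos
            self.pmls = np.zeros(len(self.read), dtype=np.int64)
            self.counters = Counters()

    next_read = 0
    slots: list[_Slot] = []
    while next_read < len(reads) and len(slots) < batch_size:
        slots.append(_Slot(next_read))
        next_read += 1

    while slots:
        keep: list[_Slot] = []
        for slot in slots:
            if slot.i < 0:  # read exhausted: emit and reload the slot
                results[slot.idx] = QueryResult(
                    name=reads[slot.idx][0], pmls=slot.pmls, counters=slot.counters
                )
                if next_read < len(reads):
                    slot = _Slot(next_read)
                    next_read += 1
                else:
                    continue
            # one inner-loop step: process read character slot.i
            i = slot.i
            code = _query_code(slot.read[i])
            if code < 0 or not thr.present[code]:
                slot.ell = 0
            else:
                if M.c_codes[slot.pos.run] == code:
                    slot.ell += 1
                    slot.pmls[i] = slot.ell
                else:
                    slot.counters.case2_events += 1
                    slot.ell = 0
                    c = slot.read[i].upper()
                    if ptrs is not None:
                        slot.pos = reposition_pointer(M, slot.pos, c, ptrs, thr, slot.counters)
                    else:
                        slot.pos = reposition_scan(M, slot.pos, c, thr, slot.counters)
                slot.pos = lf_move(M, slot.pos, slot.counters)
            slot.i -= 1
            keep.append(slot)
        slots = keep

    return results  # type: ignore[return-value]
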