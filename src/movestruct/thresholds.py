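"""Per-run thresholds and case-2 repositioning.

When the query character ``c`` differs from the BWT character under the
cursor (a "case 2" event), the cursor must move to a nearby BWT offset that
does carry ``c``: either ``jup``, the greatest such offset above, or ``jdn``,
the smallest below.  The right choice is the side whose sorted suffix shares
the longer common prefix with the suffix at the current offset, and because
LCP values between consecutive occurrences of ``c`` are unimodal around their
minimum, a single *threshold* offset per (run, character) encodes the choice:
offsets before the threshold go up, offsets at or after it go down.

Two repositioning engines are provided: a run-by-run scan (default mode) and
stored nearest-run pointers (constant mode, one table access per event).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._alphabet import ALPHABET, CHAR_TO_CODE, encode
from .move_table import BwtPosition, Counters, MoveTable
from .text_index import BwtString, IndexText


class CharacterAbsentError(KeyError):
    """The repositioning character does not occur anywhere in the BWT."""


@dataclass
class ThresholdSet:
    """Absolute threshold offsets, one per (row, alphabet code).

    ``values[i, c]`` is clamped into the row interval ``[p_i, p_i + l_i]``;
    an offset ``j`` in row ``i`` repositions upward for character ``c`` iff
    ``j < values[i, c]``.  The clamped boundary values encode the one-sided
    cases: ``p_i`` means "always down", ``p_i + l_i`` means "always up".
    ``present[c]`` is False when ``c`` occurs nowhere in the BWT (no
    reposition target exists at all).
    """

    values: np.ndarray  # (rows, sigma) int64
    present: np.ndarray  # (sigma,) bool
    n: int

    def goes_up(self, pos: BwtPosition, code: int) -> bool:
        if not self.present[code]:
            raise CharacterAbsentError(ALPHABET[code])
        return pos.offset < int(self.values[pos.run, code])


def _gap_thresholds(occ: np.ndarray, lcp: np.ndarray, n: int) -> np.ndarray:
    """Threshold offset for every gap between consecutive occurrences of a character.

    Gap g spans sorted-suffix offsets between ``occ[g-1]`` and ``occ[g]``
    (with virtual occurrences at -1 and n).  Inside gap ``(a, b)`` the
    threshold is the *last* position of the minimum of ``lcp[a+1 .. b]``:
    offsets below it have their nearest-above candidate win (or tie, which
    resolves upward), offsets at or above it lose the upward LCP to the
    minimum.  The leading gap (no occurrence above) gets threshold 0
    (always down); the trailing gap gets ``n`` (always up).
    """
    thresholds = np.empty(len(occ) + 1, dtype=np.int64)
    thresholds[0] = 0
    thresholds[-1] = n
    for g in range(1, len(occ)):
        a, b = int(occ[g - 1]), int(occ[g])
        window = lcp[a + 1 : b + 1]
        # last argmin => ties between up and down candidates resolve upward
        t = a + 1 + (len(window) - 1 - int(np.argmin(window[::-1])))
        thresholds[g] = t
    return thresholds


def compute_thresholds(
    M: MoveTable,
    bwt: "BwtString | str",
    sa: np.ndarray,
    lcp: np.ndarray,
) -> ThresholdSet:
    """Thresholds for every row and character, from the explicit LCP array.

    A row is a run of a single character, so for any other character ``c`` the
    whole row falls in one gap between consecutive ``c`` occurrences; the
    row's threshold is that gap's threshold clamped into the row interval.
    """
    s = bwt.bwt if isinstance(bwt, BwtString) else bwt
    codes = encode(s)
    n = len(s)
    rows = M.n_rows
    values = np.zeros((rows, len(ALPHABET)), dtype=np.int64)
    present = np.zeros(len(ALPHABET), dtype=bool)
    row_lo = M.p
    row_hi = M.p + M.l
    for code in range(len(ALPHABET)):
        occ = np.flatnonzero(codes == code)
        if occ.size == 0:
            continue
        present[code] = True
        gap_t = _gap_thresholds(occ, lcp, n)
        # gap index for each row: number of occurrences at or before the row head
        gap_idx = np.searchsorted(occ, row_lo, side="right")
        t = gap_t[gap_idx]
        values[:, code] = np.clip(t, row_lo, row_hi)
    return ThresholdSet(values=values, present=present, n=n)


def _range_min(lcp: np.ndarray, lo: int, hi: int) -> int:
    """min(lcp[lo..hi]) inclusive; the LCP of sorted suffixes hi-lo+1 apart."""
    return int(lcp[lo : hi + 1].min())


def reposition_oracle(
    t: IndexText,
    sa: np.ndarray,
    bwt: "BwtString | str",
    j: int,
    c: str,
    lcp: np.ndarray | None = None,
) -> int:
    """Ground-truth repositioning target for offset ``j`` and character ``c``.

    Finds ``jup`` (greatest offset < j with ``BWT = c``) and ``jdn`` (smallest
    offset > j) and returns whichever has the longer LCP between its sorted
    suffix and the one at ``j``; ties go to ``jup``.
    """
    s = bwt.bwt if isinstance(bwt, BwtString) else bwt
    if lcp is None:
        from .text_index import lcp_from_sa

        lcp = lcp_from_sa(t, sa)
    occ = np.flatnonzero(encode(s) == CHAR_TO_CODE[c])
    if occ.size == 0:
        raise CharacterAbsentError(c)
    k = int(np.searchsorted(occ, j))
    jup = int(occ[k - 1]) if k > 0 else None
    jdn = int(occ[k]) if k < occ.size else None
    if jdn is not None and occ[k] == j:
        raise ValueError("offset already carries the requested character")
    if jup is None:
        return jdn
    if jdn is None:
        return jup
    lcp_up = _range_min(lcp, jup + 1, j)
    lcp_dn = _range_min(lcp, j + 1, jdn)
    return jup if lcp_up >= lcp_dn else jdn


def _scan_up(M: MoveTable, run: int, code: int) -> BwtPosition | None:
    """Nearest run above with character ``code``; lands on its last offset."""
    i = run - 1
    while i >= 0 and M.c_codes[i] != code:
        i -= 1
    if i < 0:
        return None
    return BwtPosition(i, int(M.p[i] + M.l[i] - 1))


def _scan_down(M: MoveTable, run: int, code: int) -> BwtPosition | None:
    """Nearest run below with character ``code``; lands on its first offset."""
    i = run + 1
    while i < M.n_rows and M.c_codes[i] != code:
        i += 1
    if i >= M.n_rows:
        return None
    return BwtPosition(i, int(M.p[i]))


def reposition_scan(
    M: MoveTable,
    pos: BwtPosition,
    c: str,
    thr: ThresholdSet,
    counters: Counters | None = None,
) -> BwtPosition:
    """Default-mode repositioning: threshold decides the direction, then scan.

    Scans consecutive rows toward the nearest run of ``c`` and lands on the
    offset of that run closest to the query row (last offset when moving up,
    first when moving down).  The rows traversed are added to the
    repositioning-scan counter.
    """
    code = CHAR_TO_CODE[c]
    if M.c_codes[pos.run] == code:
        raise ValueError("position already carries the requested character")
    target = _scan_up(M, pos.run, code) if thr.goes_up(pos, code) else _scan_down(M, pos.run, code)
    if target is None:
        # thresholds always point at an existing side when the character occurs
        raise CharacterAbsentError(c)
    if counters is not None:
        counters.reposition_scans += abs(target.run - pos.run)
    return target


def build_reposition_pointers(M: MoveTable) -> np.ndarray:
    """Nearest same-character run indices, up and down, for every row.

    Shape ``(rows, sigma, 2)``; ``[:, :, 0]`` is the nearest run above with
    the character, ``[:, :, 1]`` the nearest below, ``-1`` when none exists.
    For the DNA alphabet this is the constant-mode pointer set (three other
    characters x two directions per row).
    """
    rows = M.n_rows
    sigma = len(ALPHABET)
    ptrs = np.full((rows, sigma, 2), -1, dtype=np.int64)
    last_seen = np.full(sigma, -1, dtype=np.int64)
    for i in range(rows):
        ptrs[i, :, 0] = last_seen
        last_seen[M.c_codes[i]] = i
    next_seen = np.full(sigma, -1, dtype=np.int64)
    for i in range(rows - 1, -1, -1):
        ptrs[i, :, 1] = next_seen
        next_seen[M.c_codes[i]] = i
    return ptrs


def reposition_pointer(
    M: MoveTable,
    pos: BwtPosition,
    c: str,
    ptrs: np.ndarray,
    thr: ThresholdSet,
    counters: Counters | None = None,
) -> BwtPosition:
    """Constant-mode repositioning: one stored-pointer dereference per event."""
    code = CHAR_TO_CODE[c]
    if M.c_codes[pos.run] == code:
        raise ValueError("position already carries the requested character")
    if thr.goes_up(pos, code):
        i = int(ptrs[pos.run, code, 0])
        if i < 0:
            raise CharacterAbsentError(c)
        target = BwtPosition(i, int(M.p[i] + M.l[i] - 1))
    else:
        i = int(ptrs[pos.run, code, 1])
        if i < 0:
            raise CharacterAbsentError(c)
        target = BwtPosition(i, int(M.p[i]))
    if counters is not None:
        counters.reposition_scans += 1
    return target
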