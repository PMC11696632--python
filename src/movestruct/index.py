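"""High-level index object bundling the table, thresholds and pointers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .move_table import BwtPosition, MoveTable, position_at
from .queries import QueryResult, batch_query, compute_pmls, count
from .splitting import SplitConfig, split_runs
from .text_index import (
    IndexText,
    RankOracle,
    build_suffix_array,
    build_text,
    bwt_from_sa,
    lcp_from_sa,
)
from .thresholds import ThresholdSet, build_reposition_pointers, compute_thresholds


@dataclass
class MoveIndex:
    """A queryable move-structure index over a set of reference records.

    Built with :meth:`build`; exposes :meth:`pml`, :meth:`batch_pml` and
    :meth:`count`.  In ``constant`` mode the table is balanced by run
    splitting (parameter ``d``) and carries per-row repositioning pointers, so
    every query step costs a bounded number of row accesses.
    """

    table: MoveTable
    thresholds: ThresholdSet
    repos_ptrs: np.ndarray | None
    record_boundaries: list[tuple[str, int, int]]
    includes_rc: bool

    @classmethod
    def build(
        cls,
        records: list[tuple[str, str]],
        include_rc: bool = True,
        mode: str = "default",
        d: int = 4,
        alphabet_policy: str = "strip",
    ) -> "MoveIndex":
        if mode not in ("default", "constant"):
            raise ValueError(f"unknown mode {mode!r}")
        text = build_text(records, include_rc=include_rc, alphabet_policy=alphabet_policy)
        return cls.from_text(text, mode=mode, d=d)

    @classmethod
    def from_text(cls, text: IndexText, mode: str = "default", d: int = 4) -> "MoveIndex":
        from .move_table import build_move_table, run_length_encode

        sa = build_suffix_array(text)
        bwt = bwt_from_sa(text, sa)
        ranks = RankOracle(bwt.bwt)
        table = build_move_table(run_length_encode(bwt), bwt, ranks)
        if mode == "constant":
            table = split_runs(table, SplitConfig(d=d))
        lcp = lcp_from_sa(text, sa)
        thr = compute_thresholds(table, bwt, sa, lcp)
        ptrs = build_reposition_pointers(table) if mode == "constant" else None
        return cls(
            table=table,
            thresholds=thr,
            repos_ptrs=ptrs,
            record_boundaries=list(text.record_boundaries),
            includes_rc=text.includes_rc,
        )

    # -- queries ---------------------------------------------------------

    def pml(self, read: str, name: str = "", start: BwtPosition | None = None) -> QueryResult:
        start_pos = start if start is not None else position_at(self.table, 0)
        return compute_pmls(
            self.table, self.thresholds, read, start=start_pos, ptrs=self.repos_ptrs, name=name
        )

    def batch_pml(
        self,
        reads: list[tuple[str, str]],
        batch_size: int = 16,
        start: BwtPosition | None = None,
    ) -> list[QueryResult]:
        return batch_query(
            self.table,
            self.thresholds,
            reads,
            batch_size=batch_size,
            ptrs=self.repos_ptrs,
            start=start,
        )

    def count(self, pattern: str) -> int:
        return count(self.table, pattern)

    # -- diagnostics ------------------------------------------------------

    def stats(self) -> dict:
        t = self.table
        return {
            "n": t.n,
            "r": t.r_original,
            "rows": t.n_rows,
            "n_over_r": t.n / t.r_original,
            "mode": t.mode,
            "d": t.d,
            "records": len(self.record_boundaries),
            "includes_rc": self.includes_rc,
        }
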