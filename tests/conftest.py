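from types import SimpleNamespace

import numpy as np
import pytest

from movestruct import (
    IndexText,
    RankOracle,
    build_move_table,
    build_suffix_array,
    build_text,
    bwt_from_sa,
    lcp_from_sa,
    run_length_encode,
)
from movestruct.thresholds import build_reposition_pointers, compute_thresholds

DNA = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[c] for c in rng.integers(0, 4, size=n))


def build_pipeline(text: "IndexText | str") -> SimpleNamespace:
    """All index structures for a text: oracles, move table, thresholds, pointers."""
    if isinstance(text, str):
        body = text.rstrip("$")
        text = build_text([("t", body)], include_rc=False)
    sa = build_suffix_array(text)
    bwt = bwt_from_sa(text, sa)
    ranks = RankOracle(bwt.bwt)
    lcp = lcp_from_sa(text, sa)
    M = build_move_table(run_length_encode(bwt), bwt, ranks)
    thr = compute_thresholds(M, bwt, sa, lcp)
    ptrs = build_reposition_pointers(M)
    return SimpleNamespace(t=text, sa=sa, bwt=bwt, ranks=ranks, lcp=lcp, M=M, thr=thr, ptrs=ptrs)


@pytest.fixture(scope="session")
def random_texts() -> list[SimpleNamespace]:
    """A shared set of seeded random-DNA pipelines for property sweeps."""
    rng = np.random.default_rng(20240601)
    out = []
    for _ in range(12):
        n = int(rng.integers(2, 600))
        out.append(build_pipeline(random_dna(rng, n)))
    return out
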