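"""PML and backward-search count queries, plus the round-robin batch loop."""

import numpy as np
import pytest

from movestruct import (
    BwtPosition,
    MoveIndex,
    backward_extend,
    batch_query,
    compute_pmls,
    compute_pmls_reference,
    count,
    count_oracle,
    init_range,
    matching_statistics_oracle,
)
from movestruct.queries import ConfigurationError
from movestruct.simulate import random_reads, sample_reads, simulate_pangenome
from movestruct.splitting import SplitConfig, split_runs
from movestruct.text_index import build_text
from movestruct.thresholds import build_reposition_pointers, compute_thresholds

from conftest import build_pipeline, random_dna


class TestComputePmls:
    def test_full_match_read(self):
        pipe = build_pipeline("ACG$")
        res = compute_pmls(pipe.M, pipe.thr, "ACG", start=BwtPosition(0, 0))
        assert res.pmls.tolist() == [3, 2, 1]

    def test_absent_characters_yield_zero(self):
        pipe = build_pipeline("ACG$")
        res = compute_pmls(pipe.M, pipe.thr, "NNN", start=BwtPosition(0, 0))
        assert res.pmls.tolist() == [0, 0, 0]
        res = compute_pmls(pipe.M, pipe.thr, "TTT", start=BwtPosition(0, 0))
        assert res.pmls.tolist() == [0, 0, 0]  # T absent from ACG$

    def test_empty_read(self):
        pipe = build_pipeline("ACG$")
        assert compute_pmls(pipe.M, pipe.thr, "").pmls.tolist() == []

    def test_missing_thresholds_is_configuration_error(self):
        pipe = build_pipeline("ACG$")
        with pytest.raises(ConfigurationError):
            compute_pmls(pipe.M, None, "ACG")

    def test_dominated_by_matching_statistics(self, random_texts):
        rng = np.random.default_rng(42)
        for pipe in random_texts[:6]:
            body = pipe.t.text[:-1]
            for _ in range(5):
                L = int(rng.integers(1, 40))
                if len(body) <= L:
                    continue
                st = int(rng.integers(0, len(body) - L))
                read = body[st : st + L]
                pml = compute_pmls(pipe.M, pipe.thr, read).pmls
                ms = matching_statistics_oracle(pipe.t, read)
                assert (pml <= ms).all()

    def test_mode_and_reference_identity(self, random_texts):
        """Default mode, constant mode and the plain-BWT reference agree."""
        rng = np.random.default_rng(7)
        for pipe in random_texts[:6]:
            Ms = split_runs(pipe.M, SplitConfig(d=4))
            thr_s = compute_thresholds(Ms, pipe.bwt, pipe.sa, pipe.lcp)
            ptrs_s = build_reposition_pointers(Ms)
            for _ in range(6):
                read = random_dna(rng, int(rng.integers(1, 40)))
                p_default = compute_pmls(pipe.M, pipe.thr, read).pmls
                p_constant = compute_pmls(Ms, thr_s, read, ptrs=ptrs_s).pmls
                p_reference = compute_pmls_reference(
                    pipe.t, pipe.sa, pipe.bwt.bwt, pipe.lcp, pipe.ranks, read
                )
                assert (p_default == p_constant).all()
                assert (p_default == p_reference).all()


class TestInitRange:
    def test_f_column_block(self):
        pipe = build_pipeline("ACG$")
        rng_ = init_range(pipe.M, "A")
        assert (rng_.top.offset, rng_.bottom.offset) == (1, 1)

    def test_absent_character_empty(self):
        pipe = build_pipeline("AAAA$")
        assert init_range(pipe.M, "C").empty

    def test_width_equals_character_count(self, random_texts):
        for pipe in random_texts[:6]:
            for c in "ACGT":
                rng_ = init_range(pipe.M, c)
                assert rng_.width == pipe.ranks.counts[c]


class TestBackwardExtend:
    def test_homopolymer_extension(self):
        pipe = build_pipeline("AAAA$")
        rng_ = init_range(pipe.M, "A")
        out = backward_extend(pipe.M, rng_, "A")
        assert out.width == 3  # occurrences of "AA"

    def test_extension_by_absent_character(self):
        pipe = build_pipeline("ACG$")
        rng_ = init_range(pipe.M, "A")
        assert backward_extend(pipe.M, rng_, "T").empty

    def test_empty_input_rejected(self):
        pipe = build_pipeline("ACG$")
        with pytest.raises(ValueError):
            backward_extend(pipe.M, backward_extend(pipe.M, init_range(pipe.M, "A"), "T"), "A")

    def test_width_tracks_count_oracle(self, random_texts):
        rng = np.random.default_rng(13)
        for pipe in random_texts[:6]:
            body = pipe.t.text[:-1]
            for _ in range(10):
                L = int(rng.integers(2, 8))
                P = random_dna(rng, L)
                rng_ = init_range(pipe.M, P[-1])
                suffix = P[-1]
                for c in reversed(P[:-1]):
                    if rng_.empty:
                        break
                    rng_ = backward_extend(pipe.M, rng_, c)
                    suffix = c + suffix
                    assert rng_.width == count_oracle(pipe.t, suffix)


class TestCount:
    @pytest.mark.parametrize(
        "body,P,expected",
        [("ACG", "ACG", 1), ("AAAA", "AA", 3), ("ACG", "CA", 0)],
    )
    def test_known_counts(self, body, P, expected):
        pipe = build_pipeline(body + "$")
        assert count(pipe.M, P) == expected

    def test_non_alphabet_pattern_counts_zero(self):
        pipe = build_pipeline("ACG$")
        assert count(pipe.M, "ANG") == 0

    def test_matches_oracle_on_sampled_and_absent_patterns(self, random_texts):
        rng = np.random.default_rng(23)
        for pipe in random_texts[:8]:
            body = pipe.t.text[:-1]
            for _ in range(30):
                L = int(rng.integers(1, 13))
                if rng.random() < 0.7 and len(body) > L:
                    st = int(rng.integers(0, len(body) - L + 1))
                    P = body[st : st + L]
                else:
                    P = random_dna(rng, L)
                assert count(pipe.M, P) == count_oracle(pipe.t, P)


@pytest.fixture(scope="module")
def pangenome_index():
    records = simulate_pangenome(600, 3, 0.005, seed=5)
    text = build_text(records, include_rc=True)
    return build_pipeline(text), text


class TestBatchQuery:
    def test_results_independent_of_batch_size(self, pangenome_index):
        pipe, text = pangenome_index
        reads = sample_reads(text, 40, 60, error_rate=0.05, seed=8)
        reads += random_reads(10, 60, seed=9)
        baseline = batch_query(pipe.M, pipe.thr, reads, batch_size=1)
        for B in (2, 16, 32):
            got = batch_query(pipe.M, pipe.thr, reads, batch_size=B)
            assert [r.name for r in got] == [r.name for r in baseline]
            for a, b in zip(got, baseline):
                assert (a.pmls == b.pmls).all()

    def test_batch_equals_sequential_compute_pmls(self, pangenome_index):
        pipe, text = pangenome_index
        reads = sample_reads(text, 20, 50, error_rate=0.0, seed=10)
        batched = batch_query(pipe.M, pipe.thr, reads, batch_size=16)
        for (name, seq), res in zip(reads, batched):
            single = compute_pmls(pipe.M, pipe.thr, seq, name=name)
            assert res.name == name
            assert (res.pmls == single.pmls).all()
            assert res.counters.as_dict() == single.counters.as_dict()

    def test_invalid_batch_size(self, pangenome_index):
        pipe, _ = pangenome_index
        with pytest.raises(ValueError):
            batch_query(pipe.M, pipe.thr, [], batch_size=0)


class TestMoveIndexFacade:
    def test_error_free_reads_fully_match(self):
        records = simulate_pangenome(500, 2, 0.01, seed=1)
        index = MoveIndex.build(records, include_rc=True)
        text = build_text(records, include_rc=True)
        reads = sample_reads(text, 15, 80, error_rate=0.0, seed=2)
        for name, seq in reads:
            assert index.count(seq) >= 1
            ms = matching_statistics_oracle(text, seq)
            assert ms.tolist() == list(range(len(seq), 0, -1))

    def test_constant_mode_counter_contract(self):
        records = simulate_pangenome(400, 2, 0.01, seed=3)
        index = MoveIndex.build(records, mode="constant", d=2)
        text = build_text(records, include_rc=True)
        reads = sample_reads(text, 10, 60, error_rate=0.1, seed=4)
        for name, seq in reads:
            res = index.pml(seq, name=name)
            # one pointer dereference per case-2 event, ff < 2d per LF step
            assert res.counters.reposition_scans == res.counters.case2_events
            assert res.counters.fast_forwards < 2 * 2 * max(res.counters.lf_steps, 1)
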