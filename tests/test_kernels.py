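"""Kernel correctness against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from seqfarm import (
    ProfileModel,
    ScoringScheme,
    SeqRecord,
    ToolSpec,
    open_tool_io,
    profile_scan,
    random_profile,
    sw_score,
    sw_search,
    tool_run_batch,
)
from seqfarm.errors import ValidationError
from seqfarm.kernels import load_profile, save_profile
from seqfarm.seqio import AA20, ALPHABET

from oracles import profile_best_window, sw_dp, sw_enum

SCHEME = ScoringScheme(2, -1, -2)


def _rand_seq(rng, lo, hi):
    n = int(rng.integers(lo, hi + 1))
    return "".join(AA20[k] for k in rng.integers(0, 20, size=n))


class TestOracleSelfValidation:
    def test_dp_oracle_matches_exhaustive_enumeration(self, rng):
        """The DP oracle itself agrees with brute-force alignment
        enumeration on all-pairs of short random strings."""
        for _ in range(30):
            a = _rand_seq(rng, 0, 6)
            b = _rand_seq(rng, 0, 6)
            m = int(rng.integers(1, 4))
            x = -int(rng.integers(0, 3))
            g = -int(rng.integers(1, 4))
            assert sw_dp(a, b, m, x, g) == sw_enum(a, b, m, x, g)


class TestSwScore:
    def test_perfect_match(self):
        assert sw_score("AAAA", "AAAA", SCHEME).score == 8

    def test_empty_sequence_scores_zero(self):
        assert sw_score("", "ACDE", SCHEME).score == 0
        assert sw_score("ACDE", "", SCHEME).score == 0

    def test_known_gap_case(self):
        assert sw_score("ACGT", "AGT", SCHEME).score == 4

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValidationError):
            sw_score("AC1E", "ACDE", SCHEME)

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(100):
            a = _rand_seq(rng, 1, 40)
            b = _rand_seq(rng, 1, 40)
            scheme = ScoringScheme(
                int(rng.integers(1, 4)),
                -int(rng.integers(0, 3)),
                -int(rng.integers(1, 4)),
            )
            assert (
                sw_score(a, b, scheme).score
                == sw_dp(a, b, scheme.match, scheme.mismatch, scheme.gap)
            )

    def test_matches_biotite_on_random_pairs(self, rng):
        """Cross-check against an independent C implementation."""
        import biotite.sequence as bseq
        import biotite.sequence.align as balign

        alph = bseq.ProteinSequence.alphabet
        n = len(alph)
        mat = np.full((n, n), SCHEME.mismatch, dtype=np.int32)
        np.fill_diagonal(mat, SCHEME.match)
        matrix = balign.SubstitutionMatrix(alph, alph, mat)
        for _ in range(20):
            a = _rand_seq(rng, 1, 30)
            b = _rand_seq(rng, 1, 30)
            alns = balign.align_optimal(
                bseq.ProteinSequence(a),
                bseq.ProteinSequence(b),
                matrix,
                gap_penalty=SCHEME.gap,
                local=True,
            )
            assert sw_score(a, b, SCHEME).score == max(0, alns[0].score)

    @given(
        a=st.text(alphabet=AA20, max_size=15),
        b=st.text(alphabet=AA20, max_size=15),
    )
    def test_symmetry_and_nonnegativity(self, a, b):
        fwd = sw_score(a, b, SCHEME)
        assert fwd.score == sw_score(b, a, SCHEME).score
        assert fwd.score >= 0

    @given(a=st.text(alphabet=AA20, min_size=1, max_size=20))
    def test_self_alignment_is_full_match(self, a):
        aln = sw_score(a, a, SCHEME)
        assert aln.score == len(a) * SCHEME.match
        assert aln.query_span == aln.subject_span == (0, len(a))

    def test_spans_recover_the_score(self, rng):
        """The best local score of the spanned substrings equals the score."""
        for _ in range(25):
            a = _rand_seq(rng, 5, 30)
            b = _rand_seq(rng, 5, 30)
            aln = sw_score(a, b, SCHEME)
            (qs, qe), (ss, se) = aln.query_span, aln.subject_span
            assert 0 <= qs <= qe <= len(a) and 0 <= ss <= se <= len(b)
            assert sw_score(a[qs:qe], b[ss:se], SCHEME).score == aln.score

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValidationError):
            ScoringScheme(0, -1, -2)
        with pytest.raises(ValidationError):
            ScoringScheme(2, 1, -2)
        with pytest.raises(ValidationError):
            ScoringScheme(2, -1, 0)


class TestSwSearch:
    def test_identical_record_ranks_first(self, small_db, small_image):
        query = SeqRecord("q", small_db[3].residues)
        hits = sw_search(query, small_image, SCHEME, top_k=3)
        assert hits[0].subject_id == small_db[3].id
        assert hits[0].score == query.length * SCHEME.match

    def test_min_score_above_all_yields_empty(self, small_image):
        query = SeqRecord("q", "A" * 10)
        assert sw_search(query, small_image, SCHEME, min_score=10**6) == []

    def test_ranking_matches_brute_force(self, rng, small_db, small_image):
        for _ in range(5):
            query = SeqRecord("q", _rand_seq(rng, 10, 50))
            expected = sorted(
                (
                    (-sw_dp(query.residues, r.residues, 2, -1, -2), r.id)
                    for r in small_db
                ),
            )
            hits = sw_search(query, small_image, SCHEME, top_k=10, min_score=0)
            assert [(-h.score, h.subject_id) for h in hits] == expected


class TestProfileScan:
    def test_argmax_residues_hit_sum_of_row_maxima(self):
        model = random_profile("m1", 8, seed=3)
        motif = "".join(ALPHABET[i] for i in model.weights.argmax(axis=1))
        query = SeqRecord("q", "AC" + motif + "DD")
        hit = profile_scan(query, model, threshold=0.0)
        assert hit is not None
        assert hit.score == pytest.approx(model.weights.max(axis=1).sum())
        assert hit.query_span == (2, 10)

    def test_query_shorter_than_model_is_no_hit(self):
        model = random_profile("m1", 10, seed=1)
        assert profile_scan(SeqRecord("q", "ACDE"), model, -1e9) is None

    def test_threshold_filters(self):
        model = random_profile("m1", 5, seed=2)
        q = SeqRecord("q", "ACDEFGHIKL")
        assert profile_scan(q, model, threshold=1e9) is None

    def test_leftmost_offset_wins_ties(self):
        weights = np.zeros((2, len(ALPHABET)))
        model = ProfileModel("flat", ALPHABET, weights)
        hit = profile_scan(SeqRecord("q", "ACDEF"), model, threshold=-1.0)
        assert hit.query_span == (0, 2)

    def test_matches_window_brute_force(self, rng):
        for _ in range(50):
            L = int(rng.integers(2, 9))
            model = random_profile("m", L, seed=int(rng.integers(0, 2**31)))
            q = _rand_seq(rng, L, 40)
            expected = profile_best_window(q, ALPHABET, model.weights.tolist())
            hit = profile_scan(SeqRecord("q", q), model, threshold=-1e18)
            assert hit is not None
            assert hit.query_span[0] == expected[0]
            assert hit.score == pytest.approx(expected[1])

    def test_profile_file_round_trip(self, tmp_path):
        model = random_profile("pfam_stand_in", 6, seed=9)
        save_profile(model, tmp_path / "model.psm")
        loaded = load_profile(tmp_path / "model.psm")
        assert loaded.name == model.name and loaded.alphabet == model.alphabet
        np.testing.assert_array_equal(loaded.weights, model.weights)


class _CollectingStore:
    """Minimal store double for exercising ToolIO-driven kernels."""

    def __init__(self):
        self.records = []
        self.failures = []

    def append_record(self, worker_id, query_id, payload):
        self.records.append((query_id, payload))

    def append_failure(self, query_id, reason):
        self.failures.append((query_id, reason))


def _run_tool(tool, queries, image):
    store = _CollectingStore()
    session = open_tool_io(image, queries, store, worker_id=1, batch_id=0)
    tool_run_batch(tool, session)
    session.close()
    return store


class TestToolRunBatch:
    def test_unknown_kernel_rejected_before_execution(self, small_image):
        with pytest.raises(ValidationError, match="unknown kernel"):
            _run_tool(ToolSpec("nonesuch"), [SeqRecord("q", "ACDE")], small_image)

    def test_aligner_writes_one_record_per_query(self, rng, small_image):
        queries = [SeqRecord(f"q{i}", _rand_seq(rng, 10, 30)) for i in range(4)]
        store = _run_tool(ToolSpec("aligner"), queries, small_image)
        assert [q for q, _ in store.records] == [q.id for q in queries]
        assert all(p.count("\t") == 7 for _, p in store.records)

    def test_profiler_short_queries_all_no_hit(self, small_image):
        model = random_profile("m", 30, seed=5)
        queries = [SeqRecord(f"q{i}", "ACDEF") for i in range(4)]
        store = _run_tool(
            ToolSpec("profiler", {"model": model, "threshold": 0.0}),
            queries,
            small_image,
        )
        assert len(store.records) == 4
        assert all(p.split("\t")[7] == "no-hit" for _, p in store.records)

    def test_record_set_independent_of_batch_partitioning(self, rng, small_image):
        queries = [SeqRecord(f"q{i}", _rand_seq(rng, 10, 30)) for i in range(6)]
        whole = _run_tool(ToolSpec("aligner"), queries, small_image)
        split = _CollectingStore()
        for part in (queries[:2], queries[2:5], queries[5:]):
            session = open_tool_io(small_image, part, split, worker_id=1)
            tool_run_batch(ToolSpec("aligner"), session)
            session.close()
        assert sorted(whole.records) == sorted(split.records)

    def test_kernel_determinism_byte_identical(self, rng, small_image):
        queries = [SeqRecord(f"q{i}", _rand_seq(rng, 10, 30)) for i in range(3)]
        a = _run_tool(ToolSpec("aligner"), queries, small_image)
        b = _run_tool(ToolSpec("aligner"), queries, small_image)
        assert a.records == b.records
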