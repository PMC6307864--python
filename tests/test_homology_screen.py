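"""Local aligner, E-value statistics and the reciprocal screen decision logic."""

import math

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from glur.errors import ConfigurationError
from glur.homology_screen import (
    InHouseBackend,
    TabularBackend,
    karlin_evalue,
    reciprocal_screen,
    smith_waterman,
)
from glur.io_formats import SequenceRecord
from glur.synthetic_data import make_screen_benchmark

from oracles import all_words, blosum62, brute_local


class TestSmithWaterman:
    def test_identity_scores_diagonal_sum(self):
        seq = "SYTANLAAF"
        score, (a, b) = smith_waterman(seq, seq)
        assert score == sum(blosum62(c, c) for c in seq)
        assert a == b == seq

    def test_all_negative_pairs_score_zero_with_empty_alignment(self):
        score, (a, b) = smith_waterman("PPPP", "WWWW")  # BLOSUM62 P/W = -4
        assert score == 0.0
        assert a == b == ""

    def test_matches_exhaustive_local_enumeration(self):
        words = all_words("ARN", 3)
        for a in words:
            for b in words:
                assert smith_waterman(a, b)[0] == brute_local(a, b), (a, b)

    def test_matches_enumeration_on_sampled_longer_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            a = "".join(rng.choice(list("ARN"), size=int(rng.integers(4, 6))))
            b = "".join(rng.choice(list("ARN"), size=int(rng.integers(4, 6))))
            assert smith_waterman(a, b)[0] == brute_local(a, b), (a, b)

    def test_matches_independent_library_aligner(self):
        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.mode = "local"
        aligner.open_gap_score = -12.0
        aligner.extend_gap_score = -1.0
        rng = np.random.default_rng(4)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(30):
            a = "".join(rng.choice(letters, size=int(rng.integers(10, 60))))
            b = "".join(rng.choice(letters, size=int(rng.integers(10, 60))))
            assert smith_waterman(a, b)[0] == pytest.approx(aligner.score(a, b))


class TestKarlinEvalue:
    def test_zero_score_gives_kmn(self):
        assert karlin_evalue(0, 100, 1000) == pytest.approx(0.041 * 100 * 1000)

    def test_large_score_vanishes(self):
        assert karlin_evalue(500, 100, 1000) < 1e-40

    def test_doubling_database_doubles_evalue(self):
        e1 = karlin_evalue(50, 100, 1000)
        e2 = karlin_evalue(50, 100, 2000)
        assert e2 == pytest.approx(2 * e1)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ConfigurationError):
            karlin_evalue(50, 100, 1000, lam=0.0)
        with pytest.raises(ConfigurationError):
            karlin_evalue(50, 0, 1000)


def _records(pairs):
    return [SequenceRecord(i, s, group_label=g) for i, s, g in pairs]


class TestReciprocalScreen:
    def test_identical_candidate_accepted_tier1(self, iglur_scheme):
        seq = iglur_scheme.sequence
        queries = _records([("glur_q", seq, "GluR")])
        cand = _records([("cand", seq, "")])
        db = _records([("glur_q", seq, "GluR"), ("junk", "WPWPWP" * 40, "Other")])
        (dec,) = reciprocal_screen(cand, queries, db)
        assert dec.accepted and dec.tier == 1
        assert dec.reciprocal_top_hit == "glur_q"

    def test_forward_gate_blocks_reciprocal_search(self, tmp_path):
        """A forward E-value at/above threshold is rejected without re-search."""
        hits = tmp_path / "hits.tsv"
        hits.write_text("cand\tglur_q\t90\t100\t5\t0\t1\t100\t1\t100\t0.06\t55\n")
        backend = TabularBackend(hits, {"glur_q": "GluR"})
        cand = _records([("cand", "ACDEF", "")])
        queries = _records([("glur_q", "ACDEF", "GluR")])
        (dec,) = reciprocal_screen(cand, queries, queries, backend=backend,
                                   reciprocal_backend=backend)
        assert not dec.accepted
        assert dec.forward_evalue == pytest.approx(0.06)
        assert dec.reciprocal_top_hit == ""  # reciprocal search never ran

    def test_reciprocal_top_nonglur_rejects(self, tmp_path):
        fwd = tmp_path / "f.tsv"
        fwd.write_text(
            "cand\tglur_q\t90\t100\t5\t0\t1\t100\t1\t100\t1e-30\t120\n"
            "cand\tother_p\t95\t100\t2\t0\t1\t100\t1\t100\t1e-40\t150\n"
        )
        backend = TabularBackend(fwd, {"glur_q": "GluR", "other_p": "Other"})
        cand = _records([("cand", "ACDEF", "")])
        queries = _records([("glur_q", "ACDEF", "GluR")])
        db = _records([("glur_q", "ACDEF", "GluR"), ("other_p", "ACDEF", "Other")])
        (dec,) = reciprocal_screen(cand, queries, db, backend=backend,
                                   reciprocal_backend=backend)
        assert not dec.accepted
        assert dec.reciprocal_top_hit == "other_p"

    def test_empty_reciprocal_db_is_configuration_error(self):
        cand = _records([("c", "ACDEF", "")])
        with pytest.raises(ConfigurationError):
            reciprocal_screen(cand, cand, [])

    def test_decisions_invariant_under_candidate_permutation(self):
        bench = make_screen_benchmark(seed=5, n_planted=3, n_decoys=3,
                                      n_queries=2, n_db_others=6)
        fwd = reciprocal_screen(bench["candidates"], bench["queries"],
                                bench["reciprocal_db"])
        rev = reciprocal_screen(bench["candidates"][::-1], bench["queries"],
                                bench["reciprocal_db"])
        assert {d.candidate_id: d.accepted for d in fwd} == \
               {d.candidate_id: d.accepted for d in rev}

    def test_raising_threshold_never_shrinks_accepted_set(self):
        bench = make_screen_benchmark(seed=6, n_planted=3, n_decoys=3,
                                      n_queries=2, n_db_others=6)
        args = (bench["candidates"], bench["queries"], bench["reciprocal_db"])
        accepted = {}
        for thr in (1e-6, 0.05, 10.0):
            accepted[thr] = {d.candidate_id for d in reciprocal_screen(*args, e_threshold=thr)
                             if d.accepted}
        assert accepted[1e-6] <= accepted[0.05] <= accepted[10.0]

    def test_inhouse_and_tabular_backends_agree_on_identical_hits(self, tmp_path):
        bench = make_screen_benchmark(seed=8, n_planted=2, n_decoys=2,
                                      n_queries=2, n_db_others=4)
        inhouse = InHouseBackend()
        labels = {r.id: r.group_label for r in bench["reciprocal_db"] + bench["queries"]}
        tables = {}
        for name, db in (("fwd", bench["queries"]), ("rec", bench["reciprocal_db"])):
            lines = []
            for cand in bench["candidates"]:
                for h in inhouse.search(cand, db):
                    lines.append(
                        f"{h.query_id}\t{h.subject_id}\t0\t0\t0\t0\t0\t0\t0\t0\t"
                        f"{h.evalue!r}\t{h.bit_score!r}\n"
                    )
            path = tmp_path / f"{name}.tsv"
            path.write_text("".join(lines))
            tables[name] = TabularBackend(path, labels)
        d_inhouse = reciprocal_screen(bench["candidates"], bench["queries"],
                                      bench["reciprocal_db"])
        d_tab = reciprocal_screen(bench["candidates"], bench["queries"],
                                  bench["reciprocal_db"], backend=tables["fwd"],
                                  reciprocal_backend=tables["rec"])
        assert [(d.candidate_id, d.accepted, d.reciprocal_top_hit) for d in d_inhouse] == \
               [(d.candidate_id, d.accepted, d.reciprocal_top_hit) for d in d_tab]

    def test_decoy_benchmark_scaled(self):
        """Planted homologs pass, composition-shuffled decoys do not."""
        bench = make_screen_benchmark(seed=0, n_planted=6, n_decoys=6,
                                      n_queries=2, n_db_others=15)
        decisions = reciprocal_screen(bench["candidates"], bench["queries"],
                                      bench["reciprocal_db"])
        accepted = {d.candidate_id for d in decisions if d.accepted}
        assert bench["planted_ids"] <= accepted
        assert accepted & bench["decoy_ids"] == set()
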