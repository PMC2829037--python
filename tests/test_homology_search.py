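"""Six-frame translation, local alignment, E-values and database search."""

import math

import numpy as np
import pytest

from _oracles import smith_waterman_oracle, translate_oracle
from linspec.annotation_io import SequenceRecord, reverse_complement
from linspec.homology_search import (
    ScoringScheme,
    SequenceDatabase,
    evalue_from_score,
    find_first_hit,
    local_align,
    read_tabular_hits,
    search_protein_vs_nucleotide,
    search_protein_vs_protein,
    translate_six_frames,
    write_tabular_hits,
)

SCHEME = ScoringScheme()
B62 = SCHEME.matrix


class TestTranslation:
    def test_forward_frame(self):
        frames = translate_six_frames(SequenceRecord("x", "ATGGCT"))
        assert frames[0].seq == "MA"

    def test_reverse_frame_symmetry(self):
        frames = translate_six_frames(SequenceRecord("x", "AGCCAT"))
        assert frames[3].seq == "MA"  # frame -1 of revcomp("ATGGCT")

    def test_short_sequence_empty(self):
        frames = translate_six_frames(SequenceRecord("x", "AT"))
        assert all(f.seq == "" for f in frames)

    def test_n_codon_is_x_and_stop_is_star(self):
        frames = translate_six_frames(SequenceRecord("x", "ANTTAA"))
        assert frames[0].seq == "X*"

    def test_random_300mer_matches_codon_walk(self):
        rng = np.random.default_rng(11)
        nt = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        frames = translate_six_frames(SequenceRecord("x", nt))
        rc = reverse_complement(nt)
        for offset in range(3):
            assert frames[offset].seq == translate_oracle(nt[offset:])
            assert frames[3 + offset].seq == translate_oracle(rc[offset:])


class TestLocalAlign:
    def test_self_alignment_scores_diagonal_sum(self):
        score, ident, alen = local_align("MKV", "MKV", SCHEME)
        expected = B62["M", "M"] + B62["K", "K"] + B62["V", "V"]
        assert score == expected and ident == 1.0 and alen == 3

    def test_all_mismatch_scores_zero(self):
        score, _, alen = local_align("AAAA", "CCCC", SCHEME)
        # BLOSUM62 A-vs-C is negative, so no positive local alignment
        assert score == 0.0 and alen == 0

    def test_empty_sequence(self):
        assert local_align("", "MKV", SCHEME) == (0.0, 0.0, 0)

    def test_exhaustive_enumeration_small_alphabet(self):
        """DP score equals brute-force path enumeration on short strings."""
        import itertools

        alphabet = "AC"
        strings = [
            "".join(t)
            for n in (1, 2, 3)
            for t in itertools.product(alphabet, repeat=n)
        ]
        for q in strings:
            for s in strings:
                expected = smith_waterman_oracle(
                    q, s, B62, SCHEME.gap_open, SCHEME.gap_extend
                )
                assert local_align(q, s, SCHEME)[0] == expected

    def test_enumeration_random_len5_pairs(self):
        rng = np.random.default_rng(3)
        alphabet = np.array(list("ACDE"))
        for _ in range(60):
            q = "".join(alphabet[rng.integers(0, 4, rng.integers(1, 6))])
            s = "".join(alphabet[rng.integers(0, 4, rng.integers(1, 6))])
            expected = smith_waterman_oracle(
                q, s, B62, SCHEME.gap_open, SCHEME.gap_extend
            )
            assert local_align(q, s, SCHEME)[0] == expected


class TestEvalue:
    def test_zero_score_gives_kmn(self):
        scheme = ScoringScheme(K=0.041)
        assert evalue_from_score(0, 100, 100, scheme) == pytest.approx(410.0)

    def test_linear_in_database_length(self):
        e1 = evalue_from_score(50, 100, 1000, SCHEME)
        e2 = evalue_from_score(50, 100, 2000, SCHEME)
        assert e2 == pytest.approx(2 * e1)

    def test_unit_evalue_at_closed_form_score(self):
        m = n = 500
        s = math.log(SCHEME.K * m * n) / SCHEME.lam
        assert evalue_from_score(s, m, n, SCHEME) == pytest.approx(1.0)

    def test_monotone_decreasing_in_score(self):
        es = [evalue_from_score(s, 100, 1000, SCHEME) for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))


def _random_protein(rng, n):
    return "M" + "".join(np.array(list("ACDEFGHIKLMNPQRSTVWY"))[rng.integers(0, 20, n - 1)])


class TestSearch:
    def test_self_hit_in_nucleotide_db(self):
        rng = np.random.default_rng(5)
        from linspec.synthetic_data import _back_translate

        protein = _random_protein(rng, 100)
        nt = _back_translate(rng, protein)
        db = SequenceDatabase("d", [SequenceRecord("s1", nt)], "outside_clade_genomic")
        query = SequenceRecord("q", protein)
        hits = search_protein_vs_nucleotide(query, db, SCHEME, 1e-5)
        assert hits and hits[0].subject_id == "s1"
        assert hits[0].identity_fraction == 1.0
        assert hits[0].evalue < 1e-10

    def test_random_query_vs_unrelated_db_usually_empty(self):
        empties = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            query = SequenceRecord("q", _random_protein(rng, 120))
            nt = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
            db = SequenceDatabase("d", [SequenceRecord("s", nt)], "outside_clade_genomic")
            if not search_protein_vs_nucleotide(query, db, SCHEME, 1e-5):
                empties += 1
        assert empties >= 39

    def test_planted_80pct_ortholog_recovered(self):
        rng = np.random.default_rng(9)
        protein = _random_protein(rng, 150)
        aa = list(protein)
        for i in rng.choice(len(aa), size=30, replace=False):
            aa[i] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
        from linspec.synthetic_data import _back_translate

        nt = _back_translate(rng, "".join(aa))
        db = SequenceDatabase("d", [SequenceRecord("orth", nt)], "outside_clade_transcript")
        hits = search_protein_vs_nucleotide(SequenceRecord("q", protein), db, SCHEME, 1e-5)
        assert hits and hits[0].subject_id == "orth"

    def test_protein_search_agrees_with_local_align(self):
        rng = np.random.default_rng(4)
        query = SequenceRecord("q", _random_protein(rng, 100))
        records = [SequenceRecord(f"s{i}", _random_protein(rng, 100)) for i in range(5)]
        records.append(SequenceRecord("copy", query.seq))
        db = SequenceDatabase("d", records, "knowledgebase")
        hits = search_protein_vs_protein(query, db, SCHEME, math.inf)
        assert hits[0].subject_id == "copy"
        for h in hits:
            rec = next(r for r in records if r.id == h.subject_id)
            assert h.score == local_align(query, rec, SCHEME)[0]

    def test_hit_order_evalue_matches_score_order(self):
        rng = np.random.default_rng(8)
        query = SequenceRecord("q", _random_protein(rng, 80))
        records = [SequenceRecord(f"s{i}", _random_protein(rng, 80)) for i in range(6)]
        db = SequenceDatabase("d", records, "knowledgebase")
        hits = search_protein_vs_protein(query, db, SCHEME, math.inf)
        scores = [h.score for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_record_order_invariance(self):
        rng = np.random.default_rng(12)
        query = SequenceRecord("q", _random_protein(rng, 90))
        records = [SequenceRecord(f"s{i}", _random_protein(rng, 90)) for i in range(6)]
        db1 = SequenceDatabase("d", records, "knowledgebase")
        db2 = SequenceDatabase("d", records[::-1], "knowledgebase")
        h1 = search_protein_vs_protein(query, db1, SCHEME, math.inf)
        h2 = search_protein_vs_protein(query, db2, SCHEME, math.inf)
        assert {(h.subject_id, h.score) for h in h1} == {
            (h.subject_id, h.score) for h in h2
        }

    def test_zero_cutoff_returns_nothing(self):
        query = SequenceRecord("q", "MKVLA")
        db = SequenceDatabase("d", [SequenceRecord("s", "MKVLA")], "knowledgebase")
        assert search_protein_vs_protein(query, db, SCHEME, 0.0) == []

    def test_find_first_hit_consistent_with_search(self):
        rng = np.random.default_rng(21)
        protein = _random_protein(rng, 120)
        from linspec.synthetic_data import _back_translate

        nt = _back_translate(rng, protein)
        db = SequenceDatabase(
            "d",
            [SequenceRecord("decoy", "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])),
             SequenceRecord("real", nt)],
            "clade_transcript",
        )
        query = SequenceRecord("q", protein)
        first = find_first_hit(query, db, SCHEME, 1e-5)
        full = search_protein_vs_nucleotide(query, db, SCHEME, 1e-5)
        assert first is not None and full
        assert first.subject_id == full[0].subject_id == "real"


class TestTabularInterchange:
    def test_roundtrip(self, tmp_path):
        hits = [
            __import__("linspec.homology_search", fromlist=["SearchHit"]).SearchHit(
                "q1", "s1", 55.0, 1e-8, 0.82, 120, 2
            )
        ]
        path = tmp_path / "hits.tsv"
        write_tabular_hits(hits, path)
        back = read_tabular_hits(path)
        assert back[0].query_id == "q1" and back[0].subject_id == "s1"
        assert back[0].evalue == pytest.approx(1e-8)
        assert back[0].identity_fraction == pytest.approx(0.82)
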