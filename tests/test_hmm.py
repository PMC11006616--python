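"""Profile-HMM construction, HMMER3 serialization and Viterbi search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryoident import alphabets
from cryoident.hmm import (HmmFormatError, TransitionRow, build_profile,
                           parse_hmmer3, search_database,
                           transitions_from_confidence, viterbi_search,
                           write_hmmer3, _batch_scores, _encode,
                           _score_tables)
from cryoident.model import ResiduePrediction


def one_hot_preds(sequence, polymer="amino", confidence=0.8):
    letters = alphabets.letters(polymer)
    out = []
    for ch in sequence:
        p = np.zeros(len(letters))
        p[letters.index(ch)] = 1.0
        out.append(ResiduePrediction(np.zeros(3), np.eye(3), p, confidence,
                                     polymer_class=polymer))
    return out


def noisy_preds(sequence, sharpness=0.7, seed=0, polymer="amino"):
    letters = alphabets.letters(polymer)
    rng = np.random.default_rng(seed)
    out = []
    for ch in sequence:
        K = len(letters)
        p = np.full(K, (1 - sharpness) / (K - 1))
        p[letters.index(ch)] = sharpness
        p = p + rng.uniform(0, 0.01, K)
        p /= p.sum()
        out.append(ResiduePrediction(
            np.zeros(3), np.eye(3), p, float(rng.uniform(0.3, 1.0)),
            polymer_class=polymer))
    return out


class TestTransitions:
    def test_printed_constant_example(self):
        t = transitions_from_confidence(0.9, 0.5)
        assert t.p_mm == 0.5
        assert t.p_mi == t.p_md == 0.25
        assert t.p_dm == t.p_im == 0.5
        assert t.p_dd == t.p_ii == 0.5
        assert t.p_id == t.p_di == 0.0

    def test_d_zero_limit(self):
        t = transitions_from_confidence(0.3, 0.0)
        assert t.p_mm == 0.5  # max(c, 0.5)
        assert t.p_dm == 1.0 and t.p_dd == 0.0
        t2 = transitions_from_confidence(0.8, 0.0)
        assert t2.p_mm == 0.8

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transitions_from_confidence(1.2)
        with pytest.raises(ValueError):
            transitions_from_confidence(0.5, d=1.0)

    @settings(max_examples=500, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 0.999))
    def test_rows_normalized_for_fuzzed_inputs(self, c, d):
        t = transitions_from_confidence(c, d)
        assert t.p_mm + t.p_mi + t.p_md == pytest.approx(1.0, abs=1e-9)
        assert t.p_im + t.p_ii + t.p_id == pytest.approx(1.0, abs=1e-9)
        assert t.p_dm + t.p_dd + t.p_di == pytest.approx(1.0, abs=1e-9)

    def test_invalid_row_rejected(self):
        with pytest.raises(ValueError):
            TransitionRow(0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5)


class TestBuildProfile:
    def test_one_hot_consensus_spells_sequence(self):
        prof = build_profile(one_hot_preds("ACDEF"))
        assert prof.consensus() == "ACDEF"
        assert prof.length == 5

    def test_uniform_probs_equal_background(self):
        K = 20
        preds = [ResiduePrediction(np.zeros(3), np.eye(3),
                                   np.full(K, 1 / K), 0.5)
                 for _ in range(4)]
        prof = build_profile(preds)
        np.testing.assert_allclose(prof.match_emissions,
                                   np.tile(prof.background, (4, 1)))

    def test_length_equals_residue_count(self, rng):
        for n in (1, 3, 17):
            seq = "".join(rng.choice(list(alphabets.AMINO_LETTERS), n))
            assert build_profile(noisy_preds(seq)).length == n

    def test_mixed_polymer_classes_rejected(self):
        preds = one_hot_preds("AC") + one_hot_preds("AC", "nucleotide")
        with pytest.raises(ValueError, match="polymer"):
            build_profile(preds)

    def test_transition_rows_normalized_for_random_profiles(self, rng):
        seq = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 30))
        prof = build_profile(noisy_preds(seq, seed=5))
        for t in prof.transitions:
            assert t.p_mm + t.p_mi + t.p_md == pytest.approx(1, abs=1e-9)


class TestHmmer3IO:
    def test_round_trip_recovers_probabilities(self, rng, tmp_path):
        seq = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 25))
        prof = build_profile(noisy_preds(seq, seed=2), name="rt")
        write_hmmer3(prof, tmp_path / "p.hmm")
        back = parse_hmmer3(tmp_path / "p.hmm")
        assert back.name == "rt"
        assert np.abs(back.match_emissions -
                      prof.match_emissions).max() < 1e-4
        for a, b in zip(back.transitions, prof.transitions):
            assert np.abs(a.as_array() - b.as_array()).max() < 1e-4

    def test_leng_field(self, tmp_path):
        prof = build_profile(one_hot_preds("ACDEFGH"))
        write_hmmer3(prof, tmp_path / "p.hmm")
        text = (tmp_path / "p.hmm").read_text()
        assert "LENG  7" in text.splitlines()[2]

    def test_zero_probability_serialized_as_star(self, tmp_path):
        prof = build_profile(one_hot_preds("AC"))
        write_hmmer3(prof, tmp_path / "p.hmm")
        assert "*" in (tmp_path / "p.hmm").read_text()
        back = parse_hmmer3(tmp_path / "p.hmm")
        # one-hot emission zeros survive the round trip exactly
        assert back.match_emissions[0, 1] == 0.0

    def test_nucleotide_alphabet_round_trip(self, tmp_path):
        prof = build_profile(one_hot_preds("ACGU", "nucleotide"))
        write_hmmer3(prof, tmp_path / "p.hmm")
        back = parse_hmmer3(tmp_path / "p.hmm")
        assert back.alphabet == alphabets.NUCLEOTIDE_LETTERS
        assert back.consensus() == "ACGU"

    def test_malformed_file_error_names_line(self, tmp_path):
        path = tmp_path / "bad.hmm"
        path.write_text("HMMER3/f [x]\nNAME  a\nLENG  zzz\n")
        with pytest.raises(HmmFormatError, match=r":3:"):
            parse_hmmer3(path)

    def test_non_hmmer_file_rejected(self, tmp_path):
        path = tmp_path / "bad.hmm"
        path.write_text("not an hmm\n")
        with pytest.raises(HmmFormatError, match=r":1:"):
            parse_hmmer3(path)

    def test_pyhmmer_accepts_written_profile(self, rng, tmp_path):
        """Independent cross-validation: the HMMER3 suite itself parses the
        written file and reproduces name, length and alphabet."""
        pyhmmer = pytest.importorskip("pyhmmer")
        seq = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 40))
        prof = build_profile(noisy_preds(seq, seed=3), name="xval")
        write_hmmer3(prof, tmp_path / "p.hmm")
        with pyhmmer.plan7.HMMFile(str(tmp_path / "p.hmm")) as fh:
            hmm = next(iter(fh))
        assert hmm.name in ("xval", b"xval")
        assert hmm.M == 40
        mat = np.asarray(hmm.match_emissions)[1:]  # row 0 is node 0
        assert np.abs(mat - prof.match_emissions).max() < 1e-4

    def test_external_hmmer_search_finds_planted_sequence(self, rng,
                                                          tmp_path):
        """A written profile drives a real hmmsearch run (via pyhmmer) and
        ranks the true sequence above an unrelated one."""
        pyhmmer = pytest.importorskip("pyhmmer")
        easel = pyhmmer.easel
        seq = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 60))
        junk = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 60))
        prof = build_profile(noisy_preds(seq, seed=4), name="xs")
        write_hmmer3(prof, tmp_path / "p.hmm")
        with pyhmmer.plan7.HMMFile(str(tmp_path / "p.hmm")) as fh:
            hmm = next(iter(fh))
        targets = easel.DigitalSequenceBlock(hmm.alphabet, [
            easel.TextSequence(name=b"true",
                               sequence=seq).digitize(hmm.alphabet),
            easel.TextSequence(name=b"junk",
                               sequence=junk).digitize(hmm.alphabet),
        ])
        pipeline = pyhmmer.plan7.Pipeline(hmm.alphabet, bias_filter=False,
                                          F1=1.0, F2=1.0, F3=1.0)
        def _s(name):
            return name.decode() if isinstance(name, bytes) else name

        hits = {_s(h.name): h.score
                for h in pipeline.search_hmm(hmm, targets)}
        assert "true" in hits
        assert hits["true"] > 50
        assert hits["true"] > hits.get("junk", -1e9)


def enumerate_paths_score(profile, sequence):
    """Exhaustive oracle: best score over every legal state path, using the
    same scoring tables as the engine but none of its DP."""
    em, ins, tr = _score_tables(profile)
    x = _encode(sequence, profile.alphabet)
    L, n = profile.length, len(x)
    best = [-np.inf]

    def rec(j, k, state, score):
        if state == 0:
            best[0] = max(best[0], score)
            if j < n and k + 1 < L:
                rec(j + 1, k + 1, 0, score + tr[k, 0] + em[k + 1, x[j]])
            if j < n:
                rec(j + 1, k, 1, score + tr[k, 1] + ins[k, x[j]])
            if k + 1 < L:
                rec(j, k + 1, 2, score + tr[k, 2])
        elif state == 1:
            if j < n and k + 1 < L:
                rec(j + 1, k + 1, 0, score + tr[k, 3] + em[k + 1, x[j]])
            if j < n:
                rec(j + 1, k, 1, score + tr[k, 4] + ins[k, x[j]])
        else:
            if j < n and k + 1 < L:
                rec(j + 1, k + 1, 0, score + tr[k, 5] + em[k + 1, x[j]])
            if k + 1 < L:
                rec(j, k + 1, 2, score + tr[k, 6])

    entry = -np.log2(L)
    for j0 in range(n):
        for k in range(L):
            rec(j0 + 1, k, 0, entry + em[k, x[j0]])
    return best[0]


class TestViterbi:
    def test_self_match_covers_all_positions(self):
        prof = build_profile(one_hot_preds("ACDEFGHIK", confidence=0.9))
        hit = viterbi_search(prof, "ACDEFGHIK")
        assert hit.coverage == 1.0
        assert all(st == "M" for *_, st in hit.alignment)
        assert len(hit.alignment) == 9
        assert hit.bit_score > 0

    def test_uniform_profile_scores_non_positive(self):
        K = 20
        preds = [ResiduePrediction(np.zeros(3), np.eye(3),
                                   np.full(K, 1 / K), 0.9)
                 for _ in range(5)]
        prof = build_profile(preds)
        hit = viterbi_search(prof, "ACDEF")
        assert hit.bit_score <= 0

    def test_empty_sequence_is_no_hit(self):
        prof = build_profile(one_hot_preds("ACD"))
        hit = viterbi_search(prof, "")
        assert hit.bit_score == -np.inf and hit.alignment == []

    def test_matches_enumeration_oracle_small(self):
        N = alphabets.NUCLEOTIDE_LETTERS
        prof = build_profile(noisy_preds("ACG", seed=7,
                                         polymer="nucleotide"))
        for seq in itertools.product(N, repeat=3):
            s = "".join(seq)
            assert viterbi_search(prof, s).bit_score == \
                pytest.approx(enumerate_paths_score(prof, s), abs=1e-9)

    def test_batch_scores_equal_single_scores(self, rng):
        seq = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 15))
        prof = build_profile(noisy_preds(seq, seed=8))
        seqs = ["".join(rng.choice(list(alphabets.AMINO_LETTERS),
                                   int(rng.integers(3, 30))))
                for _ in range(20)] + [seq]
        batch = _batch_scores(prof, [_encode(s, prof.alphabet)
                                     for s in seqs])
        for s, b in zip(seqs, batch):
            assert viterbi_search(prof, s).bit_score == \
                pytest.approx(b, abs=1e-6)

    def test_local_score_does_not_decrease_with_negative_flanks(self, rng):
        seq = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 20))
        prof = build_profile(noisy_preds(seq, seed=9))
        base = viterbi_search(prof, seq).bit_score
        flank = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 30))
        flanked = viterbi_search(prof, flank + seq + flank).bit_score
        assert flanked >= base - 1e-9


class TestSearchDatabase:
    def test_planted_sequence_ranks_first(self, rng):
        seq = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 50))
        prof = build_profile(one_hot_preds(seq, confidence=0.9))
        db = [(f"decoy_{i}",
               "".join(rng.choice(list(alphabets.AMINO_LETTERS), 50)))
              for i in range(99)] + [("planted", seq)]
        hits = search_database(prof, db, top_n=5)
        assert hits[0].target_id == "planted"

    def test_duplicate_targets_tie_broken_by_id(self, rng):
        seq = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 30))
        prof = build_profile(one_hot_preds(seq))
        db = [("b_copy", seq), ("a_copy", seq),
              ("junk", "".join(rng.choice(list(alphabets.AMINO_LETTERS),
                                          30)))]
        hits = search_database(prof, db, top_n=3)
        assert [h.target_id for h in hits[:2]] == ["a_copy", "b_copy"]
        assert hits[0].bit_score == hits[1].bit_score

    def test_scores_sorted_descending(self, rng):
        seq = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 40))
        prof = build_profile(noisy_preds(seq, seed=11))
        db = [(f"d{i}", "".join(rng.choice(
            list(alphabets.AMINO_LETTERS), 40))) for i in range(30)]
        hits = search_database(prof, db)
        scores = [h.bit_score for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_alphabet_mismatch_rejected(self):
        prof = build_profile(one_hot_preds("ACGU", "nucleotide"))
        with pytest.raises(ValueError, match="alphabet"):
            search_database(prof, [("x", "WYWYWYWYWY")])

    def test_empty_db_rejected(self):
        prof = build_profile(one_hot_preds("ACD"))
        with pytest.raises(ValueError, match="empty"):
            search_database(prof, [])

    def test_bit_threshold_filters(self, rng):
        seq = "".join(rng.choice(list(alphabets.AMINO_LETTERS), 40))
        prof = build_profile(one_hot_preds(seq, confidence=0.9))
        db = [("planted", seq),
              ("junk", "".join(rng.choice(list(alphabets.AMINO_LETTERS),
                                          40)))]
        hits = search_database(prof, db, bit_threshold=25.0)
        assert [h.target_id for h in hits] == ["planted"]
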