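"""ORF extraction and profile build/scan/select behaviour."""

import math

import numpy as np
import pytest

from tecurate.profiles import (
    AA_ALPHABET,
    OpenReadingFrame,
    ProfileHit,
    build_profile,
    extract_orfs,
    read_profile,
    scan_profile,
    select_best_hits,
    write_profile,
)
from tecurate.seqio import SequenceRecord, revcomp
from tecurate.simulate import back_translate, mutate_protein, random_protein


def _coding_construct(rng, n_aa):
    """Random protein of n_aa residues back-translated and stop-terminated."""
    protein = random_protein(rng, n_aa)
    return protein, back_translate(rng, protein) + "TAA"


class TestExtractOrfs:
    def test_min_size_boundary(self, rng):
        protein, nt = _coding_construct(rng, 200)
        orfs = extract_orfs(SequenceRecord("x", nt), min_aa=200)
        forward = [o for o in orfs if o.frame > 0]
        assert len(forward) == 1
        assert forward[0].aa_seq == protein
        assert (forward[0].nt_start, forward[0].nt_end) == (0, 600)

        _, nt199 = _coding_construct(rng, 199)
        assert extract_orfs(SequenceRecord("y", nt199), min_aa=200) == []

    def test_reverse_complement_yields_negative_frame(self, rng):
        protein, nt = _coding_construct(rng, 210)
        rec = SequenceRecord("z", revcomp(nt))
        orfs = [o for o in extract_orfs(rec, min_aa=210) if o.frame < 0]
        assert len(orfs) == 1
        orf = orfs[0]
        assert orf.aa_seq == protein
        # coordinates map back to the forward strand of the stored sequence
        assert orf.nt_end - orf.nt_start == 3 * 210
        assert revcomp(rec.seq[orf.nt_start : orf.nt_end]) == nt[:630]

    def test_strand_symmetry_of_orf_sets(self, rng):
        protein, nt = _coding_construct(rng, 205)
        fwd = extract_orfs(SequenceRecord("a", nt), min_aa=200)
        rev = extract_orfs(SequenceRecord("a", revcomp(nt)), min_aa=200)
        assert sorted(o.aa_seq for o in fwd) == sorted(o.aa_seq for o in rev)
        assert sorted(-o.frame for o in fwd) == sorted(o.frame for o in rev)

    def test_short_record_gives_empty(self):
        assert extract_orfs(SequenceRecord("s", "ATG" * 10), min_aa=200) == []

    def test_internal_stop_invariant(self):
        with pytest.raises(ValueError):
            OpenReadingFrame("x", 1, "MA*KL" + "A" * 200, 0, 615)


class TestBuildProfile:
    def test_consensus_positive_others_negative(self):
        seq = AA_ALPHABET[:16]
        prof = build_profile([seq, seq], "p", "LTR")
        for j, aa in enumerate(seq):
            k = AA_ALPHABET.index(aa)
            assert prof.columns[j, k] > 0
            others = np.delete(prof.columns[j], k)
            assert (others < 0).all()

    def test_uniform_column_scores_near_zero(self):
        # every residue equally often in a column -> counts match background
        seqs = [aa * 12 for aa in AA_ALPHABET]
        prof = build_profile(seqs, "p", "LTR", pseudocount=1.0)
        assert np.allclose(prof.columns, 0.0, atol=1e-12)

    def test_three_sequence_log_odds_match_hand_arithmetic(self):
        # column 0 residues: A, A, C; pseudocount 1, uniform background 1/20
        seqs = ["A" + "D" * 11, "A" + "D" * 11, "C" + "D" * 11]
        prof = build_profile(seqs, "p", "LTR", pseudocount=1.0)
        expected_a = math.log2(((2 + 1 / 20) / (3 + 1)) / (1 / 20))
        expected_c = math.log2(((1 + 1 / 20) / (3 + 1)) / (1 / 20))
        expected_g = math.log2(((0 + 1 / 20) / (3 + 1)) / (1 / 20))
        assert prof.columns[0, AA_ALPHABET.index("A")] == pytest.approx(expected_a)
        assert prof.columns[0, AA_ALPHABET.index("C")] == pytest.approx(expected_c)
        assert prof.columns[0, AA_ALPHABET.index("G")] == pytest.approx(expected_g)

    def test_gap_majority_columns_dropped(self):
        seqs = ["A-" + "D" * 10, "A-" + "D" * 10, "AC" + "D" * 10]
        prof = build_profile(seqs, "p", "LTR")
        assert prof.length == 11  # gap column removed

    def test_order_invariance(self, rng):
        seqs = [random_protein(rng, 30) for _ in range(5)]
        a = build_profile(seqs, "p", "LTR")
        b = build_profile(seqs[::-1], "p", "LTR")
        assert np.allclose(a.columns, b.columns)

    @pytest.mark.parametrize("bad", [[], ["ACDEFGHIKL"]])
    def test_too_few_sequences_rejected(self, bad):
        with pytest.raises(ValueError):
            build_profile(bad, "p", "LTR")

    def test_all_gap_rejected(self):
        with pytest.raises(ValueError):
            build_profile(["-" * 12, "-" * 12], "p", "LTR")

    def test_tsv_round_trip(self, tmp_path, rng):
        prof = build_profile(
            [random_protein(rng, 25) for _ in range(4)], "RT-Gypsy", "LTR", "Gypsy"
        )
        path = tmp_path / "p.tsv"
        write_profile(prof, path)
        back = read_profile(path)
        assert back.name == prof.name and back.te_order == prof.te_order
        assert np.allclose(back.columns, prof.columns, atol=1e-6)


class TestScanProfile:
    @pytest.fixture()
    def profile(self, rng):
        aln = [random_protein(rng, 50)]
        aln += [mutate_protein(rng, aln[0], 0.1) for _ in range(4)]
        return build_profile(aln, "dom", "LTR", "Gypsy")

    def test_self_match_is_maximal_and_located(self, profile, rng):
        consensus = profile.consensus
        flank_l = random_protein(rng, 30)
        orf = OpenReadingFrame(
            "q", 1, flank_l + consensus + random_protein(rng, 20), 0, 300
        )
        (hit,) = scan_profile(orf, profile)
        assert hit.start == 30 and hit.end == 80
        # no other offset scores higher than the planted one
        best_possible = float(np.max(profile.columns, axis=1).sum())
        assert hit.score == pytest.approx(best_possible)

    def test_mutated_copy_still_hits_same_offset(self, profile, rng):
        consensus = profile.consensus
        mutated = mutate_protein(rng, consensus, 0.10)
        orf = OpenReadingFrame(
            "q", 1, random_protein(rng, 25) + mutated + random_protein(rng, 25),
            0, 300,
        )
        (hit,) = scan_profile(orf, profile)
        assert hit.start == 25

    def test_unrelated_orf_scores_below_self_match(self, profile, rng):
        self_score = float(np.max(profile.columns, axis=1).sum())
        orf = OpenReadingFrame("q", 1, random_protein(rng, 250), 0, 750)
        hits = scan_profile(orf, profile)
        assert hits == [] or hits[0].score < self_score

    def test_short_orf_partial_window(self, profile):
        # an ORF holding only half the consensus still aligns to it
        piece = profile.consensus[10:35]
        orf = OpenReadingFrame("q", 1, piece, 0, 75)
        (hit,) = scan_profile(orf, profile)
        assert hit.score > 0


class TestSelectBestHits:
    @staticmethod
    def _hit(score, span, profile):
        return ProfileHit("q", profile, score, 0, span, "LTR")

    @pytest.mark.parametrize(
        "hits, winner",
        [
            ([("a", 50.0, 80), ("b", 40.0, 80)], "a"),  # score wins
            ([("a", 50.0, 60), ("b", 50.0, 80)], "b"),  # span breaks tie
            ([("b", 50.0, 80), ("a", 50.0, 80)], "a"),  # name breaks tie
        ],
    )
    def test_tie_breaking(self, hits, winner):
        objs = [self._hit(s, sp, name) for name, s, sp in hits]
        assert select_best_hits(objs)["q"].profile == winner
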