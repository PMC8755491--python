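import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from helpers_oracles import oracle_global_score
from domainer.io_formats import SequenceRecord
from domainer.ortholog_align import (
    ProteinAlignment,
    backtranslate,
    global_align,
    reciprocal_best_hits,
    select_longest,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, lo=20, hi=80):
    return "".join(rng.choices(AA, k=rng.randint(lo, hi)))


class TestSelectLongest:
    def test_tie_goes_to_smallest_identifier(self):
        records = [SequenceRecord("a", "X" * 100), SequenceRecord("c", "Y" * 250),
                   SequenceRecord("b", "Z" * 250)]
        chosen = select_longest({"g": records})
        assert chosen["g"].identifier == "b"

    def test_single_record(self):
        rec = SequenceRecord("t1", "MKL")
        assert select_longest({"g": [rec]})["g"] is rec

    def test_selected_length_is_group_maximum(self):
        rng = random.Random(3)
        groups = {
            f"g{i}": [SequenceRecord(f"g{i}.{j}", _random_protein(rng))
                      for j in range(rng.randint(1, 5))]
            for i in range(20)
        }
        chosen = select_longest(groups)
        for gene, records in groups.items():
            assert len(chosen[gene].residues) == max(len(r.residues) for r in records)


class TestGlobalAlign:
    def test_identical_sequences_align_gap_free(self):
        blosum = substitution_matrices.load("BLOSUM62")
        seq = "MKTAYIAKQR"
        aln = global_align(SequenceRecord("a", seq), SequenceRecord("b", seq))
        assert aln.aligned_a == aln.aligned_b == seq
        assert aln.score == sum(blosum[c, c] for c in seq)

    def test_score_matches_dp_oracle(self):
        a, b = "HEAGAWGHEE", "PAWHEAE"
        aln = global_align(SequenceRecord("a", a), SequenceRecord("b", b))
        assert aln.score == oracle_global_score(a, b)

    def test_random_pairs_match_oracle_and_strip_gaps(self):
        rng = random.Random(7)
        for _ in range(10):
            a, b = _random_protein(rng, 10, 40), _random_protein(rng, 10, 40)
            aln = global_align(SequenceRecord("a", a), SequenceRecord("b", b))
            assert aln.score == oracle_global_score(a, b)
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b

    def test_non_amino_acid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            global_align(SequenceRecord("a", "MK1L"), SequenceRecord("b", "MKL"))


class TestReciprocalBestHits:
    def test_three_mutually_best_pairs(self):
        a = [SequenceRecord("a1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),
             SequenceRecord("a2", "WWGGHHPPLLKKAAEERRQQSSTTVVYYFFMM"),
             SequenceRecord("a3", "CCNNDDEEQQGGHHIILLKKMMFFPPSSTTWW")]
        b = [SequenceRecord("b1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEV"),
             SequenceRecord("b2", "WWGGHHPPLLKKAAEERRQQSSTTVVYYFFM"),
             SequenceRecord("b3", "CCNNDDEEQQGGHHIILLKKMMFFPPSSTTW")]
        pairs = reciprocal_best_hits(a, b)
        assert [(x, y) for x, y, _ in pairs] == [("a1", "b1"), ("a2", "b2"), ("a3", "b3")]

    def test_duplicated_gene_with_tied_scores_excludes_pair(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        a = [SequenceRecord("a1", seq), SequenceRecord("a1dup", seq)]
        b = [SequenceRecord("b1", seq)]
        assert reciprocal_best_hits(a, b) == []

    def test_matches_brute_force_oracle_and_is_symmetric(self):
        rng = random.Random(11)
        a = [SequenceRecord(f"a{i}", _random_protein(rng, 25, 50)) for i in range(10)]
        b = [SequenceRecord(f"b{j}", _random_protein(rng, 25, 50)) for j in range(10)]
        pairs = {(x, y) for x, y, _ in reciprocal_best_hits(a, b, min_score=-1e9)}

        scores = np.array([[oracle_global_score(ra.residues, rb.residues) for rb in b]
                           for ra in a])
        expected = set()
        for i in range(10):
            for j in range(10):
                row, col = scores[i, :], scores[:, j]
                if (scores[i, j] == row.max() and (row == row.max()).sum() == 1
                        and scores[i, j] == col.max() and (col == col.max()).sum() == 1):
                    expected.add((a[i].identifier, b[j].identifier))
        assert pairs == expected

        swapped = {(y, x) for x, y, _ in reciprocal_best_hits(b, a, min_score=-1e9)}
        assert swapped == pairs


class TestBacktranslate:
    def test_gap_free_alignment_concatenates_codons(self):
        cds_a = "ATGGAAAAA"  # MEK
        cds_b = "ATGGAGAAG"  # MEK
        paln = ProteinAlignment("a", "b", "MEK", "MEK", 0.0)
        caln = backtranslate(paln, cds_a, cds_b)
        assert caln.row_a == cds_a and caln.row_b == cds_b

    def test_residue_gap_becomes_codon_gap(self):
        paln = ProteinAlignment("a", "b", "ME-K", "MEAK", 0.0)
        caln = backtranslate(paln, "ATGGAAAAA", "ATGGAGGCTAAG")
        assert caln.row_a == "ATGGAA---AAA"
        assert caln.row_b == "ATGGAGGCTAAG"

    def test_translation_mismatch_names_position(self):
        paln = ProteinAlignment("a", "b", "MK", "MK", 0.0)
        with pytest.raises(ValueError, match="residue 2"):
            backtranslate(paln, "ATGCCC", "ATGAAA")  # CCC is Pro, not Lys

    def test_round_trip_on_simulated_pairs(self, small_cohort):
        for gene in small_cohort.genes[:20]:
            prot_a = str(Seq(gene.cds_a).translate())
            prot_b = str(Seq(gene.cds_b).translate())
            paln = global_align(SequenceRecord(gene.gene_id, prot_a),
                                SequenceRecord(gene.gene_id, prot_b))
            caln = backtranslate(paln, gene.cds_a, gene.cds_b)
            back_a = "".join(
                str(Seq(caln.row_a[k:k + 3]).translate()) if caln.row_a[k:k + 3] != "---" else "-"
                for k in range(0, len(caln.row_a), 3))
            assert back_a == paln.aligned_a
            assert caln.row_a.replace("-", "") == gene.cds_a
            assert caln.row_b.replace("-", "") == gene.cds_b
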