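import numpy as np
import pytest
from hypothesis import given, strategies as st

from omegascan.codon_core import (
    STANDARD_CODE,
    CodonAlignment,
    GeneticCode,
    all_codons,
    classify_position_changes,
    equal_frequencies,
    f3x4_frequencies,
    read_fasta_codon_alignment,
    remove_gap_codons,
    strip_terminal_stops,
    validate_cds_alignment,
    write_fasta_codon_alignment,
)


def aln(*seqs, taxa=None):
    taxa = taxa or [f"s{i}" for i in range(len(seqs))]
    return CodonAlignment(
        taxa=taxa, codons=[[s[i : i + 3] for i in range(0, len(s), 3)] for s in seqs]
    )


class TestGeneticCode:
    def test_standard_code_has_61_sense_and_3_stops(self):
        assert len(STANDARD_CODE.sense_codons) == 61
        assert set(STANDARD_CODE.stop_codons) == {"TAA", "TAG", "TGA"}

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="64"):
            GeneticCode(table={"ATG": "M"})


class TestValidation:
    def test_clean_two_sequence_alignment_passes(self):
        assert validate_cds_alignment(aln("ATGAAA", "ATGCCC")) == []

    def test_stop_codon_reported_with_position(self):
        report = validate_cds_alignment(aln("ATGTAA", "ATGCCC"))
        assert any("TAA" in v and "codon 2" in v for v in report)

    def test_non_triplet_length_is_an_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            aln("ATGAAAC", "ATGAAAC")

    def test_unequal_lengths_hard_error(self):
        with pytest.raises(ValueError, match="unequal"):
            aln("ATGAAA", "ATG")

    def test_partial_gap_and_bad_characters_reported(self):
        report = validate_cds_alignment(aln("A-GAAA", "ATGXXX"))
        assert any("frame-breaking" in v for v in report)
        assert any("invalid characters" in v for v in report)


class TestGapRemoval:
    def test_gapped_column_removed_from_all_sequences(self):
        cleaned, colmap = remove_gap_codons(aln("ATG---AAA", "ATGCCCAAA"))
        assert cleaned.codons == [["ATG", "AAA"], ["ATG", "AAA"]]
        assert colmap == [0, 2]

    def test_gap_free_alignment_is_identity(self):
        a = aln("ATGAAA", "ATGCCC")
        cleaned, colmap = remove_gap_codons(a)
        assert cleaned.codons == a.codons
        assert colmap == [0, 1]

    def test_idempotent(self):
        once, _ = remove_gap_codons(aln("ATG---AAANNN", "ATGCCCAAACCC"))
        twice, colmap = remove_gap_codons(once)
        assert twice.codons == once.codons
        assert colmap == list(range(once.n_codons))

    def test_ambiguous_codons_removed_like_gaps(self):
        cleaned, colmap = remove_gap_codons(aln("ATGANA", "ATGCCC"))
        assert cleaned.codons == [["ATG"], ["ATG"]]
        assert colmap == [0]

    def test_frame_breaking_gap_raises(self):
        with pytest.raises(ValueError, match="frame-breaking"):
            remove_gap_codons(aln("ATGA--", "ATGCCC"))

    def test_column_map_recovers_original_columns(self):
        original = aln("ATG---AAACCT", "ATGCCCAAACCT")
        cleaned, colmap = remove_gap_codons(original)
        for new_idx, old_idx in enumerate(colmap):
            assert cleaned.column(new_idx) == original.column(old_idx)


def test_strip_terminal_stops_drops_only_final_stop_column():
    stripped = strip_terminal_stops(aln("ATGTGA", "ATGTAA"))
    assert stripped.codons == [["ATG"], ["ATG"]]
    assert strip_terminal_stops(stripped).codons == stripped.codons


class TestSubstitutionClasses:
    @pytest.mark.parametrize(
        "position, pct_nonsyn, pct_syn",
        [(1, 96, 4), (2, 99, 1), (3, 33, 67)],
    )
    def test_standard_code_percentages(self, position, pct_nonsyn, pct_syn):
        stats = classify_position_changes(STANDARD_CODE, position)
        assert stats.pct_nonsynonymous == pct_nonsyn
        assert stats.pct_synonymous == pct_syn
        assert stats.n_pairs == 96

    def test_brute_force_pair_enumeration_matches(self):
        # independent oracle: scan all unordered codon pairs directly
        import itertools

        codons = all_codons()
        for position in (1, 2, 3):
            syn = nonsyn = 0
            for a, b in itertools.combinations(codons, 2):
                diffs = [i for i in range(3) if a[i] != b[i]]
                if diffs != [position - 1]:
                    continue
                if STANDARD_CODE.translate(a) == STANDARD_CODE.translate(b):
                    syn += 1
                else:
                    nonsyn += 1
            stats = classify_position_changes(STANDARD_CODE, position)
            assert (stats.n_synonymous, stats.n_nonsynonymous) == (syn, nonsyn)

    def test_total_pairs_over_positions_is_288(self):
        assert sum(classify_position_changes(STANDARD_CODE, p).n_pairs for p in (1, 2, 3)) == 288

    def test_degenerate_code_has_no_nonsynonymous_changes(self):
        flat = GeneticCode(table={c: "A" for c in all_codons()}, id=0)
        for position in (1, 2, 3):
            assert classify_position_changes(flat, position).pct_nonsynonymous == 0

    def test_invalid_position_rejected(self):
        with pytest.raises(ValueError):
            classify_position_changes(STANDARD_CODE, 4)


class TestCodonFrequencies:
    def test_uniform_composition_gives_equal_sense_frequencies(self):
        # all four nucleotides equally frequent at every codon position
        seqs = ["".join(n * 3 for n in "TCAG")]
        freqs = f3x4_frequencies(aln(*seqs))
        assert np.allclose(freqs.pi, 1.0 / 61)

    def test_frequencies_sum_to_one(self, neutral_alignment):
        assert np.isclose(f3x4_frequencies(neutral_alignment).pi.sum(), 1.0)

    def test_toy_alignment_matches_hand_computation(self):
        a = aln("ATGAAA", "ATGCCC")
        # codons ATG, AAA, ATG, CCC -> pos1 A3 C1; pos2 T2 A1 C1; pos3 G2 A1 C1
        freqs = f3x4_frequencies(a)
        p1 = {"A": 0.75, "C": 0.25}
        p2 = {"T": 0.5, "A": 0.25, "C": 0.25}
        p3 = {"G": 0.5, "A": 0.25, "C": 0.25}
        raw = {
            c: p1.get(c[0], 0) * p2.get(c[1], 0) * p3.get(c[2], 0)
            for c in STANDARD_CODE.sense_codons
        }
        total = sum(raw.values())
        expected = np.array([raw[c] / total for c in STANDARD_CODE.sense_codons])
        assert np.allclose(freqs.pi, expected)

    def test_invariant_under_duplicating_all_sequences(self, neutral_alignment):
        doubled = CodonAlignment(
            taxa=neutral_alignment.taxa + [t + "_dup" for t in neutral_alignment.taxa],
            codons=neutral_alignment.codons + [list(r) for r in neutral_alignment.codons],
        )
        assert np.allclose(
            f3x4_frequencies(neutral_alignment).pi, f3x4_frequencies(doubled).pi
        )

    def test_equal_frequencies_are_1_over_61(self):
        assert np.allclose(equal_frequencies().pi, 1.0 / 61)

    def test_f1x4_pools_positions(self):
        from omegascan.codon_core import f1x4_frequencies

        a = aln("TTTCCCAAAGGG", "TTTCCCAAAGGG")
        freqs = f1x4_frequencies(a)
        # uniform pooled nucleotide composition -> equal sense frequencies
        assert np.allclose(freqs.pi, 1.0 / 61)
        assert freqs.estimator == "F1x4"


class TestFastaIO:
    def test_round_trip(self, tmp_path, toy_alignment):
        path = tmp_path / "aln.fasta"
        write_fasta_codon_alignment(toy_alignment, path)
        back = read_fasta_codon_alignment(path)
        assert back.taxa == toy_alignment.taxa
        assert back.codons == toy_alignment.codons

    def test_header_taken_up_to_first_whitespace(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">sp1 description here\nATGAAA\n>sp2\nATGCCC\n")
        assert read_fasta_codon_alignment(path).taxa == ["sp1", "sp2"]


@given(st.integers(0, 2**32 - 1))
def test_column_access_matches_row_layout(seed):
    rng = np.random.default_rng(seed)
    sense = STANDARD_CODE.sense_codons
    codons = [[sense[i] for i in rng.integers(0, 61, 5)] for _ in range(3)]
    a = CodonAlignment(taxa=["a", "b", "c"], codons=codons)
    j = int(rng.integers(0, 5))
    assert a.column(j) == [codons[k][j] for k in range(3)]
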