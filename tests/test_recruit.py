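import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import sw_brute
from placeprof.formats import SeqRecord
from placeprof.matrices import AA_ORDER
from placeprof.recruit import (
    ScoringScheme,
    karlin_altschul_evalue,
    merge_overlapping_pair,
    recruit_and_trim,
    reverse_complement,
    six_frame_translate,
    smith_waterman,
)
from placeprof.synth import reverse_translate, synth_refpkg

dna_seq = st.text(alphabet="ACGT", min_size=3, max_size=60)
aa_seq = st.text(alphabet=AA_ORDER, min_size=1, max_size=25)


class TestTranslation:
    def test_codon_table_identity(self):
        assert six_frame_translate("ATGGCC")[1] == "MA"

    def test_reverse_complement_symmetry_example(self):
        assert six_frame_translate("GGCCAT")[-1] == "MA"

    def test_ambiguity_and_stop_rules(self):
        assert six_frame_translate("ATGNNNTAA")[1] == "MX*"

    def test_too_short_gives_empty_map(self):
        assert six_frame_translate("AT") == {}

    @settings(deadline=None, max_examples=50)
    @given(dna_seq)
    def test_negative_frames_equal_forward_frames_of_revcomp(self, dna):
        fw = six_frame_translate(dna)
        rc = six_frame_translate(reverse_complement(dna))
        for f in (1, 2, 3):
            assert fw.get(-f) == rc.get(f)


class TestSmithWaterman:
    def test_exact_match_scores_blosum_diagonal_sum(self):
        score, qi, ri, pair = smith_waterman("MKV", "MKV", ScoringScheme())
        assert score == 14.0  # 5 + 5 + 4 on the BLOSUM62 diagonal
        assert qi == (0, 3) and ri == (0, 3)
        assert pair == ("MKV", "MKV")

    def test_classic_linear_gap_instance(self):
        scheme = ScoringScheme(matrix_name="BLOSUM50", gap_open=0.0, gap_ext=8.0)
        score, _qi, _ri, pair = smith_waterman("HEAGAWGHEE", "PAWHEAE", scheme)
        assert score == 28.0
        assert pair == ("AWGHE", "AW-HE")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("AAAA", "", ScoringScheme())

    @settings(deadline=None, max_examples=40)
    @given(aa_seq, aa_seq)
    def test_score_symmetric_under_sequence_swap(self, a, b):
        scheme = ScoringScheme()
        s1 = smith_waterman(a, b, scheme)[0]
        s2 = smith_waterman(b, a, scheme)[0]
        assert s1 == s2

    @pytest.mark.parametrize(
        "scheme",
        [
            ScoringScheme(),
            ScoringScheme(matrix_name="BLOSUM50", gap_open=10.0, gap_ext=2.0),
            ScoringScheme(gap_open=0.0, gap_ext=8.0),
        ],
        ids=["blosum62-11-1", "blosum50-10-2", "blosum62-linear8"],
    )
    def test_matches_exhaustive_dp_oracle(self, scheme):
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load(scheme.matrix_name)
        rng = np.random.default_rng(99)
        for _ in range(40):
            a = "".join(rng.choice(list(AA_ORDER), rng.integers(1, 30)))
            b = "".join(rng.choice(list(AA_ORDER), rng.integers(1, 30)))
            expect = sw_brute(a, b, lambda x, y: float(mat[x, y]),
                              scheme.gap_open, scheme.gap_ext)
            assert smith_waterman(a, b, scheme)[0] == expect


class TestEvalue:
    def test_zero_score_boundary(self):
        s = ScoringScheme(m=100, n=350)
        assert karlin_altschul_evalue(0.0, s) == pytest.approx(
            s.K * 100 * 350
        )

    def test_closed_form_value(self):
        s = ScoringScheme(lambda_=0.267, K=0.041, m=100, n=350)
        assert karlin_altschul_evalue(40.0, s) == pytest.approx(0.033, rel=0.01)

    def test_huge_score_underflows_to_zero(self):
        s = ScoringScheme(m=100, n=350)
        assert karlin_altschul_evalue(1e6, s) == 0.0

    def test_unset_search_space_rejected(self):
        with pytest.raises(ValueError):
            karlin_altschul_evalue(10.0, ScoringScheme())

    def test_monotone_decreasing_in_score(self):
        s = ScoringScheme(m=50, n=1000)
        evs = [karlin_altschul_evalue(x, s) for x in (0, 10, 20, 40)]
        assert evs == sorted(evs, reverse=True)


class TestMergePair:
    def test_exact_overlap(self):
        r1 = SeqRecord("p", "AAACCCGG")
        r2 = SeqRecord("p", reverse_complement("CCGGTTTT"))
        merged = merge_overlapping_pair(r1, r2, min_overlap=4)
        assert merged.seq == "AAACCCGGTTTT"

    def test_overlap_below_minimum_gives_none(self):
        r1 = SeqRecord("p", "AAACC")
        r2 = SeqRecord("p", reverse_complement("ACCTT"))
        # overlap 3 ("ACC") < min_overlap 4; and no longer overlap matches
        assert merge_overlapping_pair(r1, r2, min_overlap=4) is None

    def test_mismatch_fraction_threshold(self):
        r1 = SeqRecord("p", "AAAACGCG")
        r2 = SeqRecord("p", reverse_complement("GGGGTTTT"))  # overlap 4: 2 mism
        assert (
            merge_overlapping_pair(r1, r2, min_overlap=4, max_mismatch_frac=0.25)
            is None
        )

    def test_mismatch_resolved_by_higher_quality(self):
        r1 = SeqRecord("p", "AAAT", [30, 30, 30, 10])
        r2 = SeqRecord("p", reverse_complement("AAAC"), [40, 40, 40, 40])
        merged = merge_overlapping_pair(r1, r2, min_overlap=4,
                                        max_mismatch_frac=0.3)
        assert merged.seq == "AAAC"


@pytest.fixture(scope="module")
def nirk_refpkg():
    return synth_refpkg("nirK", seed=5)


class TestRecruitAndTrim:
    def test_verbatim_read_recruits_in_frame(self, nirk_refpkg):
        ref = nirk_refpkg.ungapped_references()[0]
        dna = reverse_translate(ref.seq, seed=3)
        read = SeqRecord("r", dna[300:450])  # 150 bp from the middle
        out = recruit_and_trim([read], nirk_refpkg)
        assert len(out) == 1
        rr = out[0]
        assert rr.frame == 1
        assert len(rr.aa_seq) == 50
        assert rr.evalue < 1e-10
        assert rr.dna_span == (0, 150)
        assert rr.aa_seq == ref.seq[100:150]

    def test_reverse_strand_read_recruits_negative_frame(self, nirk_refpkg):
        ref = nirk_refpkg.ungapped_references()[0]
        dna = reverse_translate(ref.seq, seed=3)
        read = SeqRecord("r", reverse_complement(dna[300:450]))
        out = recruit_and_trim([read], nirk_refpkg)
        assert len(out) == 1
        assert out[0].frame == -1
        assert out[0].aa_seq == ref.seq[100:150]

    def test_min_aa_boundary(self, nirk_refpkg):
        ref = nirk_refpkg.ungapped_references()[0]
        dna = reverse_translate(ref.seq, seed=3)
        read32 = SeqRecord("short", dna[300 : 300 + 96])  # 32 aa
        read33 = SeqRecord("ok", dna[300 : 300 + 99])  # 33 aa
        assert recruit_and_trim([read32], nirk_refpkg) == []
        kept = recruit_and_trim([read33], nirk_refpkg)
        assert len(kept) == 1 and len(kept[0].aa_seq) == 33

    def test_random_dna_rarely_recruits(self, nirk_refpkg):
        rng = np.random.default_rng(17)
        reads = [
            SeqRecord(f"r{i}", "".join(rng.choice(list("ACGT"), 150)))
            for i in range(200)
        ]
        out = recruit_and_trim(reads, nirk_refpkg)
        assert len(out) <= 2  # >= 99% rejected

    def test_recruitment_monotone_in_evalue_threshold(self, nirk_refpkg):
        ref = nirk_refpkg.ungapped_references()[1]
        dna = reverse_translate(ref.seq, seed=4)
        rng = np.random.default_rng(2)
        reads = []
        for i in range(20):
            s = int(rng.integers(0, len(dna) - 150))
            seq = list(dna[s : s + 150])
            for pos in rng.choice(150, size=15, replace=False):
                seq[pos] = "ACGT"[int(rng.integers(4))]
            reads.append(SeqRecord(f"r{i}", "".join(seq)))
        strict = {r.read_id for r in recruit_and_trim(reads, nirk_refpkg,
                                                      e_recruit=1e-10)}
        loose = {r.read_id for r in recruit_and_trim(reads, nirk_refpkg,
                                                     e_recruit=1e-3)}
        assert strict <= loose

    def test_stops_and_ambiguities_masked_not_deleted(self, nirk_refpkg):
        ref = nirk_refpkg.ungapped_references()[0]
        dna = list(reverse_translate(ref.seq, seed=3)[300:450])
        dna[60:63] = list("TAA")  # internal stop
        dna[90] = "N"
        out = recruit_and_trim([SeqRecord("r", "".join(dna))], nirk_refpkg)
        assert len(out) == 1
        assert "*" not in out[0].aa_seq
        assert out[0].aa_seq[20] == "X"
        assert len(out[0].aa_seq) == 50

    def test_empty_reference_set_rejected(self, nirk_refpkg):
        import dataclasses

        empty = dataclasses.replace(nirk_refpkg, alignment=[])
        with pytest.raises(Exception):
            recruit_and_trim([SeqRecord("r", "ACGTACGT")], empty)
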