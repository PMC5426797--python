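import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fernmir.identify import (
    CandidateVariant,
    FamilyCall,
    MiRNAAlignment,
    align_to_reference,
    best_alignment,
    bona_fide_filter,
    canonical_family,
    detect_duplex,
    duplex_geometry_ok,
    five_prime_homogeneity,
    identify_families,
    merge_family_label,
    name_variants,
    reassess_stringent,
    revcomp,
    similarity_evalue,
    solve_karlin_lambda,
    terminal_nt_summary,
)
from fernmir.io_formats import ReferenceMiRNA, parse_mirbase_id
from fernmir.preprocess import UniqueTag

from .conftest import make_reference, star_of

MIR166 = "TCGGACCAGGCTTCATTCCCC"
MIR390 = "AAGCTCAGGAGGGATAGCGCC"
MIR162 = "GGAGGCAGCGGTTCATCGATC"

BASES = "ACGT"
seqs = st.text(alphabet=BASES, min_size=18, max_size=24)


class TestAlignment:
    def test_exact_copy_aligns_at_zero_offsets(self):
        ref = make_reference("ath-miR166a-5p", MIR166)
        aln = align_to_reference(UniqueTag(MIR166, 1), ref)
        assert (aln.offset5, aln.offset3, aln.mismatches) == (0, 0, 0)

    def test_five_prime_trim_reports_positive_offset5(self):
        ref = make_reference("ath-miR166a-5p", MIR166)
        aln = align_to_reference(UniqueTag(MIR166[1:], 1), ref)
        assert (aln.offset5, aln.offset3, aln.mismatches) == (1, 0, 0)

    def test_three_prime_extension_reports_positive_offset3(self):
        ref = make_reference("ath-miR166a-5p", MIR166)
        aln = align_to_reference(UniqueTag(MIR166 + "A", 1), ref)
        assert (aln.offset5, aln.offset3, aln.mismatches) == (0, 1, 0)

    def test_offset_beyond_bound_rejected(self):
        ref = make_reference("ath-miR166a-5p", MIR166)
        assert align_to_reference(UniqueTag(MIR166[4:], 1), ref) is None

    def test_three_mismatches_rejected(self):
        mutated = "AAA" + MIR166[3:]
        ref = make_reference("ath-miR166a-5p", MIR166)
        assert align_to_reference(UniqueTag(mutated, 1), ref, max_mismatch=2) is None

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(seqs, st.integers(0, 3), st.integers(-3, 0))
    def test_truncations_recovered_with_zero_mismatches(self, ref_seq, d, o3):
        tag_seq = ref_seq[d : len(ref_seq) + o3]
        if len(tag_seq) < 15:
            return
        ref = make_reference("ath-miR9999-5p", ref_seq)
        aln = align_to_reference(UniqueTag(tag_seq, 1), ref)
        assert aln is not None and aln.mismatches == 0
        # The constructed placement is attainable, so the reported best can
        # never rank worse than it.
        constructed = MiRNAAlignment(UniqueTag(tag_seq, 1), ref, d, o3, 0)
        assert aln.rank_key <= constructed.rank_key

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(seqs, st.sets(st.integers(2, 15), min_size=0, max_size=2))
    def test_internal_mutations_bounded_mismatch_count(self, ref_seq, positions):
        tag = list(ref_seq)
        for p in positions:
            tag[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tag[p]]
        ref = make_reference("ath-miR9999-5p", ref_seq)
        aln = align_to_reference(UniqueTag("".join(tag), 1), ref)
        assert aln is not None and aln.mismatches <= len(positions)

    def test_best_alignment_prefers_fewer_mismatches(self):
        refs = [
            make_reference("ath-miR166a-5p", MIR166),
            make_reference("ath-miR166b-5p", MIR166[:-1] + "A"),
        ]
        aln = best_alignment(UniqueTag(MIR166, 1), refs)
        assert aln.reference.id == "ath-miR166a-5p"


class TestFamilies:
    @pytest.mark.parametrize(
        "ref_id,split,merged",
        [
            ("ath-miR157a-5p", "miR156", "miR156/529"),
            ("ath-miR165a-5p", "miR166", "miR166"),
            ("ppt-miR1030a", "miR530/1030", "miR530/1030"),
            ("ath-miR319a-5p", "miR319", "miR159/319"),
            ("ath-miR390a-5p", "miR390", "miR390"),
        ],
    )
    def test_synonyms_and_superfamilies(self, ref_id, split, merged):
        ref = ReferenceMiRNA.from_id(ref_id, MIR166)
        assert canonical_family(ref) == split
        assert canonical_family(ref, merge_mode="merged") == merged

    def test_fixture_family_counts_split_and_merged(self, fixtures):
        families = set(fixtures.table1["family"])
        assert len(families) == 23
        assert len({merge_family_label(f) for f in families}) == 21

    def test_fixture_terminal_nt_statistics(self, fixtures):
        summary = terminal_nt_summary(
            zip(fixtures.table1["family"], fixtures.table1["sequence"])
        )
        assert summary.n_variants == 57
        assert summary.n_u_variants == 35
        assert len(summary.families_with_u) == 18

    def test_fixture_duplex_arm_evidence(self, fixtures):
        arms_by_family: dict[str, set[str]] = {}
        for fam, ref_id in zip(
            fixtures.table1["family"], fixtures.table1["reference_mirna"]
        ):
            arms_by_family.setdefault(fam, set()).add(parse_mirbase_id(ref_id)[3])
        both = {f for f, arms in arms_by_family.items() if {"5p", "3p"} <= arms}
        assert {"miR162", "miR390", "miR395", "miR477", "miR529"} <= both


class TestHomogeneity:
    def _aln(self, arm, offset5, count):
        ref = make_reference(f"ath-miR166a-{arm}", MIR166)
        return MiRNAAlignment(UniqueTag(MIR166, count), ref, offset5, 0, 0)

    def test_single_arm_modal_fraction(self):
        alns = [self._aln("5p", 0, 8), self._aln("5p", 1, 2)]
        assert five_prime_homogeneity(alns) == pytest.approx(0.8)

    def test_minimum_over_arms(self):
        alns = [
            self._aln("5p", 0, 8), self._aln("5p", 1, 2),  # 0.8
            self._aln("3p", 0, 3), self._aln("3p", -1, 3),  # 0.5
        ]
        assert five_prime_homogeneity(alns) == pytest.approx(0.5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            five_prime_homogeneity([])


class TestDuplex:
    def test_geometry_accepts_canonical_star(self):
        assert duplex_geometry_ok(MIR166, star_of(MIR166))

    def test_geometry_rejects_unrelated(self):
        assert not duplex_geometry_ok(MIR166, "A" * 21)

    def _variant(self, seq, ref):
        aln = MiRNAAlignment(UniqueTag(seq, 1), ref, 0, 0, 0)
        return CandidateVariant("", seq, len(seq), 1, ref, 1.0, aln)

    def test_both_arms_required(self):
        v5 = self._variant(MIR166, make_reference("ath-miR166a-5p", MIR166))
        v3 = self._variant(star_of(MIR166), make_reference("ath-miR166a-3p", star_of(MIR166)))
        assert detect_duplex([v5, v3])
        assert not detect_duplex([v5])

    def test_precursor_geometry_check(self):
        from fernmir.simulate import make_precursor

        hairpin, _ = make_precursor(MIR166, seed=0)
        v5 = self._variant(MIR166, make_reference("ath-miR166a-5p", MIR166))
        v3 = self._variant(star_of(MIR166), make_reference("ath-miR166a-3p", star_of(MIR166)))
        assert detect_duplex([v5, v3], precursors={"miR166": hairpin})
        assert not detect_duplex([v5, v3], precursors={"miR166": "A" * 100})


class TestBonaFide:
    def _call(self, reads_20_22=12, homogeneity=0.9, has_duplex=False, mismatches=0):
        ref = make_reference("ath-miR166a-5p", MIR166)
        aln = MiRNAAlignment(UniqueTag(MIR166, reads_20_22), ref, 0, 0, mismatches)
        var = CandidateVariant("", MIR166, 21, reads_20_22, ref, 1e-6, aln)
        return FamilyCall("miR166", [var], reads_20_22, homogeneity, has_duplex)

    def test_all_criteria_pass(self):
        call = bona_fide_filter(self._call())
        assert call.bona_fide and not call.rescue_used

    def test_nine_reads_fails_without_duplex(self):
        call = bona_fide_filter(self._call(reads_20_22=9))
        assert not call.bona_fide
        assert any(r.startswith("reads_20_22") for r in call.failure_reasons)

    def test_ten_reads_is_the_boundary(self):
        assert bona_fide_filter(self._call(reads_20_22=10)).bona_fide

    def test_low_homogeneity_fails(self):
        call = bona_fide_filter(self._call(homogeneity=0.5))
        assert not call.bona_fide

    def test_duplex_rescues_low_read_count(self):
        call = bona_fide_filter(self._call(reads_20_22=4, has_duplex=True))
        assert call.bona_fide and call.rescue_used

    def test_low_confidence_reference_fails(self):
        ref = make_reference("ath-miR166a-5p", MIR166, high_confidence=False)
        aln = MiRNAAlignment(UniqueTag(MIR166, 20), ref, 0, 0, 0)
        var = CandidateVariant("", MIR166, 21, 20, ref, 1e-6, aln)
        call = bona_fide_filter(FamilyCall("miR166", [var], 20, 1.0, False))
        assert not call.bona_fide
        assert "reference_not_high_confidence" in call.failure_reasons


class TestNaming:
    def test_names_follow_read_count_then_sequence(self):
        ref = make_reference("ath-miR166a-5p", MIR166)

        def var(seq, n):
            aln = MiRNAAlignment(UniqueTag(seq, n), ref, 0, 0, 0)
            return CandidateVariant("", seq, len(seq), n, ref, 1.0, aln)

        call = FamilyCall(
            "miR166", [var("CCC", 5), var("AAA", 9), var("BBB", 5)], 19, 1.0, False
        )
        name_variants(call)
        assert [(v.given_name, v.sequence) for v in call.variants] == [
            ("pmi-miR166_v1", "AAA"),
            ("pmi-miR166_v2", "BBB"),
            ("pmi-miR166_v3", "CCC"),
        ]

    def test_merged_family_uses_first_number_as_stem(self):
        ref = ReferenceMiRNA.from_id("ppt-miR1030a", MIR166)
        aln = MiRNAAlignment(UniqueTag(MIR166, 1), ref, 0, 0, 0)
        var = CandidateVariant("", MIR166, 21, 1, ref, 1.0, aln)
        call = name_variants(FamilyCall("miR530/1030", [var], 1, 1.0, False))
        assert call.variants[0].given_name == "pmi-miR530_v1"


class TestKarlinAltschul:
    def test_plus1_minus1_lambda_is_ln3(self):
        assert solve_karlin_lambda(1.0, -1.0) == pytest.approx(math.log(3.0), abs=1e-9)

    def test_default_scores_lambda(self):
        assert solve_karlin_lambda(1.0, -3.0) == pytest.approx(1.374, abs=1e-3)

    def test_score_doubling_halves_lambda(self):
        lam = solve_karlin_lambda(1.0, -3.0)
        assert solve_karlin_lambda(2.0, -6.0) == pytest.approx(lam / 2, abs=1e-9)

    def test_nonnegative_expected_score_rejected(self):
        with pytest.raises(ValueError):
            solve_karlin_lambda(1.0, -0.1)

    def test_bad_frequencies_rejected(self):
        with pytest.raises(ValueError):
            solve_karlin_lambda(1.0, -3.0, base_freqs=[0.5, 0.5, 0.5, 0.5])

    def test_identity_evalue_formula(self):
        score = similarity_evalue(MIR166, MIR166)
        assert score.raw_score == len(MIR166)
        expected = 0.711 * 21 * 21 * math.exp(-score.lam * 21)
        assert score.evalue == pytest.approx(expected, rel=1e-9)

    def test_evalue_monotone_in_similarity(self):
        near = MIR166[:-1] + ("A" if MIR166[-1] != "A" else "C")
        e_exact = similarity_evalue(MIR166, MIR166).evalue
        e_near = similarity_evalue(near, MIR166).evalue
        e_far = similarity_evalue("ATATATATATATATATATATA", MIR166).evalue
        assert e_exact < e_near < e_far


class TestReassess:
    def _refs(self):
        return [make_reference("ath-miR166a-5p", MIR166)]

    def test_similar_and_abundant_kept(self):
        kept, discarded = reassess_stringent(
            [UniqueTag(MIR166, 10, rpm=2.0)], self._refs()
        )
        assert len(kept) == 1 and not discarded

    def test_similar_but_rare_discarded_for_abundance(self):
        kept, discarded = reassess_stringent(
            [UniqueTag(MIR166, 1, rpm=0.5)], self._refs()
        )
        assert not kept and discarded[0].reason.startswith("low_abundance")

    def test_dissimilar_discarded_even_when_abundant(self):
        kept, discarded = reassess_stringent(
            [UniqueTag("ATATATATATATATATATATA", 500, rpm=50.0)], self._refs()
        )
        assert not kept and discarded[0].reason.startswith("low_similarity")


class TestIdentifyFamilies:
    def test_end_to_end_calls(self, reference_set):
        tags = [
            UniqueTag(MIR166, 12),          # bona fide outright
            UniqueTag(MIR390, 9),           # fails reads criterion, one arm only
            UniqueTag(MIR162, 5),           # rescued by duplex
            UniqueTag(star_of(MIR162), 4),
            UniqueTag("A" * 30, 100),       # outside 20-24 nt selection
        ]
        calls = {c.family: c for c in identify_families(tags, reference_set)}
        assert set(calls) == {"miR166", "miR390", "miR162"}
        assert calls["miR166"].bona_fide and not calls["miR166"].rescue_used
        assert not calls["miR390"].bona_fide
        assert calls["miR162"].bona_fide and calls["miR162"].rescue_used
        assert calls["miR162"].has_duplex

    def test_variant_names_and_evalues_assigned(self, reference_set):
        calls = identify_families([UniqueTag(MIR166, 12)], reference_set)
        v = calls[0].variants[0]
        assert v.given_name == "pmi-miR166_v1"
        assert 0 < v.similarity_evalue < 0.01
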