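import pytest
from hypothesis import given, strategies as st

from nmdscan.errors import (
    HgvsParseError,
    NoTerminatorError,
    NotCodingEditError,
    ReferenceMismatchError,
    UnsupportedProteinHgvsError,
)
from nmdscan.simulate import SimulationConfig, expected_ptc, implant_variant, make_transcript
from nmdscan.variants import (
    CdsVariant,
    TranscriptEdit,
    apply_variant,
    find_ptc,
    format_hgvs,
    normalize_variant,
    parse_cdna_hgvs,
    protein_hgvs_of,
    ptc_codon_from_protein_hgvs,
)

# Printed (cDNA, protein, PTC codon) triples for the 15 coding variants.
CODING_VARIANTS = [
    ("c.380T>A", "p.Leu127*", 127),
    ("c.409A>T", "p.Lys137*", 137),
    ("c.424G>T", "p.Gly142*", 142),
    ("c.441T>A", "p.Cys147*", 147),
    ("c.88_89insA", "p.Val30Aspfs*8", 37),
    ("c.275_276delAA", "p.Lys92Argfs*9", 100),
    ("c.320dupT", "p.Ser108Leufs*15", 122),
    ("c.335dupG", "p.Cys112Trpfs*11", 122),
    ("c.355delGinsAAAAC", "p.Val119Lysfs*5", 123),
    ("c.379_380delTT", "p.Leu127Glyfs*6", 132),
    ("c.380_383dupTGGG", "p.Lys129Glyfs*6", 134),
    ("c.401_402insTT", "p.Glu134Aspfs*2", 135),
    ("c.383_392dupGCAAAGGTGG", "p.Asn132Glnfs*5", 136),
    ("c.435delGinsCGTTTA", "p.Leu145Phefs*3", 147),
    ("c.376delG", "p.Asp126Thrfs*24", 149),
]


class TestParse:
    def test_insertion(self):
        v = parse_cdna_hgvs("c.88_89insA")
        assert (v.kind, v.start, v.end, v.alt_allele) == ("insertion", 88, 89, "A")

    def test_delins(self):
        v = parse_cdna_hgvs("c.435delGinsCGTTTA")
        assert (v.kind, v.start, v.end) == ("delins", 435, 435)
        assert (v.ref_allele, v.alt_allele) == ("G", "CGTTTA")

    def test_whitespace_tolerated(self):
        v = parse_cdna_hgvs("c.380 T > A")
        assert (v.kind, v.start, v.ref_allele, v.alt_allele) == (
            "substitution", 380, "T", "A",
        )

    def test_range_deletion(self):
        v = parse_cdna_hgvs("c.275_276delAA")
        assert (v.kind, v.start, v.end, v.ref_allele) == ("deletion", 275, 276, "AA")

    def test_duplication(self):
        v = parse_cdna_hgvs("c.380_383dupTGGG")
        assert (v.kind, v.start, v.end, v.ref_allele) == ("duplication", 380, 383, "TGGG")
        assert v.length_delta == 4

    def test_trailing_garbage_rejected(self):
        with pytest.raises(HgvsParseError):
            parse_cdna_hgvs("c.88_89insA?")

    def test_intronic_offset_raises_not_coding(self):
        with pytest.raises(NotCodingEditError):
            parse_cdna_hgvs("c.358-304C>G")

    def test_utr_raises_not_coding(self):
        with pytest.raises(NotCodingEditError):
            parse_cdna_hgvs("c.-14G>A")

    def test_not_cdna_prefix(self):
        with pytest.raises(HgvsParseError):
            parse_cdna_hgvs("g.123A>T")

    def test_stated_allele_span_mismatch(self):
        with pytest.raises(HgvsParseError):
            parse_cdna_hgvs("c.275_276delAAA")

    def test_nonadjacent_insertion_flanks(self):
        with pytest.raises(HgvsParseError):
            parse_cdna_hgvs("c.88_91insA")

    @pytest.mark.parametrize("raw", [s for s, _, _ in CODING_VARIANTS])
    def test_roundtrip_normalized_string(self, raw):
        v = parse_cdna_hgvs(raw)
        assert parse_cdna_hgvs(format_hgvs(v)) == v


class TestApply:
    def test_substitution_changes_one_position(self, sod1):
        mutant = apply_variant(sod1, parse_cdna_hgvs("c.380 T > A"))
        assert len(mutant) == sod1.cds_length
        diffs = [i for i, (a, b) in enumerate(zip(sod1.cds_sequence, mutant), 1) if a != b]
        assert diffs == [380]

    def test_deletion_length_arithmetic(self, sod1):
        mutant = apply_variant(sod1, parse_cdna_hgvs("c.275_276delAA"))
        assert len(mutant) == sod1.cds_length - 2

    def test_reference_mismatch_guard(self, sod1):
        bad = CdsVariant("deletion", 275, 276, "GG")
        with pytest.raises(ReferenceMismatchError, match="275"):
            apply_variant(sod1, bad)

    def test_out_of_bounds(self, sod1):
        with pytest.raises(IndexError):
            apply_variant(sod1, CdsVariant("deletion", 464, 470, ""))

    def test_transcript_edit_insertion(self, sod1):
        edit = TranscriptEdit(insert_position=357, inserted_sequence="CAT")
        mutant = apply_variant(sod1, edit)
        assert len(mutant) == sod1.cds_length + 3
        assert mutant[357:360] == "CAT"
        assert mutant[:357] == sod1.cds_sequence[:357]

    def test_length_delta_matches_application(self, sod1):
        for raw, _, _ in CODING_VARIANTS:
            v = parse_cdna_hgvs(raw)
            assert len(apply_variant(sod1, v)) == sod1.cds_length + v.length_delta


class TestFindPtc:
    def test_reference_has_no_ptc(self, sod1):
        assert find_ptc(sod1, sod1.cds_sequence) is None

    def test_nonsense_example(self, sod1):
        ptc = find_ptc(sod1, apply_variant(sod1, parse_cdna_hgvs("c.380T>A")))
        assert ptc.codon_index == 127
        assert (ptc.cds_first_nt, ptc.cds_last_nt) == (379, 381)
        assert ptc.protein_hgvs == "p.Leu127*"

    @pytest.mark.parametrize("raw,protein,codon", CODING_VARIANTS)
    def test_table_variants(self, sod1, raw, protein, codon):
        mutant = apply_variant(sod1, parse_cdna_hgvs(raw))
        ptc = find_ptc(sod1, mutant)
        assert ptc is not None
        assert ptc.codon_index == codon
        assert ptc.protein_hgvs == protein

    def test_frameshift_reference_projection(self, sod1):
        # 2-nt deletion upstream: stop at mutant nt 298-300 maps to 300-302
        mutant = apply_variant(sod1, parse_cdna_hgvs("c.275_276delAA"))
        ptc = find_ptc(sod1, mutant)
        assert (ptc.cds_first_nt, ptc.cds_last_nt) == (300, 302)

    def test_stop_loss_raises(self, single_exon):
        with pytest.raises(NoTerminatorError):
            find_ptc(single_exon, "ATGAAACAA")

    def test_silent_edit_of_natural_stop_is_none(self, single_exon):
        assert find_ptc(single_exon, "ATGAAATGA") is None

    def test_synthetic_ground_truth_agreement(self):
        # engine vs the independent codon-table oracle on random implants
        for seed in range(40):
            cfg = SimulationConfig(seed=seed)
            t = make_transcript(cfg)
            v, truth = implant_variant(t, cfg)
            engine = find_ptc(t, apply_variant(t, v))
            if truth is None:
                assert engine is None
            else:
                assert engine is not None
                assert engine.codon_index == truth.codon_index


class TestProteinHgvs:
    def test_insertion_frameshift_name(self, sod1):
        mutant = apply_variant(sod1, parse_cdna_hgvs("c.88_89insA"))
        ptc = find_ptc(sod1, mutant)
        assert protein_hgvs_of(sod1.cds_sequence, mutant, ptc) == "p.Val30Aspfs*8"

    def test_nonsense_name(self, sod1):
        mutant = apply_variant(sod1, parse_cdna_hgvs("c.441 T > A"))
        ptc = find_ptc(sod1, mutant)
        assert protein_hgvs_of(sod1.cds_sequence, mutant, ptc) == "p.Cys147*"

    def test_identity_sequences_rejected(self, sod1):
        from nmdscan.variants import PtcCall

        fake = PtcCall(codon_index=10, cds_first_nt=28, cds_last_nt=30)
        with pytest.raises(ValueError):
            protein_hgvs_of(sod1.cds_sequence, sod1.cds_sequence, fake)


class TestPtcCodonFromProteinHgvs:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("p.Asp126Thrfs*24", 149),
            ("p.Leu127*", 127),
            ("p.Lys92Argfs*9", 100),
            ("p.Val120Glnfs*8", 127),
            ("p.L127*", 127),
            ("p.V30Dfs*8", 37),
            ("p.Cys147Ter", 147),
        ],
    )
    def test_examples(self, name, expected):
        assert ptc_codon_from_protein_hgvs(name) == expected

    @pytest.mark.parametrize("name", ["p.Leu127=", "p.*155Glnext*10", "p.Met1?", "c.380T>A"])
    def test_unsupported_forms(self, name):
        with pytest.raises(UnsupportedProteinHgvsError):
            ptc_codon_from_protein_hgvs(name)

    def test_consistent_with_computed_names(self, sod1):
        for raw, protein, codon in CODING_VARIANTS:
            assert ptc_codon_from_protein_hgvs(protein) == codon


class TestNormalization:
    def test_insertion_shifts_to_dup(self, three_exon):
        # inserting "GCT" after any GCT codon is a duplication 3'-shifted
        v = CdsVariant("insertion", 6, 7, "", "GCT")
        n = normalize_variant(v, three_exon.cds_sequence)
        assert n.kind == "duplication"

    @given(st.integers(min_value=1, max_value=460), st.sampled_from(["A", "C", "G", "T"]))
    def test_normalized_insertion_preserves_sequence(self, sod1, pos, base):
        v = CdsVariant("insertion", pos, pos + 1, "", base)
        n = normalize_variant(v, sod1.cds_sequence)
        assert apply_variant(sod1, v) == apply_variant(sod1, n)
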