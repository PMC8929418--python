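"""HGVS/SPDI translation: parsing, formatting, round trips, convergence."""

import pytest

import vrskit as vk
from vrskit.translate import (
    ReferenceMismatchError,
    TranslationError,
    UnsupportedHgvsError,
)

from conftest import literal_allele


def interval_of(allele):
    iv = allele.location.interval
    return iv.start.value, iv.end.value


class TestParseSpdi:
    def test_substitution(self, store):
        allele = vk.parse_spdi("local:tiny1:1:1:T", store)
        assert interval_of(allele) == (1, 2)
        assert allele.state.sequence == "T"

    def test_zero_length_deletion_is_insertion(self, store):
        allele = vk.parse_spdi("local:tiny1:3:0:G", store)
        assert interval_of(allele) == (3, 3)
        assert allele.state.sequence == "G"

    def test_sequence_form_deletion_validated(self, store):
        by_length = vk.parse_spdi("local:tiny1:1:1:T", store)
        by_sequence = vk.parse_spdi("local:tiny1:1:C:T", store)
        assert by_length == by_sequence

    def test_sequence_form_mismatch_errors(self, store):
        with pytest.raises(ReferenceMismatchError):
            vk.parse_spdi("local:tiny1:1:G:T", store)

    @pytest.mark.parametrize(
        "expr", ["local:tiny1:1:T", "local:tiny1:x:1:T", "local:tiny1:1:1:T:extra:y:z"]
    )
    def test_malformed_expression_errors(self, store, expr):
        with pytest.raises(TranslationError):
            vk.parse_spdi(expr, store)

    def test_unknown_accession_errors(self, store):
        with pytest.raises(KeyError):
            vk.parse_spdi("local:absent:1:1:T", store)

    def test_out_of_bounds_deletion_errors(self, store):
        with pytest.raises(ValueError):
            vk.parse_spdi("local:tiny1:4:3:T", store)


class TestFormatSpdi:
    def test_substitution(self, store):
        allele = literal_allele("local:tiny1", 1, 2, "T")
        assert vk.format_spdi(allele, store) == "local:tiny1:1:1:T"

    def test_reference_match_survives(self, store):
        allele = literal_allele("local:tiny1", 1, 2, "C")
        assert vk.format_spdi(allele, store) == "local:tiny1:1:1:C"

    def test_normalized_repeat_insertion(self, store):
        raw = literal_allele("local:rep1", 9, 9, "CA")
        normalized = vk.normalize_allele(raw, store)
        assert vk.format_spdi(normalized, store) == "local:rep1:2:7:ACACACACA"

    def test_missing_namespace_alias_errors(self, store):
        allele = literal_allele("local:tiny1", 1, 2, "T")
        with pytest.raises(TranslationError):
            vk.format_spdi(allele, store, namespace="ensembl")

    def test_non_literal_state_errors(self, store):
        allele = vk.Allele(
            location=literal_allele("local:tiny1", 1, 2, "T").location,
            state=vk.RepeatedSequenceExpression(
                seq_expr=vk.LiteralSequenceExpression(sequence="C"),
                count=vk.Number(value=2),
            ),
        )
        with pytest.raises(TranslationError):
            vk.format_spdi(allele, store)


class TestParseHgvs:
    def test_genomic_substitution(self, store):
        allele = vk.parse_hgvs("local:tiny1:g.2C>T", store)
        assert interval_of(allele) == (1, 2)
        assert allele.state.sequence == "T"

    def test_residue_span_deletion(self, store):
        allele = vk.parse_hgvs("local:tiny1:g.3_4del", store)
        assert interval_of(allele) == (2, 4)
        assert allele.state.sequence == ""

    def test_single_residue_deletion_with_assertion(self, store):
        allele = vk.parse_hgvs("local:tiny1:g.3delT", store)
        assert interval_of(allele) == (2, 3)

    def test_reference_assertion_checked(self, store):
        vk.parse_hgvs("local:tiny1:g.2C>G", store)  # C at residue 2: fine
        with pytest.raises(ReferenceMismatchError):
            vk.parse_hgvs("local:tiny1:g.2A>G", store)

    def test_insertion(self, store):
        allele = vk.parse_hgvs("local:rep1:g.9_10insCA", store)
        assert interval_of(allele) == (9, 9)
        assert allele.state.sequence == "CA"

    def test_insertion_requires_adjacent_flanks(self, store):
        with pytest.raises(TranslationError):
            vk.parse_hgvs("local:rep1:g.7_10insCA", store)

    def test_delins(self, store):
        allele = vk.parse_hgvs("local:tiny1:g.2_3delinsGG", store)
        assert interval_of(allele) == (1, 3)
        assert allele.state.sequence == "GG"

    def test_dup_is_a_molecular_insertion(self, store):
        allele = vk.parse_hgvs("local:rep1:g.8_9dup", store)
        assert interval_of(allele) == (9, 9)
        assert allele.state.sequence == "CA"
        assert isinstance(allele, vk.Allele)  # never a CopyNumber

    def test_identity_expression(self, store):
        allele = vk.parse_hgvs("local:tiny1:g.2C=", store)
        assert interval_of(allele) == (1, 2)
        assert allele.state.sequence == "C"

    def test_mito_and_rna_style_coordinates_accepted(self, store):
        for ctype in ("m", "n"):
            allele = vk.parse_hgvs(f"local:tiny1:{ctype}.2C>T", store)
            assert interval_of(allele) == (1, 2)

    def test_uncertain_breakpoints_rejected_specifically(self, store):
        with pytest.raises(UnsupportedHgvsError):
            vk.parse_hgvs("local:tiny1:g.(?_2)_(3_?)del", store)

    @pytest.mark.parametrize(
        "expr",
        ["local:tiny1:c.2C>T", "local:tiny1:p.Phe2del", "local:tiny1:g.2C", "junk"],
    )
    def test_out_of_subset_grammar_rejected(self, store, expr):
        with pytest.raises(TranslationError):
            vk.parse_hgvs(expr, store)

    def test_unknown_accession_errors(self, store):
        with pytest.raises(KeyError):
            vk.parse_hgvs("local:absent:g.2C>T", store)


class TestFormatHgvs:
    def test_substitution(self, store):
        allele = literal_allele("local:tiny1", 1, 2, "T")
        assert vk.format_hgvs(allele, store) == "local:tiny1:g.2C>T"

    def test_reference_allele_identity_syntax(self, store):
        allele = literal_allele("local:tiny1", 1, 2, "C")
        assert vk.format_hgvs(allele, store) == "local:tiny1:g.2C="

    def test_repeat_insertion_emitted_3prime_as_dup(self, store):
        raw = literal_allele("local:rep1", 3, 3, "CA")
        assert vk.format_hgvs(raw, store) == "local:rep1:g.8_9dup"

    def test_non_repeat_insertion_emitted_as_ins(self, store):
        allele = literal_allele("local:tiny1", 3, 3, "GG")
        assert vk.format_hgvs(allele, store) == "local:tiny1:g.3_4insGG"

    def test_deletion_right_shifted(self, store):
        # deleting one T of GATTACA-like TT run reports the 3'-most residue
        allele = literal_allele("local:tiny1", 0, 1, "")
        assert vk.format_hgvs(allele, store) == "local:tiny1:g.2del"

    def test_multibase_deletion(self, store):
        allele = literal_allele("local:rep1", 3, 5, "")
        assert vk.format_hgvs(allele, store) == "local:rep1:g.8_9del"


@pytest.fixture(scope="module")
def corpus():
    cases = vk.make_indel_cases(60, seed=7)
    return cases, vk.case_store(cases)


class TestRoundTrips:
    def test_spdi_roundtrip_is_identity_on_normalized_alleles(self, corpus):
        cases, store = corpus
        for case in cases:
            normalized = vk.normalize_allele(case.allele_in, store)
            expr = vk.format_spdi(normalized, store)
            assert vk.parse_spdi(expr, store) == normalized, case

    def test_spdi_roundtrip_preserves_identifier(self, corpus):
        cases, store = corpus
        for case in cases:
            expr = vk.format_spdi(
                vk.normalize_allele(case.allele_in, store), store
            )
            reparsed = vk.parse_spdi(expr, store)
            assert vk.ga4gh_identify(
                reparsed, store=store
            ) == vk.ga4gh_identify(case.allele_in, store=store), case

    def test_hgvs_roundtrip_preserves_identifier(self, corpus):
        cases, store = corpus
        for case in cases:
            expr = vk.format_hgvs(case.allele_in, store)
            reparsed = vk.parse_hgvs(expr, store)
            assert vk.ga4gh_identify(
                reparsed, store=store
            ) == vk.ga4gh_identify(case.allele_in, store=store), case

    def test_hgvs_and_spdi_converge_to_one_identifier(self, corpus):
        cases, store = corpus
        for case in cases:
            normalized = vk.normalize_allele(case.allele_in, store)
            via_spdi = vk.parse_spdi(vk.format_spdi(normalized, store), store)
            via_hgvs = vk.parse_hgvs(vk.format_hgvs(normalized, store), store)
            assert vk.ga4gh_identify(via_spdi, store=store) == vk.ga4gh_identify(
                via_hgvs, store=store
            ), case

    def test_substitution_coordinate_bijection(self, store):
        # residue <-> inter-residue mapping preserves N for substitutions
        for n in (1, 2, 3, 4, 5):
            ref = store.get_sequence("local:tiny1", n - 1, n)
            alt = "A" if ref != "A" else "G"
            expr = f"local:tiny1:g.{n}{ref}>{alt}"
            assert vk.format_hgvs(vk.parse_hgvs(expr, store), store) == expr
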