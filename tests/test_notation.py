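"""Parsing, canonical formatting and round-trip stability of the shorthand."""

import numpy as np
import pytest

from thyrostage.model import (
    Involvement,
    MCategory,
    NCategory,
    ResidualCode,
    TCategory,
    TNMCategory,
)
from thyrostage.notation import (
    ParseError,
    ParsedClassification,
    canonicalize,
    format_classification,
    parse_classification,
)

def inv(cat, sub, degree=None, rings=None):
    return Involvement(cat, sub, degree, rings)


class TestParse:
    def test_full_classification_with_tnm_and_suffix(self):
        parsed = parse_classification(
            "pT4a N1b Mx PE-E^0 Vas-V_IJ^1 LT-T_2^0 N-RLN^1"
        )
        assert parsed.tnm == TNMCategory(TCategory.T4A, NCategory.N1B, MCategory.MX)
        assert not parsed.rec_prefix
        assert parsed.residual is ResidualCode.R0
        assert parsed.involvements == frozenset(
            {
                inv("PE", "E", 0),
                inv("Vas", "V_IJ", 1),
                inv("LT", "T", 0, 2),
                inv("N", "RLN", 1),
            }
        )

    def test_rec_prefix_suppresses_tnm(self):
        parsed = parse_classification("Rec N-RLN^0 M-SCM")
        assert parsed.rec_prefix and parsed.tnm is None
        assert parsed.involvements == frozenset({inv("N", "RLN", 0), inv("M", "SCM")})

    def test_residual_code_and_slash_compressed_veins(self):
        parsed = parse_classification("R2 pT2 N1b Mx VAS-V_IJ/INN^1")
        assert parsed.residual is ResidualCode.R2
        assert parsed.tnm == TNMCategory(TCategory.T2, NCategory.N1B, MCategory.MX)
        assert parsed.involvements == frozenset(
            {inv("Vas", "V_IJ", 1), inv("Vas", "V_INN", 1)}
        )

    def test_chained_group_inherits_category(self):
        parsed = parse_classification("pT4a N0 Mx B-St^1 Clav^1")
        assert parsed.involvements == frozenset(
            {inv("B", "St", 1), inv("B", "Clav", 1)}
        )

    def test_concatenated_groups_within_token(self):
        parsed = parse_classification("pT4a N1a M1 N-RLN^1 LT-T_2^0Cr^0 PE-E^0Ph^0")
        assert parsed.involvements == frozenset(
            {
                inv("N", "RLN", 1),
                inv("LT", "T", 0, 2),
                inv("LT", "Cr", 0),
                inv("PE", "E", 0),
                inv("PE", "Ph", 0),
            }
        )

    def test_suffixes_accepted_in_either_order(self):
        assert parse_classification("Rec-LT-T^0_2") == parse_classification(
            "Rec LT-T_2^0"
        )

    def test_missing_n_and_m_default_to_x(self):
        parsed = parse_classification("pT3b N1a M-SM")
        assert parsed.tnm == TNMCategory(TCategory.T3B, NCategory.N1A, MCategory.MX)
        assert parsed.involvements == frozenset({inv("M", "SM")})

    def test_glosses_are_ignored(self):
        a = parse_classification("pT4a N1b Mx N-RLN^1 (sacrifice RLN)")
        b = parse_classification("pT4a N1b Mx N-RLN^1")
        assert a == b

    @pytest.mark.parametrize(
        "text, code",
        [
            ("M-SM^1", "muscle_degree_forbidden"),
            ("pT4a N0 Mx PE-E_2^0", "ring_count_misplaced"),
            ("pT4a N0 Mx PE-E", "degree_missing"),
            ("pT4a N0 Mx PE-E^0 PE-E^1", "duplicate_subsite"),
            ("pT4a N0 Mx PE-Z^0", "unknown_subsite"),
            ("Rec pT4a N0 Mx", "rec_with_tnm"),
            ("XX-Y^0", "unknown_token"),
            ("", "empty"),
            ("pT4a N0 Mx PE-E^7", "degree_invalid"),
        ],
    )
    def test_errors_carry_codes_and_positions(self, text, code):
        with pytest.raises(ParseError) as err:
            parse_classification(text)
        assert err.value.code == code
        assert err.value.position >= 0

    def test_slash_and_expanded_spellings_are_equivalent(self):
        assert (
            parse_classification("pT3b N1b Mx M-SM/CT").involvements
            == parse_classification("pT3b N1b Mx M-SM M-CT").involvements
        )


class TestFormat:
    def test_canonical_string_round_trips_identically(self):
        text = "pT4a N1b Mx N-RLN^1 M-SCM"
        assert canonicalize(text) == text

    def test_slash_compression_expands_to_full_tokens(self):
        # canonical expansion of a compressed muscle pair
        assert canonicalize("pT3b N1b Mx M-SM/CT") == "pT3b N1b Mx M-SM M-CT"

    def test_tnm_only_classification(self):
        parsed = ParsedClassification(
            tnm=TNMCategory(TCategory.T2, NCategory.N0, MCategory.M0)
        )
        assert format_classification(parsed) == "pT2 N0 M0"

    def test_category_and_subsite_order_is_fixed(self):
        text = "pT4a N1a M1 PE-E^0 PE-Ph^0 N-RLN^1 LT-T_2^0 LT-Cr^0"
        assert (
            canonicalize(text)
            == "pT4a N1a M1 LT-Cr^0 LT-T_2^0 N-RLN^1 PE-Ph^0 PE-E^0"
        )

    def test_rec_with_tnm_is_rejected(self):
        parsed = ParsedClassification(
            rec_prefix=True, tnm=TNMCategory(TCategory.T2)
        )
        with pytest.raises(ValueError):
            format_classification(parsed)


class TestRoundTripProperty:
    def test_parse_format_round_trip_random(self, random_classification):
        """format(parse(s)) == s and parse(format(p)) == p over random values."""
        rng = np.random.default_rng(20240917)
        for _ in range(2000):
            parsed = random_classification(rng)
            text = format_classification(parsed)
            assert parse_classification(text) == parsed
            assert format_classification(parse_classification(text)) == text


class TestPaperGolden:
    def test_every_table_classification_parses(self, paper_cohort_raw):
        """All 35 recommended classification cells parse without error."""
        entries = paper_cohort_raw["primary"] + paper_cohort_raw["recurrent"]
        assert len(entries) == 35
        for entry in entries:
            parsed = parse_classification(entry["recommended"])
            assert parsed.involvements or parsed.tnm is not None

    def test_every_reported_stage_parses(self, paper_cohort_raw):
        for entry in paper_cohort_raw["primary"]:
            assert parse_classification(entry["reported_stage"]).tnm is not None
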