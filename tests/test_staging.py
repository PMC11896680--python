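"""T-floor rules, stage derivation, risk-of-recurrence and comparison."""

import numpy as np
import pytest

from thyrostage.model import (
    ChecklistRecord,
    DiseaseStatus,
    Involvement,
    MCategory,
    MinimumDataSet,
    NCategory,
    Presence,
    ResidualCode,
    TCategory,
)
from thyrostage.notation import parse_classification
from thyrostage.staging import (
    DEFAULT_RULES,
    RuleTable,
    classify_ror,
    compare_stages,
    derive_stage,
    t_floor,
)


def inv(cat, sub, degree=None, rings=None):
    return Involvement(cat, sub, degree, rings)


def record(*involvements, status=DiseaseStatus.PRIMARY, t=None, n=None, m=None,
           residual=ResidualCode.R0, mets=Presence.UNKNOWN, case_id="x"):
    return ChecklistRecord(
        case_id=case_id,
        mds=MinimumDataSet(disease_status=status, residual=residual, distant_mets=mets),
        involvements=frozenset(involvements),
        pathology_t=t,
        pathology_n=n,
        pathology_m=m,
    )


class TestTFloor:
    @pytest.mark.parametrize(
        "involvements, expected",
        [
            ({inv("M", "SM")}, TCategory.T3B),
            ({inv("M", "SM"), inv("M", "CT")}, TCategory.T3B),
            ({inv("N", "RLN", 0)}, TCategory.T4A),
            ({inv("N", "RLN", 1)}, TCategory.T4A),
            ({inv("PE", "E", 0)}, TCategory.T4A),
            ({inv("LT", "T", 0, 2)}, TCategory.T4A),
            ({inv("B", "Clav", 1)}, TCategory.T4A),
            ({inv("Vas", "A_CC", 1)}, TCategory.T4B),
            ({inv("Vas", "V_IJ", 1), inv("Vas", "V_INN", 1)}, None),
            ({inv("M", "SM"), inv("Vas", "A_INN", 1)}, TCategory.T4B),
            (set(), None),
        ],
    )
    def test_floor_examples(self, involvements, expected):
        floor, _, _ = t_floor(involvements)
        assert floor is expected

    def test_subadventitial_artery_warns_without_floor(self):
        floor, _, warnings = t_floor({inv("Vas", "A_CC", 0)})
        assert floor is None
        assert "arterial_involvement_review" in warnings

    def test_sln_and_vagus_warn_without_floor(self):
        floor, _, warnings = t_floor({inv("N", "Vag", 1)})
        assert floor is None
        assert "nerve_outside_rule_table" in warnings

    def test_trace_references_firing_involvements(self):
        involvements = {inv("M", "SM"), inv("N", "RLN", 1)}
        _, trace, _ = t_floor(involvements)
        assert {t[1] for t in trace} <= involvements
        assert {t[0] for t in trace} == {"R1", "R2"}

    def test_permutation_invariance(self):
        involvements = [inv("M", "SM"), inv("PE", "E", 0), inv("N", "RLN", 1)]
        forward = t_floor(involvements)
        backward = t_floor(list(reversed(involvements)))
        assert forward == backward

    def test_monotonic_under_involvement_addition(self):
        """Adding an involvement never lowers the floor (random walks)."""
        from thyrostage.model import SUBSITES, _T_RANK

        rng = np.random.default_rng(5)
        pool = [
            inv(
                s.category,
                s.code,
                (int(rng.integers(0, 2)) if s.takes_degree else None),
                (2 if s.takes_ring_count else None),
            )
            for s in SUBSITES
        ]
        for _ in range(200):
            order = rng.permutation(len(pool))
            acc = []
            last_rank = -1
            for idx in order:
                acc.append(pool[int(idx)])
                floor, _, _ = t_floor(acc)
                rank = -1 if floor is None else _T_RANK[floor]
                assert rank >= last_rank
                last_rank = rank

    def test_rule_table_yaml_round_trip(self):
        text = DEFAULT_RULES.to_yaml()
        assert RuleTable.from_yaml(text) == DEFAULT_RULES


class TestDeriveStage:
    def test_floor_raises_size_based_t(self):
        staged = derive_stage(
            record(inv("M", "SM"), t=TCategory.T2, n=NCategory.N1A, m=MCategory.MX)
        )
        assert staged.classification == "pT3b N1a Mx M-SM"

    def test_pathology_t_wins_when_above_floor(self):
        staged = derive_stage(record(inv("M", "SM"), t=TCategory.T4A, n=NCategory.N0))
        assert staged.tnm.t is TCategory.T4A

    def test_recurrent_gets_rec_prefix_and_no_tnm(self):
        staged = derive_stage(
            record(inv("N", "RLN", 1), status=DiseaseStatus.RECURRENT)
        )
        assert staged.tnm is None
        assert staged.classification == "Rec N-RLN^1"
        assert staged.ror == "not_applicable"

    def test_persistent_behaves_like_recurrent(self):
        staged = derive_stage(
            record(inv("N", "RLN", 1), status=DiseaseStatus.PERSISTENT)
        )
        assert staged.tnm is None and staged.classification.startswith("Rec ")

    def test_recurrent_with_pathology_t_warns(self):
        staged = derive_stage(
            record(inv("N", "RLN", 1), status=DiseaseStatus.RECURRENT, t=TCategory.T2)
        )
        assert "ajcc_not_applicable_for_recurrent" in staged.warnings

    def test_distant_mets_force_m1(self):
        staged = derive_stage(
            record(
                inv("N", "RLN", 1),
                t=TCategory.T2,
                n=NCategory.N1A,
                m=MCategory.MX,
                mets=Presence.PRESENT,
            )
        )
        assert staged.tnm.m is MCategory.M1

    def test_no_t_information_yields_tx_with_warning(self):
        staged = derive_stage(record(inv("Vas", "V_IJ", 1), n=NCategory.N0))
        assert staged.tnm.t is TCategory.TX
        assert "t_category_unassessable" in staged.warnings

    def test_suffix_is_canonically_ordered(self):
        staged = derive_stage(
            record(
                inv("PE", "Ph", 0),
                inv("LT", "Cr", 0),
                inv("N", "RLN", 1),
                inv("PE", "E", 0),
                inv("LT", "T", 0, 2),
                t=TCategory.T2,
                n=NCategory.N1A,
                mets=Presence.PRESENT,
            )
        )
        assert (
            staged.classification
            == "pT4a N1a M1 LT-Cr^0 LT-T_2^0 N-RLN^1 PE-Ph^0 PE-E^0"
        )

    def test_invalid_record_is_rejected(self):
        with pytest.raises(ValueError):
            derive_stage(record(inv("M", "SM", 1)))


class TestClassifyRor:
    def test_gross_invasion_is_high(self):
        tier, fired, _ = classify_ror(record(inv("N", "RLN", 1), inv("M", "SCM")))
        assert tier == "high" and "ror_high_gross_invasion" in fired

    def test_residual_disease_is_high(self):
        tier, fired, _ = classify_ror(record(residual=ResidualCode.R2))
        assert tier == "high" and "ror_high_residual_disease" in fired

    def test_clean_case_degrades_to_low_with_warning(self):
        tier, fired, warnings = classify_ror(record(mets=Presence.ABSENT))
        assert tier == "low" and not fired
        assert "ror_incomplete_inputs" in warnings

    def test_recurrent_is_not_applicable(self):
        tier, _, _ = classify_ror(record(status=DiseaseStatus.RECURRENT))
        assert tier == "not_applicable"


class TestCompareStages:
    def test_understaged_t_and_missing_involvement(self):
        staged = derive_stage(
            record(inv("N", "RLN", 1), t=TCategory.T1B, n=NCategory.N1A)
        )
        cmp = compare_stages(parse_classification("pT1b N1a Mx"), staged)
        assert not cmp.accurate
        assert "t_understaged" in cmp.codes
        assert "missing_involvement:N-RLN^1" in cmp.codes

    def test_missing_residual_is_discrepant_despite_higher_reported_t(self):
        staged = derive_stage(
            record(
                inv("Vas", "V_IJ", 1),
                inv("Vas", "V_INN", 1),
                t=TCategory.T2,
                n=NCategory.N1B,
                residual=ResidualCode.R2,
            )
        )
        cmp = compare_stages(parse_classification("pT4a N1b Mx"), staged)
        assert not cmp.accurate
        assert "residual_unreported:R2" in cmp.codes
        assert any(c.startswith("missing_involvement:Vas-") for c in cmp.codes)
        assert "t_understaged" not in cmp.codes

    def test_degree_mismatch_is_discrepant(self):
        staged = derive_stage(record(inv("N", "RLN", 1), t=TCategory.T2))
        cmp = compare_stages(parse_classification("pT4a Nx Mx N-RLN^0"), staged)
        assert not cmp.accurate
        assert "degree_mismatch:N-RLN^1" in cmp.codes

    def test_identical_classifications_are_accurate(self):
        staged = derive_stage(record(inv("M", "SM"), t=TCategory.T2, n=NCategory.N1A))
        cmp = compare_stages(parse_classification(staged.classification), staged)
        assert cmp.accurate and cmp.codes == ()
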